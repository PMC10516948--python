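"""Flat-file readers and writers for every pipeline artifact.

Formats are deliberately plain: FASTA/FASTQ through Biopython, everything
tabular as TSV through pandas, truth and summaries as JSON.  Column
layouts follow common pangenome-summary conventions (gene_id / genome_id
/ cluster_id) so externally computed pangenomes can be dropped in.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .expression import CountMatrix
from .pangenome import GeneCall
from .recruitment import ReadLibrary
from .synthetic import Truth

GENE_CALL_COLUMNS = [
    "gene_id", "genome_id", "contig", "start", "end", "strand", "aa_sequence",
]


def write_fasta(sequences: dict[str, str], path: str | Path) -> Path:
    path = Path(path)
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, path, "fasta")
    return path


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> Path:
    path = Path(path)
    records = []
    for rid, seq in reads:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    SeqIO.write(records, path, "fastq")
    return path


def read_reads(path: str | Path, library_id: str, sample_id: str | None = None) -> ReadLibrary:
    """Load a FASTA or FASTQ read library (format chosen by extension)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    reads = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), fmt)]
    return ReadLibrary(library_id=library_id, sample_id=sample_id or library_id, reads=reads)


def write_gene_calls(gene_calls: Iterable[GeneCall], path: str | Path) -> Path:
    rows = []
    for g in gene_calls:
        row = {c: getattr(g, c) for c in GENE_CALL_COLUMNS}
        for src, acc in g.annotations.items():
            row[f"annot_{src}"] = acc
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_gene_calls(path: str | Path) -> list[GeneCall]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "genome_id": str, "contig": str})
    missing = set(GENE_CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene-call table missing columns: {sorted(missing)}")
    annot_cols = [c for c in df.columns if c.startswith("annot_")]
    calls = []
    for row in df.itertuples(index=False):
        annotations = {
            c[len("annot_"):]: getattr(row, c)
            for c in annot_cols
            if isinstance(getattr(row, c), str)
        }
        aa = row.aa_sequence if isinstance(row.aa_sequence, str) else None
        calls.append(
            GeneCall(
                gene_id=row.gene_id,
                genome_id=row.genome_id,
                contig=row.contig,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                aa_sequence=aa,
                annotations=annotations,
            )
        )
    return calls


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "source", "accession"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return df


def attach_annotations(gene_calls: Iterable[GeneCall], annotations: pd.DataFrame) -> None:
    by_gene: dict[str, dict[str, str]] = {}
    for row in annotations.itertuples(index=False):
        by_gene.setdefault(row.gene_id, {})[row.source] = row.accession
    for g in gene_calls:
        g.annotations.update(by_gene.get(g.gene_id, {}))


def write_counts(counts: CountMatrix, path: str | Path) -> Path:
    """Counts TSV: gene_id, length, then one column per sample."""
    out = counts.counts.copy()
    out.insert(0, "length", counts.gene_lengths)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
    return Path(path)


def read_counts(path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if "length" not in df.columns:
        raise ValueError("counts table needs a 'length' column")
    lengths = df.pop("length")
    return CountMatrix(counts=df, gene_lengths=lengths)


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> Path:
    samples.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str, "replicate": str})


def write_truth(truth: Truth, path: str | Path) -> Path:
    Path(path).write_text(json.dumps(dataclasses.asdict(truth), indent=2, sort_keys=True) + "\n")
    return Path(path)


def read_truth(path: str | Path) -> Truth:
    return Truth(**json.loads(Path(path).read_text()))


def write_manifest(path: str | Path, command: str, params: dict) -> Path:
    """Machine-readable run manifest: tool version, command, every parameter."""
    from . import __version__

    payload = {"tool": "cameta", "version": __version__, "command": command, "params": params}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
    return Path(path)
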