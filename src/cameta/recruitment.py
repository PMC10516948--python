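"""Competitive read recruitment and reference-genome selection.

Metatranscriptomic libraries are screened against every candidate genome
("all-against-all" recruitment); the genome recruiting the largest mean
mapped-read count across libraries — ties broken by mean mapping rate —
is chosen as the reference for downstream differential expression.

The bundled pseudo-mapper is an exact-k-mer screen for desk-scale data;
summaries derived from real aligner BAM files enter through
:func:`import_recruitment`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

_COMPL = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPL)[::-1]


@dataclass
class ReadLibrary:
    library_id: str
    sample_id: str
    reads: list[tuple[str, str]] = field(default_factory=list)  # (read_id, sequence)

    def __post_init__(self) -> None:
        if not self.reads:
            return
        ids = [r[0] for r in self.reads]
        if len(ids) != len(set(ids)):
            raise ValueError(f"library {self.library_id}: duplicate read ids")


@dataclass
class MappingResult:
    """Outcome of mapping one library against one genome."""

    library_id: str
    genome_id: str
    mapped_read_ids: list[str]
    per_gene_counts: dict[str, int]
    total_reads: int

    @property
    def mapped_reads(self) -> int:
        return len(self.mapped_read_ids)

    @property
    def mapping_rate(self) -> float:
        return self.mapped_reads / self.total_reads if self.total_reads else 0.0


def pseudo_map(
    library: ReadLibrary,
    genome_id: str,
    genome_sequence: str,
    gene_intervals: dict[str, tuple[int, int]] | None = None,
    kmer_size: int = 21,
    min_kmer_hits: int = 5,
) -> MappingResult:
    """Map reads to a genome by exact k-mer matching on either strand.

    A read is mapped iff at least ``min_kmer_hits`` of its k-mers occur in
    the genome (forward or reverse complement).  Each mapped read is
    assigned to the gene whose interval (0-based, half-open) contains the
    majority of matched k-mer start positions; reads with a tied or absent
    majority gene stay mapped but are excluded from per-gene counts.
    """
    if not genome_sequence:
        raise ValueError("empty genome sequence")
    if not library.reads:
        raise ValueError(f"library {library.library_id} has no reads")
    genome_sequence = genome_sequence.upper()

    index: dict[str, list[int]] = {}
    for i in range(len(genome_sequence) - kmer_size + 1):
        index.setdefault(genome_sequence[i : i + kmer_size], []).append(i)

    intervals = sorted(
        ((s, e, g) for g, (s, e) in (gene_intervals or {}).items())
    )

    def gene_at(pos: int) -> str | None:
        for s, e, g in intervals:
            if s <= pos < e:
                return g
            if s > pos:
                break
        return None

    mapped_ids: list[str] = []
    per_gene: Counter[str] = Counter()
    for read_id, seq in library.reads:
        seq = seq.upper()
        if len(seq) < kmer_size:
            raise ValueError(
                f"read {read_id} shorter than kmer_size={kmer_size}"
            )
        hit_positions: list[int] = []
        n_hits = 0
        for i in range(len(seq) - kmer_size + 1):
            km = seq[i : i + kmer_size]
            pos = index.get(km)
            if pos is None:
                pos = index.get(revcomp(km))
            if pos is not None:
                n_hits += 1
                hit_positions.extend(pos)
        if n_hits < min_kmer_hits:
            continue
        mapped_ids.append(read_id)
        if not intervals:
            continue
        votes: Counter[str] = Counter()
        for p in hit_positions:
            g = gene_at(p)
            if g is not None:
                votes[g] += 1
        if not votes:
            continue
        ranked = votes.most_common(2)
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            continue  # ambiguous within-genome assignment -> discard
        per_gene[ranked[0][0]] += 1

    return MappingResult(
        library_id=library.library_id,
        genome_id=genome_id,
        mapped_read_ids=mapped_ids,
        per_gene_counts=dict(per_gene),
        total_reads=len(library.reads),
    )


def summarize_recruitment(results: list[MappingResult]) -> pd.DataFrame:
    """Collect mapping results into a recruitment summary table."""
    rows = [
        {
            "library_id": r.library_id,
            "genome_id": r.genome_id,
            "mapped_reads": r.mapped_reads,
            "total_reads": r.total_reads,
        }
        for r in results
    ]
    return import_recruitment(pd.DataFrame(rows))


def import_recruitment(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a library_id/genome_id/mapped_reads/total_reads table.

    The mapping rate is recomputed, never trusted from the input.
    """
    required = {"library_id", "genome_id", "mapped_reads", "total_reads"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"recruitment table missing columns: {sorted(missing)}")
    df = table.loc[:, ["library_id", "genome_id", "mapped_reads", "total_reads"]].copy()
    if df.empty:
        raise ValueError("recruitment table is empty")
    if (df["mapped_reads"] < 0).any() or (df["total_reads"] <= 0).any():
        raise ValueError("mapped_reads must be >= 0 and total_reads > 0")
    bad = df[df["mapped_reads"] > df["total_reads"]]
    if not bad.empty:
        raise ValueError(
            "mapped_reads exceeds total_reads for: "
            + ", ".join(f"{r.library_id}/{r.genome_id}" for r in bad.itertuples())
        )
    tot = df.groupby("library_id")["total_reads"].nunique()
    if (tot > 1).any():
        raise ValueError(
            f"total_reads not constant within libraries: {list(tot[tot > 1].index)}"
        )
    df["mapping_rate"] = df["mapped_reads"] / df["total_reads"]
    return df.reset_index(drop=True)


def select_reference(summary: pd.DataFrame) -> tuple[str, pd.DataFrame]:
    """Pick the best reference genome from a recruitment summary.

    Ranking key: mean mapped reads across libraries (descending), then
    mean mapping rate, then lexicographic genome_id.  Returns the winning
    genome_id and the full ranking table.
    """
    summary = import_recruitment(summary)
    ranking = (
        summary.groupby("genome_id")
        .agg(mean_mapped_reads=("mapped_reads", "mean"), mean_mapping_rate=("mapping_rate", "mean"))
        .reset_index()
        .sort_values(
            by=["mean_mapped_reads", "mean_mapping_rate", "genome_id"],
            ascending=[False, False, True],
            kind="mergesort",
        )
        .reset_index(drop=True)
    )
    ranking["rank"] = range(1, len(ranking) + 1)
    return ranking.loc[0, "genome_id"], ranking
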