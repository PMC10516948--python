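"""Synthetic pangenomes, count matrices and read libraries with known truth.

The generator emulates the mesocosm study design the pipeline targets:
five treatments (biotic control BC, dispersant DISP, oil WAF, chemically
dispersed oil CEWAF, CEWAF plus nutrients CEWAFN), triplicate microcosms
sampled at 0/7/17/28/42 days (CEWAFN at 0/7/42 only), negative-binomial
counts with treatment-specific planted fold changes, and a pangenome with
a core shared by every genome plus Bernoulli-occupied accessory clusters.
DE genes are placed so that a configurable fraction (rho_core) of the
DE-containing clusters is core — the quantity the pipeline's headline
statistic estimates.

Every artifact draws from its own RNG stream spawned from the master seed
plus a fixed tag, so generating one output never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from .expression import CountMatrix, TREATMENTS, BASELINE
from .pangenome import GeneCall, Genome

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
# one codon per amino acid keeps reverse translation stop-free and simple
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}
_STREAM_TAGS = {"pangenome": 11, "counts": 23, "reads": 37}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the target experiment."""

    n_genomes: int = 10
    n_core_clusters: int = 300
    n_accessory_clusters: int = 500
    accessory_occurrence_prob: float = 0.5
    gene_length_range: tuple[int, int] = (300, 900)  # nt, multiples of 3 enforced
    aa_mutation_rate: float = 0.005
    treatments: tuple[str, ...] = TREATMENTS
    replicates: int = 3
    timepoints: tuple[float, ...] = (0, 7, 17, 28, 42)
    cewafn_timepoints: tuple[float, ...] = (0, 7, 42)
    nb_dispersion: float = 0.1
    baseline_mean: float = 100.0
    baseline_log_sd: float = 1.0
    n_de_genes: int = 250
    de_log2fc: float = 2.0
    rho_core: float = 0.4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genomes, self.n_core_clusters + self.n_accessory_clusters) <= 0:
            raise ValueError("genome and cluster counts must be positive")
        if not (0.0 < self.accessory_occurrence_prob < 1.0):
            raise ValueError("accessory_occurrence_prob must be in (0, 1)")
        if not (0.0 <= self.rho_core <= 1.0):
            raise ValueError("rho_core must be in [0, 1]")
        if self.gene_length_range[0] < 30 or self.gene_length_range[1] < self.gene_length_range[0]:
            raise ValueError("invalid gene_length_range")
        if self.nb_dispersion < 0 or self.baseline_mean <= 0:
            raise ValueError("nb_dispersion must be >= 0 and baseline_mean > 0")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence((self.rng_seed, _STREAM_TAGS[stream]))
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Truth:
    """Ground truth emitted alongside the synthetic data."""

    config: dict
    gene_to_cluster: dict[str, str] = field(default_factory=dict)
    cluster_core: dict[str, bool] = field(default_factory=dict)
    # gene_id -> {"treatment": ..., "log2fc": signed float}
    de_genes: dict[str, dict] = field(default_factory=dict)
    gene_means: dict[str, float] = field(default_factory=dict)
    read_counts: dict[str, dict[str, int]] = field(default_factory=dict)  # library -> gene -> n


def _reverse_translate(aa: str) -> str:
    return "".join(_CODON[a] for a in aa)


def _mutate_aa(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        out[i] = AA_ALPHABET[rng.integers(len(AA_ALPHABET))]
    return "".join(out)


def generate_pangenome(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneCall], Truth]:
    """Build genome sequences, gene calls and truth for a synthetic pangenome.

    Core clusters occur in every genome; each accessory cluster occurs in a
    Bernoulli(accessory_occurrence_prob) subset (at least one genome).
    Member genes are lightly mutated copies of a per-cluster seed protein,
    so k-mer clustering can recover the planted partition.  Genomes are the
    concatenation of their genes (random order, random strand) separated by
    random intergenic spacers.

    Returns (genome_id -> nucleotide sequence, gene calls, truth).
    """
    rng = config.rng("pangenome")
    genome_ids = [f"G{i + 1:03d}" for i in range(config.n_genomes)]
    n_clusters = config.n_core_clusters + config.n_accessory_clusters
    width = max(4, len(str(n_clusters)))

    truth = Truth(config=config.to_dict())
    # genome_id -> list of (gene_id, aa, cluster_id)
    per_genome: dict[str, list[tuple[str, str, str]]] = {g: [] for g in genome_ids}
    gene_counter = 0
    for ci in range(n_clusters):
        cid = f"TC_{ci + 1:0{width}d}"
        is_core_design = ci < config.n_core_clusters
        lo, hi = config.gene_length_range
        aa_len = int(rng.integers(lo // 3, hi // 3 + 1))
        seed = "".join(AA_ALPHABET[i] for i in rng.integers(len(AA_ALPHABET), size=aa_len))
        if is_core_design:
            members = list(genome_ids)
        else:
            mask = rng.random(config.n_genomes) < config.accessory_occurrence_prob
            if not mask.any():
                mask[rng.integers(config.n_genomes)] = True
            members = [g for g, m in zip(genome_ids, mask) if m]
        truth.cluster_core[cid] = len(members) == config.n_genomes
        for gid in members:
            gene_counter += 1
            gene_id = f"gene_{gene_counter:06d}"
            aa = _mutate_aa(seed, config.aa_mutation_rate, rng)
            per_genome[gid].append((gene_id, aa, cid))
            truth.gene_to_cluster[gene_id] = cid

    genomes: dict[str, str] = {}
    gene_calls: list[GeneCall] = []
    for gid in genome_ids:
        genes = per_genome[gid]
        order = rng.permutation(len(genes))
        parts: list[str] = []
        pos = 0
        for oi in order:
            gene_id, aa, cid = genes[oi]
            spacer_len = int(rng.integers(50, 151))
            spacer = "".join("ACGT"[b] for b in rng.integers(4, size=spacer_len))
            parts.append(spacer)
            pos += spacer_len
            nt = _reverse_translate(aa)
            strand = "+" if rng.random() < 0.5 else "-"
            parts.append(nt if strand == "+" else _revcomp(nt))
            gene_calls.append(
                GeneCall(
                    gene_id=gene_id,
                    genome_id=gid,
                    contig=gid,
                    start=pos,
                    end=pos + len(nt),
                    strand=strand,
                    aa_sequence=aa,
                )
            )
            pos += len(nt)
        parts.append("".join("ACGT"[b] for b in rng.integers(4, size=60)))
        genomes[gid] = "".join(parts)
    gene_calls.sort(key=lambda g: g.gene_id)
    return genomes, gene_calls, truth


_NT_COMPL = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_NT_COMPL)[::-1]


def design_samples(config: SimulationConfig) -> pd.DataFrame:
    """Sample sheet for the default design: treatments x timepoints x replicates."""
    rows = []
    for trt in config.treatments:
        tps = config.cewafn_timepoints if trt == "CEWAFN" else config.timepoints
        for t in tps:
            for r in range(1, config.replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{trt}_t{t:g}d_r{r}",
                        "treatment": trt,
                        "time_days": float(t),
                        "replicate": f"r{r}",
                    }
                )
    return pd.DataFrame(rows)


def _pick_de_genes(
    config: SimulationConfig,
    truth: Truth,
    ref_calls: list[GeneCall],
    rng: np.random.Generator,
) -> dict[str, dict]:
    """Choose DE genes so that rho_core of DE-containing clusters are core.

    One DE gene per chosen cluster (clusters restricted to those with a
    reference-genome member), split round(rho_core * n) core clusters and
    the rest accessory.
    """
    by_cluster: dict[str, str] = {}
    for g in ref_calls:
        by_cluster.setdefault(truth.gene_to_cluster[g.gene_id], g.gene_id)
    core_pool = sorted(c for c in by_cluster if truth.cluster_core[c])
    acc_pool = sorted(c for c in by_cluster if not truth.cluster_core[c])
    n_de = config.n_de_genes
    if n_de == 0:
        return {}
    n_core = int(round(config.rho_core * n_de))
    n_acc = n_de - n_core
    if n_core > len(core_pool) or n_acc > len(acc_pool):
        raise ValueError(
            f"more DE genes requested than genes available "
            f"(need {n_core} core / {n_acc} accessory clusters with reference "
            f"members; have {len(core_pool)} / {len(acc_pool)})"
        )
    chosen = list(rng.choice(core_pool, size=n_core, replace=False)) + list(
        rng.choice(acc_pool, size=n_acc, replace=False)
    )
    non_bc = [t for t in config.treatments if t != BASELINE]
    de: dict[str, dict] = {}
    for cid in chosen:
        gene = by_cluster[cid]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        de[gene] = {
            "treatment": str(non_bc[rng.integers(len(non_bc))]),
            "log2fc": sign * config.de_log2fc,
        }
    return de


def generate_counts(
    config: SimulationConfig,
    truth: Truth,
    gene_calls: list[GeneCall],
    reference_genome_id: str | None = None,
) -> tuple[CountMatrix, pd.DataFrame, Truth]:
    """Treatment-structured NB counts for the reference genome's genes.

    count_gj ~ NB(mean = m_g * 2^(lfc_g * [sample j in gene g's DE
    treatment]) * L_j, dispersion alpha), with per-gene baseline means m_g
    log-normal around ``baseline_mean`` and library size multipliers L_j
    log-uniform in [0.5, 2].  alpha = 0 degenerates to Poisson.  Extends
    and returns the truth in place.
    """
    rng = config.rng("counts")
    if reference_genome_id is None:
        reference_genome_id = sorted({g.genome_id for g in gene_calls})[0]
    ref_calls = sorted(
        (g for g in gene_calls if g.genome_id == reference_genome_id),
        key=lambda g: g.gene_id,
    )
    if not ref_calls:
        raise ValueError(f"no gene calls for reference genome {reference_genome_id}")
    samples = design_samples(config)
    truth.de_genes = _pick_de_genes(config, truth, ref_calls, rng)

    gene_ids = [g.gene_id for g in ref_calls]
    lengths = pd.Series({g.gene_id: g.nt_length for g in ref_calls}, name="length")
    m = config.baseline_mean * np.exp(
        rng.normal(0.0, config.baseline_log_sd, size=len(gene_ids))
        - config.baseline_log_sd**2 / 2
    )
    truth.gene_means = dict(zip(gene_ids, m.astype(float)))
    lib = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=len(samples)))

    lfc = np.zeros((len(gene_ids), len(samples)))
    trt_of_sample = samples["treatment"].to_numpy()
    for i, g in enumerate(gene_ids):
        info = truth.de_genes.get(g)
        if info is not None:
            lfc[i, trt_of_sample == info["treatment"]] = info["log2fc"]
    mean = m[:, None] * 2.0**lfc * lib[None, :]
    if config.nb_dispersion > 0:
        r = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mean))
    else:
        counts = rng.poisson(mean)
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=samples["sample_id"]),
        gene_lengths=lengths,
    )
    return cm, samples, truth


def generate_reads(
    config: SimulationConfig,
    truth: Truth,
    genome_sequence: str,
    gene_calls: list[GeneCall],
    library_id: str,
    n_reads: int = 1000,
    read_length: int = 100,
    error_rate: float = 0.0,
    gene_weights: dict[str, float] | None = None,
) -> tuple[list[tuple[str, str]], int]:
    """Sample fixed-length reads from gene intervals of one genome.

    Genes are drawn proportional to ``gene_weights`` (uniform by default);
    reads start uniformly within the gene, copied from the genome forward
    strand, with iid substitution errors at ``error_rate``.  Genes shorter
    than the read length are skipped; the skip count is returned and the
    per-gene truth is recorded under ``truth.read_counts[library_id]``.
    """
    rng = config.rng("reads")
    usable = [g for g in gene_calls if g.nt_length >= read_length]
    n_skipped = len(gene_calls) - len(usable)
    if not usable:
        raise ValueError("no gene is at least read_length long")
    w = np.array([(gene_weights or {}).get(g.gene_id, 1.0) for g in usable], dtype=float)
    w /= w.sum()
    picks = rng.choice(len(usable), size=n_reads, p=w)
    reads: list[tuple[str, str]] = []
    per_gene: dict[str, int] = {}
    for i, gi in enumerate(picks):
        g = usable[gi]
        off = int(rng.integers(0, g.nt_length - read_length + 1))
        seq = genome_sequence[g.start + off : g.start + off + read_length]
        if error_rate > 0:
            seq = list(seq)
            for j in np.flatnonzero(rng.random(read_length) < error_rate):
                seq[j] = "ACGT"[int(rng.integers(4))]
            seq = "".join(seq)
        reads.append((f"{library_id}.read_{i + 1:06d}", seq))
        per_gene[g.gene_id] = per_gene.get(g.gene_id, 0) + 1
    truth.read_counts[library_id] = per_gene
    return reads, n_skipped


def validate_truth(
    truth: Truth,
    gene_calls: Iterable[GeneCall],
    counts: CountMatrix | None = None,
) -> None:
    """Cross-check emitted truth against emitted data; raises on mismatch."""
    calls = {g.gene_id: g for g in gene_calls}
    missing = set(truth.gene_to_cluster) - set(calls)
    if missing:
        raise AssertionError(f"truth names genes absent from gene calls: {sorted(missing)[:5]}")
    n_genomes = len({g.genome_id for g in calls.values()})
    membership: dict[str, set[str]] = {}
    for gene, cid in truth.gene_to_cluster.items():
        membership.setdefault(cid, set()).add(calls[gene].genome_id)
    for cid, genomes in membership.items():
        if truth.cluster_core[cid] != (len(genomes) == n_genomes):
            raise AssertionError(f"truth core flag inconsistent for cluster {cid}")
    if counts is not None:
        extra = set(counts.genes) - set(truth.gene_to_cluster)
        if extra:
            raise AssertionError(f"count matrix genes missing from truth: {sorted(extra)[:5]}")
        bad_de = set(truth.de_genes) - set(counts.genes)
        if bad_de:
            raise AssertionError(f"DE truth names genes outside the count matrix: {sorted(bad_de)[:5]}")
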