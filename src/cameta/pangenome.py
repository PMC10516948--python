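"""Pangenome construction: gene clusters and the core/accessory partition.

A pangenome organizes the gene calls of many genomes of one taxon into
homologous *gene clusters*.  Clusters detected in every genome form the
core genome (bin CORE); clusters present in only a subset of genomes form
the accessory genome.  Clustering here is deterministic greedy centroid
assignment on amino-acid k-mer Jaccard similarity; externally computed
cluster memberships (e.g. from an Anvi'o or Roary summary export) can be
imported instead via :func:`import_clusters`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

ANNOTATION_SOURCES = (
    "KOfam",
    "KEGG_Module",
    "KEGG_Class",
    "COG20_FUNCTION",
    "COG20_PATHWAY",
    "COG20_CATEGORY",
)


@dataclass
class GeneCall:
    """A single gene call on a genome.

    Coordinates are 0-based, half-open; ``nt_length == end - start``.
    ``annotations`` maps an annotation source (see ``ANNOTATION_SOURCES``)
    to an accession string.
    """

    gene_id: str
    genome_id: str
    contig: str
    start: int
    end: int
    strand: str = "+"
    aa_sequence: str | None = None
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"gene {self.gene_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def nt_length(self) -> int:
        return self.end - self.start


@dataclass
class Genome:
    genome_id: str
    source: str = "isolate"  # "isolate" or "MAG"
    sequence_length: int = 0
    gene_ids: list[str] = field(default_factory=list)


@dataclass
class GeneCluster:
    """A group of homologous gene calls across genomes."""

    cluster_id: str
    members: dict[str, list[str]] = field(default_factory=dict)  # genome_id -> gene_ids

    @property
    def n_genomes(self) -> int:
        return len(self.members)

    @property
    def gene_ids(self) -> list[str]:
        return [g for genes in self.members.values() for g in genes]

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.members.values())


@dataclass
class Pangenome:
    genomes: dict[str, Genome]
    clusters: dict[str, GeneCluster]
    core_ids: set[str] = field(default_factory=set)
    accessory_ids: set[str] = field(default_factory=set)

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)

    def cluster_of_gene(self) -> dict[str, str]:
        """Map every member gene_id to its cluster_id."""
        out: dict[str, str] = {}
        for c in self.clusters.values():
            for g in c.gene_ids:
                out[g] = c.cluster_id
        return out


def _kmer_set(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def kmer_jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    """Jaccard similarity |a ∩ b| / |a ∪ b| of two k-mer sets."""
    if not a and not b:
        return 1.0
    inter = len(a & b)
    if inter == 0:
        return 0.0
    return inter / (len(a) + len(b) - inter)


def cluster_genes(
    gene_calls: Iterable[GeneCall],
    similarity_threshold: float = 0.7,
    kmer_size: int = 4,
) -> list[GeneCluster]:
    """Greedy centroid clustering of gene calls on amino-acid k-mer Jaccard.

    Genes are processed in lexicographic ``gene_id`` order; each gene joins
    the first existing cluster (in creation order) whose centroid — the
    k-mer set of the cluster's founding gene — has Jaccard similarity at
    least ``similarity_threshold``, otherwise it founds a new cluster.
    Deterministic given the input set and parameters.
    """
    calls = sorted(gene_calls, key=lambda g: g.gene_id)
    if not calls:
        raise ValueError("cluster_genes: empty input")
    if not (0.0 < similarity_threshold <= 1.0):
        raise ValueError("similarity_threshold must be in (0, 1]")
    for g in calls:
        if g.aa_sequence is None or len(g.aa_sequence) < kmer_size:
            raise ValueError(
                f"gene {g.gene_id}: amino-acid sequence missing or shorter "
                f"than kmer_size={kmer_size}"
            )
    seen = set()
    for g in calls:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)

    centroids: list[frozenset[str]] = []
    cluster_members: list[list[GeneCall]] = []
    # inverted index kmer -> centroid indices, so a gene is only compared
    # against centroids it shares at least one k-mer with
    index: dict[str, list[int]] = {}

    for g in calls:
        kset = _kmer_set(g.aa_sequence, kmer_size)
        candidates: set[int] = set()
        for km in kset:
            candidates.update(index.get(km, ()))
        assigned = None
        for ci in sorted(candidates):
            if kmer_jaccard(kset, centroids[ci]) >= similarity_threshold:
                assigned = ci
                break
        if assigned is None:
            assigned = len(centroids)
            centroids.append(kset)
            for km in kset:
                index.setdefault(km, []).append(assigned)
            cluster_members.append([])
        cluster_members[assigned].append(g)

    width = max(4, len(str(len(cluster_members))))
    clusters = []
    for i, members in enumerate(cluster_members):
        c = GeneCluster(cluster_id=f"GC_{i + 1:0{width}d}")
        for g in members:
            c.members.setdefault(g.genome_id, []).append(g.gene_id)
        clusters.append(c)
    return clusters


def import_clusters(
    membership: pd.DataFrame,
    known_genomes: Sequence[str] | None = None,
) -> list[GeneCluster]:
    """Reconstruct gene clusters from a gene_id/genome_id/cluster_id table.

    Round-trips with :func:`export_membership`.  Raises on duplicate gene
    assignments and, when ``known_genomes`` is given, on unknown genome ids.
    """
    required = {"gene_id", "genome_id", "cluster_id"}
    missing = required - set(membership.columns)
    if missing:
        raise ValueError(f"membership table missing columns: {sorted(missing)}")
    dup = membership["gene_id"][membership["gene_id"].duplicated()].unique()
    if len(dup):
        raise ValueError(f"genes assigned to more than one cluster: {sorted(dup)}")
    if known_genomes is not None:
        unknown = set(membership["genome_id"]) - set(known_genomes)
        if unknown:
            raise ValueError(f"unknown genome ids in membership table: {sorted(unknown)}")
    clusters: dict[str, GeneCluster] = {}
    for row in membership.itertuples(index=False):
        c = clusters.setdefault(row.cluster_id, GeneCluster(cluster_id=row.cluster_id))
        c.members.setdefault(row.genome_id, []).append(row.gene_id)
    return [clusters[k] for k in sorted(clusters)]


def export_membership(clusters: Iterable[GeneCluster]) -> pd.DataFrame:
    rows = [
        {"gene_id": g, "genome_id": gid, "cluster_id": c.cluster_id}
        for c in clusters
        for gid, genes in sorted(c.members.items())
        for g in genes
    ]
    return pd.DataFrame(rows, columns=["gene_id", "genome_id", "cluster_id"])


def classify_core_accessory(pangenome: Pangenome, core_fraction: float = 1.0) -> Pangenome:
    """Partition clusters into core and accessory bins, in place.

    A cluster is core iff it is detected in at least
    ``ceil(core_fraction * n_genomes)`` genomes; the default ``1.0``
    requires presence in every genome.  Returns the (mutated) pangenome.
    """
    if not (0.0 < core_fraction <= 1.0):
        raise ValueError("core_fraction must be in (0, 1]")
    n = pangenome.n_genomes
    if n == 0 or not pangenome.clusters:
        raise ValueError("pangenome has no genomes or no clusters")
    # small epsilon guards against float artifacts like 0.8 * 5 -> 4.0000000000000002
    need = math.ceil(core_fraction * n - 1e-9)
    pangenome.core_ids = {
        cid for cid, c in pangenome.clusters.items() if c.n_genomes >= need
    }
    pangenome.accessory_ids = set(pangenome.clusters) - pangenome.core_ids
    return pangenome


def annotation_coverage(
    clusters: Iterable[GeneCluster],
    gene_calls: Mapping[str, GeneCall],
    source: str,
) -> float:
    """Fraction of clusters with at least one member annotated in ``source``.

    A cluster counts once regardless of how many members carry the
    annotation.
    """
    if source not in ANNOTATION_SOURCES:
        raise ValueError(
            f"unknown annotation source {source!r}; expected one of {ANNOTATION_SOURCES}"
        )
    clusters = list(clusters)
    if not clusters:
        raise ValueError("no clusters given")
    hit = 0
    for c in clusters:
        for g in c.gene_ids:
            call = gene_calls.get(g)
            if call is not None and source in call.annotations:
                hit += 1
                break
    return hit / len(clusters)


def build_pangenome(
    genomes: dict[str, Genome],
    clusters: Iterable[GeneCluster],
    core_fraction: float = 1.0,
) -> Pangenome:
    """Assemble and partition a :class:`Pangenome` from genomes and clusters."""
    pg = Pangenome(genomes=genomes, clusters={c.cluster_id: c for c in clusters})
    return classify_core_accessory(pg, core_fraction)
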