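"""CA-Metatranscriptome assembly: DE layers on gene clusters and the
core-vs-accessory response summary.

Differential-expression calls made on the reference genome's genes are
lifted onto the pangenome's gene clusters: a cluster is flagged in a
(treatment, direction) layer when at least one of its reference-genome
member genes is significantly up- (resp. down-) regulated in that
treatment's contrast against the biotic control.  The headline statistic
is the fraction of DE-containing clusters that belong to the core
pangenome: core_pct = 100 * |DE ∩ core| / |DE|.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .pangenome import GeneCluster, Pangenome

DIRECTIONS = ("up", "down")


@dataclass
class CALayer:
    treatment: str
    direction: str  # "up" or "down"
    cluster_flags: dict[str, bool] = field(default_factory=dict)

    def flagged(self) -> set[str]:
        return {c for c, v in self.cluster_flags.items() if v}


@dataclass
class CASummary:
    n_de_clusters_total: int
    n_de_clusters_core: int
    n_de_clusters_accessory: int
    core_pct: float | None  # None when no DE clusters
    accessory_pct: float | None
    per_treatment: dict[str, dict[str, int]] = field(default_factory=dict)
    n_de_genes: dict[str, int] = field(default_factory=dict)  # per direction

    def to_dict(self) -> dict:
        return {
            "n_de_clusters_total": self.n_de_clusters_total,
            "n_de_clusters_core": self.n_de_clusters_core,
            "n_de_clusters_accessory": self.n_de_clusters_accessory,
            "core_pct": self.core_pct,
            "accessory_pct": self.accessory_pct,
            "per_treatment": self.per_treatment,
            "n_de_genes": self.n_de_genes,
        }


@dataclass
class CAMetatranscriptome:
    pangenome: Pangenome
    layers: list[CALayer]
    summary: CASummary
    detection: dict[tuple[str, str], float] = field(default_factory=dict)
    orphan_genes: list[str] = field(default_factory=list)


def map_de_to_clusters(
    de_results: pd.DataFrame,
    clusters: Iterable[GeneCluster],
    reference_genome_id: str,
    reference_gene_ids: Iterable[str] | None = None,
) -> tuple[list[CALayer], list[str]]:
    """Lift per-gene DE calls onto gene clusters as per-treatment layers.

    ``de_results`` needs columns gene_id, contrast (``<treatment>_vs_BC``)
    and status.  Every cluster of the pangenome appears in every layer's
    flags (False when no member gene is DE).  Returns the layers plus the
    list of orphan DE genes — reference genes present in the gene calls
    but absent from every cluster — which are reported, never silently
    dropped.
    """
    clusters = list(clusters)
    gene_to_cluster: dict[str, str] = {}
    for c in clusters:
        for g in c.members.get(reference_genome_id, []):
            gene_to_cluster[g] = c.cluster_id
    known_genes = (
        set(reference_gene_ids) if reference_gene_ids is not None else set(gene_to_cluster)
    )

    required = {"gene_id", "contrast", "status"}
    missing = required - set(de_results.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")

    de = de_results[de_results["status"].isin(DIRECTIONS)]
    unknown = set(de["gene_id"]) - known_genes
    if unknown:
        raise ValueError(
            f"DE genes not found among reference genome gene calls: {sorted(unknown)[:5]}"
        )

    all_ids = [c.cluster_id for c in clusters]
    layers: dict[tuple[str, str], CALayer] = {}
    orphans: set[str] = set()
    for row in de.itertuples(index=False):
        treatment = row.contrast.split("_vs_")[0]
        key = (treatment, row.status)
        if key not in layers:
            layers[key] = CALayer(
                treatment=treatment,
                direction=row.status,
                cluster_flags={cid: False for cid in all_ids},
            )
        cid = gene_to_cluster.get(row.gene_id)
        if cid is None:
            orphans.add(row.gene_id)
        else:
            layers[key].cluster_flags[cid] = True
    return [layers[k] for k in sorted(layers)], sorted(orphans)


def summarize_core_accessory(
    layers: Iterable[CALayer],
    pangenome: Pangenome,
    de_gene_counts: Mapping[str, int] | None = None,
) -> CASummary:
    """Core/accessory tally of DE clusters across all layers.

    A cluster is DE when flagged in any treatment/direction layer; clusters
    flagged in several layers count once in the totals.  Percentages are
    ``None`` (reported missing) when no cluster is DE.
    """
    layers = list(layers)
    de_clusters: set[str] = set()
    per_treatment: dict[str, dict[str, set[str]]] = {}
    for layer in layers:
        flagged = layer.flagged()
        unknown = flagged - set(pangenome.clusters)
        if unknown:
            raise ValueError(f"layer flags unknown clusters: {sorted(unknown)[:5]}")
        de_clusters |= flagged
        per_treatment.setdefault(layer.treatment, {"up": set(), "down": set()})
        per_treatment[layer.treatment][layer.direction] |= flagged

    n_core = len(de_clusters & pangenome.core_ids)
    n_acc = len(de_clusters & pangenome.accessory_ids)
    total = len(de_clusters)
    per_trt_counts = {
        trt: {
            "up": len(d["up"]),
            "down": len(d["down"]),
            "total": len(d["up"] | d["down"]),
            "core": len((d["up"] | d["down"]) & pangenome.core_ids),
            "accessory": len((d["up"] | d["down"]) & pangenome.accessory_ids),
        }
        for trt, d in sorted(per_treatment.items())
    }
    return CASummary(
        n_de_clusters_total=total,
        n_de_clusters_core=n_core,
        n_de_clusters_accessory=n_acc,
        core_pct=100.0 * n_core / total if total else None,
        accessory_pct=100.0 * n_acc / total if total else None,
        per_treatment=per_trt_counts,
        n_de_genes=dict(de_gene_counts) if de_gene_counts else {},
    )


def summary_from_counts(n_core_de: int, n_total_de: int) -> CASummary:
    """Core/accessory percentages straight from printed DE-cluster counts.

    Worked-example utility: e.g. 653 core DE clusters of 1,598 total give
    core_pct 40.9 and accessory_pct 59.1.
    """
    if n_core_de < 0 or n_total_de < 0 or n_core_de > n_total_de:
        raise ValueError("need 0 <= n_core_de <= n_total_de")
    n_acc = n_total_de - n_core_de
    return CASummary(
        n_de_clusters_total=n_total_de,
        n_de_clusters_core=n_core_de,
        n_de_clusters_accessory=n_acc,
        core_pct=100.0 * n_core_de / n_total_de if n_total_de else None,
        accessory_pct=100.0 * n_acc / n_total_de if n_total_de else None,
    )


def detection_profile(
    per_gene_coverage: Mapping[tuple[str, str], float],
    clusters: Iterable[GeneCluster],
    reference_genome_id: str,
) -> dict[tuple[str, str], float]:
    """Per (sample, cluster) mean covered fraction over reference member genes.

    Clusters with no reference-genome members are omitted (missing).
    """
    for (sample, gene), frac in per_gene_coverage.items():
        if not (0.0 <= frac <= 1.0):
            raise ValueError(
                f"coverage fraction {frac} for ({sample}, {gene}) outside [0, 1]"
            )
    samples = sorted({s for s, _ in per_gene_coverage})
    out: dict[tuple[str, str], float] = {}
    for c in clusters:
        genes = c.members.get(reference_genome_id, [])
        if not genes:
            continue
        for s in samples:
            vals = [per_gene_coverage.get((s, g), 0.0) for g in genes]
            out[(s, c.cluster_id)] = sum(vals) / len(vals)
    return out


def export_ca(ca: CAMetatranscriptome, outdir: str | Path, prefix: str = "ca") -> tuple[Path, Path]:
    """Write the CA bundle: one cluster table (TSV) + one summary JSON.

    One row per cluster with genome presence/absence columns, the core
    flag, and one boolean column per (treatment, direction) layer; stable
    column order; lossless round-trip with :func:`import_ca_table`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pg = ca.pangenome
    genome_ids = sorted(pg.genomes)
    rows = []
    for cid in sorted(pg.clusters):
        c = pg.clusters[cid]
        row: dict[str, object] = {"cluster_id": cid, "core": cid in pg.core_ids}
        for gid in genome_ids:
            row[f"presence_{gid}"] = int(gid in c.members)
        for layer in ca.layers:
            row[f"de_{layer.treatment}_{layer.direction}"] = int(
                layer.cluster_flags.get(cid, False)
            )
        rows.append(row)
    cols = (
        ["cluster_id", "core"]
        + [f"presence_{g}" for g in genome_ids]
        + [f"de_{l.treatment}_{l.direction}" for l in ca.layers]
    )
    table = pd.DataFrame(rows, columns=cols)
    table_path = outdir / f"{prefix}_clusters.tsv"
    table.to_csv(table_path, sep="\t", index=False)

    summary_path = outdir / f"{prefix}_summary.json"
    payload = {
        "schema_version": 1,
        "n_genomes": pg.n_genomes,
        "n_clusters": len(pg.clusters),
        "n_core": len(pg.core_ids),
        "n_accessory": len(pg.accessory_ids),
        "orphan_genes": ca.orphan_genes,
        "summary": ca.summary.to_dict(),
    }
    summary_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return table_path, summary_path


def import_ca_table(path: str | Path) -> tuple[pd.DataFrame, list[CALayer], set[str]]:
    """Read a CA cluster table back: (table, layers, core cluster ids)."""
    table = pd.read_csv(path, sep="\t")
    layers = []
    for col in table.columns:
        if col.startswith("de_"):
            treatment, direction = col[3:].rsplit("_", 1)
            layers.append(
                CALayer(
                    treatment=treatment,
                    direction=direction,
                    cluster_flags=dict(
                        zip(table["cluster_id"], table[col].astype(bool))
                    ),
                )
            )
    core_ids = set(table.loc[table["core"].astype(bool), "cluster_id"])
    return table, layers, core_ids
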