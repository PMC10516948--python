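"""Normalization and negative-binomial Wald differential expression.

Raw per-gene counts are normalized two ways: Transcripts per Million
(TPM) for within-sample, length-aware reporting, and median-of-ratios
size factors for between-sample inference.  Differential expression per
treatment-vs-biotic-control contrast uses a two-group negative-binomial
model with gene-wise dispersion (method-of-moments, shrunk toward a
fitted mean–dispersion trend), a Wald statistic with standard error from
the NB Fisher information, Cook's-distance outlier flagging, an
independent low-count filter, and Benjamini–Hochberg FDR control.

Counts, not TPM, feed the test: the NB model is defined on counts and a
test on rescaled values would be incoherent.  TPM is for export only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

TREATMENTS = ("BC", "DISP", "WAF", "CEWAF", "CEWAFN")
BASELINE = "BC"

#: floor applied to every dispersion estimate
ALPHA_FLOOR = 1e-8


@dataclass
class CountMatrix:
    """Genes x samples raw counts plus per-gene nucleotide lengths."""

    counts: pd.DataFrame  # genes x samples, non-negative integers
    gene_lengths: pd.Series  # nt, indexed like counts

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64, errors="raise")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any():
            missing = list(self.gene_lengths[self.gene_lengths.isna()].index[:5])
            raise ValueError(f"gene lengths missing for genes: {missing}")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns


def validate_sample_table(samples: pd.DataFrame, counts: CountMatrix | None = None) -> pd.DataFrame:
    """Check a sample metadata table (sample_id, treatment, time_days, replicate)."""
    required = {"sample_id", "treatment", "time_days", "replicate"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    bad = set(samples["treatment"]) - set(TREATMENTS)
    if bad:
        raise ValueError(f"unknown treatments {sorted(bad)}; expected {TREATMENTS}")
    if BASELINE not in set(samples["treatment"]):
        raise ValueError(f"baseline treatment {BASELINE!r} absent from sample table")
    if samples["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_ids in sample table")
    if counts is not None:
        extra = set(samples["sample_id"]) ^ set(counts.samples)
        if extra:
            raise ValueError(f"sample ids disagree between counts and metadata: {sorted(extra)}")
    return samples


def tpm(counts: CountMatrix) -> pd.DataFrame:
    """Transcripts per Million: length-normalized rates scaled to 1e6 per sample.

    Every column sums to 1e6 except all-zero columns, which stay all-zero.
    """
    lengths = counts.gene_lengths.astype(float)
    if (lengths <= 0).any():
        bad = list(lengths[lengths <= 0].index[:5])
        raise ValueError(f"non-positive gene lengths for genes: {bad}")
    rate = counts.counts.div(lengths / 1e3, axis=0)
    colsum = rate.sum(axis=0)
    out = rate.div(colsum.replace(0.0, np.nan), axis=1) * 1e6
    return out.fillna(0.0)


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    The reference is the per-gene geometric mean across samples; genes with
    any zero count are excluded from the reference.  factor_j is the median
    over reference genes of count_gj / geomean_g.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = mat.to_numpy(dtype=float)
    usable = (arr > 0).all(axis=1)
    if not usable.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; size factors are "
            "undefined (consider a pseudocount fallback)"
        )
    logs = np.log(arr[usable])
    loggeo = logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs - loggeo, axis=0))
    return pd.Series(sf, index=mat.columns, name="size_factor")


@dataclass
class DispersionEstimate:
    gene_id: str
    raw_alpha: float  # NaN for all-zero genes
    shrunk_alpha: float


def _raw_dispersions(norm: np.ndarray, group_idx: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Method-of-moments NB dispersion per gene, pooled across groups.

    For each condition group with >=2 samples, alpha_g = (s^2 - mu)/mu^2 on
    normalized counts; estimates are pooled with weights (n_g - 1) and
    truncated at zero.  Returns (raw_alpha, overall_mean); raw_alpha is NaN
    for genes with zero mean everywhere.
    """
    n_genes = norm.shape[0]
    num = np.zeros(n_genes)
    den = np.zeros(n_genes)
    any_group = False
    for idx in group_idx:
        if len(idx) < 2:
            continue
        any_group = True
        sub = norm[:, idx]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (var - mu) / mu**2
        w = len(idx) - 1
        ok = mu > 0
        num[ok] += w * a[ok]
        den[ok] += w
    if not any_group:
        raise ValueError("dispersion estimation needs >=2 replicates in some condition")
    with np.errstate(invalid="ignore"):
        raw = np.where(den > 0, np.maximum(num / np.maximum(den, 1), 0.0), np.nan)
    raw[den == 0] = np.nan
    return raw, norm.mean(axis=1)


def _fit_trend(mean: np.ndarray, raw: np.ndarray) -> tuple[float, float]:
    """Fit the parametric mean-dispersion trend alpha(mu) = a0 + a1/mu.

    Non-negative least squares over genes with informative raw estimates;
    falls back to the median raw dispersion when too few genes inform the
    fit.
    """
    ok = np.isfinite(raw) & (raw > 1e-6) & (mean > 0)
    if ok.sum() < 10:
        med = float(np.nanmedian(raw[np.isfinite(raw)])) if np.isfinite(raw).any() else 0.0
        return max(med, ALPHA_FLOOR), 0.0
    design = np.column_stack([np.ones(ok.sum()), 1.0 / mean[ok]])
    coef, _ = optimize.nnls(design, raw[ok])
    a0, a1 = float(coef[0]), float(coef[1])
    if a0 <= 0 and a1 <= 0:
        a0 = max(float(np.median(raw[ok])), ALPHA_FLOOR)
    return a0, a1


def estimate_dispersion(
    counts: CountMatrix | pd.DataFrame,
    sf: pd.Series,
    groups: pd.Series,
    trend_weight: float | None = None,
) -> pd.DataFrame:
    """Per-gene NB dispersion: raw method-of-moments plus trend shrinkage.

    ``groups`` maps sample_id -> condition label; dispersion is estimated
    within condition groups on size-factor-normalized counts and pooled.
    The shrunk estimate is a log-scale blend of the raw estimate and the
    fitted trend; with few residual degrees of freedom the blend leans on
    the trend (weight m0/(m0 + df), m0 = 8 prior degrees of freedom).
    Returns a DataFrame with columns raw_alpha, shrunk_alpha, mean_norm.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    sf = sf.reindex(mat.columns)
    groups = groups.reindex(mat.columns)
    norm = mat.to_numpy(dtype=float) / sf.to_numpy(dtype=float)
    labels = groups.to_numpy()
    group_idx = [np.flatnonzero(labels == g) for g in pd.unique(labels)]
    raw, mean = _raw_dispersions(norm, group_idx)

    a0, a1 = _fit_trend(mean, raw)
    with np.errstate(divide="ignore"):
        trend = np.where(mean > 0, a0 + a1 / np.maximum(mean, 1e-12), np.nan)
    trend = np.maximum(trend, ALPHA_FLOOR)

    if trend_weight is None:
        df_resid = sum(max(len(i) - 1, 0) for i in group_idx)
        trend_weight = 8.0 / (8.0 + max(df_resid, 1))
    w = float(np.clip(trend_weight, 0.0, 1.0))
    raw_f = np.maximum(np.where(np.isfinite(raw), raw, 0.0), ALPHA_FLOOR)
    shrunk = np.maximum(w * trend + (1 - w) * raw_f, ALPHA_FLOOR)
    shrunk[~np.isfinite(raw)] = np.nan  # all-zero genes: undefined

    return pd.DataFrame(
        {"raw_alpha": raw, "shrunk_alpha": shrunk, "trend_alpha": trend, "mean_norm": mean},
        index=mat.index,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Missing values (NaN) are passed through untouched and do not count
    toward the number of tests.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def regularized_log(counts: CountMatrix | pd.DataFrame, sf: pd.Series, prior_count: float = 1.0) -> pd.DataFrame:
    """Reporting transform log2(count/size_factor + prior_count); not used for testing."""
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    return np.log2(mat.div(sf.reindex(mat.columns), axis=1) + prior_count)


def _cooks_distance(
    y: np.ndarray, mu: np.ndarray, alpha: np.ndarray, group_mask: np.ndarray
) -> np.ndarray:
    """Max Cook's distance per gene for the two-group NB fit.

    Leverage of sample j is w_j / sum_{group} w with NB working weights
    w = mu/(1 + alpha*mu); Pearson residuals use the NB variance
    mu*(1 + alpha*mu); p = 2 model coefficients.
    """
    p_coef = 2
    var = mu * (1.0 + alpha[:, None] * mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (y - mu) ** 2 / var
    w = mu / (1.0 + alpha[:, None] * mu)
    h = np.empty_like(w)
    for mask in (group_mask, ~group_mask):
        tot = w[:, mask].sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            h[:, mask] = w[:, mask] / tot
    h = np.clip(h, 0.0, 1.0 - 1e-8)
    d = r2 * h / (p_coef * (1.0 - h) ** 2)
    d[~np.isfinite(d)] = 0.0
    return d.max(axis=1)


@dataclass
class DEOptions:
    alpha_level: float = 0.05
    lfc_pseudo: float = 0.5  # pseudo-count added to group count sums
    min_mean_norm: float = 1.0  # independent low-count filter
    cooks_quantile: float = 0.99
    use_cooks: bool = True


def wald_test(
    counts: CountMatrix,
    samples: pd.DataFrame,
    contrast: str,
    alpha_level: float = 0.05,
    time_days: float | None = None,
    options: DEOptions | None = None,
) -> pd.DataFrame:
    """Negative-binomial Wald test of one treatment against the biotic control.

    Samples of ``contrast`` and of the baseline (BC) are selected — all
    timepoints pooled, or one sampling day when ``time_days`` is given.
    Per gene, group means are fit with size-factor offsets and shrunk
    dispersion; log2 fold change uses pseudo-stabilized group rates
    q = (sum counts + pseudo) / (sum size factors); the Wald SE comes from
    the NB Fisher information I = sum mu/(1 + alpha*mu) per group.  Genes
    whose maximum Cook's distance exceeds the F(2, n-2) 99th percentile
    are flagged ``outlier``; genes below the low-count filter are flagged
    ``low_count``; both are excluded from BH adjustment.

    Returns one row per gene: log2_fold_change, se, wald_stat, p_value,
    padj, status in {up, down, ns, outlier, low_count}.
    """
    opt = options or DEOptions(alpha_level=alpha_level)
    opt.alpha_level = alpha_level
    samples = validate_sample_table(samples)
    if contrast == BASELINE:
        raise ValueError("contrast must differ from the baseline treatment")
    if contrast not in set(samples["treatment"]):
        raise ValueError(f"contrast treatment {contrast!r} absent from sample table")

    sel = samples[samples["treatment"].isin([BASELINE, contrast])]
    if time_days is not None:
        sel = sel[sel["time_days"] == time_days]
    for grp in (BASELINE, contrast):
        n = (sel["treatment"] == grp).sum()
        if n < 2:
            raise ValueError(
                f"group {grp!r} has {n} sample(s); >=2 replicates required"
                + (f" at time_days={time_days}" if time_days is not None else "")
            )

    cols = sel["sample_id"].tolist()
    mat = counts.counts.loc[:, cols]
    sf = size_factors(mat)
    groups = sel.set_index("sample_id")["treatment"].reindex(cols)
    disp = estimate_dispersion(mat, sf, groups)

    y = mat.to_numpy(dtype=float)
    s = sf.to_numpy(dtype=float)
    is_trt = (groups.to_numpy() == contrast)
    alpha_g = disp["shrunk_alpha"].to_numpy()
    alpha_fit = np.where(np.isfinite(alpha_g), alpha_g, ALPHA_FLOOR)

    def group_fit(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ysum = y[:, mask].sum(axis=1)
        ssum = s[mask].sum()
        q = (ysum + opt.lfc_pseudo) / ssum
        mu = q[:, None] * s[mask][None, :]
        info = (mu / (1.0 + alpha_fit[:, None] * mu)).sum(axis=1)
        return q, info

    q_bc, info_bc = group_fit(~is_trt)
    q_tr, info_tr = group_fit(is_trt)

    ln2 = np.log(2.0)
    lfc = np.log2(q_tr / q_bc)
    se = np.sqrt(1.0 / info_bc + 1.0 / info_tr) / ln2
    wald = lfc / se
    pval = 2.0 * stats.norm.sf(np.abs(wald))

    status = np.full(len(lfc), "ns", dtype=object)

    norm_mean = (y / s[None, :]).mean(axis=1)
    low = norm_mean < opt.min_mean_norm
    status[low] = "low_count"

    if opt.use_cooks:
        mu_full = np.where(is_trt[None, :], q_tr[:, None], q_bc[:, None]) * s[None, :]
        # judged against the trend dispersion: a gene-wise estimate inflated
        # by the very outlier under scrutiny would mask it
        alpha_cook = disp["trend_alpha"].to_numpy()
        max_cook = _cooks_distance(y, mu_full, alpha_cook, is_trt)
        n_samp = y.shape[1]
        thresh = stats.f.ppf(opt.cooks_quantile, 2, max(n_samp - 2, 1))
        outlier = (max_cook > thresh) & ~low
        status[outlier] = "outlier"

    pval_masked = pval.copy()
    pval_masked[status != "ns"] = np.nan
    padj = bh_adjust(pval_masked)

    sig = (padj < opt.alpha_level) & (status == "ns")
    status[sig & (lfc > 0)] = "up"
    status[sig & (lfc < 0)] = "down"
    pval_out = np.where(np.isin(status, ("outlier", "low_count")), np.nan, pval)

    return pd.DataFrame(
        {
            "gene_id": counts.genes,
            "contrast": f"{contrast}_vs_{BASELINE}",
            "base_mean": norm_mean,
            "log2_fold_change": lfc,
            "se": se,
            "wald_stat": wald,
            "p_value": pval_out,
            "padj": padj,
            "status": status,
        }
    ).set_index("gene_id")


def de_all_contrasts(
    counts: CountMatrix,
    samples: pd.DataFrame,
    alpha_level: float = 0.05,
    time_days: float | None = None,
) -> pd.DataFrame:
    """Run the Wald test for every non-baseline treatment present; concatenated results."""
    samples = validate_sample_table(samples, counts)
    results = []
    for trt in TREATMENTS:
        if trt == BASELINE or trt not in set(samples["treatment"]):
            continue
        results.append(
            wald_test(counts, samples, trt, alpha_level=alpha_level, time_days=time_days)
        )
    if not results:
        raise ValueError("no non-baseline treatment found in sample table")
    return pd.concat(results).reset_index()
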