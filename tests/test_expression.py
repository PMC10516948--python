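"""TPM, size factors, dispersion estimation, NB Wald test and BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cameta.expression import (
    CountMatrix,
    bh_adjust,
    estimate_dispersion,
    regularized_log,
    size_factors,
    tpm,
    wald_test,
)


def cm(counts, lengths, cols=None):
    counts = np.atleast_2d(np.asarray(counts))
    cols = cols or [f"s{j}" for j in range(counts.shape[1])]
    idx = [f"g{i}" for i in range(counts.shape[0])]
    return CountMatrix(
        counts=pd.DataFrame(counts, index=idx, columns=cols),
        gene_lengths=pd.Series(lengths, index=idx),
    )


class TestTPM:
    def test_single_gene_takes_the_whole_million(self):
        out = tpm(cm([[7]], [500]))
        assert out.iloc[0, 0] == pytest.approx(1e6)

    def test_equal_per_base_rates_split_evenly(self):
        out = tpm(cm([[10], [20], [5]], [1000, 2000, 500]))
        assert np.allclose(out.iloc[:, 0], 1e6 / 3)

    def test_hand_computed_two_gene_example(self):
        # len 100, 400 bp with counts 2, 4: rates 20 and 10 per kb
        out = tpm(cm([[2], [4]], [100, 400]))
        assert out.iloc[0, 0] == pytest.approx(666666.6667, rel=1e-6)
        assert out.iloc[1, 0] == pytest.approx(333333.3333, rel=1e-6)

    def test_all_zero_column_stays_zero(self):
        out = tpm(cm([[0, 5], [0, 5]], [100, 100]))
        assert (out.iloc[:, 0] == 0).all()
        assert out.iloc[:, 1].sum() == pytest.approx(1e6)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            tpm(cm([[1]], [0]))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_columns_sum_to_one_million_and_scale_invariance(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 1000, size=(rng.integers(2, 30), rng.integers(1, 8)))
        lengths = rng.integers(100, 5000, size=counts.shape[0])
        matrix = cm(counts, lengths)
        out = tpm(matrix)
        colsum = out.sum(axis=0)
        nonzero = counts.sum(axis=0) > 0
        assert np.allclose(colsum[nonzero], 1e6, rtol=1e-6)
        scaled = cm(counts * 3, lengths)
        assert np.allclose(tpm(scaled), out)


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        sf = size_factors(cm([[10, 10], [3, 3]], [1, 1]))
        assert np.allclose(sf, 1.0)

    def test_hand_computed_doubling_example(self):
        counts = np.array([[10, 20], [50, 100], [7, 14]])
        sf = size_factors(cm(counts, [1, 1, 1]))
        assert sf.to_numpy() == pytest.approx([2 ** -0.5, 2 ** 0.5])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 500, size=(40, 4))
        sf1 = size_factors(cm(counts, np.ones(40)))
        perm = rng.permutation(40)
        sf2 = size_factors(cm(counts[perm], np.ones(40)))
        assert np.allclose(sf1, sf2)

    def test_scalar_multiple_samples_have_unit_geometric_mean(self):
        base = np.array([[20], [80], [11], [400]])
        counts = np.hstack([base, base * 4])
        sf = size_factors(cm(counts, np.ones(4)))
        assert np.prod(sf) == pytest.approx(1.0)

    def test_no_reference_gene_suggests_pseudocount(self):
        with pytest.raises(ValueError, match="pseudocount"):
            size_factors(cm([[0, 5], [3, 0]], [1, 1]))


class TestDispersion:
    def _groups(self, cols):
        return pd.Series(["A"] * (len(cols) // 2) + ["B"] * (len(cols) - len(cols) // 2), index=cols)

    def test_poisson_limit_gives_near_zero_raw_alpha(self):
        rng = np.random.default_rng(5)
        y = rng.poisson(200, size=(500, 10))
        matrix = cm(y, np.ones(500))
        d = estimate_dispersion(matrix.counts, size_factors(matrix.counts), self._groups(matrix.samples))
        assert np.nanmean(d["raw_alpha"]) < 0.02

    def test_nb_alpha_recovered_at_twenty_replicates(self):
        rng = np.random.default_rng(6)
        alpha = 0.2
        r = 1 / alpha
        mean = 100.0
        y = rng.negative_binomial(r, r / (r + mean), size=(800, 40))
        matrix = cm(y, np.ones(800))
        d = estimate_dispersion(matrix.counts, size_factors(matrix.counts), self._groups(matrix.samples))
        assert np.nanmean(d["raw_alpha"]) == pytest.approx(alpha, abs=0.05)

    def test_constant_counts_give_zero_raw_alpha(self):
        y = np.full((5, 6), 37)
        matrix = cm(y, np.ones(5))
        d = estimate_dispersion(matrix.counts, pd.Series(1.0, index=matrix.samples), self._groups(matrix.samples))
        assert (d["raw_alpha"] == 0).all()

    def test_all_zero_gene_flagged_undefined(self):
        y = np.vstack([np.zeros(6, dtype=int), np.full(6, 50)])
        matrix = cm(y, np.ones(2))
        d = estimate_dispersion(matrix.counts, pd.Series(1.0, index=matrix.samples), self._groups(matrix.samples))
        assert np.isnan(d.loc["g0", "raw_alpha"]) and np.isnan(d.loc["g0", "shrunk_alpha"])
        assert np.isfinite(d.loc["g1", "shrunk_alpha"])


class TestBH:
    def test_hand_computed_step_up(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_degenerate_inputs(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_missing_values_pass_through(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        # the NaN does not count toward the number of tests
        assert out[[0, 2]] == pytest.approx(bh_adjust([0.01, 0.04]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=60)
    )
    def test_step_up_properties(self, pvals):
        out = bh_adjust(pvals)
        p = np.asarray(pvals)
        assert (out >= p - 1e-12).all()
        assert (out <= 1.0 + 1e-12).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(out[order]) >= -1e-12).all()


class TestWaldTest:
    def test_identical_groups_are_ns_with_zero_lfc(self):
        y = np.tile(np.array([[40], [300], [12]]), (1, 6))
        matrix = cm(y, np.ones(3))
        samples = pd.DataFrame(
            {
                "sample_id": matrix.samples,
                "treatment": ["BC"] * 3 + ["WAF"] * 3,
                "time_days": 0.0,
                "replicate": list("abcabc"),
            }
        )
        res = wald_test(matrix, samples, "WAF")
        assert np.allclose(res["log2_fold_change"], 0.0)
        assert (res["status"] == "ns").all()

    def test_group_label_swap_negates_fold_changes(self, two_group_counts):
        counts, samples = two_group_counts
        res = wald_test(counts, samples, "WAF")
        flipped = samples.copy()
        flipped["treatment"] = flipped["treatment"].map({"BC": "WAF", "WAF": "BC"})
        res_flip = wald_test(counts, flipped, "WAF")
        assert np.allclose(res["log2_fold_change"], -res_flip["log2_fold_change"], atol=1e-10)

    def test_null_fixture_has_few_discoveries(self, two_group_counts):
        counts, samples = two_group_counts
        res = wald_test(counts, samples, "WAF")
        assert res["status"].isin(("up", "down")).mean() <= 0.01

    def test_invariants_on_null_fixture(self, two_group_counts):
        counts, samples = two_group_counts
        res = wald_test(counts, samples, "WAF")
        ok = res["padj"].notna()
        assert (res.loc[ok, "padj"] >= res.loc[ok, "p_value"] - 1e-12).all()
        up = res[res["status"] == "up"]
        down = res[res["status"] == "down"]
        assert (up["log2_fold_change"] > 0).all() and (up["padj"] < 0.05).all()
        assert (down["log2_fold_change"] < 0).all() and (down["padj"] < 0.05).all()

    def test_outlier_flagged_and_excluded_from_bh(self):
        # 5 vs 5 so a single wild replicate cannot be absorbed by the group
        # mean; at 3 vs 3 Cook's distance cannot exceed the F threshold
        rng = np.random.default_rng(12)
        n_genes = 300
        m = 100 * np.exp(rng.normal(0, 0.5, n_genes))
        y = rng.negative_binomial(10, 10 / (10 + m[:, None] * np.ones(10)))
        y[0, 0] = 500000  # one wild replicate
        cols = [f"BC_r{i}" for i in range(5)] + [f"WAF_r{i}" for i in range(5)]
        idx = [f"g{i:03d}" for i in range(n_genes)]
        matrix = CountMatrix(
            counts=pd.DataFrame(y, index=idx, columns=cols),
            gene_lengths=pd.Series(900, index=idx),
        )
        samples = pd.DataFrame(
            {"sample_id": cols, "treatment": ["BC"] * 5 + ["WAF"] * 5,
             "time_days": 0.0, "replicate": [c[-2:] for c in cols]}
        )
        res = wald_test(matrix, samples, "WAF")
        assert res.iloc[0]["status"] == "outlier"
        assert np.isnan(res.iloc[0]["p_value"]) and np.isnan(res.iloc[0]["padj"])

    def test_low_count_genes_filtered(self, two_group_counts):
        counts, samples = two_group_counts
        low = counts.counts.copy()
        low.iloc[5] = [0, 1, 0, 0, 0, 1]
        matrix = CountMatrix(counts=low, gene_lengths=counts.gene_lengths)
        res = wald_test(matrix, samples, "WAF")
        assert res.iloc[5]["status"] == "low_count"
        assert np.isnan(res.iloc[5]["padj"])

    def test_missing_group_and_small_groups_rejected(self, two_group_counts):
        counts, samples = two_group_counts
        with pytest.raises(ValueError, match="CEWAF"):
            wald_test(counts, samples, "CEWAF")
        tiny = samples.iloc[[0, 1, 2, 3]]
        with pytest.raises(ValueError, match="WAF"):
            wald_test(counts.counts.pipe(lambda c: CountMatrix(c[tiny.sample_id], counts.gene_lengths)), tiny, "WAF")

    def test_baseline_is_not_a_valid_contrast(self, two_group_counts):
        counts, samples = two_group_counts
        with pytest.raises(ValueError, match="baseline"):
            wald_test(counts, samples, "BC")


def test_regularized_log_is_monotone_reporting_transform(two_group_counts):
    counts, _ = two_group_counts
    sf = size_factors(counts)
    out = regularized_log(counts, sf, prior_count=1.0)
    assert out.shape == counts.counts.shape
    col = counts.counts.iloc[:, 0].to_numpy()
    transformed = out.iloc[:, 0].to_numpy()
    order = np.argsort(col)
    assert (np.diff(transformed[order]) >= -1e-12).all()
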