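"""Cross-platform concordance statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from methcompare.concordance import (
    delta_beta_concordance,
    enrichment_fisher,
    epic_beta,
    grouped_correlation_ttest,
    mean_betas_by_method,
    ont_call_beta,
    pairwise_pearson,
    residual_vs_gc,
)
from methcompare.io import BetaTable, SampleInfo


def _beta_frame(columns: dict) -> pd.DataFrame:
    n = len(next(iter(columns.values())))
    idx = pd.MultiIndex.from_product([["chr1"], range(1, n + 1)],
                                     names=["chrom", "pos"])
    return pd.DataFrame(columns, index=idx)


class TestPairwisePearson:
    def test_identical_and_reflected_columns(self):
        base = np.linspace(0.05, 0.95, 30)
        frame = _beta_frame({"a": base, "b": base, "c": 1 - base})
        corr = pairwise_pearson(frame)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)
        assert (np.diag(corr) == 1.0).all()
        np.testing.assert_allclose(corr.values, corr.values.T)

    def test_matches_product_moment_formula(self):
        x = np.array([0.0, 0.5, 1.0])
        y = np.array([0.1, 0.4, 1.0])
        # textbook formula computed independently
        r_hand = (np.sum((x - x.mean()) * (y - y.mean())) /
                  np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
        corr = pairwise_pearson(_beta_frame({"a": x, "b": y}))
        assert corr.loc["a", "b"] == pytest.approx(r_hand)

    def test_subsample_is_shared_and_seeded(self, rng):
        frame = _beta_frame(
            {"a": rng.random(500), "b": rng.random(500), "c": rng.random(500)}
        )
        first = pairwise_pearson(frame, n_sample=100, seed=5)
        second = pairwise_pearson(frame, n_sample=100, seed=5)
        pd.testing.assert_frame_equal(first, second)
        assert not first.equals(pairwise_pearson(frame))

    def test_too_few_complete_pairs_gives_missing(self):
        frame = _beta_frame(
            {"a": [0.1, 0.2, np.nan, np.nan], "b": [0.3, np.nan, 0.2, 0.1]}
        )
        corr = pairwise_pearson(frame)
        assert math.isnan(corr.loc["a", "b"])


class TestGroupedCorrelationTtest:
    def test_identical_groups(self):
        res = grouped_correlation_ttest(
            [0.9, 0.88, 0.89, 0.9, 0.88, 0.89],
            ["x", "x", "x", "y", "y", "y"],
        )
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_matches_hand_welch_computation(self):
        a = np.array([0.9, 0.88, 0.89])
        b = np.array([0.80, 0.82, 0.81])
        res = grouped_correlation_ttest(
            np.concatenate([a, b]), ["a"] * 3 + ["b"] * 3
        )
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        p_hand = 2 * stats.t.sf(abs(t_hand), df_hand)
        assert res.t == pytest.approx(t_hand)
        assert res.p == pytest.approx(p_hand)
        assert res.group_means["a"] == pytest.approx(a.mean())
        assert res.group_sems["b"] == pytest.approx(stats.sem(b))

    def test_single_element_group_rejected(self):
        with pytest.raises(ValueError, match="at least two"):
            grouped_correlation_ttest([0.9, 0.8, 0.7], ["a", "b", "b"])


class TestDeltaBetaConcordance:
    def test_identical_vectors_fully_concordant(self):
        pct, n = delta_beta_concordance([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert pct == pytest.approx(100.0) and n == 3

    def test_half_discordant(self):
        a = np.array([0.1, 0.1, 0.5, 0.5])
        b = np.array([0.3, 0.3, 0.5, 0.5])
        pct, _ = delta_beta_concordance(a, b)
        assert pct == pytest.approx(50.0)

    def test_exact_threshold_counts_discordant(self):
        pct, _ = delta_beta_concordance([0.5], [0.65])
        assert pct == pytest.approx(0.0)

    def test_no_complete_cases(self):
        pct, n = delta_beta_concordance([np.nan], [0.5])
        assert math.isnan(pct) and n == 0


class TestResidualVsGc:
    def test_identical_betas_give_flat_fit(self, rng):
        a = rng.random(50)
        gc = rng.uniform(20, 90, 50)
        fit = residual_vs_gc(a, a, gc)
        assert np.allclose(fit.residuals, 0)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)

    def test_high_gc_overestimation_shows_in_slope_and_bins(self, rng):
        gc = rng.uniform(40, 100, 600)
        truth = rng.random(600) * 0.6 + 0.2
        inflated = truth + 0.1 * (gc > 75)
        fit = residual_vs_gc(inflated, truth, gc)
        assert fit.slope > 0
        high = fit.binned[fit.binned["gc_bin"].apply(lambda b: b.left >= 75)]
        low = fit.binned[fit.binned["gc_bin"].apply(lambda b: b.right <= 75)]
        assert high["mean"].mean() == pytest.approx(0.1, abs=0.02)
        assert low["mean"].mean() == pytest.approx(0.0, abs=0.02)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            residual_vs_gc([0.1, 0.2], [0.1], [50, 60])

    def test_too_few_points_returns_residuals_only(self):
        fit = residual_vs_gc([0.2, 0.4], [0.1, 0.1], [50, 60])
        assert fit.slope is None
        np.testing.assert_allclose(fit.residuals, [0.1, 0.3])


class TestEpicBeta:
    @pytest.mark.parametrize(
        "m, u, expected", [(0, 0, 0.0), (900, 0, 0.9), (100, 100, 1 / 3)]
    )
    def test_examples(self, m, u, expected):
        assert epic_beta(m, u) == pytest.approx(expected)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            epic_beta(-1, 10)

    @given(
        m=st.floats(0, 1e6), u=st.floats(0, 1e6), extra=st.floats(1, 1e4)
    )
    def test_bounded_below_one_and_monotone(self, m, u, extra):
        value = epic_beta(m, u)
        assert 0 <= value < 1
        assert epic_beta(m + extra, u) > value
        assert epic_beta(m, u + extra) <= value


class TestOntCallBeta:
    def test_counts_and_beta(self):
        call = ont_call_beta([0.9, 0.95, 0.1])
        assert call.beta == pytest.approx(2 / 3)
        assert (call.n_meth, call.n_unmeth, call.n_undetermined) == (2, 1, 0)

    def test_all_undetermined_gives_missing_beta(self):
        call = ont_call_beta([0.5, 0.5, 0.5])
        assert math.isnan(call.beta)
        assert call.n_undetermined == 3

    def test_exact_thresholds_are_undetermined(self):
        call = ont_call_beta([0.2, 0.8])
        assert call.n_undetermined == 2

    @given(
        probs=st.lists(st.floats(0, 1), min_size=0, max_size=30)
    )
    def test_read_counts_conserved(self, probs):
        call = ont_call_beta(probs)
        assert call.n_meth + call.n_unmeth + call.n_undetermined == len(probs)

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            ont_call_beta([1.2])


class TestEnrichmentFisher:
    def test_equal_proportions_are_null(self):
        odds, p = enrichment_fisher(1, 2, 2, 4)
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_three_zero_table_enumeration(self):
        # [[3,0],[0,3]]: the only tables as or more extreme are the two
        # perfect splits, each with hypergeometric probability 1/20
        _, p = enrichment_fisher(3, 3, 3, 6)
        assert p == pytest.approx(0.1)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            enrichment_fisher(5, 10, 4, 100)

    def test_matches_hypergeometric_enumeration(self, rng):
        for _ in range(30):
            n_total = int(rng.integers(4, 28))
            n_subset = int(rng.integers(1, n_total))
            k_total = int(rng.integers(0, n_total + 1))
            lo = max(0, k_total - (n_total - n_subset))
            hi = min(n_subset, k_total)
            k_subset = int(rng.integers(lo, hi + 1))
            _, p = enrichment_fisher(k_subset, n_subset, k_total, n_total)
            support = np.arange(lo, hi + 1)
            pmf = stats.hypergeom.pmf(support, n_total, k_total, n_subset)
            observed = stats.hypergeom.pmf(k_subset, n_total, k_total, n_subset)
            p_enum = pmf[pmf <= observed * (1 + 1e-9)].sum()
            assert p == pytest.approx(p_enum, rel=1e-7)


def test_mean_betas_by_method_skips_missing_and_drops_empty():
    samples = [
        SampleInfo("e1", "EM-seq"), SampleInfo("e2", "EM-seq"),
        SampleInfo("w1", "WGBS"), SampleInfo("w2", "WGBS"),
    ]
    idx = pd.MultiIndex.from_tuples(
        [("chr1", 1), ("chr1", 2), ("chr1", 3)], names=["chrom", "pos"]
    )
    beta = pd.DataFrame(
        {
            "e1": [0.2, 0.4, np.nan],
            "e2": [0.4, np.nan, np.nan],
            "w1": [0.6, 0.5, 0.5],
            "w2": [0.8, 0.5, 0.5],
        },
        index=idx,
    )
    table = BetaTable(beta, samples)
    means = mean_betas_by_method(table)
    assert means.loc[("chr1", 1), "EM-seq"] == pytest.approx(0.3)
    assert means.loc[("chr1", 1), "WGBS"] == pytest.approx(0.7)
    assert means.loc[("chr1", 2), "EM-seq"] == pytest.approx(0.4)
    assert np.isnan(means.loc[("chr1", 3), "EM-seq"])
    complete = means.dropna()
    assert list(complete.index.get_level_values("pos")) == [1, 2]
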