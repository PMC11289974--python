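"""Synthetic-data generator: determinism, GC structure, platform biases."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methcompare.concordance import residual_vs_gc
from methcompare.differential import estimate_dispersion, wald_test
from methcompare.simulate import (
    BetaMixture,
    MethodProfile,
    SimulationConfig,
    _window_gc_from_seq,
    biased_beta,
    default_profiles,
    inject_strand_asymmetry,
    simulate_epic_sample,
    simulate_ont_sample,
    simulate_reference,
    simulate_short_read_sample,
    simulate_study,
    simulate_true_methylome,
)
from methcompare.strand import collapse_strands


@pytest.fixture(scope="module")
def small_study():
    cfg = SimulationConfig(genome_length=40_000, n_cpg=400, seed=11,
                           n_replicates=2)
    return simulate_study(cfg)


class TestReference:
    def test_same_seed_is_byte_identical(self):
        cfg = SimulationConfig(genome_length=20_000, n_cpg=100, seed=3)
        seq1, pos1 = simulate_reference(cfg)
        seq2, pos2 = simulate_reference(cfg)
        assert seq1 == seq2
        np.testing.assert_array_equal(pos1, pos2)

    def test_windowed_gc_tracks_flat_profile(self):
        cfg = SimulationConfig(genome_length=100_000, n_cpg=500, seed=5,
                               gc_profile=0.5)
        seq, pos = simulate_reference(cfg)
        gc = _window_gc_from_seq(seq, pos)
        assert np.nanmean(gc) == pytest.approx(50.0, abs=2.0)

    def test_windowed_gc_follows_ramp(self):
        cfg = SimulationConfig(
            genome_length=60_000, n_cpg=300, seed=5,
            gc_profile=lambda x: 0.3 + 0.6 * x,
        )
        seq, pos = simulate_reference(cfg)
        gc = _window_gc_from_seq(seq, pos)
        ok = ~np.isnan(gc)
        r = stats.pearsonr(pos[ok], gc[ok]).statistic
        assert r > 0.9

    def test_planted_cpgs_are_cpgs_spanning_all_motif_bins(self):
        from methcompare.strand import gc_percent

        cfg = SimulationConfig(genome_length=30_000, n_cpg=200, seed=7)
        seq, pos = simulate_reference(cfg)
        motif_gcs = set()
        for p in pos:
            assert seq[p - 1 : p + 1] == "CG"
            motif_gcs.add(gc_percent(seq[p - 4 : p + 4]))
        assert motif_gcs == {25, 37.5, 50, 62.5, 75, 87.5, 100}

    def test_infeasible_cpg_count_rejected(self):
        with pytest.raises(ValueError, match="cannot place"):
            simulate_reference(SimulationConfig(genome_length=500, n_cpg=400))


class TestTrueMethylome:
    def test_pure_high_component_exceeds_half(self):
        cfg = SimulationConfig(beta_mixture=BetaMixture(w_low=0.0), seed=1)
        betas = simulate_true_methylome(cfg, 500)
        assert (betas > 0.5).mean() > 0.95

    def test_symmetric_mixture_centres_on_half(self):
        cfg = SimulationConfig(
            beta_mixture=BetaMixture(w_low=0.5, low=(1, 8), high=(8, 1)),
            seed=2,
        )
        betas = simulate_true_methylome(cfg, 20_000)
        assert betas.mean() == pytest.approx(0.5, abs=0.02)

    def test_bimodality_mass_near_extremes(self):
        cfg = SimulationConfig(seed=3)
        betas = simulate_true_methylome(cfg, 5000)
        assert ((betas < 0.2) | (betas > 0.8)).mean() > 0.5

    def test_seed_reproducibility(self):
        cfg = SimulationConfig(seed=9)
        np.testing.assert_array_equal(
            simulate_true_methylome(cfg, 100), simulate_true_methylome(cfg, 100)
        )


class TestBiasedBeta:
    def test_gamma_zero_is_identity(self):
        beta = np.linspace(0, 1, 11)
        np.testing.assert_allclose(biased_beta(beta, 90.0, 0.0), beta)

    def test_high_gc_inflates_intermediate_beta(self):
        assert biased_beta(0.5, 100.0, 2.0) > 0.5
        # below the pivot the transform is inert
        assert biased_beta(0.5, 60.0, 2.0) == pytest.approx(0.5)

    def test_monotone_in_beta_and_bounded(self):
        beta = np.linspace(0, 1, 101)
        out = biased_beta(beta, 95.0, 3.0)
        assert np.all(np.diff(out) >= 0)
        assert out[0] == 0.0 and out[-1] == 1.0


class TestShortReads:
    def test_unbiased_profile_recovers_truth(self, rng):
        n = 2000
        truth = rng.uniform(0.1, 0.9, n)
        positions = np.arange(100, 100 + 3 * n, 3)
        gc = np.full(n, 50.0)
        profile = MethodProfile(name="EM-seq", base_coverage=40.0)
        report = simulate_short_read_sample(truth, positions, gc, profile, rng)
        sites = collapse_strands(report).set_index("pos").loc[positions]
        ok = sites["coverage"] > 0
        err = (sites.loc[ok, "beta"] - truth[ok.to_numpy()]).mean()
        assert err == pytest.approx(0.0, abs=0.01)

    def test_recovery_bias_inflates_high_gc_betas(self, rng):
        n = 3000
        truth = np.full(n, 0.5)
        positions = np.arange(100, 100 + 3 * n, 3)
        gc = np.full(n, 95.0)
        profile = MethodProfile(name="WGBS", base_coverage=40.0,
                                recovery_bias=2.0)
        report = simulate_short_read_sample(truth, positions, gc, profile, rng)
        sites = collapse_strands(report)
        expected = biased_beta(0.5, 95.0, 2.0)
        assert sites["beta"].mean() == pytest.approx(expected, abs=0.01)
        assert sites["beta"].mean() > 0.55

    def test_wgbs_coverage_drops_at_high_gc(self, rng):
        profiles = default_profiles()
        n = 4000
        truth = np.full(n, 0.5)
        positions = np.arange(100, 100 + 3 * n, 3)
        gc_high = np.full(n, 90.0)
        gc_low = np.full(n, 45.0)
        cov = {}
        for label, gc in (("high", gc_high), ("low", gc_low)):
            report = simulate_short_read_sample(
                truth, positions, gc, profiles["WGBS"], rng
            )
            cov[label] = collapse_strands(report)["coverage"].mean()
        assert cov["high"] < 0.7 * cov["low"]


class TestStrandAsymmetry:
    def _report(self, rng, n=300):
        truth = rng.uniform(0.2, 0.8, n)
        positions = np.arange(50, 50 + 3 * n, 3)
        profile = MethodProfile(name="EM-seq", base_coverage=20.0)
        return simulate_short_read_sample(
            truth, positions, np.full(n, 50.0), profile, rng
        )

    def test_zero_fraction_is_identity(self, rng):
        report = self._report(rng)
        out = inject_strand_asymmetry(report, 0.0, rng)
        pd.testing.assert_frame_equal(out, report)

    def test_full_fraction_confines_every_covered_site(self, rng):
        report = self._report(rng)
        out = inject_strand_asymmetry(report, 1.0, rng)
        sites = collapse_strands(out)
        covered = sites[sites["coverage"] > 0]
        assert np.allclose(covered["evenness"], 1.0)

    def test_total_counts_conserved_per_site(self, rng):
        report = self._report(rng)
        out = inject_strand_asymmetry(report, 0.5, rng)
        before = collapse_strands(report)[["pos", "coverage", "beta"]]
        after = collapse_strands(out)[["pos", "coverage", "beta"]]
        pd.testing.assert_frame_equal(before, after)


def test_epic_betas_strictly_inside_unit_interval(rng):
    truth = np.concatenate([[0.0, 1.0], rng.random(2000)])
    profile = default_profiles()["EPIC"]
    sample = simulate_epic_sample(truth, profile, rng)
    assert (sample["beta"] > 0).all()
    assert (sample["beta"] < 1).all()


def test_ont_coverage_uncorrelated_with_gc(rng):
    n = 10_000
    truth = rng.random(n)
    positions = np.arange(100, 100 + 3 * n, 3)
    profile = MethodProfile(name="ONT", base_coverage=30.0)
    sample = simulate_ont_sample(truth, positions, profile, rng)
    cov = sample.groupby("pos").size().reindex(positions, fill_value=0)
    gc = rng.uniform(20, 95, n)  # any GC labelling: coverage never saw GC
    r = stats.pearsonr(cov.to_numpy(), gc).statistic
    assert abs(r) < 0.05


def test_ont_probabilities_centre_on_truth(rng):
    truth = np.array([0.05, 0.5, 0.95])
    positions = np.array([100, 200, 300])
    profile = MethodProfile(name="ONT", base_coverage=2000.0, ont_noise=0.1)
    sample = simulate_ont_sample(truth, positions, profile, rng)
    means = sample.groupby("pos")["probability"].mean()
    assert means[200] == pytest.approx(0.5, abs=0.02)
    assert (sample["probability"] >= 0).all()
    assert (sample["probability"] <= 1).all()


def test_study_determinism(small_study):
    again = simulate_study(
        SimulationConfig(genome_length=40_000, n_cpg=400, seed=11,
                         n_replicates=2)
    )
    assert again.reference == small_study.reference
    np.testing.assert_array_equal(again.truth, small_study.truth)
    for method in again.short_reads:
        for a, b in zip(again.short_reads[method], small_study.short_reads[method]):
            pd.testing.assert_frame_equal(a, b)
    for a, b in zip(again.epic, small_study.epic):
        pd.testing.assert_frame_equal(a, b)


def test_null_simulation_pvalues_are_uniform(rng):
    """Identical profiles for both groups: Wald p-values should be uniform."""
    n, k = 3000, 4
    truth = rng.uniform(0.2, 0.8, n)
    positions = np.arange(100, 100 + 3 * n, 3)
    gc = np.full(n, 50.0)
    profile = MethodProfile(name="EM-seq", base_coverage=30.0)

    def group():
        meth, cov = [], []
        for _ in range(k):
            rep = collapse_strands(
                simulate_short_read_sample(truth, positions, gc, profile, rng)
            ).set_index("pos").loc[positions]
            meth.append((rep["n_meth_w"] + rep["n_meth_c"]).to_numpy())
            cov.append(rep["coverage"].to_numpy())
        return np.column_stack(meth), np.column_stack(cov)

    m1, n1 = group()
    m2, n2 = group()
    ok = (n1 > 0).all(axis=1) & (n2 > 0).all(axis=1)
    res = wald_test(
        m1[ok], n1[ok], m2[ok], n2[ok],
        estimate_dispersion(m1[ok], n1[ok]), estimate_dispersion(m2[ok], n2[ok]),
    )
    ks = stats.kstest(res["p"], "uniform")
    assert ks.pvalue > 0.01


def test_hockey_stick_residual_pattern_recovered(rng):
    """A recovery-biased library shows positive residuals only above the
    GC pivot when compared against an unbiased one."""
    n = 4000
    truth = rng.uniform(0.2, 0.8, n)
    positions = np.arange(100, 100 + 3 * n, 3)
    gc = rng.uniform(40, 100, n)
    unbiased = MethodProfile(name="EM-seq", base_coverage=60.0)
    biased = MethodProfile(name="WGBS", base_coverage=60.0, recovery_bias=3.0)
    em = collapse_strands(
        simulate_short_read_sample(truth, positions, gc, unbiased, rng)
    ).set_index("pos").loc[positions]
    wg = collapse_strands(
        simulate_short_read_sample(truth, positions, gc, biased, rng)
    ).set_index("pos").loc[positions]
    fit = residual_vs_gc(wg["beta"].to_numpy(), em["beta"].to_numpy(), gc)
    assert fit.slope > 0
    high = gc > 80
    low = gc < 70
    resid = wg["beta"].to_numpy() - em["beta"].to_numpy()
    assert np.nanmean(resid[high]) > 0.02
    assert abs(np.nanmean(resid[low])) < 0.01
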