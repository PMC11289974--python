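"""Cross-platform concordance statistics.

Pairwise Pearson correlation of beta values, grouped correlation
comparisons, delta-beta concordance fractions, residual-versus-GC
regression, array-style beta computation, ONT probability thresholding
and Fisher enrichment — the statistics used to compare EM-seq, WGBS,
EPIC and ONT readouts of the same samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import BetaTable

EPIC_ALPHA = 100.0  # array stabilising constant added to the denominator
ONT_LOW = 0.2  # per-read probability below -> unmethylated
ONT_HIGH = 0.8  # above -> methylated; in between -> undetermined
CONCORDANCE_THRESHOLD = 0.15


def pairwise_pearson(
    table: BetaTable | pd.DataFrame,
    n_sample: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pairwise Pearson correlation of sample beta columns.

    When ``n_sample`` is below the number of positions, one seeded
    subsample of positions is drawn once and reused for every sample
    pair (a few million randomly sampled CpGs represent a genome-wide
    comparison faithfully at a fraction of the cost).  Each pair uses
    its complete cases; pairs with fewer than 3 complete observations
    give NaN.
    """
    beta = table.beta if isinstance(table, BetaTable) else table
    if beta.shape[1] < 2:
        raise ValueError("need at least two samples")
    if n_sample is not None and n_sample < len(beta):
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(beta), size=n_sample, replace=False))
        beta = beta.iloc[idx]
    corr = beta.corr(method="pearson", min_periods=3)
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass
class GroupedCorrelationResult:
    """Per-group correlation summaries and a Welch two-tailed t-test."""

    group_means: dict
    group_sems: dict
    t: float
    p: float
    degenerate: bool = False


def grouped_correlation_ttest(
    values, labels, fisher_z: bool = False
) -> GroupedCorrelationResult:
    """Compare two groups of correlation coefficients.

    Reports per-group mean +/- s.e.m. and a Welch (unequal-variance)
    two-tailed t-test.  The test is run on raw r values by default;
    ``fisher_z=True`` applies the variance-stabilising arctanh
    transform before testing (the summaries stay on the r scale).
    Groups with fewer than two values are an error; a zero-variance
    group is flagged as degenerate.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {list(uniq)}")
    a = values[labels == uniq[0]]
    b = values[labels == uniq[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    ta, tb = (np.arctanh(a), np.arctanh(b)) if fisher_z else (a, b)
    if np.allclose(ta, tb.mean()) and np.allclose(tb, ta.mean()):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(ta, tb, equal_var=False)
    degenerate = bool(np.var(a) == 0 or np.var(b) == 0)
    return GroupedCorrelationResult(
        group_means={uniq[0]: float(a.mean()), uniq[1]: float(b.mean())},
        group_sems={
            uniq[0]: float(stats.sem(a)),
            uniq[1]: float(stats.sem(b)),
        },
        t=float(t),
        p=float(p),
        degenerate=degenerate,
    )


def delta_beta_concordance(
    a, b, threshold: float = CONCORDANCE_THRESHOLD
) -> tuple[float, int]:
    """Percent of complete-case positions with |a - b| strictly < threshold.

    Returns (percent, n_complete); percent is NaN with no complete case.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("beta vectors must be aligned")
    ok = ~np.isnan(a) & ~np.isnan(b)
    n = int(ok.sum())
    if n == 0:
        return math.nan, 0
    frac = np.mean(np.abs(a[ok] - b[ok]) < threshold)
    return 100.0 * float(frac), n


@dataclass
class ResidualFit:
    """Residuals of one method against another, regressed on local GC%."""

    residuals: np.ndarray
    gc: np.ndarray
    slope: float | None
    intercept: float | None
    binned: pd.DataFrame = field(default_factory=pd.DataFrame)


def residual_vs_gc(a, b, gc, bin_width: float = 5.0) -> ResidualFit:
    """Per-position residual (a - b) against local GC%, with an OLS line.

    A flat line near the origin means the two methods agree regardless
    of GC context; a positive slope driven by high-GC bins is the
    fingerprint of a GC-dependent bias in method ``a`` relative to
    ``b``.  Also summarises the mean residual within GC% bins of
    ``bin_width``.  Fewer than 3 complete points: residuals only.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    gc = np.asarray(gc, dtype=float)
    if not (a.shape == b.shape == gc.shape):
        raise ValueError("betas and GC values must be aligned")
    ok = ~np.isnan(a) & ~np.isnan(b) & ~np.isnan(gc)
    resid = a[ok] - b[ok]
    gc_ok = gc[ok]
    slope = intercept = None
    if len(resid) >= 3 and np.ptp(gc_ok) > 0:
        fit = stats.linregress(gc_ok, resid)
        slope, intercept = float(fit.slope), float(fit.intercept)
    elif len(resid) >= 3:
        slope, intercept = 0.0, float(resid.mean())
    binned = pd.DataFrame()
    if len(resid):
        edges = np.arange(0, 100 + bin_width, bin_width)
        bins = pd.cut(gc_ok, edges, include_lowest=True)
        binned = (
            pd.DataFrame({"gc_bin": bins, "residual": resid})
            .groupby("gc_bin", observed=True)["residual"]
            .agg(["mean", "count"])
            .reset_index()
        )
    return ResidualFit(
        residuals=resid, gc=gc_ok, slope=slope, intercept=intercept, binned=binned
    )


def epic_beta(m_intensity, u_intensity, alpha: float = EPIC_ALPHA):
    """Array beta from methylated/unmethylated fluorescence intensities.

    beta = M / (M + U + alpha).  The stabilising constant ``alpha``
    (default 100) prevents division by zero but means the array can
    never report a beta of exactly 1.
    """
    m = np.asarray(m_intensity, dtype=float)
    u = np.asarray(u_intensity, dtype=float)
    if np.any(m < 0) or np.any(u < 0):
        raise ValueError("intensities must be non-negative")
    out = m / (m + u + alpha)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class OntCall:
    """Threshold-based beta from per-read methylation probabilities."""

    beta: float
    n_meth: int
    n_unmeth: int
    n_undetermined: int


def ont_call_beta(
    probabilities, low: float = ONT_LOW, high: float = ONT_HIGH
) -> OntCall:
    """Call a beta from per-read modified-base probabilities at one site.

    Reads with p strictly below ``low`` count as unmethylated, strictly
    above ``high`` as methylated; everything else (including values
    exactly at a threshold) is undetermined and excluded from the beta.
    """
    p = np.asarray(probabilities, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    n_unmeth = int(np.sum(p < low))
    n_meth = int(np.sum(p > high))
    n_undet = p.size - n_meth - n_unmeth
    determinate = n_meth + n_unmeth
    beta = n_meth / determinate if determinate else math.nan
    return OntCall(beta, n_meth, n_unmeth, n_undet)


def enrichment_fisher(
    k_subset: int,
    n_subset: int,
    k_total: int,
    n_total: int,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Fisher's exact test of enrichment of a trait in a subset.

    The 2x2 table contrasts the subset against its complement:
    ``[[k_subset, n_subset - k_subset],
       [k_total - k_subset, (n_total - n_subset) - (k_total - k_subset)]]``.
    Returns (odds ratio, exact p).  The default is two-sided (summing
    hypergeometric probabilities no larger than the observed table's);
    pass ``alternative="greater"`` for the directional enrichment
    hypothesis.
    """
    if k_subset > n_subset or k_total > n_total:
        raise ValueError("counts cannot exceed their totals")
    table = [
        [k_subset, n_subset - k_subset],
        [k_total - k_subset, (n_total - n_subset) - (k_total - k_subset)],
    ]
    if min(min(row) for row in table) < 0:
        raise ValueError(f"negative cell in contingency table {table}")
    odds, p = stats.fisher_exact(table, alternative=alternative)
    return float(odds), float(p)


def mean_betas_by_method(table: BetaTable) -> pd.DataFrame:
    """Per-method mean beta at each position (unweighted across samples).

    Missing replicate betas are skipped; a position where every sample
    of a method is missing gets NaN for that method.  Use
    ``.dropna()`` on the result for joint cross-method comparisons.
    """
    methods = table.methods()
    out = {}
    for method in pd.unique(methods):
        cols = methods.index[methods == method]
        out[method] = table.beta[cols].mean(axis=1)
    return pd.DataFrame(out, index=table.beta.index)
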