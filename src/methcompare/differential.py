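"""Per-CpG two-group differential methylation testing.

Counts are modelled per site and group with a beta-binomial: replicate
``i`` contributes ``m_i`` methylated calls out of ``N_i`` reads, with
group mean methylation ``mu`` and dispersion ``phi`` so that
``Var(m_i/N_i) = mu (1 - mu) (1 + (N_i - 1) phi) / N_i``.  Site-level
dispersions are estimated by method of moments and shrunk toward a
genome-wide log-normal prior fitted across sites (an empirical-Bayes
hierarchical scheme); a Wald test then compares the two group means at
every site.  No smoothing or coverage cut-off is applied inside the
test itself — coverage filtering is an explicit, separate step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PHI_FLOOR = 1e-4  # truncation floor for raw moment dispersions
P_FLOOR = 1e-300  # numerical floor when a zero-variance contrast differs


def coverage_filter(
    coverage: pd.DataFrame, min_cov: int = 5, min_samples: int = 3
) -> pd.Index:
    """Positions where >= ``min_samples`` samples reach ``min_cov`` reads.

    ``coverage`` is positions x samples for one method group; the filter
    is evaluated independently per group (the genome-wide three-way
    analysis keeps positions covered >= 5 times in 3 of 4 samples of
    each short-read method).
    """
    if min_samples > coverage.shape[1]:
        raise ValueError(
            f"min_samples={min_samples} exceeds the {coverage.shape[1]} "
            "samples supplied"
        )
    ok = (coverage.fillna(0) >= min_cov).sum(axis=1) >= min_samples
    return coverage.index[ok]


def site_dispersion_mom(n_meth: np.ndarray, coverage: np.ndarray) -> np.ndarray:
    """Raw method-of-moments beta-binomial dispersion per site.

    ``n_meth`` and ``coverage`` are (sites, replicates) arrays; zero
    coverage marks a missing replicate.  Sites with fewer than two
    covered replicates, or with pooled proportion exactly 0 or 1, give
    NaN (no information about overdispersion).  Estimates can be
    negative by sampling noise; they are kept signed so averaging and
    shrinkage stay unbiased, and only the final shrunk dispersion is
    clipped at zero.
    """
    n_meth = np.asarray(n_meth, dtype=float)
    coverage = np.asarray(coverage, dtype=float)
    covered = coverage > 0
    k = covered.sum(axis=1)
    tot_m = np.where(covered, n_meth, 0.0).sum(axis=1)
    tot_n = np.where(covered, coverage, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_bar = np.where(tot_n > 0, tot_m / np.maximum(tot_n, 1), np.nan)
        p_rep = np.where(covered, n_meth / np.maximum(coverage, 1), np.nan)
        # centre on the unweighted replicate mean: then E[s2] is exactly
        # pq * mean_j[(1 + (N_j - 1) phi) / N_j], the relation inverted below
        p_unw = np.nansum(p_rep, axis=1) / np.where(k > 0, k, np.nan)
        s2 = np.nansum((p_rep - p_unw[:, None]) ** 2, axis=1) / np.maximum(
            k - 1, 1
        )
        inv_n = np.where(covered, 1.0 / np.maximum(coverage, 1), 0.0)
        mean_inv_n = inv_n.sum(axis=1) / np.where(k > 0, k, np.nan)
        pq = p_bar * (1 - p_bar)
        phi = (s2 / pq - mean_inv_n) / (1 - mean_inv_n)
    return np.where((k >= 2) & (pq > 0), phi, np.nan)


@dataclass(frozen=True)
class DispersionPrior:
    """Log-normal prior over site dispersions, fitted by moments."""

    log_mean: float
    log_var: float

    @property
    def mean(self) -> float:
        return float(np.exp(self.log_mean + self.log_var / 2))

    @property
    def var(self) -> float:
        return float(self.mean**2 * np.expm1(self.log_var))


def fit_dispersion_prior(
    phi_raw: np.ndarray, floor: float = PHI_FLOOR
) -> DispersionPrior:
    """Fit the genome-wide log-normal dispersion prior by moments.

    The prior is matched to the arithmetic mean and variance of the
    raw (signed) moment estimates, with the mean truncated at
    ``floor`` — raw estimates go negative by sampling noise, and
    averaging them before truncating keeps the prior mean unbiased on
    the raw-estimate scale.
    """
    phi = np.asarray(phi_raw, dtype=float)
    phi = phi[np.isfinite(phi)]
    if phi.size == 0:
        raise ValueError("no finite dispersion estimates to fit a prior")
    m = max(float(np.mean(phi)), floor)
    v = float(np.var(phi))
    # log-normal moment match: mean = exp(mu + s2/2), var = mean^2 (e^{s2}-1)
    log_var = float(np.log1p(v / m**2)) if v > 0 else 0.0
    log_mean = float(np.log(m) - log_var / 2)
    return DispersionPrior(log_mean=log_mean, log_var=log_var)


def estimate_dispersion(
    n_meth: np.ndarray,
    coverage: np.ndarray,
    prior: DispersionPrior | None = None,
    floor: float = PHI_FLOOR,
) -> np.ndarray:
    """Shrunk per-site dispersions for one group.

    Each site's moment estimate is combined with the prior mean using
    inverse-variance weights: the site weight is the reciprocal of the
    moment estimator's (chi-square, delta-method) sampling variance
    evaluated at the prior mean — evaluating at the prior mean rather
    than the noisy raw value keeps the weights independent of the
    estimate, so the shrunk values stay unbiased on the arithmetic
    scale — and the prior weight is the reciprocal of the fitted
    log-normal's variance.  Sites with a single covered replicate
    return the prior mean; sites with no coverage at all return NaN.
    """
    n_meth = np.asarray(n_meth, dtype=float)
    coverage = np.asarray(coverage, dtype=float)
    phi_raw = site_dispersion_mom(n_meth, coverage)
    if prior is None:
        prior = fit_dispersion_prior(phi_raw, floor=floor)
    k = (coverage > 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        inv_n = np.where(coverage > 0, 1.0 / np.maximum(coverage, 1), 0.0)
        mean_inv_n = inv_n.sum(axis=1) / np.where(k > 0, k, np.nan)
    # s2 ~ pq*c * chi2_{k-1}/(k-1), c = mean(1/N) + (1 - mean(1/N)) phi,
    # so Var(phi_hat) = 2 c^2 / ((k-1) (1 - mean(1/N))^2) at phi = prior mean
    c = mean_inv_n + (1.0 - mean_inv_n) * prior.mean
    v_site = 2.0 * c**2 / (np.maximum(k - 1, 1) * (1.0 - mean_inv_n) ** 2)
    w_data = 1.0 / np.maximum(v_site, 1e-12)
    w_prior = 1.0 / max(prior.var, 1e-10)
    phi = (w_data * np.nan_to_num(phi_raw) + w_prior * prior.mean) / (
        w_data + w_prior
    )
    phi = np.where(np.isnan(phi_raw), prior.mean, phi)
    phi = np.maximum(phi, 0.0)
    phi = np.where(k == 0, np.nan, phi)
    return phi


def wald_test(
    m1: np.ndarray,
    n1: np.ndarray,
    m2: np.ndarray,
    n2: np.ndarray,
    phi1: np.ndarray | float,
    phi2: np.ndarray | float,
) -> pd.DataFrame:
    """Beta-binomial Wald test of group mean methylation at each site.

    ``m*``/``n*`` are (sites, replicates) methylated counts and
    coverages.  Group means are pooled, ``mu = sum(m) / sum(N)``, with

        var_g = mu_g (1 - mu_g) * sum_i[N_i (1 + (N_i - 1) phi_g)] / (sum_i N_i)^2

    and ``wald = (mu1 - mu2) / sqrt(var1 + var2)`` referred to the
    standard normal (two-sided).  With ``phi = 0`` and one replicate per
    group this reduces to the unpooled two-proportion z statistic.

    Degenerate sites (zero total variance) give p = 1 when the means
    agree and the numerical floor when they differ; these are flagged
    in the ``degenerate`` column.
    """
    m1, n1 = np.atleast_2d(np.asarray(m1, float)), np.atleast_2d(np.asarray(n1, float))
    m2, n2 = np.atleast_2d(np.asarray(m2, float)), np.atleast_2d(np.asarray(n2, float))
    phi1 = np.broadcast_to(np.asarray(phi1, float), (m1.shape[0],)).copy()
    phi2 = np.broadcast_to(np.asarray(phi2, float), (m2.shape[0],)).copy()
    tot_n1, tot_n2 = n1.sum(axis=1), n2.sum(axis=1)
    if np.any(tot_n1 <= 0) or np.any(tot_n2 <= 0):
        raise ValueError("every site needs total coverage > 0 in both groups")
    mu1 = m1.sum(axis=1) / tot_n1
    mu2 = m2.sum(axis=1) / tot_n2

    def group_var(n, mu, phi):
        eff = (n * (1 + (n - 1) * phi[:, None])).sum(axis=1)
        return mu * (1 - mu) * eff / n.sum(axis=1) ** 2

    var1 = group_var(n1, mu1, phi1)
    var2 = group_var(n2, mu2, phi2)
    se = np.sqrt(var1 + var2)
    delta = mu1 - mu2
    degenerate = se == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        wald = np.where(degenerate, 0.0, delta / np.where(se == 0, 1.0, se))
    p = 2 * stats.norm.sf(np.abs(wald))
    p = np.where(degenerate & (delta != 0), P_FLOOR, p)
    with np.errstate(invalid="ignore"):
        wald = np.where(degenerate & (delta != 0), np.sign(delta) * np.inf, wald)
    p = np.clip(p, P_FLOOR, 1.0)
    return pd.DataFrame(
        {
            "mu1": mu1,
            "mu2": mu2,
            "delta": delta,
            "phi1": phi1,
            "phi2": phi2,
            "wald": wald,
            "p": p,
            "degenerate": degenerate,
        }
    )


def prefilter_delta(
    results: pd.DataFrame, threshold: float = 0.1
) -> tuple[pd.DataFrame, int, int]:
    """Keep sites with |mu1 - mu2| strictly above ``threshold``.

    Applied before testing/FDR to reduce the multiplicity-correction
    penalty.  Returns (subset, n_retained, n_total).
    """
    total = len(results)
    keep = results["delta"].abs() > threshold
    subset = results[keep].reset_index(drop=True)
    return subset, len(subset), total


def adjust_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (order-invariant)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_test(
    m1,
    n1,
    m2,
    n2,
    positions: pd.DataFrame | None = None,
    delta_prefilter: float | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full two-group pipeline: dispersion shrinkage, Wald test, BH FDR.

    ``delta_prefilter`` (e.g. 0.1) restricts FDR correction to sites
    whose group-mean difference exceeds the threshold.  ``significant``
    marks q < ``alpha``.
    """
    phi1 = estimate_dispersion(m1, n1)
    phi2 = estimate_dispersion(m2, n2)
    res = wald_test(m1, n1, m2, n2, phi1, phi2)
    if positions is not None:
        res = pd.concat(
            [positions.reset_index(drop=True)[["chrom", "pos"]], res], axis=1
        )
    if delta_prefilter is not None:
        res, n_kept, n_total = prefilter_delta(res, delta_prefilter)
        res.attrs["prefilter"] = {"retained": n_kept, "total": n_total}
    if len(res):
        res["q"] = adjust_fdr(res["p"])
        res["significant"] = res["q"] < alpha
    else:
        res["q"] = np.nan
        res["significant"] = pd.Series(dtype=bool)
    return res
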