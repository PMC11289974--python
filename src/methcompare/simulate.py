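"""Synthetic methylomes with per-platform readout biases.

Generates a reference sequence with a controllable GC landscape, a
bimodal "true" methylome over planted CpG sites, and per-platform
readouts of that truth:

* short-read counts (EM-seq-like or WGBS-like) with GC-dependent
  coverage, optional preferential recovery of methylated fragments at
  high GC, and optional strand-asymmetric coverage;
* array-style betas computed from fluorescence intensities with a
  background floor and the stabilising constant in the denominator;
* ONT-style per-read methylation probabilities with GC-independent
  coverage.

Every draw flows from one seed, so identical configurations reproduce
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .concordance import epic_beta
from .io import open_text

MOTIF_FLANK = 3
GC_PIVOT = 75.0  # GC% above which bisulphite recovery bias switches on


@dataclass(frozen=True)
class BetaMixture:
    """Two-component beta mixture: mass near 0 and mass near 1.

    Genomic methylomes are strongly bimodal — most CpGs are either
    nearly fully methylated or nearly fully unmethylated.  The default
    puts 70% of sites in the near-1 component, roughly the methylated
    fraction of a typical somatic methylome.
    """

    w_low: float = 0.3
    low: tuple[float, float] = (1.0, 8.0)  # Beta(a, b) near 0
    high: tuple[float, float] = (8.0, 1.0)  # Beta(a, b) near 1

    def __post_init__(self) -> None:
        if not 0 <= self.w_low <= 1:
            raise ValueError("mixture weight must lie in [0, 1]")

    @property
    def w_high(self) -> float:
        return 1.0 - self.w_low


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic genome and true methylome."""

    genome_length: int = 100_000
    gc_profile: float | Callable[[np.ndarray], np.ndarray] = 0.42
    n_cpg: int = 1000
    beta_mixture: BetaMixture = field(default_factory=BetaMixture)
    n_replicates: int = 4
    seed: int = 0
    chrom: str = "chrSim"


@dataclass(frozen=True)
class MethodProfile:
    """Per-platform readout behaviour.

    ``gc_bias`` multiplies the mean coverage as a function of window
    GC% (None = flat).  ``recovery_bias`` (gamma >= 0) is the strength
    of the methylated-fragment recovery advantage above ``gc_pivot``
    GC%: observed methylation odds are multiplied by
    ``w = 1 + gamma * max(0, GC - pivot) / (100 - pivot)``, so gamma = 0
    is exactly unbiased and the distortion is monotone in beta.
    ``strand_asymmetry`` is the fraction of CpGs whose coverage is
    confined to a single random strand.
    """

    name: str
    base_coverage: float = 10.0
    gc_bias: Callable[[np.ndarray], np.ndarray] | None = None
    recovery_bias: float = 0.0
    strand_asymmetry: float = 0.0
    gc_pivot: float = GC_PIVOT
    coverage_dispersion: float = 8.0  # negative-binomial shape; inf -> Poisson
    bio_dispersion: float = 0.02  # beta-binomial dispersion across replicates
    epic_alpha: float = 100.0
    epic_background: float = 50.0  # fluorescence floor (autofluorescence)
    epic_scale: float = 3000.0  # full-signal intensity
    ont_noise: float = 0.15  # sd of per-read probabilities around truth


def _wgbs_gc_bias(gc: np.ndarray) -> np.ndarray:
    """Coverage multiplier for a bisulphite library: strong high-GC dips."""
    gc = np.asarray(gc, dtype=float)
    return np.clip(1.0 - 0.015 * np.maximum(gc - 55.0, 0.0), 0.15, None)


def _emseq_gc_bias(gc: np.ndarray) -> np.ndarray:
    """Coverage multiplier for an enzymatic library: mild extreme-GC dips."""
    gc = np.asarray(gc, dtype=float)
    return np.clip(1.0 - 0.004 * np.maximum(gc - 80.0, 0.0), 0.5, None)


def default_profiles() -> dict[str, MethodProfile]:
    """Profiles emulating the four platforms' qualitative biases."""
    return {
        "EM-seq": MethodProfile(
            name="EM-seq", base_coverage=10.0, gc_bias=_emseq_gc_bias,
            recovery_bias=0.0, strand_asymmetry=0.02,
        ),
        "WGBS": MethodProfile(
            name="WGBS", base_coverage=10.0, gc_bias=_wgbs_gc_bias,
            recovery_bias=2.0, strand_asymmetry=0.02,
        ),
        "EPIC": MethodProfile(name="EPIC", base_coverage=0.0),
        "ONT": MethodProfile(
            name="ONT", base_coverage=30.0, gc_bias=None, recovery_bias=0.0,
        ),
    }


def _gc_fraction_per_base(config: SimulationConfig) -> np.ndarray:
    x = np.arange(config.genome_length)
    if callable(config.gc_profile):
        frac = np.asarray(config.gc_profile(x / max(config.genome_length - 1, 1)),
                          dtype=float)
        frac = np.broadcast_to(frac, (config.genome_length,)).copy()
    else:
        frac = np.full(config.genome_length, float(config.gc_profile))
    if np.any(frac < 0) or np.any(frac > 1):
        raise ValueError("gc_profile must yield fractions in [0, 1]")
    return frac


def simulate_reference(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[str, np.ndarray]:
    """Generate a reference sequence with planted CpG sites.

    Bases are drawn so that windowed GC tracks ``gc_profile``; CpGs are
    planted on an evenly spaced grid away from contig edges.  The six
    flanking motif bases of the first planted CpGs deterministically
    cycle through 0..6 G/C so every motif-GC bin is represented; the
    rest follow the local GC profile.

    Returns (sequence, 1-based Watson-C positions of planted CpGs).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    length = config.genome_length
    frac = _gc_fraction_per_base(config)
    is_gc = rng.random(length) < frac
    strong = rng.random(length) < 0.5
    bases = np.where(is_gc, np.where(strong, ord("G"), ord("C")),
                     np.where(strong, ord("A"), ord("T"))).astype(np.uint8)

    margin = 60  # keep CpGs clear of edges for +/-50 bp windows
    usable = length - 2 * margin
    min_gap = 2 * MOTIF_FLANK + 4
    if config.n_cpg < 1 or usable / max(config.n_cpg, 1) < min_gap:
        raise ValueError(
            f"cannot place {config.n_cpg} CpGs in {length} bp"
        )
    step = usable / config.n_cpg
    positions = (margin + np.floor(step * np.arange(config.n_cpg))
                 + 1).astype(np.int64)  # 1-based Watson C

    for i, pos in enumerate(positions):
        idx = pos - 1
        bases[idx] = ord("C")
        bases[idx + 1] = ord("G")
        flank_idx = np.concatenate(
            [np.arange(idx - MOTIF_FLANK, idx),
             np.arange(idx + 2, idx + 2 + MOTIF_FLANK)]
        )
        if i < 14:  # guarantee all seven motif-GC bins are attainable
            n_gc = i % 7
        else:
            n_gc = rng.binomial(2 * MOTIF_FLANK, frac[idx])
        chosen = rng.choice(2 * MOTIF_FLANK, size=n_gc, replace=False)
        for j, fi in enumerate(flank_idx):
            if j in chosen:
                bases[fi] = ord("G") if rng.random() < 0.5 else ord("C")
            else:
                bases[fi] = ord("A") if rng.random() < 0.5 else ord("T")
    return bases.tobytes().decode("ascii"), positions


def write_fasta(seq: str, path: str | Path, name: str = "chrSim",
                line_width: int = 60) -> None:
    with open_text(path, "wt") as handle:
        handle.write(f">{name}\n")
        for i in range(0, len(seq), line_width):
            handle.write(seq[i : i + line_width] + "\n")


def simulate_true_methylome(
    config: SimulationConfig,
    n_sites: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw per-CpG true betas from the bimodal mixture."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    mix = config.beta_mixture
    low = rng.random(n_sites) < mix.w_low
    out = np.where(
        low,
        rng.beta(*mix.low, size=n_sites),
        rng.beta(*mix.high, size=n_sites),
    )
    return out


def _draw_coverage(
    mean: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Negative-binomial coverage with shape ``dispersion`` (inf=Poisson)."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    if not np.isfinite(dispersion):
        return rng.poisson(mean)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def biased_beta(beta: np.ndarray, gc: np.ndarray, gamma: float,
                pivot: float = GC_PIVOT) -> np.ndarray:
    """Recovery-biased beta: odds multiplied by w = 1 + gamma*(GC-pivot)+/25.

    Models preferential recovery of fully methylated fragments after
    bisulphite treatment in GC-rich contexts; gamma = 0 leaves beta
    untouched and the transform is monotone increasing in beta.
    """
    beta = np.asarray(beta, dtype=float)
    gc = np.asarray(gc, dtype=float)
    w = 1.0 + gamma * np.maximum(gc - pivot, 0.0) / (100.0 - pivot)
    return beta * w / (beta * w + (1.0 - beta))


def simulate_short_read_sample(
    truth: np.ndarray,
    positions: np.ndarray,
    window_gc: np.ndarray,
    profile: MethodProfile,
    rng: np.random.Generator,
    chrom: str = "chrSim",
) -> pd.DataFrame:
    """One short-read library as a stranded CG cytosine-report frame.

    Coverage is negative-binomial with mean
    ``base_coverage * gc_bias(window GC)``, split binomially between
    strands.  The sample's methylation level at each site is a beta
    draw around the recovery-biased truth with dispersion
    ``bio_dispersion`` (biological replicates are not identical), and
    methylated counts are binomial draws from that level.
    ``strand_asymmetry`` then confines the chosen fraction of sites to
    one random strand.
    """
    n = len(truth)
    mult = profile.gc_bias(window_gc) if profile.gc_bias is not None else 1.0
    mean_cov = profile.base_coverage * np.asarray(mult, dtype=float)
    cov = _draw_coverage(
        np.broadcast_to(mean_cov, (n,)), profile.coverage_dispersion, rng
    )
    cov_w = rng.binomial(cov, 0.5)
    cov_c = cov - cov_w
    beta_obs = biased_beta(truth, window_gc, profile.recovery_bias,
                           profile.gc_pivot)
    if profile.bio_dispersion > 0:
        phi = profile.bio_dispersion
        a = np.maximum(beta_obs * (1 - phi) / phi, 1e-6)
        b = np.maximum((1 - beta_obs) * (1 - phi) / phi, 1e-6)
        beta_obs = rng.beta(a, b)
    m_w = rng.binomial(cov_w, beta_obs)
    m_c = rng.binomial(cov_c, beta_obs)
    report = pd.DataFrame(
        {
            "chrom": np.repeat(chrom, 2 * n),
            "pos": np.concatenate([positions, positions + 1]),
            "strand": np.repeat(["+", "-"], n),
            "n_meth": np.concatenate([m_w, m_c]),
            "n_unmeth": np.concatenate([cov_w - m_w, cov_c - m_c]),
            "context": "CG",
            "trinucleotide": "CGN",
        }
    ).sort_values(["pos", "strand"], kind="stable").reset_index(drop=True)
    if profile.strand_asymmetry > 0:
        report = inject_strand_asymmetry(report, profile.strand_asymmetry, rng)
    return report


def inject_strand_asymmetry(
    report: pd.DataFrame,
    fraction: float,
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """Confine a random fraction of CpGs' coverage to one strand.

    For each selected CpG the combined counts of both strands are
    reassigned to one randomly chosen strand; per-site totals are
    conserved, so site betas are unchanged while evenness becomes 1.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    out = report.copy()
    watson_mask = out["strand"].to_numpy() == "+"
    watson = out[watson_mask]
    crick = out[~watson_mask].copy()
    crick_key = crick.set_index(["chrom", crick["pos"] - 1]).index
    watson_key = watson.set_index(["chrom", "pos"]).index
    common = watson_key.intersection(crick_key)
    if fraction == 0 or len(common) == 0:
        return out
    n_pick = int(round(fraction * len(common)))
    picked = common[np.sort(rng.choice(len(common), size=n_pick, replace=False))]
    to_watson = rng.random(n_pick) < 0.5

    w_idx = pd.Series(watson.index, index=watson_key)
    c_idx = pd.Series(crick.index, index=crick_key)
    for (chrom, pos), keep_watson in zip(picked, to_watson):
        wi = w_idx[(chrom, pos)]
        ci = c_idx[(chrom, pos)]
        m = out.at[wi, "n_meth"] + out.at[ci, "n_meth"]
        u = out.at[wi, "n_unmeth"] + out.at[ci, "n_unmeth"]
        keep, drop = (wi, ci) if keep_watson else (ci, wi)
        out.at[keep, "n_meth"], out.at[keep, "n_unmeth"] = m, u
        out.at[drop, "n_meth"], out.at[drop, "n_unmeth"] = 0, 0
    return out


def simulate_epic_sample(
    truth: np.ndarray,
    profile: MethodProfile,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Array-analogue betas from simulated fluorescence intensities.

    Methylated/unmethylated channel intensities are Poisson draws around
    ``truth * epic_scale`` plus a background floor, and the beta uses
    the stabilising constant in the denominator — so simulated array
    betas are always strictly inside (0, 1).
    """
    n = len(truth)
    m = profile.epic_background + rng.poisson(truth * profile.epic_scale, size=n)
    u = profile.epic_background + rng.poisson(
        (1.0 - truth) * profile.epic_scale, size=n
    )
    beta = epic_beta(m, u, alpha=profile.epic_alpha)
    return pd.DataFrame({"m_intensity": m, "u_intensity": u, "beta": beta})


def simulate_ont_sample(
    truth: np.ndarray,
    positions: np.ndarray,
    profile: MethodProfile,
    rng: np.random.Generator,
    chrom: str = "chrSim",
) -> pd.DataFrame:
    """Per-read methylation probabilities for an ONT-style readout.

    Coverage is GC-independent (long reads are unaffected by local GC
    composition); each read's probability is a truncated normal around
    the site's true beta with sd ``ont_noise``.  Returns a long frame
    (chrom, pos, read index, probability).
    """
    cov = _draw_coverage(
        np.full(len(truth), float(profile.base_coverage)),
        profile.coverage_dispersion,
        rng,
    )
    pos_col = np.repeat(positions, cov)
    beta_col = np.repeat(truth, cov)
    sd = max(profile.ont_noise, 1e-9)
    a = (0.0 - beta_col) / sd
    b = (1.0 - beta_col) / sd
    probs = stats.truncnorm.rvs(a, b, loc=beta_col, scale=sd, random_state=rng)
    read_idx = np.concatenate([np.arange(c) for c in cov]) if len(cov) else []
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos_col,
            "read": read_idx,
            "probability": probs,
        }
    )


@dataclass
class SimulatedStudy:
    """Everything one simulated study produces."""

    config: SimulationConfig
    reference: str
    cpg_positions: np.ndarray
    window_gc: np.ndarray
    truth: np.ndarray
    short_reads: dict[str, list[pd.DataFrame]]
    epic: list[pd.DataFrame]
    ont: list[pd.DataFrame]

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.config.chrom,
                "pos": self.cpg_positions,
                "true_beta": self.truth,
                "window_gc": self.window_gc,
            }
        )


def simulate_study(
    config: SimulationConfig,
    profiles: dict[str, MethodProfile] | None = None,
) -> SimulatedStudy:
    """Simulate reference, truth, and per-method replicate readouts.

    All randomness flows from ``config.seed`` through one generator, so
    identical configurations give identical studies.
    """
    profiles = default_profiles() if profiles is None else profiles
    rng = np.random.default_rng(config.seed)
    reference, positions = simulate_reference(config, rng)
    truth = simulate_true_methylome(config, len(positions), rng)

    gc = _window_gc_from_seq(reference, positions, flank=50)

    short_reads: dict[str, list[pd.DataFrame]] = {}
    epic_samples: list[pd.DataFrame] = []
    ont_samples: list[pd.DataFrame] = []
    for name, profile in profiles.items():
        if name in ("EM-seq", "WGBS"):
            short_reads[name] = [
                simulate_short_read_sample(
                    truth, positions, gc, profile, rng, chrom=config.chrom
                )
                for _ in range(config.n_replicates)
            ]
        elif name == "EPIC":
            epic_samples = [
                simulate_epic_sample(truth, profile, rng)
                for _ in range(config.n_replicates)
            ]
        elif name == "ONT":
            ont_samples = [
                simulate_ont_sample(
                    truth, positions, profile, rng, chrom=config.chrom
                )
                for _ in range(config.n_replicates)
            ]
    return SimulatedStudy(
        config=config,
        reference=reference,
        cpg_positions=positions,
        window_gc=gc,
        truth=truth,
        short_reads=short_reads,
        epic=epic_samples,
        ont=ont_samples,
    )


def _window_gc_from_seq(seq: str, positions: np.ndarray, flank: int = 50) -> np.ndarray:
    """Windowed GC% over a plain sequence string (1-based positions)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    gc_mask = (arr == ord("G")) | (arr == ord("C"))
    n_mask = arr == ord("N")
    cum_gc = np.concatenate([[0], np.cumsum(gc_mask)])
    cum_n = np.concatenate([[0], np.cumsum(n_mask)])
    positions = np.asarray(positions, dtype=np.int64)
    lo, hi = positions - flank, positions + flank
    out = np.full(positions.shape, np.nan)
    ok = (lo >= 1) & (hi <= len(arr))
    gc = cum_gc[hi[ok]] - cum_gc[lo[ok] - 1]
    nn = cum_n[hi[ok]] - cum_n[lo[ok] - 1]
    denom = (hi[ok] - lo[ok] + 1) - nn
    out[ok] = np.where(denom > 0, 100.0 * gc / np.maximum(denom, 1), np.nan)
    return out
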