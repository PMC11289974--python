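# Methods

## Scope and data model

All internal coordinates are 1-based inclusive. BED-dialect inputs
(bedMethyl, CpG-island tracks) are converted from 0-based half-open on
read; array position tables can be read with a `zero_based` flag that
adds one, matching the convention of array manifests distributed
0-based. A CpG dinucleotide is keyed by its Watson-strand cytosine
position; the paired Crick cytosine sits one base downstream. Undefined
statistics (delta beta with single-strand coverage, evenness at zero
coverage, GC% of windows running off a contig) propagate as NaN, never
as sentinel numbers, so downstream filters can always distinguish
"zero" from "unknown".

## Strand-symmetry metrics

Evenness is max(cov_W, cov_C)/(cov_W + cov_C): 0.5 for perfectly
balanced strand coverage, 1.0 for single-strand coverage. Absolute
delta beta is |β_W − β_C|, defined only when both strands are covered.
At sites whose coverage is nearly confined to one strand and whose true
methylation is intermediate, the thin strand's beta is almost surely 0
or 1, so E[|Δβ|] approaches the site beta itself — the signature by
which strand-asymmetric coverage masquerades as differential
methylation. No minimum per-strand coverage is imposed on the
strand-specific betas; a strand covered by a single read contributes a
legitimate (if noisy) 0 or 1.

Motifs are the 8-mer from 3 bp upstream of the Watson C to 3 bp
downstream of the G (5′-NNNCGNNN-3′). Because the central CG always
contributes 2 G/C and the six flanking bases contribute 0–6, the motif
GC% takes exactly the seven values 25, 37.5, 50, 62.5, 75, 87.5, 100.
Soft-masked (lowercase) reference bases are uppercased before any
composition operation; motifs containing N get a missing motif GC
rather than a partial value, which would bias the bins. GC% excludes N
from both numerator and denominator.

## GC context and genomic annotation

Local GC context is the GC% of the closed ±50 bp window (101 bp,
centre base included); the flank is configurable. Windows running off
a contig are missing, not truncated. CpG-island annotation is
exclusive — island, shore, or neither — with islands winning over
shores where they abut after merging. The island track itself is an
input; shores default to 2,000 bp each side of a merged island and
promoters to the 1,500 bp upstream of the TSS (strand-aware), both
configurable: these are standard definitions chosen because no single
canonical width exists. Gene-body and promoter labels are independent
booleans, since overlapping genes can place one position in the body of
one gene and the promoter of another.

## Differential testing

Counts are modelled per site and group as beta-binomial:
Var(m_i/N_i) = μ(1−μ)(1+(N_i−1)φ)/N_i over replicates i. The per-site
dispersion is estimated by method of moments: the replicate proportions'
sample variance s² (centred on the unweighted replicate mean, for which
E[s²] = μ(1−μ)·mean_i[(1+(N_i−1)φ)/N_i] holds exactly) is inverted for
φ. Raw estimates are kept signed — truncating negatives at zero before
averaging inflates the mean by ~45% when the true φ is small (0.02) and
makes the downstream test conservative — and only the final shrunk
value is clipped at zero.

Shrinkage is empirical-Bayes: a log-normal prior is moment-matched to
the raw estimates across sites (mean floored at 1e-4), and each site's
estimate is combined with the prior mean using inverse-variance
weights. The site weight uses the chi-square/delta-method sampling
variance of the moment estimator, 2c²/((k−1)(1−m̄)²) with
c = m̄ + (1−m̄)φ_prior and m̄ = mean(1/N_i), evaluated at the *prior*
mean rather than the raw estimate so that the weights are independent
of the estimation noise; weighting by a noise-dependent variance
systematically drags the combined estimate downward. Single-replicate
sites take the prior mean. Under simulation (1,000 sites, 4 replicates
of 30×, φ = 0.1) the mean shrunk estimate recovers the truth within a
few percent, and under a 10,000-site null the Wald p-values are uniform
(KS) with type-I error at the nominal 5% within Monte-Carlo slack.

The Wald statistic uses pooled group means μ_g = Σm/ΣN,
var_g = μ_g(1−μ_g)·Σ[N_i(1+(N_i−1)φ_g)]/(ΣN)², z = (μ₁−μ₂)/√(var₁+var₂),
referred two-sided to the standard normal; with φ = 0 and one replicate
per group this is the unpooled two-proportion z test. Zero-variance
contrasts are flagged: p = 1 when the means agree, the numerical floor
(1e-300) when they differ. No smoothing and no coverage cut-off are
applied inside the test; coverage filtering (default: ≥5× in at least
3 samples, per method group) and the optional |Δβ| > 0.1 prefilter are
explicit separate steps, the prefilter applied before FDR correction to
reduce the multiplicity penalty. FDR is Benjamini–Hochberg; the default
significance cut-off is q < 0.05.

## Concordance statistics

Pairwise Pearson correlations are computed on complete cases per sample
pair; when a subsample size is given, one seeded subsample of positions
is drawn once and shared by all pairs, so differences between entries
are never subsampling artefacts. Group comparisons of correlation
coefficients use Welch's two-tailed t on raw r values by default (an
arctanh option exists but is off, matching how such comparisons are
usually reported). Delta-beta concordance is the percent of complete
cases with |Δβ| strictly below 0.15. The residual analysis regresses
a − b on window GC% (OLS) and summarises mean residuals in 5-point GC
bins; on unbiased data the slope tends to zero, while preferential
recovery of methylated fragments at high GC shows as near-zero
residuals below the pivot and positive residuals above it.

Array betas are m/(m + u + α) with α = 100, so finite intensities can
never reach β = 1. ONT per-read probabilities are thresholded with
strict inequalities — p < 0.2 unmethylated, p > 0.8 methylated,
everything else (including values exactly at a threshold) undetermined
and excluded from the beta; the boundary handling is a deliberate
choice since "0–20% / 20–80%" wording is ambiguous at the joins.
Fisher enrichment builds the 2×2 table as subset versus complement and
defaults to the two-sided exact test; a directional alternative is
available for explicit enrichment hypotheses (for the published
cross-reactive-probe contrast, 20/235 vs 4,805/103,670, only the
directional test crosses p < 0.01 — the two-sided p is 0.0115).

## Multicopy-locus coordinates

`rotate_reference` moves the last `tail_len` bases to the front and
returns an invertible coordinate map ((p−1+t) mod L)+1; rotation by the
complement restores the original. Rotation accepts single-contig FASTA
only, since the use case is a single multicopy locus. Transcription
coordinates map the first `upstream_len` bases to −upstream_len…−1 and
the transcribed region to +1 onward; there is no position 0, so −1 is
adjacent to +1. The deep-coverage mask removes sites below 50× (kept
when equal), appropriate where all platforms exceed several hundred
fold.

## Synthetic-data generator

The generator exists so that every analysis stage can be exercised with
known truth. It emulates, per platform:

* a reference whose windowed GC tracks a configurable profile, with
  CpGs planted on an even grid, their six flanking motif bases cycling
  deterministically through 0–6 G/C for the first fourteen sites so all
  seven motif-GC bins are always represented;
* a bimodal true methylome: a two-component beta mixture, by default
  30% from Beta(1, 8) (near 0) and 70% from Beta(8, 1) (near 1),
  roughly the methylated fraction of a somatic methylome;
* short-read counts with negative-binomial coverage (shape 8 by
  default; Poisson as the dispersion → ∞) whose mean is
  base_coverage × gc_bias(window GC). The default WGBS-like curve loses
  1.5% of coverage per GC point above 55% (floored at 0.15×); the
  EM-seq-like curve only dips mildly beyond 80%. Coverage splits
  binomially between strands;
* methylated-fragment recovery bias as an odds multiplier
  w = 1 + γ·max(0, GC−75)/25 on the true beta, so γ = 0 is exactly
  unbiased, the transform is monotone in β, and the bias switches on at
  the 75% GC pivot (configurable). γ defaults to 2 for the WGBS-like
  profile and 0 elsewhere; no quantitative magnitude is established for
  this bias, so γ is a free parameter;
* between-replicate biological variation: each replicate's methylation
  level is a beta draw around the (bias-distorted) truth with
  dispersion 0.02. Without this the generated replicates would be
  exactly binomial and the differential model's null calibration could
  not hold;
* strand asymmetry: a chosen fraction of CpGs has its combined
  coverage reassigned to one random strand, conserving per-site totals
  (betas unchanged, evenness driven to 1);
* array readouts as Poisson fluorescence intensities around
  truth × 3,000 plus a background floor of 50, pushed through
  m/(m+u+100) — simulated array betas are therefore strictly inside
  (0, 1);
* ONT readouts as per-read truncated-normal probabilities around truth
  (sd 0.15) with GC-independent coverage.

All draws flow from a single seed, so identical configurations are
byte-identical. What the generator does **not** emulate: read-level
sequences and errors, mapping artefacts, conversion-efficiency drift,
cross-reactive array probes, or correlated methylation along the
genome. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not performance on real
libraries.

## Study orchestration and problem sizes

The two pipeline entry points (`run_concordance_study`,
`run_loci_study`) are driven by declarative configs whose thresholds
default to the analysis' canonical values (5× in 3-of-4 coverage,
Δβ > 0.1 prefilter, Δβ < 0.15 concordance, ±50 bp windows, 50× loci
mask, 0.2/0.8 ONT thresholds, array constant 100). Every emitted table
carries the seed and thresholds in header lines, and a JSON manifest
records the full configuration, so re-running a config reproduces
outputs bit-exactly. Default test and example problem sizes —
10⁴–10⁵ bp genomes, 10²–10⁴ CpGs, 4 replicates, hundreds-fold loci
coverage — are chosen so the full analysis runs in seconds while every
statistic still has enough data to be diagnostic; all sizes scale up
through the config.

## Known limitations

* The dispersion shrinkage is an explicit stand-in for the hierarchical
  schemes of dedicated bisulphite DMR packages; it is calibrated under
  the generator's model but has no claim to optimality on real data.
* FASTQ rarefaction holds both mates in memory; it is meant for
  desk-scale fixtures, not billion-read libraries.
* Genomic-context annotation resolves genes, not transcript isoforms;
  the promoter window is a fixed TSS-relative span.
* The two-sided Fisher default can disagree with directional claims in
  the literature; choose the alternative explicitly when the hypothesis
  is one-sided.
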