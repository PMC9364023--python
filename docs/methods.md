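# Methods

## The blink-count mixture model

The core statistical object is the number of *complete* dark intervals
(blinks) a fluorescent spot shows during one fixed-duration kymograph.
Quantum-dot dark-state entries are treated as a memoryless process in time,
so blink counts over a fixed window are Poisson. For a complex carrying two
dots, the spot is dark only when both dots are dark simultaneously; with
independent emitters the joint dark probability is the product of the
marginals, which translates at the level of per-second blink rates into

    rate_dim = rate_mon^2        (rates in blinks/s)

and at the level of per-kymograph expectations, with duration `dur` seconds,

    bl_dim = (bl_mon / dur)^2 * dur.

This link is a hard constraint of the model: `bl_dim` is recomputed from
`bl_mon` at every optimizer step and is never a free parameter. A population
containing both monomers and dimers produces the two-component mixture

    p_blink(n) = alpha * Poisson(n; bl_mon) + (1 - alpha) * Poisson(n; bl_dim),

and `100 * (1 - alpha)` is the percent of molecules that are dimers.

### Fitting

`fit_dual_poisson` fits two percentage histograms of blinks/kymograph
simultaneously with three free parameters: one shared `bl_mon` and one
`alpha` per dataset (the same dots are used in both conditions, so the same
expectations must describe both). The objective is the summed squared
difference between observed and model percentages on the dense count
support 0..max observed, zero-padded between observed values; percentages
(not raw counts) keep the two datasets commensurate. Amplitudes are
constrained to [0, 1] by bounded least squares (trust-region reflective with
an analytic Jacobian), never by post-hoc truncation.

The objective can be multimodal — a nearly-pure dataset is explained equally
well by the monomer branch or by the dimer branch with a rescaled `bl_mon`
(any pure Poisson with mean m is the dimer component of
`bl_mon = sqrt(m * dur)`). Ten multistarts (bl_mon log-spaced over
[0.5, 30], amplitudes cycling 0.1..0.9) are run and the lowest objective
wins; among optima tied within absolute tolerance 1e-9, the smallest
`bl_mon` (the monomer-branch interpretation) is chosen.

R² of the combined fit is `1 - SSE/SST` with SST taken about the grand mean
of all observed percentages across both datasets.

### Uncertainty

The reported dimer-percent standard errors are bootstrap SDs: kymographs are
resampled with replacement within each dataset (default 1,000 replicates,
seeded) and each replicate is re-fit warm-started from the point estimate.
Warm-started single solves were compared against full multistarts on
boundary-heavy resamples; they find the same optima except for rare
branch-swap outliers (~1/300 resamples) that would only inflate the SD, so
the cheap variant is used. Near the `alpha = 0` boundary the bootstrap
distribution is truncated and the SD shrinks; 2-SE intervals there cover
slightly below their nominal ~95% (see Limitations).

A maximum-likelihood fit on raw counts (`fit_mixture_mle`) is provided as a
cross-check utility only; the least-squares percentage fit is the primary
estimator.

## Kymograph analysis

Each frame's intensity profile is fit with
`amplitude * exp(-(x - center)^2 / (2 sigma^2)) + offset` by unbounded
Levenberg–Marquardt with an analytic Jacobian (fast enough for ~10^5 frames
per study). Initialization: center at the argmax pixel, offset at the
median, amplitude at max − median, sigma at 1.5 px, with one restart from
the intensity centroid. Conventions for degenerate cases: a zero-variance
profile returns R² = 0 (no spot → OFF); an outright optimizer failure
returns R² = −inf rather than raising.

Frame classification uses two thresholds with hysteresis: R² < 0.7 is OFF,
R² ≥ 0.9 is ON, and frames in between inherit the nearest preceding
resolved state. When the record *starts* in the intermediate band there is
no preceding state; such frames take the first resolved state that follows,
and an entirely intermediate record is classified ON (no evidence of a
blink). A blink is a maximal OFF run strictly inside the record — OFF runs
touching either end are censored (their true extent is unknown) and not
counted. The simulator's ground-truth blink count applies the identical
boundary rule so the two are directly comparable. Blinks separated by a
single ON frame are not merged.

`track_msd` computes mean-squared displacement over ON-frame positions at
lags 1..n/4, averaging over all frame pairs whose endpoints are both ON.
For steps drawn with variance s² px²/frame the MSD slope is s²·pixel_nm²
per frame (equivalently MSD = 2Dt with D = s²/2); fewer than 10 ON frames
yields an empty, flagged result.

## Two-color stoichiometry

Subunit colors are independent draws from (p_A, p_B); each subunit carries
any label with probability e (default 1). A dimer is dual-colored with
probability `2 p_A p_B e²` — the factor 2 because the two color orders are
distinct outcomes — which is exactly 1/2 in the default equal-color,
fully-labeled case: even complete dimerization shows only 50% dual-colored
spots. `expected_color_distribution` enumerates all categories, removes
invisible (zero-label) entities, and renormalizes. The estimator inverts
the correction, `dimer_fraction = dual_fraction / (2 p_A p_B e²)`, with
binomial error propagation `se = sqrt(p(1-p)/n) / (2 p_A p_B e²)` on pooled
counts. Estimates above 1 are capped at 1 and flagged inconsistent rather
than raising, preserving pipeline flow on noisy small-n data. With e < 1
monomers and dimers have different visibility, so the simple inversion is
approximate; its direction is conservative-upward (lower efficiency
inflates singly-colored species, so the corrected estimate rises). Only
monomers and dimers are modeled — no higher oligomers.

## Spectra

`sum_spectra` and `difference_spectrum` do pointwise arithmetic and refuse
mismatched wavelength grids; resampling is only available through the
explicit `regrid` utility (linear interpolation). The difference is defined
as **mixture − sum**, so an interaction-driven enhancement is positive.
`average_replicates` pools replicate scans pointwise with per-wavelength
standard errors.

`band_enhancement` integrates the difference over a band by the trapezoid
rule and scores it against noise estimated from the out-of-band residuals:
the null SD of the integral is `sd_out * sqrt(sum w_i²)` with w_i the
in-band trapezoid weights, and the resulting Student-t statistic
(df = n_out − 1) is mapped through the t→normal quantile transform. Under
an i.i.d.-normal null the score is therefore an exactly standard-normal
deviate regardless of how few out-of-band points estimate the noise — with
a 21-point excitation scan the uncalibrated t would exceed |2| more than 6%
of the time. Scores beyond the floating-point range of the t CDF are
clamped to ±40. Default bands: 480–520 nm (donor excitation region of the
450–650 nm scan) and 271–291 nm (±10 nm around the 281 nm DNA CD band).

## Synthetic data

The generator emulates the study's acquisition: 60 s kymographs at 10
frames/s with 63.2 nm pixels. Per frame, pixel values are Gaussian read
noise about the background plus Poisson shot noise on the summed
ON-emitter Gaussian profiles. Defaults (48 pixels, PSF sigma 1.5 px, 200
signal photons/frame, background 50 ± 3) were chosen so that ON frames fit
with R² > 0.9 and OFF frames with R² < 0.7 — reproducing the empirical
threshold behavior the analysis relies on, not any particular instrument.
The emitter center performs a reflected 1D Gaussian random walk; the
default step variance 0.2 px²/frame lets a spot explore roughly a
micrometer over 60 s. A dimer's two emitters share one center
(inter-emitter distance ≪ pixel, a single diffraction-limited spot) and
blink independently: dark-state entries are a per-frame Bernoulli process
with probability 1 − exp(−rate·dt) (default rate 0.18 s⁻¹, matching ~10.8
expected blinks/60 s), and dark dwells are geometric with mean 3 frames.

Blink-count samples are drawn directly from the mixture (monomer with
probability alpha, then Poisson with the matching expectation). Dual-color
populations assign each subunit an independent color and label. Spectra are
sums of Gaussian bands with additive Gaussian noise on each returned trace
(defaults 1.0 counts for FRET, 0.15 mdeg for CD); the interaction term is a
band-localized Gaussian whose amplitude is linear in the coupling
coefficient — in the donor band for FRET, at 281 nm for CD, and absent when
the `consensus` flag is off (emulating non-consensus DNA).

What the simulations do *not* contain: camera-specific noise calibration,
Qdot spectral emission, channel registration errors, drift, multiple
independent spots per kymograph, higher oligomers, or real fluorophore
lineshapes. Passing tests therefore demonstrate that the estimators are
correct and calibrated under the stated model assumptions, not that those
assumptions hold for any particular instrument or protein.

## Problem sizes and determinism

Every stochastic routine takes an explicit integer seed and is
bit-reproducible; there is no global random state. The test suite uses the
study-scale designs directly where they are cheap (50 kymographs per
condition, 100 replicate experiments, 1,000 bootstrap replicates, 1,000
null-spectra trials, 200 kymographs for the blink-calling oracle) and
smaller batches for quick unit checks.

## Known limitations

* Near-boundary mixtures (dimer percent ≳ 90) occasionally clamp at 100%
  when a 50-kymograph sample happens to contain almost no monomers; the
  bootstrap SE is then truncated-small, and 2-SE intervals cover below
  nominal for that condition (~93% observed vs 95.4% nominal).
* The least-squares percentage fit is less efficient than maximum
  likelihood; ML is deliberately relegated to a cross-check.
* The dual-color estimator's labeling-efficiency correction ignores the
  differential visibility of monomers vs dimers at e < 1.
* Blink counting censors boundary-touching dark runs, slightly
  undercounting relative to an uncensored renewal process; the simulator's
  ground truth applies the same rule, so comparisons are unbiased.
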