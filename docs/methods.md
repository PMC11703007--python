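# Methods

## Scope and design

`spcpanel` re-implements, as a single seeded pipeline, the quantification
and population analysis of the NMR-derived five-marker inflammatory panel:
two acute-phase glycoprotein windows (GlycA δ 2.05–2.09, GlycB
δ 2.09–2.12 ppm) and the three sub-regions of the Supramolecular
Phospholipid Composite (SPC₁ δ 3.20–3.236, SPC₂ δ 3.236–3.262, SPC₃
δ 3.262–3.30 ppm). Because no cohort data are distributed with the
package, a synthetic-data module generates cohorts and DIRE-like spectra
carrying the statistical structure the analysis is designed to detect; all
tests and the acceptance script run entirely on that layer.

## Spectrum emulation

A spectrum is the sum of one Lorentzian line per marker, a residual-water
Lorentzian at the suppression frequency, a smooth baseline and white
noise, multiplied by the per-sample ERETIC factor. Choices that matter:

* **Lorentzian lineshape** — NMR lines are Lorentzian to first order.
  The model is an emulation, not physics: no diffusion/T₂ editing, field
  inhomogeneity or phase error is simulated.
* **Line half-widths, 0.001 ppm.** Every line must keep ≥ 95% of its area
  inside its own integration window (checked with the Lorentzian CDF at
  config validation). The narrowest window half-extent is 0.013 ppm
  (SPC₂), which forces γ ≤ 0.00102 ppm; the grid bound (half-width
  ≥ 2 × step) forces γ ≥ 0.001. Real composite signals are broader; the
  narrow stand-in is what makes fixed-window summation quantitative at
  the 0.5% level on this grid.
* **Joint non-negative amplitude solve.** Line amplitudes are solved
  against the 5×5 matrix of unit-line window sums computed on the actual
  grid (not the continuous integral), so each window's point-sum equals
  the requested marker value exactly for strictly positive panels.
  Degenerate panels (a zero marker beside a large neighbour) are kept
  non-negative (NNLS); the empty window then reports only Lorentzian tail
  leakage, ~1% of the neighbour for adjacent Glyc windows.
* **Artefacts.** Baseline = quadratic polynomial + three Gaussian humps
  (σ 0.6–2.0 ppm), scaled by `baseline_amplitude` (default 10 A.U.
  against peak heights of ~300–900); residual water height 300 A.U.;
  white noise `noise_sd` = 0.05 A.U./point (processed DIRE spectra of
  these intense composites are high-SNR); ERETIC factor uniform on
  (0.8, 1.25). With these defaults the full artefact stack perturbs
  quantified SPC markers by ≲ 0.4% (bias) ± ~0.2–1% (per-sample).
* **Grid** — 0.40–9.50 ppm at 0.0005 ppm (18 201 points): integer point
  counts per window and desk-scale runtime (~25 ms per spectrum through
  synthesis + preprocessing + integration).

## Preprocessing

Order: ERETIC division → water referencing → baseline subtraction →
exclusion masking. All steps are linear/affine, so the order is
mathematically irrelevant; it is fixed for provenance, and the baseline is
estimated on the full axis so the smoother sees context around the
excluded bands. Referencing finds the water argmax in 4.50–4.90 ppm with
3-point parabolic refinement; an undetectable maximum (prominence below
8 robust SDs of the band) leaves the axis unshifted with a warning flag.
Exclusions: water band closed ([4.50, 4.90]), noise bounds strict
(δ < 0.4, δ > 9.5, so the boundary points are kept).

**ALS baseline.** The baseline is the Whittaker smoother with
second-difference penalty λ and asymmetric weights (p above the running
baseline, 1−p below), iterated 10 times; the pentadiagonal system is
solved by banded Cholesky (cost linear in points, verified against a
dense solver to 1e-8). A linear trend is removed before solving and added
back: linear functions lie in the penalty null space, and detrending
preserves them to machine precision at large λ. Defaults **λ = 1e8,
p = 1e-5**: the asymmetric bump the smoother places under a peak cluster
scales with p times the cluster area (with overshoot from the stiff
penalty), and these values keep that bias under 0.3% of every window
while still tracking baseline structure broader than ~0.05 ppm. Softer
penalties with larger p (e.g. λ = 1e6, p = 1e-3) put several percent of
the peak area into the baseline for lines this tall and narrow, which is
why the defaults sit where they do. The residual trade-off: very small p
makes the smoother treat broad baseline humps it cannot fully track as
"peaks" and carve under them — hence the ≥ 0.6 ppm hump scale in the
generator, matching smoothly varying instrument baselines.

## Quantification conventions

Integrals are raw point-sums over half-open windows [lo, hi): the shared
boundaries (2.09, 3.236, 3.262 ppm) belong to the upper window only, so
the SPC windows tile [3.20, 3.30) exactly and SPC total equals the
one-shot band integral. Point-sums make the A.U. grid-dependent; the
pipeline therefore refuses to mix grids within a cohort. Negative
integrals (possible under noise) are flagged, not clipped, preserving
rank-test validity. The SPC/Glyc ratio uses GlycA + GlycB as denominator
and is NaN (flagged) when that total is not positive.

## Cohort generator

* **Marginals** — markers are positive and right-skewed, so log-normal
  with the stratum median as scale parameter. Log-scale SDs: 0.15 for the
  SPC sub-regions (IQR/median ≈ 20%, typical of HDL/LDL lipid measures)
  and 0.25/0.22 for GlycA/GlycB (acute-phase signals are more dispersed).
  No dispersion values were available to calibrate against; these are
  free parameters chosen once.
* **Stratum medians** — full-population SPC₂ medians fall with BMI class
  with a large female excess (normal weight 5123.65/6837.86 A.U.
  male/female; overweight 4609.95/6136.34; obese 4085.73/5502.43); SPC₁
  is nearly flat (obese 3221.94/3362.88); SPC₃ ≈ SPC₂/5; GlycA/GlycB
  rise with BMI, GlycB with a female excess. The healthy-reference preset
  uses age- and BMI-flat medians with a uniform 33.7% female excess in
  SPC₂ and no obese class, and pooled medians keeping SPC₂ ≈ 2× SPC₁ and
  ≈ 5× SPC₃.
* **Repeated measures** — two timepoints per participant, five years
  apart, share a participant-level random intercept (ICC 0.5), so the
  pooled-vs-first-timepoint question is exercisable
  (`--first-timepoint-only`).
* **Copula** — marker values are converted to rank-based normal scores;
  each lipoprotein fraction's latent is a linear combination of the
  relevant scores with coefficients solved from the empirical score
  correlations against latent targets inverted via the bivariate
  log-normal correlation formula. Residual mismatch from the
  mixture-of-lognormals marginals is ≤ ~0.01. HDL1-3 is split into
  HDL1/2/3 by a Dirichlet draw and re-summed so the total is exactly the
  sum of its parts.
* **Cohort composition** — 1976 population participants × 2 timepoints
  − 7 missed follow-ups + 80 single-visit reference participants = 4025
  samples (healthy preset: 1960 × 2 + 80 = 4000). BMI class weights
  0.002/0.37/0.40/0.228 give a handful of underweight samples (removed
  from the BMI figures) and healthy-flag rates are set so the healthy
  filter retains roughly one population participant in ten.

What the generator does **not** emulate: real acquisition physics,
chemical-shift drift between samples, non-Lorentzian composite
lineshapes, age trends within the healthy reference, missingness other
than the missed follow-ups, or any real-data covariance beyond the
configured copula targets. Passing tests therefore demonstrate that the
pipeline recovers known structure through the full spectral round trip —
not that it would reproduce any particular real cohort.

## Statistics

* Mann–Whitney tests are two-sided with midranks; p is exact (full
  enumeration) when the smaller group has ≤ 8 observations and no ties,
  otherwise normal approximation with tie and continuity corrections
  (scipy). Which variant the original in-house analysis used is not
  documented; at cohort sizes here the two agree to < 0.02.
* The BH family is the set of strata within one marker × one analysis
  (age-sex figure, BMI-sex figure, or the successive-BMI-pair family in
  the sex-adjusted analysis).
* Sex adjustment is OLS residualisation on a sex indicator with the grand
  mean added back — equivalent to shifting each sex by a constant, so
  within-sex ranks are untouched and post-adjustment sex means coincide.
* Star annotation: * < 0.05, ** < 0.01, *** < 0.001 (age-sex analysis),
  plus **** < 0.0001 in the BMI analyses.
* BMI classes partition at 18.5/25/30 with 30.0 assigned to obese (the
  healthy filter uses BMI < 30). Ages outside [20, 70] are excluded from
  age-stratified analyses only.

## Problem sizes and determinism

The acceptance script and the heavy tests run both preset cohorts
(4025 + 4000 samples, 18 201-point spectra) through the complete round
trip, about two minutes each on one CPU. All randomness flows from one
integer seed through `numpy` SeedSequence spawning (one child per
sample), so any subset of spectra is reproducible and identical seeds
give byte-identical outputs.

## Known limitations

* A.U. are tied to the default grid; comparing cohorts quantified on
  different grids is refused rather than rescaled.
* The copula calibrates pairwise Pearson targets only; higher-order
  dependence between markers and fractions is whatever the Gaussian
  copula implies.
* The healthy filter's condition flags are Bernoulli/Poisson caricatures;
  they exist to exercise the filter, not to model comorbidity structure.
* With `p = 1e-5` the ALS baseline sits ~2–3 noise SDs below zero in
  signal-free regions, adding a small positive, window-width-proportional
  offset to every integral (≲ 0.2 A.U./point at default noise). This is
  inherent to asymmetric baselines under noise and is part of the ≲ 1%
  net bias budget above.
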