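# Methods

## The synthetic cohort model

Each simulated plasma spectrum is a sum over metabolites of Lorentzian
multiplets on a fixed frequency-domain grid (δ 0.50–9.00 ppm, spacing
10⁻³ ppm, 700 MHz for Hz↔ppm conversion), plus a smooth quadratic
baseline and i.i.d. Gaussian noise:

    y(δ) = Σ_m  s_m · Σ_lines  a · w · γ² / (γ² + (δ − δ₀)²)  + b(δ) + ε

Multiplet geometry follows first-order coupling rules: a doublet is two
equal lines split by J; a triplet 1:2:1 at spacing J; a quartet 1:3:3:1;
a doublet-of-doublets four equal lines (second splitting J/2 when only
one coupling is given); singlets, multiplets and broad envelopes render
as a single line with the template's linewidth.  `relative_amplitude`
is the tallest-component height at unit concentration, taken from the
published median signal-to-noise heights of the assigned plasma
resonances; the integrated multiplet area is therefore proportional to
concentration × amplitude.  Sharp lines use a 0.002 ppm FWHM (≈1.4 Hz),
unresolved multiplets 0.004 ppm, and macromolecular envelopes
0.020–0.025 ppm — the narrow end of the plausible 0.02–0.05 ppm range,
chosen so that envelope tails do not dominate neighbouring sharp-signal
windows.  Three panel metabolites lack a published resonance row
(3-aminoisobutyrate, threonine, glutamate); templates at literature
shifts were added, including a second 3-AIB resonance at δ 2.60 because
its methyl doublet at δ 1.19 is unresolvable inside the lipoprotein
CH₂ envelope.

Per-sample concentration multipliers are lognormal with configurable
within-group coefficient of variation (default 0.15, a conservative
global figure consistent with the ~11 % reported for creatinine in the
patient group) and group means calibrated as below.  Ages and genders
are drawn per group (HC 18–54 y, 25 % male; GM1T2 3–20 y, 40 % male)
and by default exert **no** effect on intensities, matching the
partial-RDA finding that age and gender contribute nothing once disease
is accounted for.  Optional outlier profiles inflate all of a sample's
multipliers five-fold — an arbitrary stand-in, since the removed real
outlier's spectral appearance was never described.  The baseline level
defaults to 12 intensity units with ±20 % smooth per-sample variation,
standing in for the residual macromolecule background of CPMG plasma
profiles; the noise SD defaults to 0.5, which reproduces the published
signal-to-noise magnitudes given the template heights.

## Planting effect sizes

Published fold-changes are ratios of group means of *normalized*
intensities, so they cannot simply be applied to raw concentrations:
diagnostic windows overlap neighbouring resonances, and the constant
sum couples every region to the case group's total spectral mass.  The
generator therefore solves, once per cohort specification, a small
linear system for the case-group mean multipliers μ:

- **CS basis** — for each planted metabolite m with target ratio F_m,
  E[window_m(μ)] = F_m · E[window_m(1)] · (T(μ)/T(1)), where T is the
  total over the active (water-excluded) region; background metabolites
  keep μ = 1 and the total-mass ratio enters linearly because T is
  linear in μ.
- **Ile basis** — ratios are planted on raw window ratios relative to
  the isoleucine-CH₃ window (δ 0.988–1.008), whose multiplier is fixed
  at 1; the constant sum cancels.

Solved multipliers generally differ from the planted ratios (lactate at
a planted CS ratio of 4.19 needs μ ≈ 5–7 depending on the panel) — the
point is that the *measured* ratio comes out right in expectation.  A
planted panel is rejected (with an error) if the solution requires a
non-positive concentration; with the bundled template library the full
25-metabolite published panel is feasible.  The residual bias of the
whole simulate→bucket→normalize→estimate loop is below ~2 % (dominated
by ratio-of-means convexity terms of order CV²), comfortably inside the
5 % recovery band the acceptance checks use.

## Preprocessing choices

**Intelligent bucketing** starts from a uniform nominal grid (default
0.04 ppm over δ 0.5–9.0) and moves every interior boundary to the
deepest point of the cohort mean spectrum within ±0.02 ppm, subject to
all bucket widths staying within nominal ± tolerance.  The mean
spectrum is first smoothed with a ±0.005 ppm moving average so that
boundaries track genuine inter-peak valleys rather than noise dips or
the valleys inside J-coupled multiplets (line spacings ≲ 0.011 ppm at
700 MHz); ties resolve to the smallest displacement, then the lower
ppm, so a flat spectrum keeps its nominal grid.  Bucket values are
trapezoidal integrals.

**Targeted (Model 2) panel.**  The 25 targeted intensities integrate
*fixed* diagnostic windows (see `DEFAULT_MODEL2_INTERVALS`) rather than
whichever variable bucket happens to contain a shift: in the congested
branched-chain amino-acid region (valine δ 0.98/1.03, isoleucine
δ 0.926/0.997, leucine δ 0.949) bucket composition is not stable under
boundary snapping, whereas fixed windows make the targeted values —
and hence fold-change estimates — reproducible.  CS normalization of
the panel still divides by each sample's total over the bucket table's
active buckets.  A bucket-annotation variant (`build_model2`) maps
shifts to containing buckets for users who want strictly bucket-based
panels.

**Normalization and scaling.**  CS normalization scales each sample's
active buckets to sum to 1 (the constant is arbitrary; it cancels in
every downstream statistic).  Ile normalization divides raw intensities
by the isoleucine-CH₃ value (δ 0.997), reported as exactly 1 for the
reference itself.  The generalized logarithm uses base 2 with
λ defaulting to the squared minimum positive intensity; Pareto scaling
mean-centres and divides by √SD, zeroing constant features with a
warning.  Noise-only buckets are auto-excluded when their median
STN = 2.50·A/N_pp falls below 10 (the LLOQ rule: signal under ten times
the noise level); the published analysis gives no explicit noise-region
list, so this rule is a stand-in and manual region lists override it.

## Statistical conventions

- Welch's t with Welch–Satterthwaite df throughout; both group
  variances zero with equal means yields p = 1 by convention.
  Bonferroni multiplies by the active feature count of the model under
  test and caps at 1.
- Fold-change CIs: first-order Taylor expansion with zero covariance
  (independent cohorts), t quantile on Welch–Satterthwaite df.  Planted
  ratios fall inside the 95 % CI in 93–97 % of replicates at the study's
  group sizes (verified by simulation).
- All permutation p-values use the add-one convention
  p = (1 + #{null ≥ obs})/(n_perm + 1), so p ≥ 1/(n_perm+1) > 0.
- Q² cross-validation defaults to 10-fold (the scheme the published
  10-fold validation used); LOO and repeated 67/33 splits are available
  and the scheme is recorded.  Folds that lose a class are reshuffled
  (error after 100 attempts).
- P-RDA residualizes both the response matrix and the tested design on
  the conditioning factors and permutes reduced-model residuals
  (Freedman–Lane style); no permutation scheme was named in the source
  analysis.
- "Maximum dissimilarity" clustering = complete linkage on Euclidean
  distances.
- OPLS-DA removes a configurable number of orthogonal components
  (default 1) before the single predictive component; S-plot
  coordinates are cov(t, x_j) and corr(t, x_j) on the filtered matrix.
  Whether the original S-plot used Pareto- or unit-variance scaling is
  unstated; this pipeline's default is Pareto.
- Varimax rotation operates on Kaiser (row-)normalized factor loadings
  (loadings × √eigenvalue); communalities are invariant.
- Global-test Q: with standardized columns and centred outcome,
  Q_i = (x_iᵀz)²/(σ̂²·x_iᵀx_i) = n·r_i²; the set statistic is the
  member mean.  Significance is by outcome permutation rather than the
  asymptotic distribution, given the ~37-sample scale.  Holm–Bonferroni
  (a familywise procedure, as cited) adjusts across sets;
  Benjamini–Hochberg is available for correlations.
- Random-forest MDA is permutation importance scored on each repeat's
  held-out third, averaged over repeats (per-tree out-of-bag
  permutation would need non-public scikit-learn internals).  The
  redundancy plateau cut is the largest ratio drop in the sorted MDA
  profile — "little or no change" made quantitative.  Note that fully
  redundant informative features mask one another under any
  permutation importance.
- The SVM "power" kernel, undefined in the source description, is the
  conditionally positive-definite negative-distance kernel
  K(u,v) = −‖u−v‖^β (β = 1 by default).
- AUROC Monte-Carlo CV uses balanced training subsamples (majority
  class undersampled), per-split univariate |t| feature selection (no
  selection leakage), and percentile 95 % intervals across splits.
- Hold-out schemes: n9 = 6 HC + 3 GM1T2 held out with 19/9 inner
  train/test splits, 72 repeats by default (12 for the SVM confirmation
  run); n12 = 9 HC + 3 GM1T2.  The hold-out set is fixed per seed,
  inner splits are redrawn per repeat.

## What the simulations do and do not show

The generator reproduces the *published effect structure* — resonance
positions, multiplicities, relative heights, between-group
fold-changes, group sizes, within-group lognormal variation, an
inflated outlier, and age/gender covariates without intensity effects —
on top of idealized physics: first-order multiplets, no peak-position
drift (pH/ionic-strength shifts), no phasing or baseline-correction
artifacts, no second-order coupling, and independent lognormal
metabolite levels (no physiological correlation structure beyond shared
resonances).  Passing recovery and classification checks therefore
demonstrates that the *pipeline* is unbiased and correctly calibrated
under the stated study conditions, not that real GM1T2 plasma would be
classified with these accuracies; with the published effect sizes the
classification problem is genuinely easy (near-total separation), which
is exactly what the original validation reported.

Problem sizes in the test suite and acceptance script (200 replicate
cohorts for recovery means, 2000 replicates for CI coverage, 99–199
permutations inside null-uniformity checks, reduced forest repeat
counts) were chosen so each check's Monte-Carlo error is small relative
to the tolerance it asserts.

## Known limitations

- Exact published multivariate outputs (loadings tables, Q² values,
  enrichment Q statistics and p-values) depend on the unavailable
  patient spectra and proprietary set libraries; only structural
  properties and planted-truth recovery are asserted.
- The bundled GMT pathway library is a small synthetic stand-in with
  realistic set names and plausible members; real analyses should
  supply real libraries.
- The calibration guarantees expected normalized ratios; second-order
  (CV²-scale) ratio-of-means bias of up to ~2 % remains by design.
- Degenerate designs (a class with fewer than 2 samples, hold-outs
  larger than a class, confounded P-RDA designs) raise errors rather
  than degrading silently.
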