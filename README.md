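# nmrmetab

An untargeted ¹H NMR plasma metabolomics biomarker-discovery pipeline for
case/control studies, built around GM1 gangliosidosis type 2 (GM1T2) — a
lysosomal storage disorder caused by β-galactosidase deficiency — versus
healthy controls (HC).  It is aimed at metabolomics researchers who want a
tested, scriptable re-implementation of the full analysis chain that such
studies run through point-and-click software, plus a synthetic spectrum
generator with known ground truth for validating every stage.

Because patient spectra from such rare-disease cohorts are not publicly
deposited, the package ships a cohort **simulator**: 700 MHz CPMG-style
plasma spectra assembled from Lorentzian multiplet templates (chemical
shift δ, multiplicity, J coupling, linewidth) for the assigned plasma
resonances, with lognormal within-group biological variation, a smooth
baseline and Gaussian noise.  Disease effect sizes are *planted*: the
generator solves a linear system for raw case-group concentration
multipliers so that the expected constant-sum (CS)-normalized — or
isoleucine-normalized — intensity ratio of each metabolite's diagnostic
window equals the requested GM1T2:HC fold-change exactly, accounting for
spectral overlap and the constant-sum coupling.

## The analysis chain

- **Preprocessing** (`nmrmetab.preprocess`): intelligent bucketing
  (0.04 ± 0.02 ppm buckets whose boundaries snap between peaks), exclusion
  of the residual water region (δ 4.7–4.9) and noise-only buckets
  (signal-to-noise STN = 2.50·A/N_pp below the LLOQ rule), CS
  normalization, reference-metabolite (Ile-CH₃, δ 0.997) normalization,
  the generalized logarithm g(x) = log₂((x + √(x²+λ))/2), Pareto scaling
  (x−x̄)/√s, and the targeted 25-metabolite "Model 2" panel.
- **Univariate screening** (`nmrmetab.univariate`): Welch's
  unequal-variance t test with Bonferroni correction; fold-changes
  R = ȳ/x̄ with first-order Taylor-expansion (delta-method) standard
  errors, Var(R) ≈ R²(s²_y/(n_y ȳ²) + s²_x/(n_x x̄²)), and t-based 95 %
  CIs on Welch–Satterthwaite degrees of freedom; comparison against
  reference fold-changes; Pearson correlations with BH adjustment.
- **Multivariate modelling** (`nmrmetab.multivariate`): PCA with optional
  Varimax rotation and Kaiser normalization, Hotelling-T² outlier
  detection, PLS-DA with VIP scores (mean VIP² = 1), cross-validated
  Q² = 1 − PRESS/TSS (LOO, 10-fold, or repeated 67/33 splits), label
  permutation tests, OPLS-DA with the p(corr)[1]-vs-p[1] S-plot, partial
  redundancy analysis (P-RDA) permutation tests for disease/age/gender,
  and complete-linkage hierarchical clustering.
- **Classifier validation** (`nmrmetab.ml`): random forest
  (ntree = 1000, mtry = 7) with mean-decrease-in-accuracy ranking and
  plateau pruning, SMO-style SVM (C = 1.0, tolerance 10⁻³, linear kernel
  by default), Monte-Carlo cross-validated AUROC panels with per-split
  feature selection, and the stratified hold-out schemes (n = 9: 6 HC +
  3 GM1T2; n = 12: 9 HC + 3 GM1T2).
- **Enrichment** (`nmrmetab.enrichment`): quantitative metabolite set
  enrichment with a global-test Q statistic per metabolite (Q_i = n·r²_i
  for standardized columns), set Q as the member mean, permutation
  p-values and Holm–Bonferroni adjustment, against GMT set libraries.

## Worked example

```python
import numpy as np
from nmrmetab import synth, preprocess as pp, univariate as uv, multivariate as mv
from nmrmetab.effects import FOLD_CHANGES_CS

sim = synth.CohortSimulator()
spec = synth.CohortSpec(n_control=28, n_case=9,
                        fold_changes=FOLD_CHANGES_CS, seed=42)
spectra, truth = sim.simulate(spec)

table = pp.exclude_regions(pp.intelligent_bucket(spectra))
panel = pp.targeted_panel(spectra, table, values="cs")
print(uv.screen(panel).loc[["Lactate", "Creatinine", "Valine", "Total TAGs"],
                           ["direction", "fold_change", "ci_lo", "ci_hi", "p_bonf"]])

scaled = pp.pareto_scale(pp.glog_transform(panel))
q2 = mv.cross_validate_q2(scaled, scaled.groups, scheme="kfold10",
                          rng=np.random.default_rng(0))
obs, p, _ = mv.permutation_test(scaled, scaled.groups, n_perm=199,
                                rng=np.random.default_rng(0))
print(f"PLS-DA Q2 = {q2:.3f} (permutation p = {p:.4f})")
```

prints

```
           direction  fold_change   ci_lo   ci_hi  p_bonf
feature
Lactate           up       4.2168  3.6525  4.7812  0.0000
Creatinine        up       2.8442  2.5835  3.1048  0.0000
Valine            up       2.3633  2.1167  2.6098  0.0000
Total TAGs      down       0.8071  0.7219  0.8922  0.0088

PLS-DA Q2 = 0.986 (permutation p = 0.0050)
```

One simulated 28-vs-9 cohort carries the full published effect panel;
the screen recovers the planted up-regulations of lactate, creatinine
and valine and the down-regulated lipoprotein triacylglycerols (this
single replicate scatters around the planted 4.19 / 2.65 / 2.10 / 0.75),
and the cross-validated PLS-DA Q² far exceeds the common ≥ 0.50
model-merit cut-off with a significant label-permutation p.

A `nmrmetab` console script exposes `simulate`, `preprocess`, `classify`
and `enrich` subcommands for file-based workflows.

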