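# Methods

`ssmetab` implements a bucket-based serum ¹H-NMR metabolomics workflow for
discriminating growth-hormone deficiency (GHD) from idiopathic short stature
(ISS) in preadolescents and adolescents, together with a synthetic-cohort
generator that makes every stage testable against known ground truth.  This
note records the models, the defaults and why, and what the synthetic results
do and do not demonstrate.

## The synthetic cohort

**Design.** Six groups — preadolescent controls/GHD/ISS (PAC/PAG/PAI) and
adolescent controls/GHD/ISS (ADC/ADG/ADI) — with sizes 88/94/61/40/43/19
(345 children), per-group age models (means 7.1–12.8 y, SD 1.5–2.6 y) and
male proportions (0.51–0.84) taken from the study's demographic table.

**Concentrations.** Each of the 48 library metabolites has a baseline serum
level (arbitrary relative units).  A sample from group *g* draws
`log c = log(base × FC(g, met)) + β_age·(age − 9) + β_sex·male + ε`,
`ε ~ N(0, σ²)` with σ = 0.20 (a ~20% coefficient of variation, typical of
serum NMR metabolites).  Mild nuisance slopes (creatinine, creatine, the
glucose anomers, citrate, taurine) make the age/sex correction in the screen
do real work.

**Planted effects.** Fold-change directions follow the reported serum
changes: preadolescent disease lowers the VLDL/lipid/N-acetyl-glycoprotein
envelopes and lactate and raises glycerol, the glucose anomers, ketone
bodies, succinate, acetate and the cholines; adolescent disease lowers the
branched-chain amino acids, glutamine, lysine, methionine and creatine, with
eight additional amino-acid decreases unique to adolescent ISS.  Magnitudes
are not published at metabolite level, so defaults were fixed once at
FC 1.3–1.4 (up) or 0.70–0.80 (down) — about one within-group SD on the log
scale.  The between-disease discriminators (aspartate, ethanolamine,
trimethylamine, phosphocholine for PAI-vs-PAG; histidine, isobutyrate,
methanol, phosphocholine for ADI-vs-ADG) are planted as *split weak* effects
(≈1.10 on one side, ≈0.90 on the other): each side stays below the joint
vs-control screening criteria, while the combined ≈1.25 contrast is
detectable between the disease groups — reproducing the study's structure in
which these metabolites appear only in the between-disease models.  The
ground-truth manifest records the intended biomarker set per contrast; the
recovery tests score the screen against it.

**Spectra.** Pure Lorentzian lineshapes (CPMG spectra are approximately
Lorentzian; analytic areas make the calibration tests exact), FWHM
0.0025 ppm (≈1.5 Hz at 600 MHz), multiplets with binomial line intensities
and 7-Hz couplings; macromolecule envelopes (VLDL, lipid, NAG) as extra-broad
single resonances (4–8× linewidth).  Raw-looking features: residual water
(δ≈4.93) and urea (δ≈5.79) Gaussian humps, a slow cosine + tilt baseline
drift, additive Gaussian noise (SD 0.05 intensity units), and one global
chemical-shift offset per sample (SD 0.003 ppm).  Not modelled: FID-domain
relaxation physics, J-evolution under CPMG, pH-dependent shift changes,
per-peak jitter, field dependence.  Assignment regions are the first
("assignment") multiplet of each metabolite, ±3 linewidths (capped at
±0.045 ppm); neighbouring peaks deliberately overlap in crowded regions
(0.9–1.1, 2.0–2.5, 3.0–3.3 ppm), so quantification carries realistic
cross-talk — the round-trip Spearman correlation between true and quantified
concentrations is ≈0.95 (median) rather than 1.

## Spectral processing

The optional time-domain path applies `exp(−π·lb·t)` apodization (lb = 1 Hz
default), zero-fills to 64 K, Fourier transforms, phases automatically
(entropy minimisation on the derivative of the real part with a negative-area
penalty, multi-start over four initial zeroth-order angles) and removes an
iterative degree-3 polynomial baseline.  The frequency-domain path — the
pipeline default, since the generator emits spectra — calibrates each
spectrum to the endogenous lactate doublet at δ1.33 (intensity-weighted
centroid of the points above half the window maximum; error if the peak's
prominence is below 5× the spectrum's MAD noise floor).

Bucketing integrates δ0.6–8.6 into half-open `[0.6 + 2k, 0.6 + 2(k+1))` mppm
buckets (trapezoid rule), drops every bucket overlapping the residual-water
(δ4.67–5.20) or urea (δ5.50–6.08) windows — leaving exactly 3445 buckets —
and then normalises each row to unit total area (exclusion before
normalisation).  Relative metabolite concentrations are integrals of the
normalised spectrum over the assignment regions.  Pareto scaling divides
each centred column by the square root of its SD; zero-variance columns are
zeroed and flagged rather than fatal.

## Latent-variable models

All fits are written from first principles on the (Pareto-scaled) matrix:

* **PCA** by SVD of the centred matrix.
* **PLS-DA** by NIPALS with a single centred class-indicator response; each
  component is exact (no inner iteration) and X/y are deflated between
  components.
* **OPLS-DA** by the orthogonal-signal-correction embedding: the predictive
  weight `w ∝ X'y`; each orthogonal component takes the part of the loading
  orthogonal to `w`, deflates X, and leaves scores exactly uncorrelated with
  y (enforced by construction, verified to 1e-8 in tests).  One predictive
  plus `n_orthogonal` components (default 1; the study software's component
  counts are not published).
* **VIP** over predictive components,
  `VIP_j = sqrt(p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a)`, so `Σ VIP² = p`
  identically.
* **p(corr)** is the Pearson correlation of each input variable with the
  predictive score — the S-plot correlation axis.
* **Q²** from stratified 10-fold cross-validation, `1 − PRESS/SS`; folds are
  seeded and recorded because the reference software's deterministic fold
  assignment is not reproducible.
* **CV-ANOVA** as `F = ((SS − PRESS)/A)/(PRESS/(N − A − 1))` with A the
  model's component count; F ≤ 0 maps to p = 1.  This F-approximation is
  conservative under the null (observed null rejection ≈0% at nominal 5%),
  which we prefer to an anti-conservative calibration; the permutation test
  is the primary overfitting guard.
* **Permutation validation** (default 200 relabellings; identity
  relabellings are redrawn): records R²Y/Q² against the signed correlation
  between permuted and original labels, regresses both on |corr| with the
  original model as the corr = 1 anchor, and declares the model valid when
  every permuted R² and Q² lies below the original values and the Q²
  intercept is negative.

## Biomarker screening

For each case/control contrast the OPLS-DA model is fitted to the
Pareto-scaled **bin matrix** (as in SIMCA-based bucket workflows), and a
metabolite's VIP/p(corr) are read off its best assigned bucket.  A
metabolite is a potential biomarker when jointly:

1. age- and sex-adjusted p < 0.05 (OLS of concentration on group + age +
   sex; the group coefficient's two-sided t-test; constant covariates are
   dropped, collinear designs yield missing p),
2. |p(corr)| > 0.300 (0.600 for the ADI-vs-ADC contrast), and
3. VIP at or above the 90th percentile of the per-bucket VIP distribution.

The percentile is taken over buckets, not metabolites: a metabolite-level
90th percentile of ~50 values could never admit the 9–15-metabolite panels
this workflow is built to find (at most ~5 can exceed it).  A
metabolite-level reference remains available (`vip_reference="metabolites"`).

Selection is only ever read off a model with predictive power: when the
contrast's cross-validated Q² ≤ 0 the flag is suppressed for all metabolites
(statistics still reported).  This validate-then-screen order matters under
the global null, where the overfit predictive score correlates with exactly
the metabolites that are univariately significant by chance, so the three
criteria are far from independent; the Q² > 0 gate (the standard validity
floor) restores a near-zero null selection rate.

At the default effect magnitudes the ADI-vs-ADC contrast — the smallest
group (n = 19) combined with the stricter |p(corr)| > 0.600 criterion —
recovers only part of its planted panel: a planted FC of 0.75 at 20% CV sits
right at the p(corr) ≈ 0.6 boundary, so sampling variation decides each
metabolite.  This is the power actually available at that size, and the
package reports it as such rather than inflating the planted effects.

Raw two-group tests (Welch default; Student and Mann-Whitney available),
fold change as the ratio of case/control means, Pearson chi-square without
continuity correction for categorical clinical variables, and one-way ANOVA
computed exactly from per-group (n, mean, SD) — identical to the raw-data
ANOVA when the summaries are exact — complete the univariate layer.  No
multiple-testing correction is applied in the screen (the joint criteria are
the guard); a Benjamini–Hochberg column is available in the ORA output for
information.

## Diagnostic models

Candidates are metabolites with raw two-group p < 0.05.  The LASSO solves
`½‖y − Xβ‖² + λ‖β‖₁` on standardized features over a 100-point log grid from
λ_max = max_j |x_jᵀ(y − ȳ)| down three decades; λ is chosen by stratified
cross-validated MSE with the one-standard-error rule (largest λ within one SE
of the minimum).  The surviving panel feeds three classifiers — random
forest (200 trees), logistic regression and RBF-SVM (both behind a
standardizing pipeline).  Scores are **cross-validated** by default
(stratified 5-fold; each sample scored by the fold that held it out) because
resubstitution inflates AUC; resubstitution is available for comparison.
ROC curves come from an explicit threshold sweep with tied scores grouped;
AUC is the normalised Mann-Whitney pairwise count (ties ½), identical to the
trapezoid area of that sweep to 1e-12; the CI is a stratified bootstrap
percentile interval (2000 resamples default) — valid for all three score
types, unlike DeLong.

## Over-representation analysis

Each pathway of the bundled KEGG-like catalog (30 pathways over the library
metabolites) is tested with the hypergeometric upper tail
`P(X ≥ k), X ~ Hypergeom(N, K, n)`; p < 0.01 flags a disturbed pathway.  The
universe is the catalog's full annotatable compound set — pathway members
plus a ~150-compound serum background — matching the behaviour of
annotation services that test against their complete compound collection; a
universe this size is also necessary for a complete 3-of-3 overlap to reach
p < 0.01 at all.  A detected-only universe is available via
`ora(detected=...)`.

## Pipeline, seeding, problem sizes

`run_pipeline` chains simulate → preprocess → screen → diagnose → enrich
into a run directory; every stage draws from a named sub-seed hashed from
the config seed, later stages read the files earlier stages wrote (so any
prefix can be cached), and `provenance.json` records the config hash plus a
SHA-256 digest of every output — two runs with one config are file-identical.

The test-suite and acceptance simulations use deliberately scaled problem
sizes chosen for tight feedback: null calibrations at n = 60 samples × 59
variables over 50 seeds with 20 permutations each; screen recovery at the
full 94/88 contrast over a few seeds and the global null over 20 seeds;
classifier null checks at n = 30 over 50 seeds; the end-to-end determinism
check on a two-contrast configuration with reduced permutation/bootstrap
counts.  These sizes preserve the statistical behaviour being asserted while
keeping a full run in minutes.

## Limitations

* Synthetic spectra demonstrate correctness of the machinery, not clinical
  validity: planted effect magnitudes are configuration, and the published
  cohort's AUCs and biomarker lists cannot be reproduced without its data.
* Peak positions are fixed; pH/ionic-strength shift variation, which makes
  real bucket-to-metabolite mapping harder, is absent.
* Two-class models only; the multi-group structure is handled as pairwise
  contrasts, as in the original workflow.
* The CV-ANOVA p is conservative; treat it as a companion to, not a
  replacement for, permutation validation.
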