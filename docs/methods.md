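# Methods

This note documents the models, conventions and parameter choices behind
`nmrmeat`, in the order the pipeline applies them, together with what the
synthetic data generator does and does not emulate.

## Synthetic spectrum model

A simulated polar-extract spectrum on a regular ppm grid (default −0.50 to
9.60 ppm, step 0.001 ppm) is

    y(x) = Σ_m c_m Σ_p r_{m,p} L(x; δ_{m,p}, γ) + b(x) + w(x) + T(x) + ε(x)

* **Metabolite signals.** `L` is a unit-area Lorentzian, the natural NMR
  lineshape; half-width at half-maximum γ = 0.002 ppm (≈ 0.8 Hz at
  400 MHz, comfortably inside a routine line-width acceptance of ~1.2 Hz).
  The polar library holds 15 metabolites with peaks at their literature
  shifts (e.g. carnosine 8.500/7.239/2.67 ppm, anserine 8.536/3.842 ppm,
  hypoxanthine 8.230/8.19 ppm, choline 3.212 ppm, carnitine 3.239 ppm,
  *O*-acetyl-carnitine 3.203 ppm, inosine 8.275/8.374 ppm, lactate
  1.34/4.12 ppm, creatine 3.04/3.97 ppm, α/β-glucose 5.24/4.64 ppm).
  Relative intensities r are fixed per peak; no J-coupling or multiplet
  structure is modelled (a stated non-goal: the classifier consumes bucket
  averages, which wash out fine structure anyway).
* **Concentrations.** Per sample, each metabolite concentration is drawn
  log-normal and mean-preserving: c = μ·exp(zσ − σ²/2), z ~ N(0,1),
  σ = √ln(1+CV²). Species differ only through the means μ. The published
  evidence for the marker metabolites is *orderings*, not concentrations,
  so the absolute levels are free parameters of the generator, chosen once:
  shared metabolites (lactate, alanine, creatine, glucose, aromatic amino
  acids) have identical means everywhere; marker metabolites (carnosine,
  anserine, hypoxanthine, choline, carnitine, *O*-acetyl-carnitine,
  inosine, betaine) have between-class ratios of 1.5–3×, encoding carnosine/
  hypoxanthine/choline elevated in pork vs lamb and anserine/inosine/
  carnitine/*O*-acetyl-carnitine elevated in lamb vs pork, with distinct
  beef and poultry combinations. Within-class CV is 0.15 for raw meat; the
  processed-product condition multiplies every CV by 2 (processed products
  disperse more). These defaults *are* the study conditions: they are tuned
  to produce the reported accuracy regime (≈99 % raw, ≥93 % processed)
  without being trivially separable, and are not adjusted per experiment.
* **Nuisance terms.** b(x) is a smooth random baseline (flat offset 1.0
  intensity unit plus a 10 % two-term Chebyshev wobble with standard-normal
  coefficients, clipped positive); w(x) is a broad Gaussian residual-water
  hump confined to 4.84–5.10 ppm with random amplitude (the region is
  excluded downstream, so only its confinement matters); T(x) is a
  fixed-area (1.0) Lorentzian TSP reference at 0 ppm — fixed because the
  reference standard is added volumetrically and its invariance is the
  premise of reference normalization; ε is i.i.d. Gaussian point noise
  (sd 0.3 intensity units, ≈ 0.1 after bucket averaging, i.e. ≈ 10 % of the
  baseline level).
* **Sample sizes.** Raw: 175 pork, 105 beef, 61 lamb, 38 poultry (379).
  Processed: 31 pork, 18 beef, 27 poultry (76). External/mixture samples
  are generated on demand.
* **Non-polar block.** A paired lipid-extract spectrum per sample on
  0.50–6.80 ppm, built from a fatty-acyl peak library (chain CH₂ 1.28 ppm,
  allylic 2.02 ppm, diallylic 2.77 ppm, olefinic 5.32 ppm, cholesterol
  0.68 ppm, …). Poultry (polyunsaturated-rich) and pork are well separated;
  beef and lamb differ by only ~1.1–1.2× ratios, so this block alone
  confuses beef and lamb — the situation that motivates mid-level fusion.
* **Reproducibility.** Every draw flows from explicit seeds (one per
  sample, derived from the dataset master seed); a generator call is a pure
  function of (configuration, seed). One draw is consumed per metabolite
  regardless of CV so that changing one mean never perturbs another
  metabolite's realisation.

What the generator does **not** emulate: peak-position jitter and
temperature/pH shift drift (no alignment step is needed or provided),
multiplets and J-coupling, protein background, correlated metabolite levels
within a pathway, and instrument artefacts. Passing tests therefore show
that the *statistical machinery* behaves correctly under the assumed class
structure — not that real meat spectra of these species are this separable.

## Pretreatment

Per spectrum: bucket → normalize → exclude → log.

* **Bucketing.** The region [0.50, 9.50] ppm is split into 1000 equal
  buckets (width 0.009 ppm). The bucket value is the trapezoidal integral
  of the linearly interpolated spectrum over the bucket divided by the
  bucket width (a *mean* intensity), making values independent of digital
  resolution. Exact partial-cell integration is used (bucket edges are
  merged into the grid), verified against direct numerical integration.
* **Exclusion.** A bucket is dropped iff its half-open interval overlaps a
  closed exclusion interval at all — the conservative convention that no
  excluded signal can leak into a retained feature. With the default
  geometry the water window drops 30 buckets, retaining 970. The retained
  count is recorded in the pretreatment record rather than hard-coded,
  since other exclusion conventions give slightly different counts.
* **Normalization.** Division by the trapezoidal integral of the *spectrum*
  (not the bucket vector) over the reference region — TSP at −0.5 to
  0.5 ppm for the polar block, which lies outside the bucketed range; the
  non-polar block normalizes over 1.50–4.05 ppm. Because the normalizer
  comes from the spectrum, normalization commutes with exclusion (asserted
  in tests). A non-positive reference integral is an error.
* **Log transform.** x → log₁₀(max(x, 0) + 10⁻⁶). Base and offset are
  conventions (only "a log transform" is specified); the offset guards the
  singularity at 0 and negatives (noise) are clipped. The transform
  compresses large values more than small ones, acting as a pseudo-scaling
  that removes the need for unit-variance scaling of buckets.
* **Non-polar variant.** 0.50–6.80 ppm, 2000 buckets, water (4.84–5.10 ppm)
  plus methanol (3.33–4.40 ppm) exclusions.

Every feature matrix carries its full pretreatment record; models refuse
samples whose record differs from their own.

## PCA / LDA / nearest class mean

* **PCA** on the mean-centred (never autoscaled) log-bucket matrix via SVD.
  Default dimension policy: the smallest component count reaching 98.9 %
  cumulative explained variance, hard-capped at 16 — both knobs
  configurable, neither treated as a constant of nature. Component signs
  are fixed deterministically (largest-magnitude entry positive).
* **LDA** solves the generalised symmetric eigenproblem S_b v = λ S_w v
  with a ridge of 10⁻⁸·trace(S_w)/dim added to S_w for numerical stability;
  up to g−1 discriminants are kept, S_w-whitened. Pooled covariance is used
  for the discriminants; per-class LD covariances are stored for ellipses
  and external validation. For two classes LD1 is collinear with
  S_w⁻¹(μ₁−μ₂) (asserted against that closed form).
* **NCM.** Euclidean distance to class means in LD space; argmin wins;
  exact ties go to the lexicographically smallest label and are flagged.
* **Confidence ellipses.** For a 2-D class cloud, semi-axes are
  √(eigenvalue · χ²₂(level)) along the covariance eigenvectors (level 0.95
  by default).
* **Marker reports.** Two-class models (a pair or one-vs-rest) rank buckets
  by |LD1 loading| composed back to bucket space (PCA loadings × LDA
  discriminant); the elevated class per bucket is decided by group means,
  and five-number summaries (quartiles by linear interpolation) support
  box-whisker plots.

## Validation

* **MCCV.** 10 Monte-Carlo runs × 10-fold CV. Folds are contiguous blocks
  of a seeded permutation (sizes differ by ≤ 1; 379 samples give nine folds
  of 38 and one of 37); run r uses seed master+r, so the segmentation is
  fresh every run. Folds are unstratified by default, matching plain random
  segmentation; a stratified option exists because very small classes can
  otherwise leave < 2 training samples in a fold (that condition is checked
  and raises). The *entire* chain — centering, PCA, LDA — is refit on the
  training folds only; leakage is guarded by tests (corrupting held-out
  rows never changes the fitted model) and by refusing prefit models. All
  n_mc × n_folds confusion matrices are summed; accuracies are percentages
  of the aggregate.
* **External validation.** New samples are NCM-assigned, then scored by the
  squared Mahalanobis distance d² to the assigned class mean using that
  class's own LD covariance (pooled fallback, with a warning, if singular),
  and p = P(χ²_df ≥ d²) with df = number of LD dimensions. "Inside the 95 %
  region" means p ≥ 0.05. The class's own covariance (rather than the
  pooled one) is the documented convention implementing a per-class
  confidence region; per-class membership p-values for *all* classes are
  available for mixture screening.
* **Null calibration.** With all between-class differences removed
  (pooled profiles) the MCCV accuracy sits at the chance level
  Σᵢ priorᵢ² ≈ 32.6 % for the raw design. The acceptance band is ± 8
  percentage points, fixed beforehand: the binomial sd on 3790 correlated
  assignments (~2.5 pp effective) plus the spread between the
  uniform-assignment (25 %) and prior-matched (32.6 %) chance regimes.
  The Šidák-corrected Kruskal-Wallis scan finds 0 significant buckets in a
  seeded null run (expected false positives k·α_SID ≈ 10⁻³).

## Univariate screening

Kruskal-Wallis per retained bucket with midranks and tie correction
(division by 1 − Σ(t³−t)/(n³−n)); the fully tied case returns H = 0, p = 1.
p-values come from the χ² approximation with g−1 degrees of freedom — no
exact small-sample null, appropriate for group sizes ≥ 38. The family-wise
level α = 0.001 is Šidák-corrected over k = retained-bucket count
(α_SID = 1 − (1−α)^(1/k); for k = 967 this is 1.03×10⁻⁶). Screening is
per bucket, not per grid point, because k in the correction is the bucket
count. The implementation is cross-checked against an independent
rank-based oracle, and its rank invariance under strictly monotone
transforms is property-tested. Profile bands are mean ± 1 SD by default
("range of variation" is not a defined statistic); a percentile band
(5–95 %) is available.

## Mid-level fusion

Per-block PCA scores are concatenated column-wise after aligning rows by
sample id; a single LDA/NCM model is fitted on the joint space (no second
PCA). Blocks are not rescaled before concatenation by default — plain score
fusion — but an option scales each block to unit total score variance for
cases where one block's scores dominate. Inside cross-validation the
per-block PCAs are refit on each fold's training rows before fusing, so the
fused model never sees held-out samples. Column provenance (block and
component) survives serialization.

## Problem sizes and runtime

All shipped checks run the full-size designs: 379-sample raw and 76-sample
processed sets, 100 model fits per MCCV, 970/1575 retained buckets per
block. The complete test suite takes well under a minute on one CPU; the
acceptance script under ten seconds.

## Known limitations

* The generator's marker effect sizes are package choices consistent with
  published *orderings*; absolute accuracies on synthetic data are
  statements about the tuned study conditions, not about meat.
* A 9 % admixture of a second species shifts the fingerprint by far less
  than the within-class 95 % Mahalanobis radius under these variance
  settings, so low-level admixture is *not* rejected by class-membership
  testing — only balanced mixtures are. Detecting trace admixture would
  require a dedicated mixture model or lower within-class variance, not a
  membership test.
* No peak alignment, variable-width bucketing, probabilistic-quotient
  normalization, PLS-DA or FDR-based screening; these are deliberate
  non-goals.
* The χ² form of the external p-value treats the class LD covariance as
  known; with small classes (18 beef products) it is optimistic.
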