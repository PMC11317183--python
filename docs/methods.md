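# Methods

This note documents the statistical model behind `seroscreen`, the
assumptions of the synthetic cohort generator, the numerical conventions,
and the design choices made where more than one reasonable option existed.

## The screening model

The workflow mirrors a two-phase autoantibody screen on duplicate-printed
protein arrays.

**Phase I (discovery).** A small early-disease subset (default 5
ACPA-positive and 5 ACPA-negative RA cases with duration < 2 years, against
3 healthy controls) is screened on the full array together with three
reference arrays: a blank (no serum), a secondary-antibody-only array, and a
pooled healthy-control array. A probe counts as a *hit* for a serum only if
both duplicate spots are present — net signal at least `presence_z` (= 3)
local background standard deviations — while no duplicate of that probe is
present on either negative reference. Candidates for the focused array must
additionally show, in at least 2 case sera, signal-to-noise ratio strictly
above 13 and net signal strictly above 2.5× the pooled-control net, and must
be hit-positive in zero healthy controls. "Strictly" follows the protocol's
"higher than / more than" wording; the presence heuristic, and the
2-case/0-control frequency rule, are this package's choices where the
protocol is silent.

**Phase II (validation).** For each candidate, the seropositivity cutoff is
the healthy-control mean + 2 SD (sample SD, n−1); positivity is strictly
above the cutoff (tie handling is unstated upstream; strict keeps the
cutoff itself negative). Sensitivity/specificity by default compare cases
against *all* control-role samples (healthy + disease controls pooled,
switchable to healthy-only). Discrimination is the Mann–Whitney AUC —
midranks, so ties count ½, identical to the exhaustive pairwise count — with
a DeLong-variance 95% CI. Subgroup prevalence comparisons use chi-square
with continuity correction, or Fisher's exact test whenever any expected
cell count is below 5. Antibody/clinical correlations default to Spearman
rank; Pearson is used only when both paired variables pass a Shapiro–Wilk
screen at α = 0.05. The Bonferroni factor is the number of tests actually
performed (cells with < 3 complete pairs are excluded from both the grid and
the factor). The cohort embedding is ordinary t-SNE on log10,
column-standardised intensities; it is deterministic for a fixed seed and
promises neighbourhood structure only.

## The classifier

Features are log10 floored net intensities of the candidate antigens,
z-scored with training statistics (population SD; zero-variance features get
SD 1). The cohort is split 120 cases / 120 controls into training, the
remainder (62/141 at the default sizes) into test.

* **Grid search**: RBF SVM over the standard coarse powers-of-two lattice
  (C ∈ 2⁻⁵…2¹⁵, γ ∈ 2⁻¹⁵…2³, step 2 in the exponent), maximising the mean
  of the four out-of-fold AUROCs under a stratified, seeded 4-fold split;
  exact ties break toward smaller C, then smaller γ. Standardisation is
  refit inside every fold so no validation information leaks.
* **Kernel RFE**: with the SVM fit on the surviving features,
  `J = ½ Σᵢⱼ αᵢαⱼyᵢyⱼK(xᵢ,xⱼ)`; for each feature the kernel is re-evaluated
  with that feature's column removed (for an RBF kernel this multiplies K
  elementwise by `exp(+γ(x_f−z_f)²)`) with α held fixed, and the feature
  with the smallest `|ΔJ|` is eliminated, ties to the lowest index, one
  feature per round. A constant feature changes no pairwise distance and is
  eliminated first. In the γ→0 limit on standardised data `|ΔJ| → γ·w_f²`,
  the linear-SVM ranking at the matching effective box constraint.
  RFE runs once on the full training set; the fold-wise AUROC along the
  elimination path only chooses the feature count k (argmax, ties to the
  smallest k). Whether the original analysis nested RFE inside each fold is
  unknowable from the protocol; running it once is the documented
  reproducibility risk here.
* **Threshold calibration**: the decision threshold is the smallest
  training-set score of the *final* model reaching the target specificity
  (90%) on training controls, with the target first raised by a
  cross-validated estimate of calibration optimism (per fold, a threshold
  calibrated on the fold model's own training scores is scored on held-out
  controls; the mean specificity shortfall, clipped at zero, is the
  optimism). Calibrating instead on raw out-of-fold scores is scale
  inconsistent — fold models and the final model produce scores of
  different magnitude, and in our experiments such a threshold landed near
  the 99th percentile of final-model control scores. Out-of-fold scores are
  still used, with their own out-of-fold threshold, for the reported
  cross-validated sensitivity/specificity, and the pooled and per-fold CV
  AUROCs are both reported.
* **Single-marker comparison**: each comparison marker (CH-28, NH-26) is
  dichotomised at the smallest training value whose specificity on training
  controls reaches the target; the CH-28+NH-26 combination is positive when
  either member is positive (the combination rule is unspecified upstream;
  OR is the clinical convention for parallel tests).

Everything upstream of `evaluate` — standardisation, grid search, RFE,
feature count, threshold — depends on training data only.

## The synthetic cohort generator

No array data are publicly deposited for this kind of study, so the
generator is a first-class, tested component that emulates the study
conditions: 182 RA cases (48 ACPA-negative), 103 healthy and 158 disease
controls (48 AS, 47 SLE, 31 SS, 32 OA), 200 protein probes of which 15
informative, printed in duplicate with buffer/IgG/IgM/biotin-BSA/BSA/GST
controls, plus pooled-control, blank and secondary-only arrays.

Latent serum reactivity of sample *s* on antigen *a*, in log10 fluorescence
units:

```
log10 L[s,a] = mu_a + sigma * z[s,a]                          (everyone)
             + R[s,a] * (effect_a + boost_a + kappa * act_s)  (cases)
```

* `mu_a ~ U(1.3, 1.4)`, `sigma = 0.4`: non-reactive antigens sit near the
  local background (net ≈ 20–25 units against background SD 60), as on real
  serum arrays where most of the proteome is dark.
* `R[s,a] ~ Bernoulli(0.5)`: autoantibody repertoires are sparse — each
  patient reacts with only part of the informative panel. This is what
  produces per-antibody sensitivities in the 20–50% range at high
  specificity and keeps any small feature subset from separating the cohort
  perfectly.
* `effect_a = 0.6` decades for ACPA-positive cases, halved
  (`acpa_neg_attenuation = 0.5`) in ACPA-negative cases — the planted
  version of the heterogeneous, overlapping ACPA-negative profile.
* `boost_a = 1.4` decades extra for early cases (duration < 2 years) on the
  designated early antigen subset (default: all informative antigens). The
  boost, the responder rate and the baseline were chosen together,
  analytically, so that ten early sera against three controls can clear the
  conjunction of presence (3 SD), SNR > 13 and fold > 2.5 thresholds — the
  geometry of those thresholds (a 0.64-decade gap between presence and SNR
  cut, both scaling with background SD) forces an early-disease signal well
  above the 0.6-decade case effect, consistent with candidate antigens
  being discoverable in early-stage sera at all.
* `act_s ~ N(0,1)` is a disease-activity factor; it scales antibody
  responses (κ = 0.6 × `clinical_coupling`, default coupling 0.4) and loads
  on ESR, CRP, RF, IgG, DAS28, joint counts and the radiographic score with
  loadings 0.2–0.6, so planted antibodies correlate positively with
  inflammation markers.
* Technical layer: every probe renders as two duplicate spots with
  multiplicative log-normal noise (CV 0.08) over a Gaussian local
  background (mean 300, SD 60); values are quantised to 1/64 fluorescence
  units so net = fg − bg is exact in binary floating point. Anti-GST-style
  QC arrays draw every protein spot log10-normal (mean 3.65, SD 0.35), which
  puts ≈95% of spots in the canonical [1000, 24000] window. Blank and
  secondary-only arrays carry background only; the pooled-control array is
  the per-probe geometric mean of the healthy-control latents with fresh
  technical noise.
* CH-28/NH-26 reference markers react only in ACPA-positive cases
  (responder rates 0.5 / 0.2), giving test sensitivities near 0.4 / 0.25 at
  90% specificity, with their OR-combination adding roughly independently.

All draws come from one seeded generator in a fixed order, so identical
configurations yield byte-identical files. Disease duration is exponential
(mean 5 y, ≈ a third of cases early), with 16% of durations missing;
missing durations are excluded from the early/established comparison.

**What the generator does not model** — and hence what passing tests do not
show about real arrays: spatial artifacts (gradients, scratches, block
effects), batch/array-to-array normalisation issues, cross-reactivity
between antigens, non-log-normal intensity tails, informative missingness,
and any true biological identity of the antigens. Recovery results are
statements about the pipeline's correctness under the stated generative
model, not about clinical performance.

## Numerical conventions and degenerate inputs

* Net signal is floored at 1 fluorescence unit so log transforms are always
  defined; how negative nets were handled upstream is unstated.
* SNR is the GenePix-style per-spot `(fg − bg) / bg_sd`, averaged over
  duplicates; undefined (NaN) without a background SD.
* RPD uses the floored nets, so its denominator is always positive.
* Coordinates are 1-based; channel 532 is the analysis channel; flagged
  spots (negative GPR flag) are retained in files but excluded from
  aggregation; a probe with one usable spot is reported `single` with
  undefined RPD; with none, `missing` (NaN, never zero).
* No cross-array normalisation is applied by default.
* Percentages in report tables round half-up to one decimal.
* t-SNE perplexity defaults to `min(30, max(2, (n−1)/3))` so small cohorts
  embed without error; identical samples embed to finite coordinates.
* Threshold search scans observed score values only; if the target
  specificity is unreachable the threshold is placed just above the maximum
  score with a warning.

## Problem sizes

Default analyses run the full 443-sample, 200-antigen cohort; unit tests
use reduced cohorts (24–56 samples, 30–40 antigens) and the workflow-level
recovery checks run the full cohort over three seeds. These sizes keep a
complete run of the suite and of `scripts/acceptance.py` in the tens of
seconds to low minutes on one CPU while leaving every selection margin
(candidate counts, feature counts, binomial noise on specificities) at
realistic scale.

## Known limitations

* The held-out specificity of the calibrated threshold carries ~±0.04
  binomial noise (120 calibration, 141 test controls); only averages over
  several seeds estimate calibration accuracy stably.
* The per-antibody AUC confidence interval is DeLong's; a different
  nonparametric CI (e.g. exponential-approximation software defaults) will
  differ slightly in the third decimal.
* RFE is not nested per CV fold (see above); with strongly correlated
  panels the chosen feature count is noisy on the AUROC plateau.
* The generator's effect scale is not identifiable from published summary
  statistics; defaults are calibrated to the screening thresholds, not to
  any measured biology.
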