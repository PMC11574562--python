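# Methods

`metaboscreen` implements a serum-metabolome screening workflow that
classifies samples as cancer or non-cancer from untargeted LC-MS peak
lists. This note documents the model at each stage, the tunable parameters
and their defaults, what the synthetic cohort generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Synthetic cohorts

No public cohort of annotated serum metabolome profiles with per-run peak
lists exists for this problem, so the package ships a generator whose
output has the statistical structure the pipeline assumes. All
distributional choices below are stand-ins: nothing is known publicly
about the intensity distributions of the real data, and passing tests on
these cohorts demonstrates correctness of the pipeline's mechanics, not
clinical performance.

**Reference library.** `generate_library(n, fraction_nonhuman, seed)`
lays metabolite monoisotopic masses on a jittered log-spaced grid over
70–1200 Da (jitter ±30% of the grid step), guaranteeing pairwise mass
spacing far wider than twice the 10 ppm annotation tolerance, so
annotation is unambiguous by construction. Exactly
`round(fraction_nonhuman * n)` records receive a drug / plant / ambiguous
origin (default fraction 0.20). Nominal retention times are uniform on
30–900 s; per-feature base log10 abundances are N(5.0, 0.8).

**Intensity model.** The true log10 abundance of feature *f* in sample
*s* is

```
base_f + batch_offset(b) + batch_interaction(b, f)
       + sum_k score(s, k) * loading(k, f)
       + 1[cancer] * sign_f * effect_size * attenuation(stage) + eps
```

with `batch_offset ~ N(0, batch_sd)` shared by all features of a batch
(shifts whole-sample location, the component quantile normalization
removes), `batch_interaction ~ N(0, batch_sd/2)` per batch × feature,
`eps ~ N(0, residual_sd)`, and a latent-factor term (`n_latent_factors`
standard-normal per-sample scores, per-feature loadings
`N(0, latent_sd)`; defaults 5 and 0.15) that induces the substantial
between-metabolite correlation characteristic of serum profiles — the
structure chained-equations imputation exists to exploit. The class effect applies only to the
`n_signature` signature features of cancer samples; each signature feature
carries a random sign, so the cancer shift is a pattern, not a global
intensity increase. `attenuation` defaults to 1.0 for every clinical
stage, reflecting the near-constant detection rates across stages that
motivate the workflow; it is exposed for power studies.

**Defaults (the package's reference conditions).** 400 cancer samples
over eight cancer types plus 400 normal controls; 1000 library
metabolites, 60 signature features; `effect_size` 0.6 log10 units
(≈2 pooled SDs per feature given `residual_sd` 0.30 — a strongly
separable regime); 4 batches, `batch_sd` 0.15; drift ±30 ppm;
`mcar_rate` 0.03 and `mnar_threshold_quantile` 0.05 (≈8% missing cells).
Metadata margins (cancer-type mix, stage distribution, age bins, sex) are
patterned on the composition tables of a 6445-participant case-control
study spanning 30 cancer types; the embedded tables also drive the
cohort-arithmetic checks in the acceptance suite.

**Missingness.** A cell is dropped as MNAR when its intensity falls
strictly below its feature's `mnar_threshold_quantile` quantile
(abundance-dependent dropout), and as MCAR with probability `mcar_rate`
otherwise. A missing measurement is an *absent peak*, never a zero.

**Mass drift.** One multiplicative drift per run, in ppm. Drifts are
drawn as antithetic pairs about the center of `drift_ppm_range`, pinning
the cohort-mean drift to the center exactly. This is an identifiability
choice: an internal-anchor correction can only remove *relative*
run-to-run error, so a nonzero sample-mean drift would reappear as a
constant offset in every "recovered vs injected" comparison (~2 ppm at 60
runs) that no anchor-based method could remove.

**Not emulated:** chromatographic peak shapes, isotopologues, adducts
beyond a single protonation, MS2 spectra, retention-time drift between
runs, instrument QC drift within a batch, and pathway-specific biology —
the latent factors give generic metabolite covariance, not the
association of particular metabolites with particular cancer types.

## Virtual-lock-mass alignment

Pooled peaks from all runs are clustered greedily along m/z (a cluster
break wherever the relative gap exceeds `ppm_window`). A cluster becomes
an anchor iff every peak lies within ±`ppm_window` of the cluster mean,
no run contributes two peaks (ambiguous windows are discarded outright),
and at least `min_presence` of runs contribute one. Each run's signed ppm
deviation from the consensus is its observed mass error at that mass;
correction divides every peak's m/z by `1 + e(mz)/1e6`, with `e`
piecewise-linear between flanking anchors and constant beyond the ends.
This is a re-specification of the lock-mass idea in its simplest form
that removes run-wise mass shifts, not a reproduction of any particular
published implementation.

Two default sets coexist deliberately. The *operation* defaults
(`ppm_window` 10, `min_presence` 0.95) are the conventional values for a
high-resolution instrument with modest drift. The *pipeline* defaults
(`ppm_window` 45, `min_presence` 0.75) reflect the reference study
conditions: before correction, one metabolite's peaks spread across the
full ±30 ppm drift span, so the anchor window must cover that span, and
~8% missingness makes a 0.95 presence requirement reject nearly every
feature. On the reference cohort the per-run anchor-median error matches
the injected drift to well under 1 ppm and correction removes ≈97–98% of
the median absolute mass error.

Annotation assigns each corrected peak to the library record minimizing
absolute ppm difference of the neutral mass (observed m/z minus one
proton mass; positive ion mode, single-adduct model), subject to
`annotation_ppm` (10) and an RT gate (`rt_tolerance` 30 s). Ties per
(sample, metabolite) cell resolve to the higher-intensity peak, so every
matrix cell derives from at most one peak.

## Preprocessing

Order of operations is fixed: origin curation → feature reduction → log10
→ quantile normalization → imputation. Curation retains only
`origin == human` features. Feature reduction has two modes because both
conventions exist for this workflow: *prevalence* (default; keep features
observed in ≥ 20% of samples, boundary inclusive) and
*abundance-percentile* (drop the lowest 20% by mean observed log10
intensity, ties broken by metabolite id, `floor(k/100 · p)` dropped).

Quantile normalization is train-referenced and single-sample. Fitting
sorts each training sample's observed values, interpolates them onto the
common grid `(r + 0.5)/p` (`p` = retained features — well-defined under
unequal missingness), and averages across samples; the result reduces to
textbook quantile normalization on complete data. Applying ranks a
sample's `m` observed values (ties → average rank) and maps rank `r` to
the reference at grid position `(r − 0.5)/m` by linear interpolation.
Each sample is processed independently, so normalizing a matrix row by
row is *identical* to normalizing it at once — the property that lets a
deployed test process one sample at a time against frozen training
artifacts. A sample with zero observed values is an error; a single
observed value maps as a constant.

## Imputation

Chained equations with LightGBM gradient-boosted tree regressors.
Initialization fills missing cells with observed training feature means.
Each iteration visits features in ascending missingness count (ties by
metabolite id), fits a regressor from predictor features to the target's
observed cells, and overwrites the target's missing cells with
predictions. Iteration stops at `max_iterations` (default 5) or as soon
as the sum of squared differences between successive imputations grows,
in which case the grown iteration is rolled back — so the recorded SSD
trace is non-increasing by construction.

Each target's regression uses its 30 most-correlated companion features
(absolute Pearson correlation on the mean-initialized matrix, ties by
metabolite id) rather than all features. Predictor preselection is
standard chained-equations practice on wide matrices and is what makes
hundreds of per-feature ensemble fits tractable on one CPU; on the
latent-factor test matrices it does not measurably change imputation
error. Ensemble settings (100 trees, ≤7 leaves, depth ≤3, learning rate
0.1, 63 histogram bins, single-threaded deterministic mode) favour
smooth, cheap fits over raw capacity.

After convergence a final regressor per feature is fit on the completed
matrix; these frozen regressors, the means, predictor lists and visit
order form the `ImputationModel` applied at test time *without
refitting*: means initialize, then each originally-missing feature is
overwritten once per sweep (the model's iteration count, minimum one
sweep) by its frozen regressor. Chains use only the sample's own values,
so batch and one-at-a-time application agree exactly. Observed cells are
never modified anywhere.

## Classification

Soft-margin SVM with Gaussian kernel
`k(x, x') = exp(−‖x − x'‖²/(2σ²))` and decision function
`F(x) = Σ αᵢ yᵢ k(x, xᵢ) + b` (cancer = +1). The dual QP is solved by
libsvm's SMO; the fitted expansion is extracted into an explicit model
(support vectors, weights, intercept, kernel width) whose scores the
package computes itself, and the tests verify the KKT conditions, dual
feasibility, and agreement of the dual objective with an independent
SLSQP solution on a toy problem. A sample is called cancer when its
y-score exceeds 0; a score exactly at the cutoff is called normal (the
boundary had to be assigned somewhere; ties at exactly zero have measure
zero for this kernel).

Hyperparameters come from a grid search over mean stratified k-fold
(default 20) CV accuracy with shared fold assignments:
C ∈ {0.1, 1, 10, 100} and σ on a log grid (×0.25…×4) around the median
pairwise-distance heuristic. Ties break toward smaller C (weaker fit to
noise), then larger σ (smoother boundary). Accuracy is the selection
metric; sensitivity-weighted selection would be a one-line change.

Evaluation: confusion counts at the cutoff; sensitivity, specificity and
accuracy as percentages; AUC by the tie-corrected rank (Mann–Whitney)
construction, verified against brute-force pair counting; per-subgroup
(cancer type, stage, age group) sensitivities with 95% Wilson score
intervals, which remain sensible at 0% and 100% observed rates.

Feature ranking is SVM-RFE with the kernel-space drop-one criterion: the
importance of feature *j* is |W² − W²₍₋ⱼ₎| where
`W² = Σ αᵢαₖyᵢyₖ k(xᵢ, xₖ)` and the kernel without *j* is obtained by
multiplying K elementwise by `exp(dⱼ/(2σ²))`. Each round retrains on the
survivors, records held-out sensitivity, and removes the `step` least
important; rank 1 is the last survivor. On the reference cohort
(step 25) ≥ 80% of the top-60 ranked features are true signature
features.

## Pipeline and problem sizes

`run_train` splits the cohort by sample, stratified on class and cancer
type (per-class split fractions supported, mirroring published
train-test/validation allocations); fits anchors, normalization
reference, imputation model and SVM on the training side only; and
archives every artifact with SHA-256 hashes in a run manifest.
`run_validate` refuses any sample id seen in training and pushes each
validation run through frozen artifacts only.

The reference problem size used throughout the acceptance checks — 800
samples × 1000 metabolites, 60-run alignment cohorts, 200 × 80 imputation
benchmarks — was chosen as the smallest scale at which every statistical
property under test (drift recovery, imputation benefit, held-out
separation, chance-level null behaviour) is comfortably out of sampling
noise; a full training run takes a few minutes on one CPU.

## Known limitations

* The generator's intensity model is log-normal with linear batch, factor
  and class effects; real serum intensities have heavier tails, structured
  pathway covariance and RT-dependent artifacts it does not attempt.
* Single-adduct annotation; no RT alignment, centroiding or deisotoping.
* Single imputation (m = 1): imputation uncertainty is not propagated.
* No probability calibration and no tissue-of-origin assignment; the
  classifier is strictly binary.
* Published headline performance of the clinical workflow this package
  re-implements depends on a private 6445-sample cohort and cannot be
  reproduced here; all performance figures in the tests refer to the
  synthetic reference conditions above.
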