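# Methods

## Problem and design

`hsibench` benchmarks preprocessing choices for pixel-wise classification of
hyperspectral tissue images (cancer vs non-malignant), under the constraint
that the *only* thing allowed to differ between two benchmark runs is the
preprocessing itself. Clinical hyperspectral cohorts in this setting are
small (tens of patients), strongly imbalanced (roughly ten non-malignant
pixels per cancerous one), and contaminated by two optical artifacts — blood,
whose spectra resemble cancer spectra and inflate false positives, and
specular glare. The benchmark grid spans scaling, smoothing, artifact
filtering, imbalance weighting and patch size; a full grid at clinical scale
is computationally prohibitive, which is why the pipeline trains each
combination on a small per-patient, per-class stratified subset whose
representativeness is certified statistically.

The confound controls are:

1. **One representative subset, reused everywhere.** 1% of labeled pixels per
   patient and class, drawn without replacement (ceiling rounding so tiny
   classes contribute at least one pixel). The draw is accepted only if, for
   every wavelength band, a two-sample Kolmogorov–Smirnov test cannot
   distinguish the subset's reflectance distribution from the full labeled
   cohort's (α = 0.05); otherwise the draw is discarded entirely and redrawn
   from a fresh stream. The comparison pools both classes by default (a
   per-class mode exists behind a flag). Typical cohorts accept in fewer
   than five draws.
2. **One cross-validation plan, reused everywhere.** Leave-one-patient-out:
   every patient is the test set exactly once; the three validation patients
   for test patient X are a pure function of `(mapping_seed, X)` (a seeded
   draw without replacement from the remaining ids), so every combination
   consumes the identical plan.
3. **One sample order, reused everywhere.** The subset is permuted once with
   `shuffle_seed`; batches are sequential slices of that order. Artifact
   filtering may remove pixels but never reorders survivors, so any two
   combinations deliver the same pixels in the same relative order.
4. **One model state.** The classifier is rebuilt from `init_seed` for every
   fold and combination; dropout has its own seeded stream. Training is pure
   numpy, so identical inputs give bit-identical outputs on one platform
   (cross-platform bit-identity is not promised — only same-platform
   determinism plus a complete run manifest of seeds, stages and epochs).

## Preprocessing pipeline

Stages run in a fixed, trace-observable order: artifact metrics on the raw
full-band cube → band exclusion → scaling → smoothing → exclusion mask →
patch extraction.

* **Band exclusion.** Bands below 540 nm are dropped as noisy, taking the
  500–1000 nm, 5 nm-step grid from 100 to 92 bands.
* **Scaling** operates per pixel spectrum, not per band. Unit-length
  normalization divides by the Euclidean norm (a flat 92-band spectrum maps
  to 1/√92 ≈ 0.104; outputs live in ~[0, 0.14]). Z-score standardization
  subtracts the spectrum mean and divides by its population standard
  deviation (outputs roughly in [−3, 2]). Standardization is also invariant
  to per-patient gain/offset nuisances, which is one mechanism behind its
  empirical advantage.
* **Smoothing** comes in spectral (1D), spatial (2D) and joint (3D) modes
  with median, Gaussian and Savitzky–Golay filters; Savitzky–Golay is
  spectral-only, default window 9 / order 2. Median and Gaussian use
  replicate (nearest) edge padding on every smoothed axis.
* **Artifact filtering.** Three per-pixel band-window metrics are computed on
  the raw full-band cube (before band exclusion — metric B's window overlaps
  the excluded range): A = mean reflectance over 500–1000 nm, B = mean over
  510–570 nm, C = ln(mean over 650–710 nm ÷ c), c configurable, default 0.1.
  The light predicate excludes pixels with A below the light threshold; the
  blood predicate excludes pixels with B above the blood threshold; each may
  be conjoined with C < 0 (the original three-way background rule) via
  `use_c_conjunct`; the exclusion is the union of enabled predicates, and it
  removes pixels from the labeled sample set (training *and* evaluation)
  before patch extraction. Window bounds are inclusive.
* **Patch extraction.** One `(patch, patch, bands)` block per labeled pixel,
  centered on it; spatial borders are reflect-padded (mirror) so border
  pixels still yield patches. Patch sizes 3 and 5.
* **Imbalance weighting.** Class weights (`total / class count`, ≈10 for the
  cancerous class at the study's printed counts) or sample weights
  (`total / (class, patient) count`, so every patient-class group receives
  equal total loss attention); the two modes are mutually exclusive. Weights
  are computed on the post-filtering, post-subsampling training set each
  fold's model actually sees, keeping the loss weighting consistent with
  delivered batches.

## Classifier and training

A single Inception-style block of 'same'-padded 3-D convolutions over the
patch: a 1×1×1 branch (6 filters), a 1×1×1 (4) → 3×3×3 (6) branch, and a
3×3×3 stride-1 max-pool → 1×1×1 (4) branch, concatenated channel-wise, then
flatten → dense(32, ReLU) → dropout(0.2, seeded) → one sigmoid unit. Exact
filter counts are configuration, not contract; the defaults are deliberately
small. Forward and backward passes, Adam (β₁ = 0.9, β₂ = 0.99, ε = 1e-7) and
dropout are implemented directly in numpy, which makes the determinism
contract exact.

Loss is binary cross-entropy with per-sample weights normalized by their
batch sum. Early stopping monitors F1 on the pooled validation pixels at
probability threshold 0.5 and stops once the score has failed to strictly
improve for more than `patience` (5) epochs; the weights kept are those of
the best validation epoch, with ties resolved toward the later (more
trained) epoch so a flat-F1 run keeps its most-trained state.

Numerical safeguards: parameters are Glorot-normal initialized, and
gradients are clipped to global norm 1.0 by default. Both matter here:
sample weights of 10–60× make early batches spiky, and with ~13k flattened
features feeding the dense layer, Adam's sign-coherent per-coordinate steps
can otherwise drive every dense pre-activation negative in the first epoch —
a dead-ReLU collapse from which training cannot recover.

Study-scale defaults are batch 500, learning rate 1e-4, at most 50 epochs.
At desk scale (a 10-patient 64×64 cohort, 1% subset ≈ 350 training samples
per fold) those settings yield ~50 tiny optimizer steps, far too few for any
learning, so `desk_scale_config()` uses batch 16 / lr 3e-4 / at most 10
epochs; everything stays overridable. Test patients are scored on all their
labeled, non-excluded pixels, optionally capped by a seeded subsample
(`eval_max_pixels`) to bound inference cost in small-scale runs.

## Evaluation: the MSS metric

Sensitivity and specificity are computed per patient (prediction positive
iff score ≥ t) and averaged over patients with equal weight, giving a
nonincreasing mean-sensitivity and a nondecreasing mean-specificity curve
over a 1001-point threshold grid on [0, 1]. The optimal threshold T sits at
their intersection, located by the sign change of the difference and refined
by linear interpolation (plateau of exact equality → plateau midpoint; no
crossing → boundary threshold with minimal gap, flagged). MSS is the common
curve value at T, i.e. (sensitivity + specificity)/2 there. Patients missing
a class are dropped from the affected mean with a warning. AUC is the rank
probability that a positive pixel outscores a negative one (ties ½),
patient-averaged for consistency with the curves; a pixel-pooled variant was
considered and rejected because it would re-weight patients by lesion size,
exactly what the patient-level aggregation is meant to avoid.

## Factor analysis

The results table holds one row per combination: factor levels (scaling,
smoothing mode/filter/param, blood threshold, light threshold, weighting,
patch size — "none" is a level, not a missing value) and the MSS response.
A main-effects OLS with Type II ANOVA gives per-factor F and p plus overall
R² and model-F p (Type II chosen because the benchmark grids are balanced
and main-effects only; the sum-of-squares type was genuinely open). OLS
contrasts dummy-code one contributor family at a time against its "none"
baseline — coefficient, two-tailed p, 95% CI — mirroring the separate
smoothing/blood/light analyses. Diagnostics: variance inflation factors per
dummy predictor (duplicated predictors surface as ∞) and a Shapiro–Wilk
residual-normality summary standing in for the Q-Q inspection. Raw p-values
are reported by default; Holm adjustment is behind a flag. A constant
response is reported as F = 0, p = 1 by convention rather than 0/0.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, not
tissue appearance. Per patient: one elliptical lesion whose area is
log-normally dispersed around the 9% cancer share (≈10:1 imbalance), a
1-pixel MARGIN ring, per-patient multiplicative gain (sd 0.05) and additive
offset (sd 0.01) on the class signatures, and per-voxel Gaussian noise
(sd 0.02, clipped at zero). Class signatures are sums of Gaussian bumps over
wavelength chosen so the classes are separable but only through spectral
shape. Every patient has its own random stream derived from
`(seed, patient_id)`, so cohorts are bit-identical across runs and stable
under reordering. Default geometry is 64×64×100 with 8–12 patients;
full-size 480×640 works but is not the default.

Artifacts: blood is laid down as contiguous dilated random-walk streaks
(spatial smoothing interacts with contiguous artifacts, so i.i.d. pixels
would understate its effect); glare as small disks. The blood signature is
the cancer signature plus a Gaussian bump at 515 nm — nearly
indistinguishable from cancer in the retained ≥540 nm bands (the
false-positive mechanism) yet clearly elevated on metric B, which is
computed on the full-band cube; `true_blood_threshold()` returns the
midpoint separating blood's B level from the tissues'. The glare plateau
defaults to 0.05 reflectance, modelling saturated specular pixels whose
calibrated reflectance clips to an unreliable near-zero level, which is what
the low-broadband-mean light predicate catches. Two placement modes exist
deliberately: cohort-spec artifacts are relabeled MARGIN (never samples),
while `inject_artifacts` overlays spectra *keeping* the tissue labels,
emulating unannotated blood on top of annotated tissue — the scenario in
which blood pixels are evaluated as negatives, misclassified as cancer, and
recoverable by the blood filter.

What passing tests on these cohorts do **not** show: robustness to real
inter-patient biology (the generator's patient effect is a gain/offset,
which standardization removes exactly), to annotation noise, to spatially
textured tissue, or to camera noise structure. End-to-end results here
certify the pipeline's mechanics and controls, not clinical performance;
the study-scale clinical numbers require the request-only patient data.

## Numerical and scale choices

* Desk-scale problem sizes used by the test suite: unit tests run on 6
  patients of 32×32; the end-to-end recovery test uses the 10-patient
  64×64×100 cohort with a 600-pixel evaluation cap per test patient, one
  clean run plus three seeds × (blood, blood+filter).
* Threshold grid 1001 points + interpolation; K-S p-values from the
  asymptotic two-sample distribution; ties in the prediction rule go to the
  positive class (score ≥ t).
* Degenerate inputs fail loudly: zero spectra (unit-length), constant
  spectra (z-score), empty band windows, single-class patients (AUC),
  single-level factors (ANOVA), infeasible artifact fractions.
* The `0x7FFFFFFF` masks keep all derived seeds below 2³¹.

## Known limitations

* The numpy network is single-threaded and small; it is a faithful harness
  component, not a performance-competitive classifier.
* The K-S certification tests each band marginally; joint spectral structure
  is not certified.
* `find_intersection` assumes the monotone mean curves cross at most once,
  which the prediction rule guarantees; adversarial non-curve inputs are not
  defended against beyond the boundary flag.
* The grid enumerator's default option lists reflect the parameter values
  named in the benchmark's description; the exact full grid that yields 792
  combinations per patch size is configuration-dependent and must be
  supplied explicitly if needed.
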