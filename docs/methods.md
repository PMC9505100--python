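# Methods

This note documents the statistical procedure `msprog` implements, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about real data.

## Progression labeling

The binary outcome is confirmed-progression-style EDSS worsening with a
baseline-dependent threshold: an increase of ≥ 1.5 points from baseline
0, ≥ 1.0 point from baselines 1.0–5.0, and ≥ 0.5 points from baselines
≥ 5.5. The comparison is `increase ≥ threshold` (equality progresses),
the standard convention for threshold-based worsening. A baseline of 0.5
falls between the defined branches; the package applies the 1-point
threshold there and logs a warning, since no published branch covers it.
Follow-up confirmation visits are not modeled.

## Geometry

Volumes are assumed registered to MNI space on the 2 mm grid
(91×109×91). Printed slice coordinates are interpreted as 0-based voxel
indices on that grid — the only standard grid consistent with all three
analysis ranges (x ≤ 77, y ≤ 95, z ≤ 73). Intensity normalization is
per-volume linear max-scaling to 255 through the origin, so background
zeros are preserved and the inclusion rule is unaffected. The slice
inclusion rule is read as "at least 10% of the slice's pixels are
non-zero"; the alternative reading (10% of the volume's non-zero voxels)
is not implemented. The four slabs per projection are fixed inclusive
coordinate ranges that tile each analysis range exactly:
coronal (17–36, 37–51, 52–76, 77–95), sagittal (14–29, 30–45, 46–61,
62–77), axial (12–26, 27–41, 42–56, 57–73), giving 20/15/25/19,
16/16/16/16 and 15/15/15/17 slices per slab.

When a shared training tensor is built for a projection, a coordinate is
kept only if its slice passes the inclusion rule for *every* subject.
For MNI-registered brains (and for the synthetic ellipsoid phantom) the
per-subject inclusion sets coincide, so this intersection is a no-op in
practice; it merely guarantees a dense (slice × patient) tensor.

## Replica ensemble

Replicas are stratified train/validation splits: per class,
`round(train_fraction × class size)` patients (round half up — the
remainder lands in the training set) go to training. For the reference
cohort (119 stable / 62 progressed, fraction 0.9) this reproduces the
163 = 107 + 56 train and 18 = 12 + 6 validation split exactly; for
arbitrary sizes the split is within one patient of proportional.
Replicas overlap by design: they are distinct but not independent
resamples of one small cohort, and the replica AUC distribution must be
read as such.

Per-replica seeds derive from the master seed by a counter scheme,
`seed_r = (master × 100003 + r) mod (2³¹−1)`, recorded in each split so
any single replica can be reproduced in isolation. Null discriminators
use `seed_r + 1`, so real and null training differ only in the label
vector and in their (independent) initialization draw.

## Classifier backbone

The pipeline's contribution is the statistical machinery around the
classifier, not the classifier itself, so the default backbone is
deliberately small: downsample each slice to 8×8 pixels (anti-aliased),
standardize, project onto 16 principal components, and fit an L2
logistic regression. The two-step structure of the training protocol is
preserved: step one fits the scaler + PCA + a 4-class logistic head on
the *slab-location* task (every included slice of every subject, labeled
by its slab) and reports held-out accuracy; step two freezes that
representation and fits the binary progression head per slab, replica
and projection — a transfer-learning warm start in miniature. Heavier
backbones (e.g. a convolutional network) can be plugged in through
`ClassifierSpec.factory`; they only need `fit(images, labels)` and
`score(images) → [0, 1]`.

Training instances are (slice, patient) pairs: every included slice of
the slab carries its patient's label. Validation scores are recorded per
slice per patient, never aggregated to hard labels, so ROC curves can be
thresholded downstream.

## ROC and AUC

With 6 positive and 12 negative validation patients the ROC is a coarse
step function; AUC is therefore computed exactly as the Mann–Whitney
probability with ties counted ½ (midranks), and the returned step curve
integrates to the same value to machine precision. The minimal AUC
increment is δ = 1/(n⁺ n⁻) = 0.0139 for the 6/12 split; this granularity
is also the natural half-width of the null admissibility band. Replica
distributions are summarized with linear-interpolation quartiles and the
standard 1.5×IQR boxplot fences (strict inequality, so constant
distributions have no outliers). Slab-folded AUCs treat each
(patient, slice) pair as one classification instance, giving
6·k positives and 12·k negatives for a k-slice slab.

## Selection

Each real model is compared to its index-matched null twin (same
replica, same validation patients), which makes DeLong's *paired* test
the appropriate comparison: the covariance of the two placement-value
vectors is subtracted from the variance of the AUC difference. The
implementation follows the structural-components formulas directly and
was verified against an independent loop-based transcription, a
stratified patient bootstrap, and R's pROC on spot checks. A pair is
selected iff (i) the null AUC lies in 0.5 ± δ, (ii) Z > 1.96, and
(iii) the real AUC exceeds the null AUC. Z is signed (real − null), so
(ii) and (iii) together implement a one-sided test in the improvement
direction; the two-sided p-value is still reported. Identical score
vectors are defined to give Z = 0, p = 1; any other zero-variance pair
is recorded as untestable (Z = NaN, never selected). No multiple-testing
correction is applied — the ensemble's selection criterion is reported
as designed — but the number of tests is included in every summary so
users can post-correct.

## Voxel mapping

Selected slices fix one coordinate each (sagittal → x, coronal → y,
axial → z); the Cartesian product of the per-projection coordinate lists
is the significant-voxel set. Two counting rules coexist because a slice
can host several selected classifiers: `product_of_counts` multiplies
raw list lengths (the headline combination count), `unique_voxels`
deduplicates first and is the rule used for the exported binary NIfTI
mask, where a voxel is either marked or not.

## Synthetic cohorts

The generator emulates the *statistical structure* of the study, not MS
anatomy:

- **Cohort:** default 181 patients, prevalence 62/181 (34%); exactly
  `round(n × prevalence)` positives. EDSS pairs are sampled so the
  labeling rule reproduces the truth labels across all three threshold
  branches (baselines drawn from a clinical-looking discrete
  distribution over {0, 1.0–5.0, 5.5–7.5}).
- **Volumes:** an ellipsoidal brain phantom (95% of the grid
  half-extent) on the 2 mm MNI grid, zero outside the mask. Intensities
  are generated directly in normalized 0–255 units: base 120, additive
  Gaussian noise (default sd 15), plus a linear intensity ramp
  (default 0.4 intensity units per voxel summed over the three axes).
  The ramp breaks the phantom's mirror symmetry so slice location is
  decodable — as it is in real anatomy — which the slab-location
  pre-training task requires; without it, mirrored slabs would be
  indistinguishable by construction.
- **Rim saturation:** the one-voxel boundary shell of the mask is set to
  255. This pins every subject's maximum so per-volume max-normalization
  is the identity for all subjects; otherwise a strongly planted signal
  could raise positive subjects' maxima and leak a *global* class-
  correlated intensity scale into every slice, defeating the regional
  ground truth.
- **Signal:** progressed subjects get `effect_size` (default 25, in
  0–255 units) added inside each signal box (default one frontal box,
  x ∈ [30, 60], y ∈ [78, 92], z ∈ [40, 60]). Sites are round-robin
  metadata only.

What passing tests on these cohorts show: the machinery recovers a
regional mean-intensity class difference and stays calibrated when none
exists. What they do not show: performance on real MS anatomy — lesions,
atrophy, scanner effects, registration error and confirmation-visit
noise are all absent, and effect sizes in real data are far smaller and
spatially diffuse.

## Desk-scale defaults used by the test suite

The full factorial (100 replicas × 3 projections × 4 slabs, 181
patients) is enumerated and its arithmetic verified exactly, but trained
runs in the test suite use scaled-down study conditions chosen once: 45
patients at prevalence 1/3, 12 (or 6) replicas, one projection, 0.8
train fraction (validation 3 positives / 6 negatives, δ = 1/18), 8×8
slice features. At these sizes a full run takes seconds to tens of
seconds on one CPU while every stage — including the permutation-null
calibration — remains statistically meaningful.

## Known limitations

- The default backbone is linear; interactions or texture cues beyond
  block means are invisible to it. This is a feature for testability,
  not a recommendation for real data.
- DeLong's variance estimate is asymptotic; at 6/12 validation sizes it
  is noisy (the bootstrap agreement check is correspondingly loose), and
  the discrete AUC grid makes the 1.96 threshold conservative in places.
- Replicas share patients, so replica AUCs are positively correlated;
  outlier counts in the replica distributions should not be read as
  independent evidence.
- The voxel map is geometric: no atlas lookup or anatomical labeling is
  performed.
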