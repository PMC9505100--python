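# msprog

Slice-ensemble mapping of the brain regions whose MRI appearance predicts
short-term disability progression in multiple sclerosis (MS).

## The problem

MS disability is scored on the Expanded Disability Status Scale (EDSS,
0–10 in half points). Whether a patient will progress over the next few
years is hard to predict, but structural T1-weighted MRI acquired at
baseline may carry regional hints. `msprog` implements a slice-based
strategy for locating those regions: instead of classifying whole 3D
volumes, it cuts every MNI-registered volume into coronal, sagittal and
axial slices, trains a separate binary classifier ensemble per brain
slab, and asks *which individual slices* support statistically defensible
prediction.

The package is aimed at neuroimaging researchers who want the full
statistical machinery — replica ensembles, permutation nulls, AUC
admissibility bands, DeLong tests and 3D intersection maps — with a
pluggable classifier backbone, and a synthetic-cohort generator with
planted ground truth so every stage is testable without patient data.

## The method

1. **Labeling.** Progression is a baseline-dependent EDSS increase:
   ≥ 1.5 points from a baseline of 0, ≥ 1.0 from baselines 1.0–5.0, and
   ≥ 0.5 from baselines ≥ 5.5.
2. **Geometry.** Volumes on the 2 mm MNI grid (91×109×91) are
   max-normalized to 255 and cut into 79 coronal (y ∈ [17, 95]),
   64 sagittal (x ∈ [14, 77]) and 62 axial (z ∈ [12, 73]) slices; a slice
   is analysed when ≥ 10% of its pixels are non-zero. Each projection is
   partitioned into four contiguous slabs.
3. **Ensemble.** 100 stratified 90/10 train/validation replicas are drawn
   (for a 119 stable / 62 progressed cohort: train 163 = 107+56,
   validation 18 = 12+6). Per replica, projection and slab, a binary
   discriminator is fine-tuned from a slab-location pre-trained state —
   100 × 3 × 4 = 1200 discriminators — and each gets a matched **null**
   twin trained on permuted labels (class counts preserved, validation
   untouched).
4. **ROC.** Validation scores give an exact stepwise ROC per slice; the
   AUC is the Mann–Whitney probability P(score⁺ > score⁻) with ties
   counted ½. The minimal AUC step is δ = 1/(n⁺ n⁻) — 1/(6·12) = 0.0139
   for the reference validation split. Replica AUC distributions are
   summarized by median, quartiles and 1.5×IQR outliers; slab-folded
   AUCs treat every (patient, slice) pair as one instance.
5. **Selection.** A (slice, classifier) pair survives iff its null AUC
   lies in 0.5 ± δ, DeLong's paired test on the correlated ROC curves
   gives Z > 1.96, and the real AUC exceeds the null AUC.
6. **Mapping.** One selected slice per projection pins an (x, y, z)
   voxel; the Cartesian product of selected coordinates forms the
   significant-voxel map, exportable as a NIfTI mask (both the
   combination-product and unique-voxel counting rules are provided).

## Worked example

Desk-scale run on a synthetic cohort with a signal box planted at
x ∈ [30, 60], y ∈ [78, 92], z ∈ [40, 60]:

```python
from msprog import GeneratorConfig, SliceEnsembleModel, generate_cohort

config = GeneratorConfig(
    n_patients=45, prevalence=1/3, seed=3,
    signal_regions=(((30, 60), (78, 92), (40, 60)),),
    effect_size=60.0, noise_sd=15.0,
)
cohort = generate_cohort(config)
model = SliceEnsembleModel(
    cohort.volumes, cohort.patients,
    n_replicas=12, train_fraction=0.8, projections=("axial",), seed=11,
)
results = model.fit()
print(results.summary())
print("selected slices:", sorted(set(results.significant_slices("axial"))))
```

prints

```
Slice-ensemble disability-progression analysis
======================================================
patients: 45  (progressed 15 / stable 30)
replicas: 12  train fraction: 0.80
projections: axial
selection: null AUC in 0.5 +/- delta, Z > 1.96, real AUC towards 1
------------------------------------------------------
    axial:  62 slices | location acc 1.00 |   6 selected pairs | selected AUC [1.00-1.00]
------------------------------------------------------
significant voxels: 0 (product rule), 0 (unique)
tests run without multiplicity correction: 744

selected slices: [18, 29, 43, 44, 48, 50]
```

Reading the output: all 62 axial slices were analysed; the slab-location
pre-training reached held-out accuracy 1.00; six (slice, classifier)
pairs survived the null-band + DeLong selection, four of them (43, 44,
48, 50) inside the planted box z ∈ [40, 60] — the ensemble localizes the
planted signal, with a couple of multiplicity-driven false selections,
as expected from 744 uncorrected tests. The voxel map is empty because
only one projection was analysed; running all three projections
(`projections=("coronal", "sagittal", "axial")`) yields the 3D
intersection and `results.save(outdir)` writes the NIfTI mask.

The same run from the shell:

```bash
msprog simulate --n-patients 45 --prevalence 0.333 --effect-size 60 --seed 3 --out cohort/
msprog run --cohort cohort/ --replicas 12 --train-fraction 0.8 --projection axial --seed 11 --out out/
```

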