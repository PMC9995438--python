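# Methods

## Scope and model

`ctpseg` implements a voxel-wise patch-classification pipeline for ischemic
core/penumbra segmentation on CT-perfusion (CTP) parameter maps, together
with a synthetic phantom generator that emulates the statistical structure
the pipeline assumes.  The pipeline stages are strictly layered: phantom
generation → dual-threshold ground truth → class-balanced patch sampling →
classifier tuning/training → whole-volume inference → evaluation.  Each
stage is usable on real NIfTI data with the same interfaces; the phantom
only replaces the data source.

## Ground-truth labeling

The perfusion lesion is defined as brain voxels with delay time DT ≥ 3 s
(inclusive), the core as lesion voxels with CBF strictly below 30 % of a
reference CBF, the penumbra as the remainder of the lesion.  Inclusivity at
the two thresholds is a convention fixed here for determinism.  The
reference CBF is the mean over non-candidate brain tissue of the hemisphere
contralateral to the candidate's center of mass (midline = central sagittal
plane, axis 0 of the grid); when laterality cannot be established the
whole-brain non-candidate mean is used.  Clinical CTP software computes a
relative CBF threshold against an unspecified normal-tissue reference, so
the reference is configurable (`ThresholdConfig.reference_region`).

After thresholding, the candidate mask is reduced to its largest connected
component (26-connectivity by default; 6/18 available).  Ties are broken
toward the lowest scan-order component.  Cleanup operates on the combined
perfusion-lesion mask, not separately per class, so the core always remains
nested inside the retained lesion.  An empty candidate mask is valid (a
study without a perfusion lesion) and yields a {0, 1} label map.

## Synthetic phantoms

A phantom is an ellipsoidal brain (default semi-axes 55×55×40 mm in a
64×64×24 grid at 2×2×4 mm spacing) containing a spherical penumbra (default
radius 20 mm) with a nested spherical core (default 12 mm; a radius of 0
produces a penumbra-only study).  Each tissue class draws every map from a
Gaussian with class-specific mean and SD, plus additive per-map noise;
values are clipped at 0 and zeroed outside the brain mask.  Defaults
(arbitrary flow/volume units; healthy CBF normalized to 100):

| class    | DT (s)      | CBF        | MTT (s)     | CBV         |
|----------|-------------|------------|-------------|-------------|
| healthy  | 1.0 ± 0.15  | 100 ± 6    | 4.0 ± 0.4   | 4.0 ± 0.3   |
| penumbra | 6.0 ± 0.5   | 60 ± 4     | 9.0 ± 0.8   | 3.2 ± 0.3   |
| core     | 9.0 ± 0.8   | 10 ± 3     | 13.0 ± 1.2  | 1.2 ± 0.25  |

additive noise: DT 0.15, CBF 3, MTT 0.3, CBV 0.2 (SDs, scalable).

The SDs place every class mean ≥ ~5 standard deviations from the nearest
decision threshold, so the class structure of a generated study is stable
across seeds: thresholding a default phantom reproduces its generating
geometry voxel-for-voxel, and cohort-level sample accounting is exact rather
than approximate.  With all SDs set to zero the equivalence is literal: the
ground-truth builder recovers the generator's voxel sets exactly, which the
tests use as a two-sided oracle between the two modules.

Cohorts jitter lesion center (±6/±6/±4 mm), side (left/right flip,
optional) and radii (±8 %); per-study generation seeds are
`cohort_seed + index`, and all jitters come from a single cohort-level RNG,
so cohorts are bit-reproducible.  The core radius is sized so the smallest
jittered core comfortably exceeds the per-class sampling quota, mirroring
the intended use where the smallest real core far exceeds the 300-voxel
quota.  Healthy tissue is homogeneous-plus-noise; no gray/white contrast,
vasculature, or time-attenuation simulation is attempted.  Consequently,
passing tests demonstrate correctness of the pipeline mechanics and
recoverability under the stated noise model — not segmentation performance
on real, spatially heterogeneous patient data.

**Skull-rim artifacts.**  Beam hardening and partial-volume effects near the
skull elevate DT in brain-edge voxels, mimicking a perfusion lesion.  The
artifact model elevates DT (plus optional Gaussian noise) in the set of
brain voxels within `thickness_mm` of the brain boundary restricted to an
axial angular sector (`arc_deg` wide at `center_deg`); the affected voxel
set is recorded in the study metadata for robustness measurements.  A
sector, rather than a full ring, matches the localized appearance of such
artifacts and keeps the artifact component smaller than the true lesion, so
single-lesion cleanup removes it — which is exactly the behavior the
robustness tests assert.

## Sampling, patches, standardization

Per image, an equal number of voxels (default 300) is sampled uniformly
without replacement from each class of the lesion map; an image whose map
has no core contributes its core quota as extra non-ischemic samples
instead, so every image yields 4 × n rows.  A present class smaller than the
quota is an error by design.  Each sample's feature row concatenates, per
selected map (default order DT, CBF, MTT, CBV), the 27 neighborhood values
in a fixed raster order over offsets (−1,−1,−1) … (1,1,1) (center at index
13); out-of-volume neighbors contribute 0.  Rows from all images are stacked
into one matrix with per-row provenance (study id, voxel coordinate), split
60/40 into train/validation at the row level, and standardized per column to
mean 0 / SD 1 with moments fitted on the training rows only (zero-variance
columns pass through centered with scale 1).  Min-max scaling to [−1, 1] is
available as an alternative (`standardize_method="minmax"`); z-scoring is
the default because it is what the standard scaler of scikit-learn computes.

## Model tuning

Hyperparameter spaces live in `ctpseg.hyperparams` (LR: C log-uniform
10⁻³–10³; RF: trees, depth, split size, feature fraction; XGB: trees, depth,
learning rate, subsample; SVM: linear/polynomial kernels, decade C grid,
degree 2–3).  Tuning is a randomized search (default 10 candidates, 3-fold
CV, accuracy scoring) followed, except for SVM, by a grid refinement of ×0.5
/ ×1 / ×2 around the randomized optimum over the two most influential
numeric parameters, clipped to the space bounds; refining a small
neighborhood keeps the grid affordable while narrowing the optimum.  The
winner is refit on the full training split.  Multiclass handling is native
for RF/XGB, multinomial for LR, one-vs-rest for SVM; SVM class scores for
ROC-AUC are a softmax over the one-vs-rest decision margins (row-stochastic
and argmax-consistent with `predict`), avoiding Platt calibration.
Everything downstream of a fixed seed is deterministic with `n_jobs=1`.

Validation metrics are sample-level: macro one-vs-rest ROC-AUC, accuracy,
and per-class Dice/Jaccard computed on the label vectors.  Feature-set
comparisons (two-map DT+CBF vs four-map) subset the stored channel blocks of
the same matrix; rows are never re-sampled.

## Inference and evaluation

Whole-volume prediction classifies every brain-mask voxel (optionally every
grid voxel) in batches; batch size is a memory knob and never changes
results.  The bundle's training-time standardizer is reused verbatim.
Predicted labels are written back at their coordinates; optional per-voxel
score channels satisfy argmax(scores) = label everywhere.  A
`largest_component` post-processing mirroring the ground-truth cleanup is
available but off by default, since raw reconstructions are what get
evaluated.

Core and penumbra are evaluated separately as binary masks.  DSC and JI use
the convention that two empty masks score 1 (perfect agreement on absence)
and exactly one empty mask scores 0 — required for penumbra-only studies.
Agreement bands are half-open ([0.2, 0.4) "Fair", etc.), with exactly 0 its
own "No Agreement" category and 1.0 in the top band; the band edges at 0.2,
0.4, 0.6, 0.8 are assigned upward by convention.  Volumes are voxel counts
× voxel volume / 1000 (mL).  Cohort summaries report per-class mean/SD,
two-tailed paired t-tests of DSC vs JI (identical lists give t = 0, p = 1;
constant nonzero differences a degenerate infinite t), and Pearson
correlations of the metrics against ground-truth volume and of predicted
core volume against follow-up volumes when provided (overall and excluding
artifact-flagged images).

## Experiment protocols and problem sizes

`ctpseg.workflows` fixes the shared experimental designs.  The
sample-accounting protocol uses the full-size default phantom (86 studies,
2 without core, 300 voxels/class/image).  Training/inference experiments use
a compact 32×32×20 grid at 3×3×4 mm — chosen so a complete
generate→label→sample→tune→predict→evaluate cycle over a 20-study cohort
runs in minutes on a single CPU — with 100 voxels/class/image and a 3-candidate
search.  The noise-robustness experiment scales all additive noise SDs by a
common factor (1, 5, 12) and re-runs the full cycle per level; because the
ground truth itself is re-derived from the noisy maps (as with patient
data), rising noise both corrupts the labels near region boundaries and
blurs the feature distributions, and reconstruction Dice degrades
monotonically.

The artifact-robustness protocol uses a deliberately nonlinear construction:
the penumbra matches healthy tissue on every map except DT, and the rim
artifact elevates DT *beyond* penumbral values (≈11 s vs ≈6 s) at healthy
CBF, with a rim thick enough (9 mm) that its inner voxels contain no
out-of-brain zeros in their patches.  Along any monotone combination of
DT-derived features the penumbra is then a band strictly between two
non-ischemic regimes; a multinomial logistic model, whose pairwise decision
boundaries are single hyperplanes, cannot separate both sides and
misclassifies much of the rim as penumbra, while trees and polynomial-kernel
SVMs represent the interval rule directly.  This is the desk-scale analogue
of the clinical observation that linear first-order models are the most
susceptible to artifactual perfusion lesions.

## Known limitations

- Phantoms are homogeneous ellipsoids/spheres; no anatomy, no spatial
  autocorrelation of noise, no partial-volume mixing at region borders.
  Near-perfect phantom Dice therefore says nothing quantitative about
  patient-data performance.
- The relative-CBF reference in clinical software is unspecified; the
  contralateral-hemisphere default here is one reasonable choice and
  alternatives change core volumes.
- Hyperparameter spaces are desk-scale; no claim is made that the searched
  ranges match any particular clinical study's budget.
- DSC/JI conventions for empty masks and band edges are package conventions
  where the literature is silent or ambiguous.
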