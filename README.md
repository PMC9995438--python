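# ctpseg

Voxel-wise machine-learning segmentation of **ischemic core and penumbra**
from CT-perfusion (CTP) parameter maps, with a synthetic whole-brain phantom
generator so the entire pipeline is testable without patient data.

In acute ischemic stroke triage, four co-registered hemodynamic maps are
derived from a CTP acquisition: delay time (DT, s), cerebral blood flow
(CBF), mean transit time (MTT) and cerebral blood volume (CBV).  The
clinical dual-threshold definition labels each brain voxel as

- **perfusion lesion**: DT ≥ 3 s;
- **ischemic core**: perfusion-lesion voxels with CBF < 30 % of the mean CBF
  of normally perfused (contralateral) tissue;
- **penumbra**: perfusion lesion minus core,

followed by a single-lesion cleanup that keeps only the largest connected
component (removing skull-related artifact islands).  `ctpseg` implements
this labeling, then learns to reproduce it with voxel-wise classifiers: each
voxel is described by the 27 values of its 3×3×3 neighborhood in every map
(zero-padded at the volume border, 27·C features for C maps), classes are
balanced by sampling an equal number of voxels per class per image, and four
model families — multinomial logistic regression (LR), random forest (RF),
gradient-boosted trees (XGB) and one-vs-rest SVM — are tuned by randomized
search with 3-fold cross-validation (plus a local grid refinement).  Trained
models are applied to every voxel of a study and the predictions are
reconstructed into a label volume (0 background, 1 non-ischemic brain,
2 penumbra, 3 core), which is scored against the dual-threshold ground truth
with the Dice similarity coefficient DSC(A,B) = 2|A∩B|/(|A|+|B|), the
Jaccard index JI = |A∩B|/|A∪B| = DSC/(2−DSC), agreement categories and
volumes in mL.

## Layout

- `src/ctpseg/` — the library: `synthetic_ctp` (phantom generator),
  `ground_truth` (dual-threshold labeling), `patch_sampling` (balanced
  sampling, patches, split, standardization), `modeling` (tuning/training),
  `inference` (whole-volume reconstruction), `evaluation` (DSC/JI, volumes,
  cohort statistics), `workflows` (end-to-end protocols).
- `analysis/` — numbered narrative drivers that run the study and write
  tables under `results/`.
- A thin `ctpseg` CLI mirrors the stages
  (`simulate` / `label` / `sample` / `train` / `predict` / `evaluate`).

## Worked example

```bash
python analysis/01_simulate_cohort.py
```

```
cohort: 86 studies (2 without core), 300 voxels/class/image, seed 20260901
total patch rows: 103200
class totals: background 25800, non-ischemic 26400, penumbra 25800, core 25200
images without core: 2 (each contributes 600 non-ischemic samples)
```

Every image yields 4 × 300 = 1,200 samples: images lacking a core substitute
300 extra non-ischemic voxels, so the 86-study cohort always produces exactly
103,200 balanced rows — the bookkeeping above is a deterministic consequence
of the sampling rules.

```bash
python analysis/03_whole_image_eval.py
```

```
trained XGB (four-map), CV accuracy 1.0000
study_000: core DSC 1.0000 (6.6 vs 6.6 mL, Almost perfect agreement), penumbra DSC 1.0000
...
cohort: core DSC 1.000 (SD 0.001), JI 0.999; penumbra DSC 1.000 (SD 0.001)
predicted core vs follow-up core volume: r = 1.000 (p = 5.87e-13)
```

On clean, well-separated phantoms the pipeline recovers the ground-truth
lesion maps essentially voxel-exactly; the per-image table reports Dice,
Jaccard, agreement category and core/penumbra volumes in mL for each
held-out study.  `analysis/02_train_and_compare.py` compares the four model
families on two-map (DT, CBF) vs four-map feature sets, and
`analysis/04_artifact_robustness.py` measures false-positive rates inside
simulated skull-rim DT artifacts (LR 0.43 vs RF 0.00 / XGB 0.00 / SVM 0.03
— flexible models suppress artifactual lesions that a linear model cannot).

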