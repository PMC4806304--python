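# alfa — multi-atlas brain extraction for neonatal MRI

Whole-brain segmentation (brain extraction / skull stripping) is the first
step of most neuroimaging pipelines, and tools developed on adult data often
fail on neonatal scans: head size and shape vary strongly in early life,
grey/white contrast is low, and T1w/T2w sequences invert tissue contrast.
This package implements a multi-atlas approach designed for that setting,
built to work with very few labelled training images:

1. **Uniform atlas selection (UAS)** — a greedy max–min (Kennard–Stone-style)
   rule, initialised at the image closest to the dataset mean, picks k
   atlases spread "uniformly" through the intensity data space:
   `argmax_{i∉S} min_{j∈S} d(x_i, x_j)`, with d the Euclidean distance
   between flattened, histogram-standardized intensity vectors. The
   selection is target-independent and favours *complementary* atlases over
   redundant near-duplicates (the most-similar baseline, MSAS, is included
   for comparison).
2. **Registration** — each selected atlas is aligned to the target by a
   12-dof affine followed by a coarse-to-fine B-spline free-form deformation
   (20/10/5 mm control spacing, mutual-information metric; SimpleITK-based,
   pluggable) and its brain mask is propagated.
3. **Voxel-wise label fusion** — every target voxel is labelled by its own
   local classifier (LDA or Naive Bayes), trained on the k × 26 samples from
   the 26-neighbourhoods of the warped atlases, each sample a 5-vector
   (I, |I_x|, |I_y|, |I_z|, r) of intensity, [−1 0 1] derivative magnitudes
   and gradient norm. A majority-vote baseline is included.

Evaluation utilities (Dice, Hausdorff, sensitivity/specificity, volumes,
Bland–Altman, cohort FP/FN projection maps), a synthetic head-phantom
generator with exact ground truth, and a CLI round out the package. See
`docs/methods.md` for the model details and design decisions.

## Worked example

Run leave-one-out cross-validation on a small synthetic cohort — each subject
in turn is held out as the target and segmented from atlases selected among
the rest:

```python
from alfa import PhantomSpec, make_cohort, RunConfig, FusionConfig, loocv

spec = PhantomSpec(shape=(32, 32, 32), brain_axes=(10., 8., 9.),
                   skull_thickness=2., scalp_thickness=2., noise_sigma=2.,
                   deform_amplitude=1.5, deform_scale=5., seed=11)
library = [(s.image, s.truth_mask) for s in make_cohort(spec, 6)]
cfg = RunConfig(k=2, registration_mode="affine",
                fusion=FusionConfig(classifier="lda", k=2))
df = loocv(cfg, cohort_manifest="", library=library)
print(df[["case_id", "dice_pct", "hausdorff_mm"]].to_string(index=False))
print(f"mean Dice: {df['dice_pct'].mean():.2f}%")
```

prints

```
   case_id  dice_pct  hausdorff_mm
subject_11 99.185641      2.000000
subject_12 98.981806      2.236068
subject_13 98.186702      2.236068
subject_14 99.220176      2.236068
subject_15 98.692153      1.732051
subject_16 99.319050      1.732051
mean Dice: 98.93%
```

Each row is one held-out phantom: `dice_pct` is the overlap between the fused
mask and the exact ground truth (100 = perfect), `hausdorff_mm` the worst
surface-to-surface error in mm — here about two voxels, concentrated at the
brain boundary where the local classifiers arbitrate between atlases.

The same pipeline is scriptable from the shell:

```sh
alfa phantom --out cohort/ --n 10 --shape 64 --seed 0
alfa select  --manifest cohort/manifest.tsv --k 3 --strategy uas
alfa loocv   --config run.yaml --cohort cohort/manifest.tsv --out metrics.csv
```

(`alfa run --config run.yaml` segments configured targets against an atlas
manifest; `register`, `fuse` and `evaluate` expose the individual stages.)

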