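# Methods

## Problem and approach

Brain extraction (skull stripping) of neonatal MRI segments a head image into
brain and non-brain voxels. The neonatal setting is hard for tools tuned on
adult data: head size and shape vary strongly, grey/white-matter contrast is
low and changes with maturation, and T1w/T2w sequences invert the tissue
contrast. This package implements a multi-atlas strategy built from three
stages:

1. **Uniform atlas selection (UAS).** All library images are brought to a
   common space, intensity-standardized, and flattened into data vectors
   x_i. A subset S of k atlases is chosen greedily: the first is the vector
   closest to the dataset mean μ, and each subsequent atlas maximises its
   minimum distance to the already-selected set,
   argmax_{i∉S} min_{j∈S} d(x_i, x_j). This is the Kennard–Stone max–min
   design with a mean-centred initialisation: the selected atlases are spread
   "uniformly" through the data space rather than clustered around any one
   anatomy, and the selection is independent of the test image. The baseline
   comparator, most-similar atlas selection (MSAS), instead ranks the library
   by distance to the target and keeps the k nearest.
2. **Registration.** Each selected atlas is aligned to the target by a
   12-degree-of-freedom affine followed by a coarse-to-fine free-form
   B-spline deformation with control-point spacings of 20, 10 and 5 mm, and
   its brain mask is propagated through the resulting transform.
3. **Label fusion by local classification.** Every target voxel gets its own
   training set: in each warped atlas, the 26 neighbours of the voxel
   contribute one sample each (k × 26 samples at interior voxels; truncated
   at the grid boundary), with features (I, |I_x|, |I_y|, |I_z|, r) — the
   intensity, the absolute responses of the central-difference filter
   [−1 0 1] along each axis, and the gradient magnitude
   r = sqrt(I_x² + I_y² + I_z²) — and labels taken from the warped atlas
   masks. A linear classifier (LDA or Gaussian Naive Bayes) fitted on those
   samples labels the voxel from its own feature vector.

## Distance and intensity standardization

The inter-image distance d(i, j) is the Euclidean norm of the difference of
the flattened intensity vectors (L1 and a normalised-cross-correlation
distance are selectable). To keep the distance from being dominated by
scanner gain, vectors are built after histogram-landmark standardization:
percentile landmarks (1st, deciles, 99th) of the above-mean foreground are
averaged over the library and each image is mapped piecewise-linearly onto
those reference landmarks, clipped to the [first, last] landmark. The same
landmarks standardize a test image before most-similar selection, and target
and atlases before feature extraction (both disableable). The mapping is
monotone non-decreasing; tied landmarks (which arise for piecewise-constant
synthetic images) collapse to steps.

## Classifiers

The per-voxel fits use closed-form batched linear algebra rather than
per-voxel estimator objects (the difference between seconds and hours on a
64³ grid):

- **LDA**: class means μ_c, pooled covariance Σ = scatter/(n−2) plus a ridge
  `lda_regularization`·I (default 1e-6, keeping Σ invertible for degenerate
  neighbourhoods), discriminants δ_c(x) = xᵀΣ⁻¹μ_c − ½μ_cᵀΣ⁻¹μ_c + log π_c.
- **Naive Bayes**: per-class, per-feature Gaussians with variances floored at
  1e-9 and empirical priors.

Posterior ties label the voxel brain (favouring sensitivity at boundaries).
A single-class training set short-circuits to that class. Where all k × 26
neighbour labels agree, the unanimous label is returned without fitting; this
*unanimity shortcut* provably cannot change the output (a single-class fit
predicts nothing else) and confines classification to a thin band around the
brain boundary. Note the shortcut condition is agreement of the neighbour
*training labels*, not of the atlas labels at the centre voxel: a voxel whose
atlas labels agree centrally may still be re-classified from its mixed
neighbourhood, so fusion of even perfectly identical atlases reproduces their
mask only up to boundary voxels (in practice > 99% Dice); the majority-vote
mode copies labels exactly. Majority vote assigns the modal atlas label with
ties labelled brain.

An optional post-process keeps the largest 26-connected component and fills
enclosed holes (off by default).

## Registration backend

The built-in backend drives SimpleITK's v4 registration framework:

- Affine stage: Mattes mutual information (32 bins), moments initialisation,
  regular-step gradient descent (300 iterations, min step 1e-6), 3-level
  pyramid (shrink 4/2/1, smoothing 2/1/0 mm), 25% regular sampling with a
  fixed seed.
- Nonlinear stage: multi-scale B-spline initialised at the coarsest
  control-point spacing and refined per level (20/10/5 mm by default),
  line-search gradient descent (10 iterations/level), 10% sampling, shrink
  4/2/2. Per-parameter scale estimation is deliberately disabled: B-spline
  coefficients all share units of mm, and ITK's physical-shift estimator
  dominates runtime for fine meshes.

The framework exposes Mattes mutual information rather than the normalised
variant; for the registration problems here the two are interchangeable in
practice, and the backend records its metric values (initial and converged)
in the transform metadata. Mutual information's discretisation bias means
self-registration returns identity only to ≈0.3°/0.1 mm rather than exactly.
Transforms are exported as a world-coordinate affine plus a dense residual
displacement field on the target grid, so applying a transform (trilinear for
images, nearest-neighbour for masks, out-of-field filled with the image
minimum) is plain NumPy/SciPy and bitwise reproducible. Any object providing
`register`/`apply_transform` can replace the backend; an adapter that shells
out to an external registration command and exchanges a dense displacement
field via NIfTI is included but never required.

## Synthetic phantoms

The phantom generator stands in for a clinical cohort. A deterministic
template nests scalp, skull and brain ellipsoid compartments (the brain holds
a white-matter core and grey-matter rim; swapping their mean intensities
emulates T2w-like contrast). Each subject warps the template by a smooth
random displacement (white noise, Gaussian-smoothed at `deform_scale`,
rescaled to a maximum amplitude `deform_amplitude`), applies a global
intensity scaling drawn from [0.8, 1.2], and adds i.i.d. Gaussian noise to
the image only — truth masks are warped with the same field
(nearest-neighbour) and never see noise. Defaults: 64³ grid at 1 mm,
brain semi-axes (20, 16, 18) mm, 3 mm skull and 4 mm scalp shells,
deform_amplitude 2.5 mm, deform_scale 8 mm, noise σ = 5 intensity units
(≈ 4% of the WM mean; end-to-end benchmarks use σ = 2, a mild-noise regime).
A clustered variant shares one large deformation per cluster with small
(0.5 mm) individual perturbations, emulating a library containing groups of
near-duplicate anatomies — the regime in which most-similar selection picks
redundant training data while the max–min rule picks complementary ones.

What the phantoms do **not** model: bias fields, partial-volume averaging,
Rician noise statistics, cortical folding, or real inter-subject anatomy.
Passing phantom benchmarks therefore demonstrates the pipeline's mechanics —
selection spread, registration recovery of smooth warps, classifier
behaviour at controlled boundaries — not clinical-grade accuracy on real
neonatal data.

## Evaluation

Dice (2|A∩M|/(|A|+|M|), percent; two empty masks count as perfect, flagged
by convention), Hausdorff distance (strict maximum surface-to-surface
Euclidean distance in mm; surfaces are foreground voxels with a six-connected
background neighbour, distances via exact distance transforms), sensitivity
TP/(TP+FN) and specificity TN/(TP+FP) with undefined rates reported missing
rather than zero, mask volume in ml, Bland–Altman agreement of paired
volumes (mean difference ± 1.96 sample SD), and cohort FP/FN localisation
maps: per-voxel error frequencies across subjects in a common space projected
on the axial/coronal/sagittal planes by maximum intensity (mean projection by
flag), preserving the 0–1 scale.

## Benchmarks and problem sizes

`alfa.benchmarks` fixes the two end-to-end experiments the acceptance script
re-runs. The *recovery* benchmark uses a 15-subject 64³ cohort (10 atlases,
5 targets), k = 3, UAS, affine+FFD registration, LDA fusion, with a
majority-vote baseline fused from the same warped atlases. The
*selection-strategy* benchmark uses a clustered 20-atlas library (4 clusters)
and 10 independent targets at k = 2, with registrations cached per
(atlas, target) pair so both strategies share identical warps where their
choices overlap. These sizes keep a full run in minutes on one CPU while
leaving the comparisons well away from their decision thresholds.

## Numerical and design notes

- All randomness flows from explicit integer seeds; identical seeds give
  bitwise-identical phantoms, selections and fusion masks.
- Ties in selection argmin/argmax break to the lowest library index.
- Windowed-sinc resampling renormalises by a resampled ones-image because the
  truncated Lanczos kernel's weights do not sum exactly to one (a constant
  image must stay constant).
- Boundary handling: feature extraction uses replicate padding; neighbourhood
  gathering truncates to in-grid voxels (corner voxels contribute 7 samples
  per atlas) rather than fabricating data.
- Composition of transforms resamples the inner displacement field at the
  outer-mapped points; for pure affines it reduces to the matrix product.

## Known limitations

- The built-in registration is tuned for roughly-aligned same-protocol
  volumes of moderate size; strongly rotated or cropped inputs need the
  hyperparameters (pyramid, iterations, sampling) adjusted via
  `BuiltinBackend`.
- Fusion assumes atlases already live on the target grid; no implicit
  resampling is performed.
- N4-style bias-field correction is assumed done upstream; DICOM and 4-D
  inputs are out of scope.
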