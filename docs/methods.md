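# Methods

This note documents the models, numerical choices and limitations of the
`organseg` stack: what each stage computes, which parameters matter, and
what the desk-scale phantom experiments do and do not demonstrate.

## Problem setting

Automated organ segmentation of whole-body CT assigns one of 100 organ
labels (77 bones, 23 soft-tissue organs) to every voxel, so that
quantitative measurements — volumes, mean/max intensities, and, with a
co-registered PET series, standardised uptake values and total lesion
uptake — can be extracted per organ without manual contouring.  Vertebrae
and ribs are *instance* labels: the voxel class ("vertebra") is locally
recognisable, but the anatomical index (Th7 vs Th8) is not, because a
network's receptive field is far smaller than the spine.

## Coordinate and data conventions

Volumes are scalar fields on an `ImageGrid`: arrays indexed `[x, y, z]`
(z = slice axis), 0-based voxel indices, world position =
`origin + index * spacing` (mm), +x towards the patient's left.  CT is in
Hounsfield units; PET activity concentration is carried in kBq/ml.  The
organ catalogue is shipped as a versioned plain-text table and expands
deterministically (bilateral organs to left/right entries, vertebral
groups to numbered vertebrae, the rib group to left/right pairs per
level), giving contiguous label indices 1..100.

## Preprocessing

CT intensities are clamped to [-800, 800] HU and divided by 800, so
network inputs lie in [-1, 1].  Images at other resolutions are resampled
to the operating spacing of (1.36, 1.36, 3) mm by trilinear
interpolation; predicted label maps travel back to the native grid by
nearest-neighbour interpolation (labels are categorical; half-way ties
round up).  Training patches are augmented with in-plane rotations
(±0.15 rad), isotropic scaling (±10%) and intensity shifts (±100 HU).
The intensity shift is applied in HU *before* clamping — a ±100 HU shift
only has meaning on the HU scale; the order is configurable.  Geometric
transforms are computed in millimetres (so anisotropic voxels rotate
correctly) and applied with trilinear interpolation to the image and
nearest-neighbour to label channels.  Volumes smaller than a patch are
mirror-padded to avoid HU discontinuities at the border.

## Networks

Two fully convolutional networks share one body: a multi-resolution
valid-convolution design in the U-Net family.  Pooling early in the
network produces up to four resolution levels (full field of view only on
the coarsest, which keeps early full-resolution layers cheap); each level
runs a stack of valid 3D convolutions; coarse features are nearest-
neighbour upsampled, centre-cropped against the skip path, concatenated
and refined.  Two kernel shapes, (3, 3, 3) and (3, 3, 1), are interleaved
at every level so the receptive field stays approximately cubic in
millimetres on (1.36, 1.36, 3) mm voxels.

* **Semantic head**: one SoftMax channel per label plus background.
* **Instance head**: three SoftMax channels (background, vertebra, rib)
  plus three linear channels regressing, per foreground voxel, the offset
  from the voxel to the centre of the instance that owns it.  Offsets are
  learned in units of 30 mm (a scale knob) for conditioning; predictions
  are reported as absolute world-mm centres.  Offset-from-voxel
  parameterisation keeps the target translation-invariant, which suits a
  fully convolutional net; an absolute-coordinate mode is retained as an
  option.

The receptive field is derived analytically from the layer stack (a valid
convolution with kernel k adds `(k-1)·jump`; a stride-2 pool adds `jump`
and doubles it; nearest upsampling halves it).  The full-scale default
configuration — per-level conv counts 8/4/4/4 (encoder+decoder), half of
each level's kernels flat in z — yields exactly (136, 136, 72) voxels =
(184.96, 184.96, 216) mm.  A gradient-support test (ReLUs disabled so no
path can be masked) confirms the algebra empirically on a small
configuration.  The exact filter counts and depths of the full-scale
system are free parameters of the config system; the constraints that are
checkable — four resolutions, valid convolutions, pooling at the start,
the two kernel shapes, the declared receptive field — are enforced.

Implementation note: the networks, backpropagation and the Nadam
optimiser (Adam with Nesterov momentum) are implemented directly in
NumPy (float32, im2col-style convolutions via strided views and
`tensordot`).  Gradients are verified against finite differences in the
test suite.

### Training

Categorical cross-entropy, averaged over voxels whose validity mask is
set; studies in which an organ was never annotated contribute nothing
for that organ's voxels (mask zero), which is how per-study-incomplete
annotation is handled.  The instance net adds a masked squared-error term
on centre offsets over true vertebra/rib voxels (weight 1:1 by default —
a config knob; the balance is not critical on phantoms).  Studies split
80/20 into train/validation at the study level.  Patches are drawn at
uniformly random valid origins, with a configurable probability
(default 0.5) of centring on a random foreground voxel to counter class
imbalance.  Optimisation is Nadam with its reference hyperparameters
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8); everything is seeded and a training run
is bit-reproducible.  A NaN loss raises immediately.

### Tiled inference

All convolutions are valid, so the network commutes with translations by
its pooling stride (2^(levels-1)).  Whole volumes are processed in
overlapping tiles placed on the stride lattice, with the input
mirror-padded by the network margin so the output covers the full grid;
the result is mathematically independent of the tiling plan.  In float32
arithmetic BLAS summation order introduces deviations at the 1e-7 level;
equivalence is asserted at 1e-5.

## Instance assembly

Vertebra-class and rib-class voxels are clustered separately over their
predicted centre coordinates, after quantising centres to cells of a
quarter of the linkage threshold (keeps the pairwise problem small;
quantisation error ≤ threshold/8·√3).  The merge criterion is
agglomerative **average** linkage with a millimetre threshold defaulting
to half the expected inter-vertebra pitch (9 mm for an 18 mm pitch).
Single linkage — the natural "connected groups of centres within the
threshold" reading — is available as an option and behaves identically on
clean fields, but under per-voxel centre noise its chaining property lets
a handful of stray predictions bridge adjacent vertebrae; average linkage
keeps clusters compact without fixing their number in advance, which
matters because the number of instances varies between images.  Clusters
below a minimum size (default 5 voxels) are discarded.

Vertebra instances are numbered cranio-caudally (descending z centroid)
into consecutive registry labels of a declared region run; the anchor
(which instance is C1 vs Th1) is heuristic by design and the region is an
explicit argument.  Ribs take the level of the z-nearest vertebra and the
side of the midline (mean vertebra centroid x) their centroid falls on.
More instances than registry slots triggers a warning and truncation.

Morphological cleanup applies to every label: keep the largest
26-connected component (size ties break toward the component containing
the lexicographically lowest (z, y, x) voxel), then fill interior
cavities (background 6-components not connected to the volume border).
The composite is idempotent.  In fusion, voxels claimed by the instance
pipeline take their anatomical instance label; everything else takes the
semantic argmax (ties toward the lower channel index); labels are
post-processed in ascending index order, so a later label's hole fill may
overwrite an earlier one's.

## Evaluation metrics

Per-label voxel confusion counts are exact integers; Dice =
2TP/(2TP+FP+FN), recall = TP/(TP+FN), precision = TP/(TP+FP), and Dice is
identically the harmonic mean of the other two.  When both masks are
empty all three default to 1 ("agreement on absence") with a NaN option —
the convention must be explicit under sparse annotation.  Labels missing
from a study's annotation are excluded entirely and never affect other
labels.  Two aggregations are reported separately because they genuinely
differ: the unweighted mean of per-organ metrics (per group and overall)
and pooled-voxel foreground metrics on the union of all labels.
Inter-observer agreement reuses the same machinery; Dice is symmetric
under reader exchange while recall and precision swap.

## Quantification and SUV

Per label: volume = voxel count × voxel volume (exact), mean and max of
the value volume, 26-connected component count, and total uptake =
Σ value × voxel volume (identically mean × volume).  SUV uses the
body-weight variant, the clinical default:
`SUVbw = concentration[Bq/ml] · weight[g] / dose_at_scan[Bq]`, with the
injected dose decay-corrected to the series start
(`dose · 2^(-Δt/T½)`; F-18 half-life 6586.2 s default).  Stored-value
units (Bq/ml or kBq/ml) are read from the PET metadata; a
"decay already applied" dialect is handled by a zero injection-to-scan
delay.  Missing dose or weight yields a report without SUV columns
rather than an error.

## DICOM handling

CT/PT series are written slice-wise with standard geometry tags and the
linear rescale (the CT intercept adapts downwards so noisy air voxels
below -1024 HU are not clipped; stored values are integers, so float HU
round-trip to the nearest unit).  Label maps are stored as binary DICOM
Segmentation objects: one packed 1-bit frame per (segment, slice), the
organ name in SegmentLabel and the registry index in SegmentDescription,
so write→read reproduces the array and names exactly.  NIfTI-1 is the
internal interchange format.

De-identification applies a configurable attribute profile modelled on
the DICOM confidentiality profile: identifying attributes are removed or
replaced with dummies, private tags are always stripped, pixel data is
untouched, and UIDs are remapped through a consistent injection per
session so study/series linkage survives.  The default profile is
conservative (dates dummied rather than shifted), which also makes a
second pass a no-op on attribute values.  A byte-scan test asserts that
no profile-listed value survives anywhere in the output files.

## The phantom generator

Phantoms stand in for annotated patient studies.  They are geometric,
not anatomical: ellipsoid/box/tube "organs" with tissue-like HU means
(lung ≈ -700, liver ≈ +60, bone ≈ +700 on an air background), optional
per-organ texture jitter, global Gaussian noise (default sd 20 HU,
a plausible low-dose CT noise level), and a spine of stacked vertebra
boxes (24×20×12 mm, 6 mm gaps, small z-jitter) with rib tubes attached
left and right — reproducing the "repeated instances with similar
appearance" structure the instance network targets, at toy scale.
Default grid: 64³ voxels at (2, 2, 3) mm, CPU-trainable in minutes.
All geometry is specified in millimetres, so a spec rasterised at
different resolutions yields consistent truth; geometry jitter and voxel
noise draw from independent seed streams so labels do not depend on
voxel counts.  Ground truth is exact: label maps, per-instance
voxel-centroid centres, and an annotation mask that can be sparsified
per study.

What phantoms do **not** emulate: real anatomical shape variation,
contrast phases, soft-tissue boundaries with genuinely low contrast,
metal and motion artefacts, inter-reader disagreement.  Passing the
phantom experiments demonstrates that the machinery — losses, geometry,
clustering, numbering, quantification — is correct, not that the trained
surrogates would segment patients.

## Desk-scale experiment sizes

The surrogate experiments (also re-run by `scripts/acceptance.py`) use:
20 phantoms of 64³ voxels per cohort, a reduced 2-resolution network
(width 10, receptive field 14³ voxels), 28³ training patches, batch 8,
16 epochs × 25 Nadam steps at learning rate 1.5e-3 — about two minutes
per network on one CPU core.  Held-out per-label Dice for the three-organ
semantic task is typically ≥ 0.93; the instance net's mean centre error
on vertebra voxels is ≈ 10 mm, comfortably below the 18 mm inter-vertebra
pitch that separates instances.  Clustering experiments use 50 spine
phantoms with 3–8 vertebrae; oracle-equivalence checks use 100 random
≤ 13³ arrays per operation.

## Known limitations

* The instance surrogate's centre error (~10 mm) is adequate for
  instance separation at an 18 mm pitch but would need a finer operating
  resolution and more capacity for cervical-scale anatomy.
* Vertebra numbering is anchored heuristically at the most cranial
  instance; a missed or spurious top vertebra shifts every subsequent
  index by one.  No shape-model or graph-matching refinement is applied.
* The DICOM writers produce minimal, internally consistent objects (no
  orientation other than axial identity, single series per directory).
* Average-vs-single linkage and the linkage threshold are behavioural
  knobs; the defaults are tuned to the phantom geometry scale and should
  be re-examined for other spacings.
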