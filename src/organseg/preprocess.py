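"""Intensity normalisation, resampling, patch sampling and augmentation.

CT intensities are clamped to [-800, 800] HU and divided by 800 before
entering a network, so inputs live in [-1, 1].  Images acquired at a
different resolution are resampled to the training spacing of
(1.36, 1.36, 3) mm with trilinear interpolation; predicted label maps are
resampled back to the native grid with nearest-neighbour interpolation.
Training patches are drawn at random positions, augmented with moderate
rotations (±0.15 rad), scaling (±10%) and intensity shifts (±100 HU), and
carry a validity mask so organs that were never annotated in a study do
not contribute to the loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

import numpy as np
from scipy import ndimage

from .core import AnnotationMask, ImageGrid, LabelMap, Modality, Volume

if TYPE_CHECKING:  # pragma: no cover
    from .phantom import PhantomTruth

__all__ = [
    "NormalizationParams",
    "AugmentationParams",
    "PatchSample",
    "TRAINING_SPACING",
    "clamp_scale",
    "resample_image",
    "resample_labels_back",
    "sample_patch",
    "augment",
    "threshold_mask",
]

#: Voxel spacing (mm) at which the networks were designed to operate.
TRAINING_SPACING = (1.36, 1.36, 3.0)


@dataclass(frozen=True)
class NormalizationParams:
    """Clamp bounds and scale for CT normalisation (HU)."""

    clamp_low: float = -800.0
    clamp_high: float = 800.0
    scale: float = 800.0

    def __post_init__(self):
        if self.clamp_low >= self.clamp_high:
            raise ValueError("clamp_low must be < clamp_high")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")


@dataclass(frozen=True)
class AugmentationParams:
    """Ranges for the training-time augmentations.

    Rotation is in-plane (about z) in radians, scaling is an isotropic
    relative factor, and the intensity shift is in HU applied to the image
    before clamping/normalisation.
    """

    rotation_rad: float = 0.15
    scale_fraction: float = 0.10
    intensity_shift_hu: float = 100.0

    def __post_init__(self):
        if min(self.rotation_rad, self.scale_fraction, self.intensity_shift_hu) < 0:
            raise ValueError("augmentation ranges must be non-negative")


@dataclass
class PatchSample:
    """One training example: image patch, targets and loss-validity mask.

    ``image`` is in HU (augmentation shifts are HU-domain; normalisation is
    applied by the training loop just before the network).  For instance
    training, ``class_targets`` holds 0/1/2 = background/vertebra/rib and
    ``centre_offsets`` the per-voxel (instance centre - voxel position) in
    mm, shaped (3, nx, ny, nz).
    """

    image: np.ndarray
    labels: np.ndarray
    validity: np.ndarray
    origin_voxel: tuple[int, int, int]
    spacing: tuple[float, float, float]
    class_targets: np.ndarray | None = None
    centre_offsets: np.ndarray | None = None


# ---------------------------------------------------------------------------
# intensity
# ---------------------------------------------------------------------------

def clamp_scale(volume: Volume, params: NormalizationParams = NormalizationParams()) -> Volume:
    """Clamp HU to [clamp_low, clamp_high] and divide by ``scale``.

    Total and monotone; output values lie in [-1, 1] for the default
    parameters.  Idempotent after the first application in the sense that
    re-normalising the *values* of an already-normalised volume changes
    nothing when they lie inside [clamp_low/scale, clamp_high/scale].
    """
    if volume.modality is Modality.PET_ACTIVITY:
        raise ValueError("clamp_scale applies to CT (or already-normalised) volumes")
    out = np.clip(volume.values, params.clamp_low, params.clamp_high) / params.scale
    return Volume(volume.grid, out, Modality.NORMALIZED)


def threshold_mask(volume: Volume, hu_range: tuple[float, float],
                   region: np.ndarray | None = None) -> np.ndarray:
    """Binary mask of voxels with HU inside ``hu_range`` (inclusive).

    This is the kernel behind a threshold-restricted annotation brush: the
    mask may be intersected with a user-drawn ``region``.
    """
    lo, hi = hu_range
    if lo > hi:
        raise ValueError(f"empty HU range: low {lo} > high {hi}")
    if volume.modality is not Modality.CT_HU:
        raise ValueError("threshold_mask expects a CT volume in HU")
    mask = (volume.values >= lo) & (volume.values <= hi)
    if region is not None:
        mask &= np.asarray(region, dtype=bool)
    return mask


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def _target_grid(grid: ImageGrid, target_spacing) -> ImageGrid:
    ts = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in ts):
        raise ValueError("target spacing must be positive")
    shape = tuple(max(1, int(round(e / s))) for e, s in zip(grid.extent_mm, ts))
    return ImageGrid(shape, ts, grid.origin)


def _map_to_input_indices(out_grid: ImageGrid, in_grid: ImageGrid) -> np.ndarray:
    """Continuous input-voxel indices of every output voxel centre, (3, ...)."""
    coords = np.meshgrid(*[np.arange(n) for n in out_grid.shape], indexing="ij")
    idx = np.stack(
        [
            (out_grid.origin[a] + coords[a] * out_grid.spacing[a] - in_grid.origin[a])
            / in_grid.spacing[a]
            for a in range(3)
        ]
    )
    return idx


def resample_image(volume: Volume, target_spacing=TRAINING_SPACING) -> Volume:
    """Trilinear resampling of a scalar volume onto ``target_spacing``.

    The output grid keeps the input origin and covers the same physical
    extent (voxel counts rounded).  Values outside the input are clamped to
    the nearest edge voxel, so constant volumes stay exactly constant.
    """
    out_grid = _target_grid(volume.grid, target_spacing)
    if out_grid.spacing == volume.grid.spacing:
        return Volume(out_grid, volume.values.copy(), volume.modality)
    idx = _map_to_input_indices(out_grid, volume.grid)
    out = ndimage.map_coordinates(volume.values.astype(np.float64), idx,
                                  order=1, mode="nearest")
    return Volume(out_grid, out, volume.modality)


def resample_labels_back(labels: LabelMap, original_grid: ImageGrid) -> LabelMap:
    """Nearest-neighbour resampling of a label map onto ``original_grid``.

    Used to bring network-resolution segmentations back to the native image
    grid; never invents label values.
    """
    for a in range(3):
        in_lo = labels.grid.origin[a]
        in_hi = in_lo + labels.grid.extent_mm[a]
        out_lo = original_grid.origin[a]
        out_hi = out_lo + original_grid.extent_mm[a]
        if in_hi <= out_lo or out_hi <= in_lo:
            raise ValueError(f"grids are disjoint along axis {a}")
    if original_grid == labels.grid:
        return LabelMap(original_grid, labels.labels.copy(), labels.registry_ref)
    idx = _map_to_input_indices(original_grid, labels.grid)
    idx = np.floor(idx + 0.5).astype(np.int64)  # ties round up: conventional NN
    for a in range(3):
        np.clip(idx[a], 0, labels.grid.shape[a] - 1, out=idx[a])
    out = labels.labels[idx[0], idx[1], idx[2]]
    return LabelMap(original_grid, out, labels.registry_ref)


# ---------------------------------------------------------------------------
# patch sampling
# ---------------------------------------------------------------------------

def _mirror_pad_to(arr: np.ndarray, size, order_zero: bool = False) -> np.ndarray:
    pads = []
    for a in range(3):
        deficit = max(0, size[a] - arr.shape[a])
        pads.append((deficit // 2, deficit - deficit // 2))
    if any(p != (0, 0) for p in pads):
        arr = np.pad(arr, pads, mode="symmetric")
    return arr


def sample_patch(volume: Volume, labels: LabelMap, annotation: AnnotationMask,
                 size: tuple[int, int, int], rng: np.random.Generator,
                 foreground_bias: float = 0.5,
                 instance_truth: "PhantomTruth | None" = None) -> PatchSample:
    """Draw one training patch.

    With probability ``foreground_bias`` the patch is centred on a random
    foreground voxel (clamped to stay inside the volume); otherwise the
    origin is uniform over all valid positions.  Volumes smaller than the
    patch are mirror-padded.  The validity mask is zero wherever the voxel's
    true label is missing from the study's annotation.
    """
    img = np.asarray(volume.values, dtype=np.float32)
    lab = labels.labels
    inst = instance_truth.instance_map if instance_truth is not None else None

    img = _mirror_pad_to(img, size)
    lab = _mirror_pad_to(lab, size)
    if inst is not None:
        inst = _mirror_pad_to(inst, size)

    max_origin = [img.shape[a] - size[a] for a in range(3)]
    fg = None
    if foreground_bias > 0 and rng.random() < foreground_bias:
        fg_idx = np.argwhere(lab > 0)
        if len(fg_idx):
            fg = fg_idx[rng.integers(len(fg_idx))]
    if fg is not None:
        origin = tuple(int(np.clip(fg[a] - size[a] // 2, 0, max_origin[a]))
                       for a in range(3))
    else:
        origin = tuple(int(rng.integers(0, max_origin[a] + 1)) for a in range(3))

    sl = tuple(slice(origin[a], origin[a] + size[a]) for a in range(3))
    patch_img = img[sl].copy()
    patch_lab = lab[sl].copy()
    validity = annotation.validity_mask(patch_lab)

    class_targets = centre_offsets = None
    if instance_truth is not None:
        patch_inst = inst[sl]
        class_targets = np.zeros_like(patch_lab, dtype=np.int8)
        centre_offsets = np.zeros((3,) + tuple(size), dtype=np.float32)
        from .core import InstanceClass  # local to avoid cycle at import time
        grid = volume.grid
        # world position of each patch voxel (padding treated as edge-clamped)
        pos = np.stack(np.meshgrid(*[np.arange(size[a]) + origin[a] for a in range(3)],
                                   indexing="ij")).astype(np.float64)
        for a in range(3):
            pos[a] = grid.origin[a] + pos[a] * grid.spacing[a]
        for iid, icls in instance_truth.instance_classes.items():
            m = patch_inst == iid
            if not m.any():
                continue
            class_targets[m] = 1 if icls is InstanceClass.VERTEBRA else 2
            centre = instance_truth.instance_centres[iid]
            for a in range(3):
                centre_offsets[a][m] = centre[a] - pos[a][m]

    return PatchSample(patch_img, patch_lab, validity, origin,
                       volume.grid.spacing, class_targets, centre_offsets)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment(patch: PatchSample, params: AugmentationParams,
            rng: np.random.Generator) -> PatchSample:
    """Rotate/scale/shift one patch; draws stay inside the stated ranges.

    The geometric transform (in-plane rotation about the patch centre plus
    isotropic scaling, computed in mm so anisotropic voxels rotate
    correctly) is applied identically to the image (trilinear) and to the
    categorical targets (nearest-neighbour).  The intensity shift applies
    to the image only, in HU, before any clamping.  Zero-width ranges give
    the identity transform exactly.
    """
    theta = rng.uniform(-params.rotation_rad, params.rotation_rad) \
        if params.rotation_rad > 0 else 0.0
    scale = 1.0 + (rng.uniform(-params.scale_fraction, params.scale_fraction)
                   if params.scale_fraction > 0 else 0.0)
    shift = rng.uniform(-params.intensity_shift_hu, params.intensity_shift_hu) \
        if params.intensity_shift_hu > 0 else 0.0

    if theta == 0.0 and scale == 1.0:
        image = patch.image + np.float32(shift)
        return replace(patch, image=image)

    spacing = np.asarray(patch.spacing)
    shape = patch.image.shape
    centre_idx = (np.asarray(shape) - 1) / 2.0
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    # pull-back map: output index -> mm -> inverse transform -> input index
    fwd_mm = rot * scale
    inv_mm = np.linalg.inv(fwd_mm)
    matrix = np.diag(1.0 / spacing) @ inv_mm @ np.diag(spacing)
    offset = centre_idx - matrix @ centre_idx

    def warp(arr, order):
        return ndimage.affine_transform(arr, matrix, offset=offset, order=order,
                                        mode="nearest", output=arr.dtype)

    image = warp(patch.image.astype(np.float32), 1) + np.float32(shift)
    labels = warp(patch.labels, 0)
    validity = warp(patch.validity.astype(np.uint8), 0).astype(bool)
    class_targets = warp(patch.class_targets, 0) if patch.class_targets is not None else None
    centre_offsets = None
    if patch.centre_offsets is not None:
        # resample each component, then rotate/scale the vectors themselves
        comps = np.stack([warp(patch.centre_offsets[a], 1) for a in range(3)])
        centre_offsets = np.einsum("ij,j...->i...", fwd_mm, comps).astype(np.float32)
    return PatchSample(image, labels, validity, patch.origin_voxel, patch.spacing,
                       class_targets, centre_offsets)
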