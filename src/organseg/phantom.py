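"""Synthetic CT/PET phantoms with known ground truth.

The generator builds desk-scale stand-ins for annotated whole-body CT
studies: a handful of geometric "organs" (ellipsoids, boxes, tubes) with
tissue-like Hounsfield means, optionally a spine of repeated vertebra-like
instances with rib tubes attached left and right, and an optional PET
volume with configurable per-organ uptake.  Every phantom carries exact
ground truth: the label map, the per-instance centres that the instance
network regresses against, and an annotation mask that can be sparsified
to emulate per-study incomplete annotation.

All geometry is specified in millimetres, so the same spec rasterised on
grids of different resolution produces geometrically consistent truth.
Generation is deterministic given the spec's seed; geometric randomness
(instance jitter) and voxel noise use independent seed streams so label
geometry does not depend on voxel counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import (
    AnnotationMask,
    ImageGrid,
    InstanceClass,
    LabelMap,
    LabelRegistry,
    Modality,
    Volume,
    default_registry,
)

__all__ = [
    "OrganSpec",
    "SpineSpec",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "generate_pet",
    "sparsify_annotation",
    "instance_field_from_truth",
    "make_organ_phantom_spec",
    "make_spine_phantom_spec",
]

# Default desk-scale grid: 64^3 voxels at (2, 2, 3) mm.
DEFAULT_GRID = ImageGrid((64, 64, 64), (2.0, 2.0, 3.0))

AIR_HU = -1000.0
WATER_HU = 0.0
BONE_HU = 700.0


@dataclass(frozen=True)
class OrganSpec:
    """One geometric organ primitive.

    ``primitive`` is one of ``ellipsoid`` / ``box`` / ``tube``; ``radii_mm``
    are half-extents per axis.  A tube is a cylinder whose axis is ``axis``;
    the radius along the axis acts as the half-length.  ``hu_jitter_sd``
    adds per-voxel Gaussian texture inside the organ only.
    """

    label: int
    primitive: str
    centre_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    hu_mean: float
    hu_jitter_sd: float = 0.0
    axis: int = 0  # tube axis

    def __post_init__(self):
        if self.primitive not in ("ellipsoid", "box", "tube"):
            raise ValueError(f"unknown primitive {self.primitive!r}")
        if any(r <= 0 for r in self.radii_mm):
            raise ValueError("radii must be positive")


@dataclass(frozen=True)
class SpineSpec:
    """A stack of vertebra-like instances along z with optional rib tubes.

    Vertebra 1 is the most cranial (largest z).  ``region`` selects which
    run of registry vertebra labels the instances receive (``cervical`` /
    ``thoracic`` / ``lumbar``).  ``rib_pair_range`` gives the inclusive
    range of rib *pairs* attached per vertebra (0 or 1 pair each).
    """

    n_vertebrae: int
    vertebra_size_mm: tuple[float, float, float] = (24.0, 20.0, 12.0)
    gap_mm: float = 6.0
    rib_pair_range: tuple[int, int] = (1, 1)
    rib_radius_mm: float = 4.0
    rib_length_mm: float = 30.0
    region: str = "thoracic"
    z_jitter_sd_mm: float = 0.5
    hu_mean: float = BONE_HU
    hu_jitter_sd: float = 0.0

    def __post_init__(self):
        if self.n_vertebrae < 0:
            raise ValueError("vertebra count must be >= 0")
        if not (0 <= self.rib_pair_range[0] <= self.rib_pair_range[1] <= 1):
            raise ValueError("rib_pair_range must be within (0, 1) pairs per vertebra")

    @property
    def pitch_mm(self) -> float:
        """Centre-to-centre inter-vertebra distance along z."""
        return self.vertebra_size_mm[2] + self.gap_mm


@dataclass(frozen=True)
class PhantomSpec:
    grid: ImageGrid = DEFAULT_GRID
    organs: tuple[OrganSpec, ...] = ()
    spine: SpineSpec | None = None
    background_hu: float = AIR_HU
    noise_sd: float = 0.0
    seed: int = 0


@dataclass
class PhantomTruth:
    """Ground truth bundle produced by :func:`generate_phantom`."""

    ct: Volume
    labels: LabelMap
    annotation: AnnotationMask
    # instance ground truth for the spine
    instance_map: np.ndarray            # 0 = none, i >= 1 = instance id
    instance_centres: dict[int, np.ndarray]   # id -> (3,) centre in mm
    instance_classes: dict[int, InstanceClass]
    pet: Volume | None = None

    @property
    def grid(self) -> ImageGrid:
        return self.ct.grid


# ---------------------------------------------------------------------------
# rasterisation
# ---------------------------------------------------------------------------

def _rasterise(grid: ImageGrid, spec: OrganSpec) -> np.ndarray:
    X, Y, Z = grid.coordinate_arrays()
    cx, cy, cz = spec.centre_mm
    rx, ry, rz = spec.radii_mm
    if spec.primitive == "ellipsoid":
        return ((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2 + ((Z - cz) / rz) ** 2 <= 1.0
    if spec.primitive == "box":
        return (np.abs(X - cx) <= rx) & (np.abs(Y - cy) <= ry) & (np.abs(Z - cz) <= rz)
    # tube: cylinder with axis spec.axis; radius along the axis = half-length
    coords = [X - cx, Y - cy, Z - cz]
    radii = [rx, ry, rz]
    ax = spec.axis
    cross = [a for a in range(3) if a != ax]
    r2 = sum((coords[a] / radii[a]) ** 2 for a in cross)
    return (r2 <= 1.0) & (np.abs(coords[ax]) <= radii[ax])


def _check_inside(grid: ImageGrid, spec: OrganSpec) -> None:
    lo = grid.world_coordinates(np.zeros(3))
    hi = grid.world_coordinates(np.asarray(grid.shape) - 1.0)
    for a in range(3):
        if spec.centre_mm[a] - spec.radii_mm[a] < lo[a] - grid.spacing[a] or \
           spec.centre_mm[a] + spec.radii_mm[a] > hi[a] + grid.spacing[a]:
            raise ValueError(
                f"primitive for label {spec.label} extends outside the grid on axis {a}"
            )


def _spine_primitives(spec: SpineSpec, grid: ImageGrid, registry: LabelRegistry,
                      rng: np.random.Generator) -> list[tuple[OrganSpec, InstanceClass]]:
    """Expand a SpineSpec into labelled primitives with instance classes."""
    region_names = {"cervical": "Cervical vertebrae",
                    "thoracic": "Thoracic vertebrae",
                    "lumbar": "Lumbar vertebrae"}
    if spec.region not in region_names:
        raise ValueError(f"unknown spine region {spec.region!r}")
    vert_labels = [i for i in registry.vertebra_indices()
                   if registry[i].name.startswith(region_names[spec.region].split()[0])]
    if spec.n_vertebrae > len(vert_labels):
        raise ValueError(
            f"{spec.n_vertebrae} vertebrae requested but region {spec.region!r} "
            f"has only {len(vert_labels)} registry slots"
        )
    ex, ey, ez = grid.extent_mm
    ox, oy, oz = grid.origin
    cx, cy = ox + ex / 2.0, oy + ey / 2.0
    span = (spec.n_vertebrae - 1) * spec.pitch_mm if spec.n_vertebrae else 0.0
    z_top = oz + ez / 2.0 + span / 2.0
    vx, vy, vz = spec.vertebra_size_mm
    prims: list[tuple[OrganSpec, InstanceClass]] = []
    for i in range(spec.n_vertebrae):
        zj = rng.normal(0.0, spec.z_jitter_sd_mm)
        cz = z_top - i * spec.pitch_mm + zj
        prims.append((OrganSpec(vert_labels[i], "box", (cx, cy, cz),
                                (vx / 2, vy / 2, vz / 2),
                                spec.hu_mean, spec.hu_jitter_sd),
                      InstanceClass.VERTEBRA))
        n_pairs = int(rng.integers(spec.rib_pair_range[0], spec.rib_pair_range[1] + 1))
        if n_pairs >= 1:
            level = i + 1  # rib level follows the vertebra ordinal
            x_off = vx / 2 + spec.rib_length_mm / 2 + 1.0
            # LPS-style convention: +x is the patient's left
            for side, sign in (("left", 1.0), ("right", -1.0)):
                lab = registry.by_name(f"Rib {side} {level}").index
                prims.append((OrganSpec(lab, "tube",
                                        (cx + sign * x_off, cy, cz),
                                        (spec.rib_length_mm / 2,
                                         spec.rib_radius_mm, spec.rib_radius_mm),
                                        spec.hu_mean, spec.hu_jitter_sd, axis=0),
                              InstanceClass.RIB))
    return prims


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec, registry: LabelRegistry | None = None) -> PhantomTruth:
    """Rasterise a :class:`PhantomSpec` into CT + labels + instance truth.

    Later primitives overwrite earlier ones at overlaps.  Deterministic for
    a given spec (the seed covers both geometry jitter and voxel noise).
    """
    registry = registry or default_registry()
    grid = spec.grid
    geom_rng, noise_rng = [np.random.default_rng(s)
                           for s in np.random.SeedSequence(spec.seed).spawn(2)]

    ct = np.full(grid.shape, spec.background_hu, dtype=np.float64)
    labels = np.zeros(grid.shape, dtype=np.int32)
    instance_map = np.zeros(grid.shape, dtype=np.int32)
    instance_classes: dict[int, InstanceClass] = {}

    prims: list[tuple[OrganSpec, InstanceClass | None]] = [
        (o, None) for o in spec.organs
    ]
    if spec.spine is not None:
        prims.extend(_spine_primitives(spec.spine, grid, registry, geom_rng))

    next_instance = 0
    for organ, icls in prims:
        _check_inside(grid, organ)
        mask = _rasterise(grid, organ)
        ct[mask] = organ.hu_mean
        if organ.hu_jitter_sd > 0:
            ct[mask] += noise_rng.normal(0.0, organ.hu_jitter_sd, int(mask.sum()))
        labels[mask] = organ.label
        if icls in (InstanceClass.VERTEBRA, InstanceClass.RIB):
            next_instance += 1
            instance_map[mask] = next_instance
            instance_classes[next_instance] = icls

    if spec.noise_sd > 0:
        ct += noise_rng.normal(0.0, spec.noise_sd, grid.shape)

    centres = {}
    for iid in instance_classes:
        idx = np.argwhere(instance_map == iid)
        if idx.size == 0:  # fully overwritten instance
            continue
        centres[iid] = grid.world_coordinates(idx).mean(axis=0)
    instance_classes = {i: c for i, c in instance_classes.items() if i in centres}

    present = [int(v) for v in np.unique(labels) if v != 0]
    return PhantomTruth(
        ct=Volume(grid, ct, Modality.CT_HU),
        labels=LabelMap(grid, labels, registry_ref=registry.ref),
        annotation=AnnotationMask(present),
        instance_map=instance_map,
        instance_centres=centres,
        instance_classes=instance_classes,
    )


def generate_pet(truth: PhantomTruth, uptake: Mapping[int, float],
                 noise_sd: float = 0.0, seed: int = 0,
                 background: float = 0.0) -> Volume:
    """Synthesize a co-registered PET volume from per-label uptake (kBq/ml).

    Voxel activity = uptake[label] (+ Gaussian noise); labels without an
    entry get the background uptake.
    """
    for lab, u in uptake.items():
        if u < 0:
            raise ValueError(f"uptake for label {lab} must be non-negative")
    if background < 0:
        raise ValueError("background uptake must be non-negative")
    rng = np.random.default_rng(seed)
    act = np.full(truth.grid.shape, float(background), dtype=np.float64)
    for lab, u in uptake.items():
        act[truth.labels.labels == lab] = u
    if noise_sd > 0:
        act += rng.normal(0.0, noise_sd, truth.grid.shape)
    pet = Volume(truth.grid, act, Modality.PET_ACTIVITY)
    truth.pet = pet
    return pet


def sparsify_annotation(truth: PhantomTruth, keep_fraction: float,
                        seed: int = 0) -> AnnotationMask:
    """Keep each annotated label independently with probability ``keep_fraction``.

    Emulates studies in which only a subset of organs was annotated.
    """
    if not (0 < keep_fraction <= 1):
        raise ValueError("keep_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    labels = sorted(truth.annotation.annotated_labels)
    kept = [lab for lab in labels if rng.random() < keep_fraction] \
        if keep_fraction < 1 else labels
    return AnnotationMask(kept)


def instance_field_from_truth(truth: PhantomTruth, centre_jitter_sd: float = 0.0,
                              seed: int = 0):
    """Build the ideal instance-network output from phantom ground truth.

    Class probabilities are one-hot (background / vertebra / rib) and every
    instance voxel carries its instance's true centre, optionally perturbed
    by per-voxel Gaussian jitter of ``centre_jitter_sd`` mm — the oracle
    input for clustering experiments.
    """
    from .model.inference import InstanceField

    grid = truth.grid
    probs = np.zeros((3,) + grid.shape, dtype=np.float32)
    centres = np.zeros((3,) + grid.shape, dtype=np.float32)
    X, Y, Z = grid.coordinate_arrays()
    centres[0], centres[1], centres[2] = X, Y, Z
    probs[0] = 1.0
    rng = np.random.default_rng(seed)
    for iid, icls in truth.instance_classes.items():
        m = truth.instance_map == iid
        ch = 1 if icls is InstanceClass.VERTEBRA else 2
        probs[0][m] = 0.0
        probs[ch][m] = 1.0
        c = truth.instance_centres[iid]
        for a in range(3):
            centres[a][m] = c[a]
    if centre_jitter_sd > 0:
        fg = truth.instance_map > 0
        centres[:, fg] += rng.normal(0.0, centre_jitter_sd, (3, int(fg.sum())))
    return InstanceField(grid, probs, centres)


# ---------------------------------------------------------------------------
# canned specs used throughout tests, training surrogates, and the CLI
# ---------------------------------------------------------------------------

def make_organ_phantom_spec(seed: int = 0, grid: ImageGrid = DEFAULT_GRID,
                            noise_sd: float = 20.0,
                            registry: LabelRegistry | None = None) -> PhantomSpec:
    """Three-organ soft phantom: a lung, a liver and a hip bone.

    The organs have well separated Hounsfield means (about -700 / +60 /
    +700 HU) on an air background, with seeded position and size jitter so
    each phantom in a cohort differs geometrically.
    """
    registry = registry or default_registry()
    rng = np.random.default_rng([seed, 0xA11CE])
    ex, ey, ez = grid.extent_mm
    ox, oy, oz = grid.origin
    # geometry scales with the grid extent (fractions chosen for a
    # 128 x 128 x 192 mm default volume)
    scale = min(ex, ey, ez) / 128.0

    def jitter(j_mm):
        return rng.uniform(-j_mm, j_mm) * scale

    def centre(fx, fy, fz, j=6.0):
        return (ox + fx * ex + jitter(j), oy + fy * ey + jitter(j), oz + fz * ez + jitter(j))

    def radii(base, j=0.12):
        return tuple(b * scale * (1 + rng.uniform(-j, j)) for b in base)

    lung = OrganSpec(registry.by_name("Lung left").index, "ellipsoid",
                     centre(0.30, 0.50, 0.68), radii((22.0, 18.0, 30.0)), -700.0)
    liver = OrganSpec(registry.by_name("Liver").index, "ellipsoid",
                      centre(0.62, 0.48, 0.42), radii((28.0, 22.0, 26.0)), 60.0)
    bone = OrganSpec(registry.by_name("Hip bone left").index, "box",
                     centre(0.38, 0.55, 0.20, j=4.0), radii((16.0, 12.0, 10.0)), BONE_HU)
    return PhantomSpec(grid=grid, organs=(lung, liver, bone),
                       background_hu=AIR_HU, noise_sd=noise_sd, seed=seed)


def make_spine_phantom_spec(seed: int = 0, n_vertebrae: int = 5,
                            grid: ImageGrid = DEFAULT_GRID,
                            noise_sd: float = 20.0,
                            with_ribs: bool = True) -> PhantomSpec:
    """Spine phantom: ``n_vertebrae`` stacked vertebra boxes with rib tubes."""
    spine = SpineSpec(n_vertebrae=n_vertebrae,
                      rib_pair_range=(1, 1) if with_ribs else (0, 0))
    return PhantomSpec(grid=grid, organs=(), spine=spine,
                       background_hu=AIR_HU, noise_sd=noise_sd, seed=seed)
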