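"""Domain types shared across the segmentation stack.

The central objects are :class:`ImageGrid` (voxel lattice geometry),
:class:`Volume` (a scalar field on a grid, tagged with its modality),
:class:`LabelMap` (integer organ labels on a grid) and
:class:`LabelRegistry` (the catalogue of the 100 organs the segmentation
tool knows about: 77 bones and 23 soft-tissue organs, with vertebrae and
ribs flagged as instance classes).

Coordinate convention
---------------------
Arrays are indexed ``[x, y, z]`` with ``z`` the slice axis.  Voxel indices
are 0-based and the world (mm) position of voxel centre ``(i, j, k)`` is
``origin + index * spacing``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Modality",
    "Group",
    "InstanceClass",
    "Laterality",
    "ImageGrid",
    "Volume",
    "LabelMap",
    "AnnotationMask",
    "RegistryEntry",
    "LabelRegistry",
    "CatalogueRow",
    "build_registry",
    "load_catalogue",
    "default_registry",
    "voxel_volume_ml",
]


class Modality(str, Enum):
    """Physical interpretation of a :class:`Volume`'s values."""

    CT_HU = "CT_HU"              # Hounsfield units
    PET_ACTIVITY = "PET_ACTIVITY"  # activity concentration, kBq/ml
    NORMALIZED = "NORMALIZED"    # dimensionless, values in [-1, 1]


class Group(str, Enum):
    BONE = "bone"
    SOFT_TISSUE = "soft_tissue"


class InstanceClass(str, Enum):
    VERTEBRA = "vertebra"
    RIB = "rib"
    PLAIN = "plain"


class Laterality(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    NONE = "none"


@dataclass(frozen=True)
class ImageGrid:
    """A 3D voxel lattice: counts, spacing (mm/voxel) and origin (mm).

    ``shape`` is ``(nx, ny, nz)``; physical extent per axis is
    ``shape * spacing`` mm.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("grid fields must be 3-vectors")
        if any(int(n) < 1 for n in self.shape):
            raise ValueError(f"all shape components must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacing components must be > 0, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world mm coordinates (..., 3)."""
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def index_coordinates(self, world: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`world_coordinates` (continuous indices)."""
        w = np.asarray(world, dtype=float)
        return (w - np.asarray(self.origin)) / np.asarray(self.spacing)

    def coordinate_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-coordinate arrays (each of grid shape) for x, y, z."""
        axes = [
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))


def voxel_volume_ml(grid: ImageGrid) -> float:
    """Volume of one voxel in millilitres (product of mm spacings / 1000)."""
    sx, sy, sz = grid.spacing
    return sx * sy * sz / 1000.0


@dataclass
class Volume:
    """A scalar field on an :class:`ImageGrid` with a modality tag."""

    grid: ImageGrid
    values: np.ndarray
    modality: Modality = Modality.CT_HU

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if tuple(self.values.shape) != self.grid.shape:
            raise ValueError(
                f"value array shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        self.modality = Modality(self.modality)
        if self.modality is Modality.NORMALIZED:
            lo, hi = float(self.values.min()), float(self.values.max())
            if lo < -1.0 - 1e-6 or hi > 1.0 + 1e-6:
                raise ValueError(
                    f"NORMALIZED volume must lie in [-1, 1], got [{lo}, {hi}]"
                )

    def with_values(self, values: np.ndarray, modality: Modality | None = None) -> "Volume":
        return Volume(self.grid, values, modality or self.modality)


@dataclass
class LabelMap:
    """Integer organ labels on a grid; 0 is background.

    Nonzero values index a :class:`LabelRegistry`; ``registry_ref`` records
    which registry (by its ``ref`` string) the indices resolve against.
    """

    grid: ImageGrid
    labels: np.ndarray
    registry_ref: str = "organseg-catalogue-v1"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if tuple(self.labels.shape) != self.grid.shape:
            raise ValueError(
                f"label array shape {self.labels.shape} != grid shape {self.grid.shape}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    def present_labels(self) -> list[int]:
        vals = np.unique(self.labels)
        return [int(v) for v in vals if v != 0]

    def validate_against(self, registry: "LabelRegistry") -> None:
        for v in self.present_labels():
            if v not in registry:
                raise KeyError(f"label {v} does not resolve in registry {registry.ref!r}")


@dataclass(frozen=True)
class AnnotationMask:
    """Which registry labels were actually annotated/verified in a study.

    Not every organ is annotated in every study; voxels whose true label is
    missing from ``annotated_labels`` must contribute nothing to losses or
    metrics.  Background voxels are always considered valid (an annotation,
    where present, is assumed complete over its own extent).
    """

    annotated_labels: frozenset[int]

    def __init__(self, annotated_labels: Iterable[int]):
        object.__setattr__(self, "annotated_labels", frozenset(int(v) for v in annotated_labels))
        if any(v <= 0 for v in self.annotated_labels):
            raise ValueError("annotated labels must be positive registry indices")

    def validity_mask(self, labels: LabelMap | np.ndarray) -> np.ndarray:
        """Boolean per-voxel mask: True where the voxel may enter a loss/metric."""
        arr = labels.labels if isinstance(labels, LabelMap) else np.asarray(labels)
        valid = arr == 0
        for lab in self.annotated_labels:
            valid |= arr == lab
        return valid

    def includes(self, label: int) -> bool:
        return int(label) in self.annotated_labels


# ---------------------------------------------------------------------------
# Label registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegistryEntry:
    index: int
    name: str
    group: Group
    instance_class: InstanceClass
    laterality: Laterality


@dataclass(frozen=True)
class CatalogueRow:
    """One catalogue line before expansion, e.g. ("Ribs", bone, 24, ribs)."""

    name: str
    group: Group
    count: int
    kind: str  # single | bilateral | vertebrae | ribs
    singular: str


DEFAULT_REGISTRY_REF = "organseg-catalogue-v1"

_EXPECTED_TOTALS = {Group.BONE: 77, Group.SOFT_TISSUE: 23}


class LabelRegistry:
    """Ordered catalogue of organ labels with contiguous indices from 1."""

    def __init__(self, entries: Sequence[RegistryEntry], ref: str = DEFAULT_REGISTRY_REF):
        entries = list(entries)
        for pos, e in enumerate(entries, start=1):
            if e.index != pos:
                raise ValueError(
                    f"registry indices must be contiguous from 1; entry {e.name!r} "
                    f"has index {e.index} at position {pos}"
                )
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate entry names: {dupes}")
        self._entries = tuple(entries)
        self._by_name = {e.name: e for e in entries}
        self.ref = ref

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries)

    def __contains__(self, index: int) -> bool:
        return 1 <= int(index) <= len(self._entries)

    def __getitem__(self, index: int) -> RegistryEntry:
        if index not in self:
            raise KeyError(f"no registry entry with index {index}")
        return self._entries[int(index) - 1]

    def __eq__(self, other) -> bool:
        return isinstance(other, LabelRegistry) and self._entries == other._entries

    # -- queries ------------------------------------------------------------
    def by_name(self, name: str) -> RegistryEntry:
        return self._by_name[name]

    def indices(self, *, group: Group | None = None,
                instance_class: InstanceClass | None = None) -> list[int]:
        out = []
        for e in self._entries:
            if group is not None and e.group != group:
                continue
            if instance_class is not None and e.instance_class != instance_class:
                continue
            out.append(e.index)
        return out

    @property
    def n_bone(self) -> int:
        return len(self.indices(group=Group.BONE))

    @property
    def n_soft_tissue(self) -> int:
        return len(self.indices(group=Group.SOFT_TISSUE))

    def vertebra_indices(self) -> list[int]:
        """Vertebra labels in cranio-caudal order (C1..C7, Th1..Th12, L1..L5)."""
        return self.indices(instance_class=InstanceClass.VERTEBRA)

    def rib_indices(self, laterality: Laterality | None = None) -> list[int]:
        idx = self.indices(instance_class=InstanceClass.RIB)
        if laterality is None:
            return idx
        return [i for i in idx if self[i].laterality == laterality]

    # -- serialisation ------------------------------------------------------
    def to_table(self, path: str | Path) -> None:
        """Write the registry as a versioned plain-text table."""
        lines = [f"# organseg label registry\t{self.ref}",
                 "index\tname\tgroup\tinstance_class\tlaterality"]
        for e in self._entries:
            lines.append(
                f"{e.index}\t{e.name}\t{e.group.value}\t{e.instance_class.value}\t{e.laterality.value}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_table(cls, path: str | Path) -> "LabelRegistry":
        text = Path(path).read_text().splitlines()
        ref = DEFAULT_REGISTRY_REF
        entries = []
        for line in text:
            if line.startswith("#"):
                parts = line.split("\t")
                if len(parts) == 2:
                    ref = parts[1]
                continue
            if not line.strip() or line.startswith("index\t"):
                continue
            idx, name, group, icls, lat = line.split("\t")
            entries.append(RegistryEntry(int(idx), name, Group(group),
                                         InstanceClass(icls), Laterality(lat)))
        return cls(entries, ref=ref)


def load_catalogue(path: str | Path | None = None) -> list[CatalogueRow]:
    """Read the packaged organ catalogue (or a user-supplied one)."""
    if path is None:
        source = importlib.resources.files("organseg.data") / "organ_catalogue.tsv"
        text = source.read_text()
    else:
        text = Path(path).read_text()
    rows = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, group, count, kind, singular = line.split("\t")
        rows.append(CatalogueRow(name, Group(group), int(count), kind, singular))
    return rows


def _expand_row(row: CatalogueRow) -> list[tuple[str, InstanceClass, Laterality]]:
    if row.kind == "single":
        if row.count != 1:
            raise ValueError(f"row {row.name!r}: kind 'single' requires count 1")
        return [(row.name, InstanceClass.PLAIN, Laterality.NONE)]
    if row.kind == "bilateral":
        if row.count != 2:
            raise ValueError(f"row {row.name!r}: kind 'bilateral' requires count 2")
        return [(f"{row.singular} left", InstanceClass.PLAIN, Laterality.LEFT),
                (f"{row.singular} right", InstanceClass.PLAIN, Laterality.RIGHT)]
    if row.kind == "vertebrae":
        return [(f"{row.singular} {i}", InstanceClass.VERTEBRA, Laterality.NONE)
                for i in range(1, row.count + 1)]
    if row.kind == "ribs":
        if row.count % 2:
            raise ValueError(f"row {row.name!r}: rib count must be even")
        out = []
        for level in range(1, row.count // 2 + 1):
            out.append((f"{row.singular} left {level}", InstanceClass.RIB, Laterality.LEFT))
            out.append((f"{row.singular} right {level}", InstanceClass.RIB, Laterality.RIGHT))
        return out
    raise ValueError(f"unknown catalogue kind {row.kind!r}")


def build_registry(catalogue: Sequence[CatalogueRow], *,
                   require_full: bool = False,
                   ref: str = DEFAULT_REGISTRY_REF) -> LabelRegistry:
    """Expand catalogue rows into a :class:`LabelRegistry`.

    Multi-instance rows expand deterministically: bilateral organs to
    "<name> left"/"<name> right", vertebral rows to numbered vertebrae in
    cranio-caudal order, and the rib row to left/right pairs per level
    ("Rib left 1", "Rib right 1", ... "Rib right 12").

    With ``require_full=True`` the expanded totals are checked against the
    catalogue contract (77 bone + 23 soft-tissue entries).
    """
    entries: list[RegistryEntry] = []
    idx = 0
    totals = {Group.BONE: 0, Group.SOFT_TISSUE: 0}
    for row in catalogue:
        expanded = _expand_row(row)
        if len(expanded) != row.count:
            raise ValueError(
                f"row {row.name!r} declares count {row.count} but expands to {len(expanded)}"
            )
        totals[row.group] += len(expanded)
        for name, icls, lat in expanded:
            idx += 1
            entries.append(RegistryEntry(idx, name, row.group, icls, lat))
    if require_full and totals != _EXPECTED_TOTALS:
        raise ValueError(
            f"catalogue totals {totals[Group.BONE]} bone / {totals[Group.SOFT_TISSUE]} "
            f"soft tissue do not match the expected 77 / 23"
        )
    return LabelRegistry(entries, ref=ref)


def default_registry() -> LabelRegistry:
    """The full 100-organ registry (77 bones, 23 soft-tissue organs)."""
    return build_registry(load_catalogue(), require_full=True)
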