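"""From per-voxel centre predictions to numbered vertebrae and ribs.

The instance network cannot know a vertebra's anatomical index from its
local appearance (the receptive field is too small), so it predicts, per
foreground voxel, the centre of the instance owning that voxel.  Voxels
whose predicted centres agree are the same instance: single-linkage
clustering of the centre coordinates with a millimetre threshold recovers
the instances without a preset count.  Instances are then numbered
cranio-caudally into registry labels, ribs are assigned to the nearest
vertebra level and to the left/right of the midline, and every label gets
the morphological cleanup (largest connected component + hole filling)
that is applied to all organs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage

from .core import ImageGrid, InstanceClass, LabelMap, LabelRegistry, Laterality
from .model.inference import InstanceField

__all__ = [
    "ClusterParams",
    "ClusteredInstances",
    "cluster_instances",
    "assign_indices",
    "largest_component",
    "fill_holes",
    "fuse",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class ClusterParams:
    """Single-linkage clustering of predicted instance centres.

    ``linkage_mm`` is the distance threshold joining two centre predictions
    into one instance; the default is half a typical inter-vertebra pitch.
    Clusters smaller than ``min_cluster_size`` voxels are discarded to
    background.  Centres are quantised to ``linkage_mm / 4`` cells before
    linkage so the pairwise problem stays small.

    ``algorithm`` selects the agglomerative merge criterion: "average"
    (default) is robust to noisy centre predictions, where the chaining
    behaviour of "single" linkage can bridge neighbouring instances
    through stray points; "single" reproduces pure
    connected-groups-within-threshold semantics on clean fields.
    """

    linkage_mm: float = 9.0
    min_cluster_size: int = 5
    algorithm: str = "average"

    def __post_init__(self):
        if self.linkage_mm <= 0:
            raise ValueError("linkage threshold must be > 0")


@dataclass
class ClusteredInstances:
    """Instance partition: per-voxel ids, centroids and classes."""

    instance_map: np.ndarray                 # 0 = background
    centroids: dict[int, np.ndarray]         # id -> (3,) mm
    classes: dict[int, InstanceClass]


def _cluster_points(points: np.ndarray, threshold: float,
                    method: str) -> np.ndarray:
    """Agglomerative cluster ids (1-based) for each point."""
    n = len(points)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    if n == 1:
        return np.ones(1, dtype=np.int64)
    cell = threshold / 4.0
    quant = np.round(points / cell).astype(np.int64)
    uniq, inverse = np.unique(quant, axis=0, return_inverse=True)
    upts = uniq * cell
    if len(upts) == 1:
        return np.ones(n, dtype=np.int64)
    Z = linkage(upts, method=method)
    ucl = fcluster(Z, t=threshold, criterion="distance")
    return ucl[inverse]


def cluster_instances(field: InstanceField, params: ClusterParams = ClusterParams()
                      ) -> ClusteredInstances:
    """Partition vertebra/rib foreground voxels into instances.

    Vertebra-class and rib-class voxels are clustered separately over their
    predicted centre coordinates.  Every foreground voxel belongs to
    exactly one instance; clusters below the minimum size are dropped.
    Instance ids are assigned in cranio-caudal (descending z) centroid
    order, vertebrae first, and centroids are the mean predicted centre of
    the member voxels.
    """
    class_map = field.class_map()
    instance_map = np.zeros(class_map.shape, dtype=np.int32)
    raw: list[tuple[InstanceClass, np.ndarray, tuple]] = []

    for class_value, icls in ((1, InstanceClass.VERTEBRA), (2, InstanceClass.RIB)):
        mask = class_map == class_value
        if not mask.any():
            continue
        vox = np.nonzero(mask)
        pts = field.centres_mm[:, vox[0], vox[1], vox[2]].T.astype(np.float64)
        method = params.algorithm.replace("-linkage", "")
        cl = _cluster_points(pts, params.linkage_mm, method)
        for cid in np.unique(cl):
            member = cl == cid
            if int(member.sum()) < params.min_cluster_size:
                continue
            centroid = pts[member].mean(axis=0)
            raw.append((icls, centroid,
                        tuple(v[member] for v in vox)))

    # deterministic ids: vertebrae before ribs, each cranio-caudal
    raw.sort(key=lambda t: (t[0] is not InstanceClass.VERTEBRA, -t[1][2]))
    centroids: dict[int, np.ndarray] = {}
    classes: dict[int, InstanceClass] = {}
    for iid, (icls, centroid, vox) in enumerate(raw, start=1):
        instance_map[vox] = iid
        centroids[iid] = centroid
        classes[iid] = icls
    return ClusteredInstances(instance_map, centroids, classes)


def assign_indices(instances: ClusteredInstances, registry: LabelRegistry,
                   region: str = "thoracic") -> LabelMap | np.ndarray:
    """Number instances into anatomical registry labels.

    Vertebra instances are sorted cranio-caudally (descending z centroid)
    and given consecutive vertebra labels of the declared ``region`` run;
    ribs get the level of the nearest vertebra (by z) and the side of the
    midline their centroid falls on (+x = patient left).  More instances
    than registry slots triggers a warning and truncation to background.

    Returns an integer label array aligned with the instance map.
    """
    region_prefix = {"cervical": "Cervical", "thoracic": "Thoracic",
                     "lumbar": "Lumbar"}[region]
    vert_labels = [i for i in registry.vertebra_indices()
                   if registry[i].name.startswith(region_prefix)]

    vids = [i for i, c in instances.classes.items() if c is InstanceClass.VERTEBRA]
    rids = [i for i, c in instances.classes.items() if c is InstanceClass.RIB]
    vids.sort(key=lambda i: -instances.centroids[i][2])

    out = np.zeros(instances.instance_map.shape, dtype=np.int32)
    if len(vids) > len(vert_labels):
        warnings.warn(
            f"{len(vids)} vertebra instances but only {len(vert_labels)} "
            f"{region} registry slots; extra instances dropped")
        vids = vids[:len(vert_labels)]
    vert_level = {}
    for ordinal, iid in enumerate(vids, start=1):
        out[instances.instance_map == iid] = vert_labels[ordinal - 1]
        vert_level[iid] = ordinal

    midline_x = (np.mean([instances.centroids[i][0] for i in vids])
                 if vids else 0.0)
    n_levels = len(registry.rib_indices(Laterality.LEFT))
    rids_by_z = sorted(rids, key=lambda i: -instances.centroids[i][2])
    for iid in rids_by_z:
        c = instances.centroids[iid]
        if vids:
            nearest = min(vids, key=lambda v: abs(instances.centroids[v][2] - c[2]))
            level = vert_level[nearest]
        else:
            level = 1
        if level > n_levels:
            warnings.warn(f"rib level {level} exceeds registry range; dropped")
            continue
        side = "left" if c[0] >= midline_x else "right"
        lab = registry.by_name(f"Rib {side} {level}").index
        out[instances.instance_map == iid] = lab
    return out


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 26-connected component of a binary mask.

    Size ties break toward the component containing the lexicographically
    lowest (z, y, x) voxel.
    """
    mask = np.asarray(mask, dtype=bool)
    labelled, n = ndimage.label(mask, structure=_STRUCT_26)
    if n <= 1:
        return mask.copy()
    sizes = np.bincount(labelled.ravel())[1:]
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if len(best) > 1:
        def seed_key(comp):
            idx = np.argwhere(labelled == comp)
            zyx = idx[:, ::-1]
            return tuple(zyx[np.lexsort((zyx[:, 2], zyx[:, 1], zyx[:, 0]))][0])
        best = sorted(best, key=seed_key)
    return labelled == best[0]


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill interior cavities: background 6-components not touching the border."""
    mask = np.asarray(mask, dtype=bool)
    bg, n = ndimage.label(~mask, structure=_STRUCT_6)
    if n == 0:
        return mask.copy()
    border_labels = set()
    for a in range(3):
        border_labels.update(np.unique(np.take(bg, 0, axis=a)))
        border_labels.update(np.unique(np.take(bg, -1, axis=a)))
    border_labels.discard(0)
    out = mask.copy()
    for comp in range(1, n + 1):
        if comp not in border_labels:
            out[bg == comp] = True
    return out


def fuse(semantic_probs: np.ndarray, instance_labels: np.ndarray,
         registry: LabelRegistry, grid: ImageGrid,
         label_values=None, registry_ref: str | None = None) -> LabelMap:
    """Combine the two networks' outputs into the final label map.

    Voxels the instance pipeline claims (nonzero anatomical instance label)
    take that label; all other voxels take the semantic argmax (ties break
    toward the lower channel index).  ``label_values`` maps semantic
    channels 1..C-1 to registry indices (identity when omitted).  Every
    label then gets largest-component extraction followed by hole filling;
    labels are processed in ascending index order, so a later label's fill
    may overwrite an earlier one's.
    """
    instance_labels = np.asarray(instance_labels)
    if semantic_probs.shape[1:] != instance_labels.shape or \
            tuple(instance_labels.shape) != grid.shape:
        raise ValueError("semantic, instance and grid shapes must agree")
    channels = np.argmax(semantic_probs, axis=0)
    if label_values is None:
        label_values = list(range(1, semantic_probs.shape[0]))
    mapping = np.array([0] + [int(v) for v in label_values], dtype=np.int32)
    fused = mapping[channels]
    claimed = instance_labels > 0
    fused[claimed] = instance_labels[claimed]

    out = np.zeros_like(fused)
    for lab in sorted(int(v) for v in np.unique(fused) if v != 0):
        m = fill_holes(largest_component(fused == lab))
        out[m] = lab
    return LabelMap(grid, out, registry_ref or registry.ref)
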