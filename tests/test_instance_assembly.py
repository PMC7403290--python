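"""Centre clustering, anatomical numbering, morphology and fusion."""

import numpy as np
import pytest

from organseg.core import ImageGrid, InstanceClass, default_registry
from organseg.instance_assembly import (
    ClusterParams,
    cluster_instances,
    assign_indices,
    fill_holes,
    fuse,
    largest_component,
)
from organseg.model.inference import InstanceField
from organseg.phantom import (
    PhantomSpec,
    SpineSpec,
    generate_phantom,
    instance_field_from_truth,
    make_spine_phantom_spec,
)


def _partition_matches(truth, clustered, exact=True):
    if len(clustered.centroids) != len(truth.instance_classes):
        return False
    used = set()
    for iid in truth.instance_classes:
        m = truth.instance_map == iid
        ids, counts = np.unique(clustered.instance_map[m], return_counts=True)
        if exact and (len(ids) != 1 or ids[0] == 0):
            return False
        maj = int(ids[np.argmax(counts)])
        if maj == 0 or maj in used or counts.max() / counts.sum() < 0.95:
            return False
        used.add(maj)
    return True


class TestClustering:
    def test_exact_centre_field_recovers_partition(self, spine_truth):
        clustered = cluster_instances(instance_field_from_truth(spine_truth))
        assert _partition_matches(spine_truth, clustered, exact=True)

    @pytest.mark.parametrize("n_vertebrae", [3, 8])
    def test_recovery_across_phantom_sizes(self, n_vertebrae):
        truth = generate_phantom(make_spine_phantom_spec(seed=2, n_vertebrae=n_vertebrae))
        clustered = cluster_instances(instance_field_from_truth(truth))
        n_verts = sum(c is InstanceClass.VERTEBRA for c in clustered.classes.values())
        assert n_verts == n_vertebrae
        assert _partition_matches(truth, clustered, exact=True)

    def test_jittered_centres_still_recovered(self, spine_truth):
        field = instance_field_from_truth(spine_truth, centre_jitter_sd=1.8, seed=0)
        clustered = cluster_instances(field)
        assert _partition_matches(spine_truth, clustered, exact=False)

    def test_empty_foreground_gives_no_instances(self):
        grid = ImageGrid((8, 8, 8), (2, 2, 3))
        probs = np.zeros((3,) + grid.shape, dtype=np.float32)
        probs[0] = 1.0
        field = InstanceField(grid, probs, np.zeros((3,) + grid.shape, np.float32))
        clustered = cluster_instances(field)
        assert clustered.centroids == {}
        assert not clustered.instance_map.any()

    def test_min_cluster_size_filters_specks(self, spine_truth):
        field = instance_field_from_truth(spine_truth)
        big = cluster_instances(field, ClusterParams(min_cluster_size=10 ** 6))
        assert big.centroids == {}

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            ClusterParams(linkage_mm=0.0)


class TestAssignIndices:
    def test_lumbar_run_in_z_order(self, registry):
        spine = SpineSpec(n_vertebrae=5, region="lumbar", rib_pair_range=(0, 0),
                          z_jitter_sd_mm=0.0)
        truth = generate_phantom(PhantomSpec(spine=spine, seed=4))
        clustered = cluster_instances(instance_field_from_truth(truth))
        labels = assign_indices(clustered, registry, region="lumbar")
        lumbar = registry.vertebra_indices()[19:]  # L1..L5
        got = [lab for lab in np.unique(labels) if lab != 0]
        assert got == lumbar
        np.testing.assert_array_equal(labels, truth.labels.labels)

    def test_singleton_instance(self, registry):
        spine = SpineSpec(n_vertebrae=1, rib_pair_range=(0, 0))
        truth = generate_phantom(PhantomSpec(spine=spine, seed=1))
        clustered = cluster_instances(instance_field_from_truth(truth))
        labels = assign_indices(clustered, registry, region="thoracic")
        assert set(np.unique(labels)) == {0, registry.by_name("Thoracic vertebrae 1").index}

    def test_ribs_get_side_and_level(self, spine_truth, registry):
        clustered = cluster_instances(instance_field_from_truth(spine_truth))
        labels = assign_indices(clustered, registry, region="thoracic")
        np.testing.assert_array_equal(labels, spine_truth.labels.labels)

    def test_left_rib_is_left_of_midline(self, spine_truth, registry):
        left = registry.by_name("Rib left 1").index
        mask = spine_truth.labels.labels == left
        xs = np.argwhere(mask)[:, 0] * spine_truth.grid.spacing[0]
        centre_x = spine_truth.grid.extent_mm[0] / 2
        assert xs.mean() > centre_x  # +x is the patient's left

    def test_equivariant_to_z_translation(self, registry):
        spine = SpineSpec(n_vertebrae=4, rib_pair_range=(0, 0), z_jitter_sd_mm=0.0)
        truth = generate_phantom(PhantomSpec(spine=spine, seed=6))
        clustered = cluster_instances(instance_field_from_truth(truth))
        labels = assign_indices(clustered, registry, region="thoracic")
        # shift the whole field two voxels down in z
        shifted = np.roll(clustered.instance_map, -2, axis=2)
        dz = 2 * truth.grid.spacing[2]
        from organseg.instance_assembly import ClusteredInstances
        moved = ClusteredInstances(
            shifted,
            {k: v - np.array([0, 0, dz]) for k, v in clustered.centroids.items()},
            clustered.classes)
        labels2 = assign_indices(moved, registry, region="thoracic")
        np.testing.assert_array_equal(labels2, np.roll(labels, -2, axis=2))

    def test_overflow_warns_and_truncates(self, registry):
        spine = SpineSpec(n_vertebrae=7, region="lumbar", rib_pair_range=(0, 0))
        with pytest.raises(ValueError):
            generate_phantom(PhantomSpec(spine=spine, seed=0))  # only 5 slots
        # construct overflow directly at the assignment stage
        from organseg.instance_assembly import ClusteredInstances
        inst = np.zeros((4, 4, 10), np.int32)
        centroids, classes = {}, {}
        for i in range(6):
            inst[:, :, i] = i + 1
            centroids[i + 1] = np.array([0.0, 0.0, 30.0 - i * 5])
            classes[i + 1] = InstanceClass.VERTEBRA
        with pytest.warns(UserWarning, match="slots"):
            labels = assign_indices(ClusteredInstances(inst, centroids, classes),
                                    registry, region="lumbar")
        assert (np.unique(labels) != 0).sum() == 5


# ---------------------------------------------------------------------------
# morphology oracles
# ---------------------------------------------------------------------------

def _brute_components(mask):
    """Flood-fill 26-connected components by exhaustive BFS."""
    from collections import deque
    comp = np.zeros(mask.shape, int)
    n = 0
    for seed in map(tuple, np.argwhere(mask)):
        if comp[seed]:
            continue
        n += 1
        q = deque([seed])
        comp[seed] = n
        while q:
            p = q.popleft()
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        if dx == dy == dz == 0:
                            continue
                        r = (p[0] + dx, p[1] + dy, p[2] + dz)
                        if all(0 <= r[a] < mask.shape[a] for a in range(3)) \
                                and mask[r] and not comp[r]:
                            comp[r] = n
                            q.append(r)
    return comp, n


class TestMorphology:
    def test_largest_of_two_components(self):
        mask = np.zeros((10, 6, 6), bool)
        mask[0:5, 0:2, 0] = True      # 10 voxels
        mask[8:9, 3:6, 0] = True      # 3 voxels
        out = largest_component(mask)
        assert out.sum() == 10
        assert out[0:5, 0:2, 0].all()

    def test_single_component_unchanged(self):
        mask = np.zeros((6, 6, 6), bool)
        mask[2:5, 2:5, 2:5] = True
        np.testing.assert_array_equal(largest_component(mask), mask)

    def test_empty_mask(self):
        mask = np.zeros((4, 4, 4), bool)
        assert not largest_component(mask).any()
        assert not fill_holes(mask).any()

    def test_matches_brute_force_components(self, rng):
        for _ in range(20):
            mask = rng.random((9, 9, 9)) < 0.2
            comp, n = _brute_components(mask)
            if n == 0:
                continue
            sizes = np.bincount(comp.ravel())[1:]
            out = largest_component(mask)
            assert out.sum() == sizes.max()
            # the result is one brute-force component
            ids = np.unique(comp[out])
            assert len(ids) == 1 and sizes[ids[0] - 1] == sizes.max()

    def test_hollow_shell_becomes_solid(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[1:7, 1:7, 1:7] = True
        mask[2:6, 2:6, 2:6] = False
        out = fill_holes(mask)
        expected = np.zeros((8, 8, 8), bool)
        expected[1:7, 1:7, 1:7] = True
        np.testing.assert_array_equal(out, expected)

    def test_open_cavity_not_filled(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[1:7, 1:7, 1:7] = True
        mask[2:6, 2:6, 2:6] = False
        mask[3, 3, 6:] = False  # channel to the border
        out = fill_holes(mask)
        assert not out[3, 3, 3]

    def test_solid_sphere_idempotent(self):
        x, y, z = np.mgrid[:9, :9, :9]
        mask = (x - 4) ** 2 + (y - 4) ** 2 + (z - 4) ** 2 <= 9
        np.testing.assert_array_equal(fill_holes(mask), mask)
        once = fill_holes(largest_component(mask))
        twice = fill_holes(largest_component(once))
        np.testing.assert_array_equal(once, twice)


class TestFuse:
    def test_no_instance_foreground_reduces_to_semantic(self, registry):
        grid = ImageGrid((10, 10, 10), (1, 1, 1))
        probs = np.zeros((3,) + grid.shape, np.float32)
        probs[0] = 1.0
        probs[:, 3:7, 3:7, 3:7] = 0.0
        probs[2, 3:7, 3:7, 3:7] = 1.0  # channel 2 -> label 90 (liver)
        inst = np.zeros(grid.shape, np.int32)
        fused = fuse(probs, inst, registry, grid, label_values=[52, 90])
        assert set(np.unique(fused.labels)) == {0, 90}
        assert (fused.labels == 90).sum() == 4 ** 3

    def test_spine_and_organ_phantom_all_labels_disjoint(self, registry):
        spine = SpineSpec(n_vertebrae=3, rib_pair_range=(0, 0))
        truth = generate_phantom(PhantomSpec(spine=spine, seed=8))
        clustered = cluster_instances(instance_field_from_truth(truth))
        inst_labels = assign_indices(clustered, registry, region="thoracic")
        # ideal semantic output: background everywhere (spine is instance-net turf)
        probs = np.zeros((1,) + truth.grid.shape, np.float32)
        probs[0] = 1.0
        fused = fuse(probs, inst_labels, registry, truth.grid, label_values=[])
        np.testing.assert_array_equal(fused.labels, truth.labels.labels)

    def test_argmax_tie_breaks_to_lower_channel(self, registry):
        grid = ImageGrid((4, 4, 4), (1, 1, 1))
        probs = np.full((3,) + grid.shape, 1 / 3, np.float32)
        fused = fuse(probs, np.zeros(grid.shape, np.int32), registry, grid,
                     label_values=[5, 6])
        assert not fused.labels.any()  # ties resolve to channel 0 = background

    def test_grid_mismatch_rejected(self, registry):
        grid = ImageGrid((4, 4, 4), (1, 1, 1))
        probs = np.zeros((2, 5, 4, 4), np.float32)
        with pytest.raises(ValueError, match="shapes"):
            fuse(probs, np.zeros(grid.shape, np.int32), registry, grid)
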