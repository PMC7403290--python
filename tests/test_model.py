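"""Network construction, receptive fields, losses, training, inference."""

import numpy as np
import pytest

from organseg.core import ImageGrid, Modality, Volume
from organseg.model import (
    NetworkConfig,
    TrainingConfig,
    build_network,
    desk_instance_config,
    desk_semantic_config,
    find_valid_input_size,
    full_scale_instance_config,
    full_scale_semantic_config,
    load_network,
    masked_loss,
    output_shape,
    predict_volume,
    receptive_field,
    receptive_field_mm,
    save_network,
    softmax,
    total_margin,
    train,
)
from organseg.model.training import _loss_and_grad


class TestConfigAndReceptiveField:
    def test_semantic_head_channel_count(self):
        cfg = desk_semantic_config(n_labels=2)
        assert cfg.n_out_channels == 3  # 2 labels + background

    def test_instance_head_channel_count(self):
        cfg = desk_instance_config()
        assert cfg.n_class_channels == 3
        assert cfg.n_out_channels == 6  # 3 SoftMax + 3 linear offsets

    def test_full_scale_receptive_field(self):
        for cfg in (full_scale_semantic_config(), full_scale_instance_config()):
            assert cfg.n_resolutions == 4
            assert receptive_field(cfg) == (136, 136, 72)

    def test_receptive_field_mm_matches_training_spacing(self):
        mm = receptive_field_mm((136, 136, 72), (1.36, 1.36, 3.0))
        assert mm == pytest.approx((184.96, 184.96, 216.0))

    @pytest.mark.parametrize("field,spacing,expected", [
        ((1, 1, 1), (1, 1, 1), (1, 1, 1)),
        ((10, 20, 30), (2, 2, 2), (20, 40, 60)),
    ])
    def test_receptive_field_mm_products(self, field, spacing, expected):
        assert receptive_field_mm(field, spacing) == pytest.approx(expected)

    def test_declared_field_mismatch_rejected(self):
        with pytest.raises(ValueError, match="declared receptive field"):
            NetworkConfig(levels=desk_semantic_config().levels,
                          declared_receptive_field=(99, 99, 99))

    def test_config_json_round_trip(self, tmp_path):
        cfg = full_scale_instance_config()
        cfg.to_json(tmp_path / "c.json")
        assert NetworkConfig.from_json(tmp_path / "c.json") == cfg

    def test_empirical_receptive_field_matches_algebra(self):
        """Gradient support of one output voxel spans exactly the computed field.

        ReLUs are switched off so the network is linear and no influence
        path can be masked by a dead unit.
        """
        cfg = desk_semantic_config(n_labels=1, width=3)
        rf = receptive_field(cfg)
        net = build_network(cfg, seed=0)
        for conv in net._convs():
            conv.relu = False
        size = find_valid_input_size(cfg, tuple(r + 10 for r in rf))
        out_sz = output_shape(cfg, size)
        x = np.random.default_rng(0).normal(0, 1, (1,) + size).astype(np.float32)
        y = net.forward(x, train=True)
        g = np.zeros_like(y)
        g[(0,) + tuple(s // 2 for s in out_sz)] = 1.0
        gx = net.backward(g)
        idx = np.argwhere(np.abs(gx[0]) > 1e-12)
        extent = tuple(idx.max(axis=0) - idx.min(axis=0) + 1)
        assert extent == rf


class TestMaskedLoss:
    def test_perfect_prediction_zero_loss(self):
        targets = np.zeros((4, 4, 4), dtype=np.int64)
        probs = np.zeros((3, 4, 4, 4))
        probs[0] = 1.0
        assert masked_loss(probs, targets, np.ones((4, 4, 4), bool)) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("n_classes", [2, 3, 5])
    def test_uniform_prediction_gives_log_c(self, n_classes, rng):
        probs = np.full((n_classes, 3, 3, 3), 1.0 / n_classes)
        targets = rng.integers(0, n_classes, (3, 3, 3))
        loss = masked_loss(probs, targets, np.ones((3, 3, 3), bool))
        assert loss == pytest.approx(np.log(n_classes), rel=1e-9)

    def test_masked_subset_matches_brute_force(self, rng):
        probs = softmax(rng.normal(0, 1, (4, 5, 5, 5)), axis=0)
        targets = rng.integers(0, 4, (5, 5, 5))
        validity = rng.random((5, 5, 5)) < 0.5
        loss = masked_loss(probs, targets, validity)
        brute = np.mean([-np.log(probs[(targets[i, j, k], i, j, k)])
                         for i in range(5) for j in range(5) for k in range(5)
                         if validity[i, j, k]])
        assert loss == pytest.approx(brute, rel=1e-9)

    def test_all_zero_mask_warns_and_returns_zero(self):
        probs = np.full((2, 2, 2, 2), 0.5)
        with pytest.warns(UserWarning, match="all zero"):
            loss = masked_loss(probs, np.zeros((2, 2, 2), np.int64),
                               np.zeros((2, 2, 2), bool))
        assert loss == 0.0

    def test_centre_term_is_masked_mse(self, rng):
        probs = np.zeros((3, 2, 2, 2))
        probs[1] = 1.0
        targets = np.ones((2, 2, 2), np.int64)
        pred = rng.normal(0, 1, (3, 2, 2, 2))
        tgt = rng.normal(0, 1, (3, 2, 2, 2))
        m = np.zeros((2, 2, 2), bool)
        m[0, 0, 0] = True
        loss = masked_loss(probs, targets, np.ones((2, 2, 2), bool),
                           pred, tgt, m, centre_weight=2.0)
        expected = 2.0 * np.mean((pred[:, 0, 0, 0] - tgt[:, 0, 0, 0]) ** 2)
        assert loss == pytest.approx(expected, rel=1e-6)

    def test_loss_gradient_matches_finite_difference(self, rng):
        cfg = desk_semantic_config(n_labels=2)
        logits = rng.normal(0, 1, (3, 3, 3, 3)).astype(np.float64)
        targets = rng.integers(0, 3, (3, 3, 3))
        validity = rng.random((3, 3, 3)) < 0.7
        loss, grad = _loss_and_grad(cfg, logits, targets, validity, None, None, 1.0)
        eps = 1e-5
        idx = (1, 2, 0, 1)
        lp = _loss_and_grad(cfg, np.where(np.zeros_like(logits, bool), logits, logits)
                            + eps * np.eye(1), targets, validity, None, None, 1.0)
        # simpler: perturb one entry
        l2 = logits.copy()
        l2[idx] += eps
        lp, _ = _loss_and_grad(cfg, l2, targets, validity, None, None, 1.0)
        assert grad[idx] == pytest.approx((lp - loss) / eps, abs=1e-4)


class TestNetworkForward:
    def test_softmax_channels_sum_to_one(self, rng):
        cfg = desk_instance_config(width=4)
        net = build_network(cfg, seed=0)
        grid = ImageGrid((20, 20, 20), (2, 2, 3))
        vol = Volume(grid, rng.normal(0, 300, grid.shape), Modality.CT_HU)
        field = predict_volume(net, vol, tile_out=24)
        np.testing.assert_allclose(field.class_probs.sum(axis=0), 1.0, atol=1e-5)

    def test_output_strictly_smaller_than_input(self):
        cfg = desk_semantic_config(n_labels=2)
        size = find_valid_input_size(cfg, receptive_field(cfg))
        out = output_shape(cfg, size)
        assert all(o < s for o, s in zip(out, size))
        assert all(s - o == m for s, o, m in zip(size, out, total_margin(cfg)))

    def test_patch_smaller_than_receptive_field_rejected(self):
        cfg = desk_semantic_config(n_labels=2)
        with pytest.raises(ValueError):
            output_shape(cfg, (8, 8, 8))

    def test_tiling_plan_invariance(self, rng):
        cfg = desk_semantic_config(n_labels=2, width=4)
        net = build_network(cfg, seed=1)
        grid = ImageGrid((40, 34, 30), (2, 2, 3))
        vol = Volume(grid, rng.normal(0, 300, grid.shape), Modality.CT_HU)
        outs = [predict_volume(net, vol, tile_out=t) for t in (8, 14, 48)]
        for other in outs[1:]:
            np.testing.assert_allclose(outs[0], other, atol=1e-5)

    def test_constant_input_gives_constant_interior(self, rng):
        cfg = desk_semantic_config(n_labels=2, width=4)
        net = build_network(cfg, seed=2)
        grid = ImageGrid((30, 30, 30), (2, 2, 3))
        vol = Volume(grid, np.full(grid.shape, 100.0), Modality.CT_HU)
        probs = predict_volume(net, vol, tile_out=48)
        interior = probs[:, 10:-10, 10:-10, 10:-10]
        for c in range(interior.shape[0]):
            assert interior[c].std() < 1e-6


@pytest.fixture(scope="module")
def tiny_studies():
    from organseg.phantom import generate_phantom, make_organ_phantom_spec
    grid = ImageGrid((32, 32, 32), (2, 2, 3))
    return [generate_phantom(make_organ_phantom_spec(seed=s, grid=grid))
            for s in range(4)]


class TestTraining:
    def _tiny_config(self, seed=0):
        return TrainingConfig(patch_size=(16, 16, 16), batch_size=2, epochs=1,
                              steps_per_epoch=3, seed=seed)

    def test_fixed_seed_reproducible_trajectory(self, tiny_studies):
        losses = []
        for _ in range(2):
            net = build_network(desk_semantic_config(n_labels=3, width=4), seed=0)
            hist = train(net, tiny_studies, self._tiny_config())
            losses.append(hist.step_loss)
        assert losses[0] == losses[1]

    def test_zero_learning_rate_leaves_parameters_unchanged(self, tiny_studies):
        net = build_network(desk_semantic_config(n_labels=3, width=4), seed=0)
        before = {k: v.copy() for k, v in net.state_arrays().items()}
        cfg = self._tiny_config()
        cfg.learning_rate = 0.0
        train(net, tiny_studies, cfg)
        after = net.state_arrays()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_split_is_disjoint_and_exhaustive(self, tiny_studies):
        net = build_network(desk_semantic_config(n_labels=3, width=4), seed=0)
        hist = train(net, tiny_studies, self._tiny_config())
        assert sorted(hist.train_indices + hist.val_indices) == [0, 1, 2, 3]
        assert not set(hist.train_indices) & set(hist.val_indices)

    def test_checkpoint_round_trip(self, tiny_studies, tmp_path, rng):
        net = build_network(desk_semantic_config(n_labels=3, width=4), seed=0)
        hist = train(net, tiny_studies, self._tiny_config())
        save_network(net, tmp_path / "model", hist.label_values)
        net2, labels = load_network(tmp_path / "model")
        assert labels == hist.label_values
        x = rng.normal(0, 1, (1, 16, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(net.forward(x), net2.forward(x))

    def test_wrong_label_channel_count_rejected(self, tiny_studies):
        net = build_network(desk_semantic_config(n_labels=5, width=4), seed=0)
        with pytest.raises(ValueError, match="label"):
            train(net, tiny_studies, self._tiny_config())
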