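"""Losses, the Nadam optimiser and the patch-based training loop.

The loss is categorical cross-entropy, weighted by a per-voxel validity
mask so organs that were never annotated in a study contribute nothing.
The instance network adds a masked squared-error term on the centre
offsets over true vertebra/rib voxels.  Optimisation uses the adaptive
moment method with Nesterov momentum (Nadam); everything is seeded, so a
training run is bit-reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ..core import Modality
from ..phantom import PhantomTruth
from ..preprocess import (
    AugmentationParams,
    NormalizationParams,
    PatchSample,
    augment,
    sample_patch,
)
from .network import NetworkConfig, UNet3D, output_shape, total_margin

__all__ = ["TrainingConfig", "TrainingHistory", "softmax", "masked_loss",
           "train", "save_network", "load_network"]


def softmax(logits: np.ndarray, axis: int = 0) -> np.ndarray:
    """Numerically stable SoftMax along ``axis``."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def masked_loss(class_probs: np.ndarray, targets: np.ndarray,
                validity: np.ndarray,
                centre_pred: np.ndarray | None = None,
                centre_target: np.ndarray | None = None,
                centre_mask: np.ndarray | None = None,
                centre_weight: float = 1.0,
                eps: float = 1e-12) -> float:
    """Masked categorical cross-entropy (+ optional centre-regression term).

    ``class_probs`` is channel-first (C, nx, ny, nz); ``targets`` holds the
    true class index per voxel.  The result is the mean of ``-log p(true)``
    over voxels with a nonzero validity mask.  For the instance network,
    ``centre_pred``/``centre_target`` (3, nx, ny, nz) add
    ``centre_weight`` times the mean squared offset error over
    ``centre_mask`` voxels.  An all-zero mask yields 0 with a warning.
    """
    valid = np.asarray(validity, dtype=bool)
    n = int(valid.sum())
    if n == 0:
        warnings.warn("masked_loss: validity mask is all zero; returning 0")
        ce = 0.0
    else:
        p = np.take_along_axis(class_probs, targets[None].astype(np.int64), axis=0)[0]
        ce = float(-np.log(np.maximum(p[valid], eps)).mean())
    loss = ce
    if centre_pred is not None:
        m = np.asarray(centre_mask, dtype=bool)
        if m.any():
            diff = (centre_pred - centre_target)[:, m]
            loss += centre_weight * float((diff ** 2).mean())
    return loss


def _loss_and_grad(net_cfg: NetworkConfig, logits: np.ndarray,
                   targets: np.ndarray, validity: np.ndarray,
                   centre_target: np.ndarray | None,
                   centre_mask: np.ndarray | None,
                   centre_weight: float) -> tuple[float, np.ndarray]:
    """Loss and gradient wrt the raw head outputs, for one sample."""
    nc = net_cfg.n_class_channels
    probs = softmax(logits[:nc], axis=0)
    grad = np.zeros_like(logits)
    valid = np.asarray(validity, dtype=bool)
    n = int(valid.sum())
    if n:
        p_true = np.take_along_axis(probs, targets[None].astype(np.int64), axis=0)[0]
        ce = float(-np.log(np.maximum(p_true[valid], 1e-12))[...].mean())
        onehot_grad = probs.copy()
        idx = np.nonzero(valid)
        onehot_grad[(targets[idx],) + idx] -= 1.0
        onehot_grad[:, ~valid] = 0.0
        grad[:nc] = onehot_grad / n
    else:
        ce = 0.0
    loss = ce
    if net_cfg.head == "instance" and centre_target is not None:
        m = np.asarray(centre_mask, dtype=bool)
        if m.any():
            pred = logits[nc:]
            diff = pred - centre_target
            diff[:, ~m] = 0.0
            k = int(m.sum()) * 3
            loss += centre_weight * float((diff[:, m] ** 2).mean())
            grad[nc:] = centre_weight * 2.0 * diff / k
    return loss, grad.astype(np.float32)


class Nadam:
    """Adam with Nesterov momentum (Dozat's Nadam update)."""

    def __init__(self, params, lr: float = 2e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(w) for w, _ in self.params]
        self.v = [np.zeros_like(w) for w, _ in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2, t = self.b1, self.b2, self.t
        for (w, g), m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1 ** t)
            v_hat = v / (1 - b2 ** t)
            update = (b1 * m_hat + (1 - b1) * g / (1 - b1 ** t))
            w -= self.lr * update / (np.sqrt(v_hat) + self.eps)


@dataclass
class TrainingConfig:
    """Hyperparameters for patch-based training.

    Defaults follow the operating point of the full-scale system (batch 50,
    cross-entropy, Nadam, 80/20 study-level split); desk-scale surrogates
    pass smaller ``patch_size``/``batch_size``.
    """

    patch_size: tuple[int, int, int] = (136, 136, 72)
    batch_size: int = 50
    epochs: int = 5
    steps_per_epoch: int = 20
    learning_rate: float = 2e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    val_fraction: float = 0.2
    seed: int = 0
    augmentation: AugmentationParams | None = None
    foreground_bias: float = 0.5
    centre_weight: float = 1.0
    normalization: NormalizationParams = field(default_factory=NormalizationParams)
    label_values: tuple[int, ...] | None = None  # registry labels per channel


@dataclass
class TrainingHistory:
    train_loss: list[float]          # per epoch (mean over steps)
    val_loss: list[float]            # per epoch
    step_loss: list[float]           # every optimisation step
    label_values: tuple[int, ...]
    train_indices: tuple[int, ...]
    val_indices: tuple[int, ...]


def _normalise(img_hu: np.ndarray, p: NormalizationParams) -> np.ndarray:
    return (np.clip(img_hu, p.clamp_low, p.clamp_high) / p.scale).astype(np.float32)


def _patch_targets(net_cfg: NetworkConfig, patch: PatchSample,
                   lut: np.ndarray, crop):
    """Crop patch targets to the network's output window and encode classes."""
    if net_cfg.head == "semantic":
        targets = lut[patch.labels[crop]]
        validity = patch.validity[crop]
        return targets, validity, None, None
    targets = patch.class_targets[crop].astype(np.int64)
    validity = patch.validity[crop]
    centre_target = (patch.centre_offsets[(slice(None),) + crop]
                     / net_cfg.offset_scale_mm).astype(np.float32)
    centre_mask = (targets > 0) & validity
    return targets, validity, centre_target, centre_mask


def train(network: UNet3D, studies: Sequence[PhantomTruth],
          config: TrainingConfig) -> TrainingHistory:
    """Train a network on a set of studies with randomly sampled patches.

    The studies are split 80/20 (configurable) into disjoint train and
    validation sets at the study level.  Each optimisation step draws
    ``batch_size`` patches from random training studies, augments them if
    configured, normalises the CT intensities and takes one Nadam step on
    the mean per-sample loss.  A NaN loss raises rather than being
    swallowed.
    """
    if not studies:
        raise ValueError("no studies given")
    cfg = network.config
    out_sz = output_shape(cfg, config.patch_size)  # raises if patch invalid
    margin = total_margin(cfg)
    delta_l = tuple(m // 2 for m in margin)
    crop = tuple(slice(delta_l[a], delta_l[a] + out_sz[a]) for a in range(3))

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(studies))
    n_val = int(round(config.val_fraction * len(studies)))
    n_val = min(n_val, len(studies) - 1)
    val_idx, train_idx = order[:n_val], order[n_val:]

    if cfg.head == "semantic":
        if config.label_values is not None:
            label_values = tuple(config.label_values)
        else:
            present: set[int] = set()
            for s in studies:
                present.update(s.labels.present_labels())
            label_values = tuple(sorted(present))
        if len(label_values) != cfg.n_labels:
            raise ValueError(
                f"network has {cfg.n_labels} label channels but {len(label_values)} "
                f"label values were supplied/found"
            )
        lut = np.zeros(max(label_values) + 1, dtype=np.int64)
        for ch, lab in enumerate(label_values, start=1):
            lut[lab] = ch
    else:
        label_values = ()
        lut = np.zeros(1, dtype=np.int64)

    def draw_batch(indices, batch_rng, n):
        batch = []
        for _ in range(n):
            truth = studies[indices[batch_rng.integers(len(indices))]]
            patch = sample_patch(
                truth.ct, truth.labels, truth.annotation, config.patch_size,
                batch_rng, foreground_bias=config.foreground_bias,
                instance_truth=truth if cfg.head == "instance" else None)
            if config.augmentation is not None:
                patch = augment(patch, config.augmentation, batch_rng)
            batch.append(patch)
        return batch

    opt = Nadam(network.parameters(), lr=config.learning_rate,
                beta1=config.beta1, beta2=config.beta2, eps=config.eps)
    step_losses: list[float] = []
    epoch_train: list[float] = []
    epoch_val: list[float] = []

    for epoch in range(config.epochs):
        losses = []
        for _ in range(config.steps_per_epoch):
            batch = draw_batch(train_idx, rng, config.batch_size)
            network.zero_grad()
            batch_loss = 0.0
            for patch in batch:
                x = _normalise(patch.image, config.normalization)[None]
                logits = network.forward(x, train=True)
                t, v, ct, cm = _patch_targets(cfg, patch, lut, crop)
                loss, grad = _loss_and_grad(cfg, logits, t, v, ct, cm,
                                            config.centre_weight)
                network.backward(grad / len(batch))
                batch_loss += loss / len(batch)
            if not np.isfinite(batch_loss):
                raise RuntimeError(f"training diverged at epoch {epoch}: loss={batch_loss}")
            opt.step()
            losses.append(batch_loss)
            step_losses.append(batch_loss)
        epoch_train.append(float(np.mean(losses)))

        # validation loss on a fixed, per-epoch-seeded patch draw
        val_rng = np.random.default_rng((config.seed, 0x5EED, epoch))
        vsrc = val_idx if len(val_idx) else train_idx
        vloss = 0.0
        n_val_patches = max(4, config.batch_size // 4)
        for patch in draw_batch(vsrc, val_rng, n_val_patches):
            x = _normalise(patch.image, config.normalization)[None]
            logits = network.forward(x, train=False)
            t, v, ct, cm = _patch_targets(cfg, patch, lut, crop)
            nc = cfg.n_class_channels
            vloss += masked_loss(softmax(logits[:nc], axis=0), t, v,
                                 logits[nc:] if cfg.head == "instance" else None,
                                 ct, cm, config.centre_weight) / n_val_patches
        epoch_val.append(float(vloss))

    return TrainingHistory(epoch_train, epoch_val, step_losses, label_values,
                           tuple(int(i) for i in train_idx),
                           tuple(int(i) for i in val_idx))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_network(network: UNet3D, directory: str | Path,
                 label_values: Sequence[int] = ()) -> None:
    """Persist weights (npz) plus a JSON sidecar with the NetworkConfig."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savez(d / "weights.npz", **network.state_arrays())
    network.config.to_json(d / "config.json")
    (d / "labels.json").write_text(json.dumps([int(v) for v in label_values]))


def load_network(directory: str | Path) -> tuple[UNet3D, tuple[int, ...]]:
    d = Path(directory)
    config = NetworkConfig.from_json(d / "config.json")
    net = UNet3D(config)
    with np.load(d / "weights.npz") as arrays:
        net.load_state_arrays(arrays)
    labels = tuple(json.loads((d / "labels.json").read_text())) \
        if (d / "labels.json").exists() else ()
    return net, labels
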