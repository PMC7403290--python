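"""Tiled whole-volume inference for the valid-convolution networks.

Because all convolutions are valid and the network is translation
equivariant at shifts of its pooling stride, a volume can be processed in
overlapping tiles whose outputs are bit-identical to a single whole-volume
pass.  Tile origins are placed on the stride lattice and the input is
mirror-padded by the network margin so the output covers the full grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from ..core import ImageGrid, LabelMap, Modality, Volume
from ..preprocess import NormalizationParams, clamp_scale
from .network import (
    NetworkConfig,
    UNet3D,
    find_valid_input_size,
    output_shape,
    receptive_field,
    total_margin,
)
from .training import softmax

__all__ = ["InstanceField", "predict_volume", "predict_labelmap"]


@dataclass
class InstanceField:
    """Instance-network output over a whole grid.

    ``class_probs`` (3, nx, ny, nz) are SoftMax probabilities for
    background / vertebra / rib; ``centres_mm`` (3, nx, ny, nz) is, per
    voxel, the predicted world-mm centre of the instance owning it.
    """

    grid: ImageGrid
    class_probs: np.ndarray
    centres_mm: np.ndarray

    def class_map(self) -> np.ndarray:
        """Per-voxel argmax class (0 background, 1 vertebra, 2 rib)."""
        return np.argmax(self.class_probs, axis=0).astype(np.int8)


def _pad_axis(arr: np.ndarray, axis: int, lo: int, hi: int) -> np.ndarray:
    """Mirror padding that tolerates pads larger than the array size."""
    while lo > 0 or hi > 0:
        l = min(lo, arr.shape[axis] - 1) if arr.shape[axis] > 1 else lo
        h = min(hi, arr.shape[axis] - 1) if arr.shape[axis] > 1 else hi
        pads = [(0, 0)] * arr.ndim
        pads[axis] = (l, h)
        mode = "symmetric" if arr.shape[axis] > 1 else "edge"
        arr = np.pad(arr, pads, mode=mode)
        lo -= l
        hi -= h
    return arr


def _tile_sizes(cfg: NetworkConfig, vol_shape, tile_out: int) -> tuple[int, ...]:
    """Per-axis tile output sizes: valid for the net, multiples of the stride."""
    q = cfg.stride
    s_min = find_valid_input_size(cfg, receptive_field(cfg))
    t_min = output_shape(cfg, s_min)
    sizes = []
    for a in range(3):
        target = max(t_min[a], min(tile_out, int(vol_shape[a])))
        extra = max(0, target - t_min[a])
        sizes.append(t_min[a] + q * int(np.ceil(extra / q)))
    return tuple(sizes)


def predict_volume(network: UNet3D, volume: Volume, tile_out: int = 48,
                   normalization: NormalizationParams | None = None):
    """Apply a network to a whole volume via exact overlap tiling.

    CT volumes are clamp/scale normalised first; already-normalised volumes
    pass straight through.  Returns, for a semantic network, the SoftMax
    probability array (n_labels + 1, nx, ny, nz); for an instance network,
    an :class:`InstanceField`.  The result is independent of the tiling
    plan (``tile_out`` only trades memory for speed).
    """
    cfg = network.config
    if volume.modality is Modality.CT_HU:
        volume = clamp_scale(volume, normalization or NormalizationParams())
    elif volume.modality is not Modality.NORMALIZED:
        raise ValueError("predict_volume expects a CT or normalised volume")

    vals = np.asarray(volume.values, dtype=np.float32)
    S = vals.shape
    margin = total_margin(cfg)
    delta_l = tuple(m // 2 for m in margin)
    delta_r = tuple(m - m // 2 for m in margin)
    T = _tile_sizes(cfg, S, tile_out)
    S_out = tuple(int(np.ceil(S[a] / T[a])) * T[a] for a in range(3))

    padded = vals
    for a in range(3):
        padded = _pad_axis(padded, a, delta_l[a], delta_r[a] + S_out[a] - S[a])

    out = np.empty((cfg.n_out_channels,) + S_out, dtype=np.float32)
    for gx, gy, gz in product(*[range(0, S_out[a], T[a]) for a in range(3)]):
        g = (gx, gy, gz)
        tile = padded[tuple(slice(g[a], g[a] + T[a] + margin[a]) for a in range(3))]
        y = network.forward(tile[None], train=False)
        out[(slice(None),) + tuple(slice(g[a], g[a] + T[a]) for a in range(3))] = y

    out = out[(slice(None),) + tuple(slice(0, S[a]) for a in range(3))]

    nc = cfg.n_class_channels
    probs = softmax(out[:nc], axis=0)
    if cfg.head == "semantic":
        return probs
    X, Y, Z = volume.grid.coordinate_arrays()
    centres = np.stack([X, Y, Z]).astype(np.float32) \
        + out[nc:] * np.float32(cfg.offset_scale_mm)
    return InstanceField(volume.grid, probs, centres)


def predict_labelmap(network: UNet3D, volume: Volume,
                     label_values, registry_ref: str = "organseg-catalogue-v1",
                     tile_out: int = 48) -> LabelMap:
    """Semantic argmax segmentation mapped back to registry label values.

    Argmax ties break toward the lower channel index (deterministic).
    """
    probs = predict_volume(network, volume, tile_out=tile_out)
    channels = np.argmax(probs, axis=0)
    mapping = np.array([0] + [int(v) for v in label_values], dtype=np.int32)
    return LabelMap(volume.grid, mapping[channels], registry_ref)
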