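"""Network configuration, construction and receptive-field algebra.

The body is a valid-convolution multi-resolution network loosely in the
U-Net family: pooling early in the network produces coarser levels (full
field of view only on the coarsest), each level runs a stack of valid
convolutions, and coarse features are upsampled, centre-cropped against
the skip path and merged back up.  Two kernel shapes, (3, 3, 3) and
(3, 3, 1), are interleaved so the receptive field stays approximately
cubic in millimetres on anisotropic voxels.

The full-scale default configuration has a layer-stack receptive field of
exactly (136, 136, 72) voxels, i.e. (184.96, 184.96, 216) mm at the
(1.36, 1.36, 3) mm operating spacing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .layers import AvgPool2, Conv3d, Upsample2, centre_crop, uncrop_grad

__all__ = [
    "LevelConfig", "NetworkConfig", "UNet3D", "build_network",
    "receptive_field", "receptive_field_mm", "output_shape", "total_margin",
    "find_valid_input_size", "full_scale_semantic_config",
    "full_scale_instance_config", "desk_semantic_config", "desk_instance_config",
]

Kernel = tuple[int, int, int]

K_ISO: Kernel = (3, 3, 3)   # near-isotropic in mm at (1.36, 1.36, 3) spacing
K_FLAT: Kernel = (3, 3, 1)  # flat in z: compensates the coarse slice spacing


@dataclass(frozen=True)
class LevelConfig:
    """Conv stacks and width for one resolution level.

    The last (coarsest) level is the bottom of the network and must have an
    empty decoder stack.
    """

    enc_kernels: tuple[Kernel, ...]
    dec_kernels: tuple[Kernel, ...]
    channels: int

    def __post_init__(self):
        object.__setattr__(self, "enc_kernels",
                           tuple(tuple(int(v) for v in k) for k in self.enc_kernels))
        object.__setattr__(self, "dec_kernels",
                           tuple(tuple(int(v) for v in k) for k in self.dec_kernels))
        if self.channels < 1:
            raise ValueError("channels must be >= 1")


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture description for either network flavour.

    ``head`` selects the output: "semantic" emits ``n_labels + 1`` SoftMax
    channels (background first); "instance" emits 3 SoftMax channels
    (background, vertebra, rib) plus 3 linear centre-offset channels.
    Offsets are regressed in units of ``offset_scale_mm`` millimetres.
    """

    levels: tuple[LevelConfig, ...]
    head: str = "semantic"
    n_labels: int = 1
    in_channels: int = 1
    offset_scale_mm: float = 30.0
    declared_receptive_field: tuple[int, int, int] | None = None

    def __post_init__(self):
        if self.head not in ("semantic", "instance"):
            raise ValueError(f"unknown head {self.head!r}")
        if len(self.levels) < 1:
            raise ValueError("need at least one level")
        if self.levels[-1].dec_kernels:
            raise ValueError("the bottom level must have an empty decoder stack")
        if self.declared_receptive_field is not None:
            rf = receptive_field(self)
            if tuple(self.declared_receptive_field) != rf:
                raise ValueError(
                    f"declared receptive field {self.declared_receptive_field} does not "
                    f"match the layer-stack-derived field {rf}"
                )

    @property
    def n_resolutions(self) -> int:
        return len(self.levels)

    @property
    def n_class_channels(self) -> int:
        return self.n_labels + 1 if self.head == "semantic" else 3

    @property
    def n_out_channels(self) -> int:
        return self.n_class_channels + (3 if self.head == "instance" else 0)

    @property
    def stride(self) -> int:
        """Overall translation-equivariance stride (2^(levels-1))."""
        return 2 ** (self.n_resolutions - 1)

    # -- (de)serialisation --------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NetworkConfig":
        d = json.loads(Path(path).read_text())
        levels = tuple(LevelConfig(tuple(map(tuple, lv["enc_kernels"])),
                                   tuple(map(tuple, lv["dec_kernels"])),
                                   lv["channels"]) for lv in d.pop("levels"))
        drf = d.pop("declared_receptive_field", None)
        return cls(levels=levels,
                   declared_receptive_field=tuple(drf) if drf else None, **d)


# ---------------------------------------------------------------------------
# receptive-field and shape algebra
# ---------------------------------------------------------------------------

def receptive_field(config: NetworkConfig) -> tuple[int, int, int]:
    """Receptive field in voxels, derived from the configured layer stack.

    Walking the deepest path: a valid convolution with kernel ``k`` adds
    ``(k - 1) * jump`` input voxels, a stride-2 pool adds ``jump`` and
    doubles the jump, nearest upsampling halves the jump and adds nothing.
    """
    rf = [1, 1, 1]
    for a in range(3):
        jump = 1
        for lv in config.levels[:-1]:
            for k in lv.enc_kernels:
                rf[a] += (k[a] - 1) * jump
            rf[a] += jump          # pool
            jump *= 2
        for k in config.levels[-1].enc_kernels:
            rf[a] += (k[a] - 1) * jump
        jump //= 2
        for lv in reversed(config.levels[:-1]):
            for k in lv.dec_kernels:
                rf[a] += (k[a] - 1) * jump
            jump //= 2
    return tuple(rf)


def receptive_field_mm(field_voxels, spacing) -> tuple[float, float, float]:
    """Physical receptive-field extent: elementwise voxels x mm spacing."""
    if any(v <= 0 for v in field_voxels) or any(s <= 0 for s in spacing):
        raise ValueError("field and spacing must be positive")
    return tuple(float(v) * float(s) for v, s in zip(field_voxels, spacing))


def _axis_out(config: NetworkConfig, s: int, axis: int, level: int = 0) -> int:
    """Output size along one axis; raises ValueError on invalid sizes."""
    lv = config.levels[level]
    for k in lv.enc_kernels:
        s -= k[axis] - 1
    if s < 1:
        raise ValueError("input too small for the encoder stack")
    if level == config.n_resolutions - 1:
        return s
    if s % 2:
        raise ValueError(f"size {s} before pooling at level {level} is odd")
    u = 2 * _axis_out(config, s // 2, axis, level + 1)
    if u > s:
        raise ValueError("upsampled path larger than the skip path")
    if (s - u) % 2:
        raise ValueError("skip-path crop is asymmetric")
    for k in lv.dec_kernels:
        u -= k[axis] - 1
    if u < 1:
        raise ValueError("input too small for the decoder stack")
    return u


def output_shape(config: NetworkConfig, in_shape: tuple[int, int, int]) -> tuple[int, int, int]:
    """Spatial output shape for a given input shape (raises if invalid)."""
    return tuple(_axis_out(config, int(in_shape[a]), a) for a in range(3))


def find_valid_input_size(config: NetworkConfig, minimum: tuple[int, int, int],
                          search: int = 4096) -> tuple[int, int, int]:
    """Smallest per-axis input size >= ``minimum`` the network accepts."""
    out = []
    for a in range(3):
        s = int(minimum[a])
        for _ in range(search):
            try:
                _axis_out(config, s, a)
                break
            except ValueError:
                s += 1
        else:
            raise ValueError(f"no valid input size found on axis {a}")
        out.append(s)
    return tuple(out)


def total_margin(config: NetworkConfig) -> tuple[int, int, int]:
    """Per-axis difference between input and output size (constant)."""
    size = find_valid_input_size(config, receptive_field(config))
    out = output_shape(config, size)
    return tuple(size[a] - out[a] for a in range(3))


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class UNet3D:
    """Valid-convolution multi-resolution FCN built from a NetworkConfig.

    Operates on single samples ``(in_channels, nx, ny, nz)`` and returns
    raw head outputs ``(n_out_channels, mx, my, mz)``; SoftMax over the
    class channels is applied by the loss / inference code.
    """

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.enc: list[list[Conv3d]] = []
        self.dec: list[list[Conv3d]] = []
        self.pools = [AvgPool2() for _ in config.levels[:-1]]
        self.ups = [Upsample2() for _ in config.levels[:-1]]

        cin = config.in_channels
        skip_channels = []
        for lv in config.levels:
            stack = []
            c = cin
            for k in lv.enc_kernels:
                stack.append(Conv3d(c, lv.channels, k, rng))
                c = lv.channels
            self.enc.append(stack)
            skip_channels.append(c)
            cin = c
        # decoder, coarse to fine
        above = skip_channels[-1]
        for li in range(config.n_resolutions - 2, -1, -1):
            lv = config.levels[li]
            stack = []
            c = skip_channels[li] + above
            for k in lv.dec_kernels:
                stack.append(Conv3d(c, lv.channels, k, rng))
                c = lv.channels
            self.dec.append(stack)  # stored coarse-to-fine
            above = c
        self.dec.reverse()          # now indexed by level
        self.head = Conv3d(above, config.n_out_channels, (1, 1, 1), rng, relu=False)
        self._trace: list | None = None

    # -- forward ------------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        cfg = self.config
        trace = [] if train else None
        skips = []

        def run(level: int, h: np.ndarray) -> np.ndarray:
            for conv in self.enc[level]:
                h = conv.forward(h, train)
            if level == cfg.n_resolutions - 1:
                return h
            skips.append(h)
            p = self.pools[level].forward(h, train)
            b = run(level + 1, p)
            u = self.ups[level].forward(b, train)
            skip = skips.pop()
            cropped = centre_crop(skip, u.shape[1:])
            h = np.concatenate([cropped, u], axis=0)
            if train:
                trace.append((level, skip.shape, cropped.shape[0]))
            for conv in self.dec[level]:
                h = conv.forward(h, train)
            return h

        out = run(0, np.ascontiguousarray(x, dtype=np.float32))
        y = self.head.forward(out, train)
        if train:
            self._trace = trace
        return y

    # -- backward -----------------------------------------------------------
    def backward(self, gy: np.ndarray) -> np.ndarray:
        cfg = self.config
        g = self.head.backward(gy)
        trace = {t[0]: t for t in (self._trace or [])}

        def back(level: int, g: np.ndarray) -> np.ndarray:
            if level < cfg.n_resolutions - 1:
                for conv in reversed(self.dec[level]):
                    g = conv.backward(g)
                _, skip_shape, n_skip = trace[level]
                g_skip_cropped = g[:n_skip]
                g_up = g[n_skip:]
                g_b = self.ups[level].backward(g_up)
                g_p = back(level + 1, g_b)
                g_pool = self.pools[level].backward(g_p)
                g_skip = uncrop_grad(g_skip_cropped, skip_shape[1:]) + g_pool
                g = g_skip
            for conv in reversed(self.enc[level]):
                g = conv.backward(g)
            return g

        return back(0, g)

    # -- parameter plumbing -------------------------------------------------
    def _convs(self):
        for stack in self.enc:
            yield from stack
        for stack in self.dec:
            yield from stack
        yield self.head

    def parameters(self):
        for conv in self._convs():
            yield from conv.parameters()

    def zero_grad(self):
        for conv in self._convs():
            conv.zero_grad()

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, conv in enumerate(self._convs()):
            out[f"w{i}"] = conv.w
            out[f"b{i}"] = conv.b
        return out

    def load_state_arrays(self, arrays) -> None:
        for i, conv in enumerate(self._convs()):
            conv.w[...] = arrays[f"w{i}"]
            conv.b[...] = arrays[f"b{i}"]


def build_network(config: NetworkConfig, seed: int = 0) -> UNet3D:
    """Instantiate a network; the config's declared invariants are checked."""
    return UNet3D(config, seed=seed)


# ---------------------------------------------------------------------------
# stock configurations
# ---------------------------------------------------------------------------

def _full_scale_levels() -> tuple[LevelConfig, ...]:
    # Two kernel shapes interleaved; per-level conv counts chosen so the
    # layer stack yields a (136, 136, 72)-voxel receptive field.
    pair = (K_FLAT, K_ISO)
    return (
        LevelConfig(pair * 2, pair * 2, 32),   # full resolution
        LevelConfig(pair, pair, 64),
        LevelConfig(pair, pair, 128),
        LevelConfig(pair * 2, (), 256),        # bottom: full field of view
    )


def full_scale_semantic_config(n_labels: int = 100) -> NetworkConfig:
    """Full-scale semantic network: 4 resolutions, RF (136, 136, 72)."""
    return NetworkConfig(levels=_full_scale_levels(), head="semantic",
                         n_labels=n_labels,
                         declared_receptive_field=(136, 136, 72))


def full_scale_instance_config() -> NetworkConfig:
    """Full-scale vertebra/rib instance network (3 classes + 3 offsets)."""
    return NetworkConfig(levels=_full_scale_levels(), head="instance",
                         declared_receptive_field=(136, 136, 72))


def _desk_levels(width: int = 8) -> tuple[LevelConfig, ...]:
    return (
        LevelConfig((K_ISO,), (K_ISO,), width),
        LevelConfig((K_ISO, K_ISO), (), width * 2),
    )


def desk_semantic_config(n_labels: int = 3, width: int = 8) -> NetworkConfig:
    """Reduced 2-resolution semantic net for CPU-scale phantom training."""
    return NetworkConfig(levels=_desk_levels(width), head="semantic",
                         n_labels=n_labels)


def desk_instance_config(width: int = 8, offset_scale_mm: float = 30.0) -> NetworkConfig:
    """Reduced instance net (3 classes + centre offsets) for phantom training."""
    return NetworkConfig(levels=_desk_levels(width), head="instance",
                         offset_scale_mm=offset_scale_mm)
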