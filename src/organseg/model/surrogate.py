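"""Desk-scale training surrogates on seeded phantom cohorts.

The full-scale system was trained on hundreds of annotated whole-body CT
studies; that experiment is not reproducible on a workstation.  These
surrogates exercise the identical code path — patch sampling, masked
cross-entropy, Nadam, valid-convolution tiled inference — on cohorts of
64x64x64 phantoms small enough to train in a few CPU-minutes, and measure
the quantities that show the machinery works: held-out per-label Dice for
the semantic net, and the centre-regression error of the instance net on
vertebra voxels.
"""

from __future__ import annotations

import numpy as np

from ..core import InstanceClass
from ..metrics import metrics_table
from ..phantom import (
    PhantomTruth,
    generate_phantom,
    make_organ_phantom_spec,
    make_spine_phantom_spec,
)
from .inference import predict_labelmap, predict_volume
from .network import UNet3D, build_network, desk_instance_config, desk_semantic_config
from .training import TrainingConfig, TrainingHistory, train

__all__ = [
    "derive_seed",
    "semantic_surrogate_studies",
    "spine_surrogate_studies",
    "surrogate_training_config",
    "train_semantic_surrogate",
    "train_instance_surrogate",
    "heldout_semantic_dice",
    "heldout_centre_error_mm",
]

#: cohort size of the desk-scale experiments
N_STUDIES = 20


def derive_seed(seed: int, stream: int) -> int:
    """A decorrelated 31-bit child seed for one named random stream."""
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2 ** 31))


def semantic_surrogate_studies(seed: int = 0, n: int = N_STUDIES) -> list[PhantomTruth]:
    """Cohort of three-organ phantoms (lung / liver / hip bone)."""
    return [generate_phantom(make_organ_phantom_spec(seed=derive_seed(seed, i)))
            for i in range(n)]


def spine_surrogate_studies(seed: int = 0, n: int = N_STUDIES,
                            n_vertebrae: int = 5) -> list[PhantomTruth]:
    """Cohort of spine phantoms with rib tubes."""
    return [generate_phantom(make_spine_phantom_spec(seed=derive_seed(seed, 1000 + i),
                                                     n_vertebrae=n_vertebrae))
            for i in range(n)]


def surrogate_training_config(seed: int) -> TrainingConfig:
    """The desk-scale training recipe (28-cube patches, 16 short epochs)."""
    return TrainingConfig(patch_size=(28, 28, 28), batch_size=8, epochs=16,
                          steps_per_epoch=25, learning_rate=1.5e-3,
                          foreground_bias=0.6, seed=seed)


def train_semantic_surrogate(seed: int = 0, studies=None
                             ) -> tuple[UNet3D, list[PhantomTruth], TrainingHistory]:
    studies = studies or semantic_surrogate_studies(seed)
    net = build_network(desk_semantic_config(n_labels=3, width=10),
                        seed=derive_seed(seed, 2))
    history = train(net, studies, surrogate_training_config(derive_seed(seed, 3)))
    return net, studies, history


def train_instance_surrogate(seed: int = 0, studies=None
                             ) -> tuple[UNet3D, list[PhantomTruth], TrainingHistory]:
    studies = studies or spine_surrogate_studies(seed)
    net = build_network(desk_instance_config(width=10),
                        seed=derive_seed(seed, 4))
    history = train(net, studies, surrogate_training_config(derive_seed(seed, 5)))
    return net, studies, history


def heldout_semantic_dice(net: UNet3D, studies, history: TrainingHistory,
                          max_cases: int = 4) -> dict[int, float]:
    """Worst per-label Dice over held-out validation studies."""
    worst: dict[int, float] = {}
    for vi in history.val_indices[:max_cases]:
        s = studies[vi]
        pred = predict_labelmap(net, s.ct, history.label_values, tile_out=64)
        table = metrics_table(pred, s.labels)
        for lab, dice in zip(table.label, table.dice):
            lab = int(lab)
            worst[lab] = min(worst.get(lab, 1.0), float(dice))
    return worst


def heldout_centre_error_mm(net: UNet3D, studies, history: TrainingHistory,
                            max_cases: int = 3) -> float:
    """Mean centre-prediction error (mm) over vertebra voxels, held out."""
    errs = []
    for vi in history.val_indices[:max_cases]:
        s = studies[vi]
        field = predict_volume(net, s.ct, tile_out=64)
        for iid, icls in s.instance_classes.items():
            if icls is not InstanceClass.VERTEBRA:
                continue
            m = s.instance_map == iid
            true_c = s.instance_centres[iid]
            err = np.linalg.norm(field.centres_mm[:, m] - true_c[:, None], axis=0)
            errs.append(float(err.mean()))
    return float(np.mean(errs))
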