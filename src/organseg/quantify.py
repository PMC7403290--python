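"""Per-label quantification: volumes, intensity statistics and SUV.

Given any segmentation (manual or automatic) and a value volume, the
quantification panel reports, per label: volume in ml, mean and max voxel
value, the number of 26-connected components, and the total uptake
(sum of voxel value x voxel volume).  For PET, activity concentration is
converted to the body-weight standardised uptake value

    SUVbw = concentration [Bq/ml] * weight [g] / decay-corrected dose [Bq]

with the injected dose decay-corrected to the scan start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import LabelMap, LabelRegistry, Volume, voxel_volume_ml

__all__ = ["SuvContext", "label_stats", "suv_scale", "total_uptake",
           "QUANT_COLUMNS"]

QUANT_COLUMNS = ["label", "name", "volume_ml", "mean", "max",
                 "components", "total_uptake"]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class SuvContext:
    """Everything needed to scale stored PET values to SUVbw.

    ``injected_dose_bq`` is the activity at ``injection_to_scan_s`` seconds
    before the scan start; ``half_life_s`` is the radionuclide half-life
    (6586.2 s for F-18).  ``stored_units`` says what the PET voxels hold:
    "BQML" (Bq/ml, the common DICOM case) or "KBQML".
    """

    injected_dose_bq: float
    patient_weight_kg: float
    half_life_s: float = 6586.2
    injection_to_scan_s: float = 0.0
    stored_units: str = "BQML"

    def __post_init__(self):
        if self.injected_dose_bq <= 0 or self.patient_weight_kg <= 0 \
                or self.half_life_s <= 0:
            raise ValueError("dose, weight and half-life must all be > 0")
        if self.stored_units not in ("BQML", "KBQML"):
            raise ValueError(f"unsupported stored units {self.stored_units!r}")


def suv_scale(context: SuvContext) -> float:
    """Multiplicative factor taking stored activity values to SUVbw.

    The injected dose is decayed to the scan start:
    ``dose_at_scan = dose * 2^(-t / T_half)``; the factor is
    ``weight[g] / dose_at_scan[Bq]`` (times 1000 for kBq/ml storage).
    One half-life of delay therefore doubles the factor.
    """
    dose_at_scan = context.injected_dose_bq * 2.0 ** (
        -context.injection_to_scan_s / context.half_life_s)
    factor = context.patient_weight_kg * 1000.0 / dose_at_scan
    if context.stored_units == "KBQML":
        factor *= 1000.0
    return float(factor)


def label_stats(labels: LabelMap, values: Volume,
                registry: LabelRegistry | None = None,
                include_labels=None) -> pd.DataFrame:
    """Per-label statistics table over ``values``.

    One row per label: exact mean/max over the label's voxels, volume from
    the voxel count, 26-connected component count, and total uptake
    ``sum(value) * voxel_volume``.  Empty labels (requested via
    ``include_labels`` but absent) get a zero-volume row with 0 components.
    """
    if labels.grid != values.grid:
        raise ValueError("labels and values are on different grids")
    vv = voxel_volume_ml(labels.grid)
    arr = labels.labels
    vals = values.values
    present = labels.present_labels()
    report_labels = sorted(set(present) | set(int(v) for v in (include_labels or [])))
    rows = []
    for lab in report_labels:
        mask = arr == lab
        n = int(mask.sum())
        name = registry[lab].name if registry is not None and lab in registry else str(lab)
        if n == 0:
            rows.append((lab, name, 0.0, np.nan, np.nan, 0, 0.0))
            continue
        v = vals[mask]
        _, ncomp = ndimage.label(mask, structure=_STRUCT_26)
        rows.append((lab, name, n * vv, float(v.mean()), float(v.max()),
                     int(ncomp), float(v.sum()) * vv))
    return pd.DataFrame(rows, columns=QUANT_COLUMNS)


def total_uptake(labels: LabelMap, pet_suv: Volume) -> dict[int, float]:
    """Per-label integral of SUV over the label volume (SUV x ml).

    Identically equals mean x volume for every label.
    """
    if labels.grid != pet_suv.grid:
        raise ValueError("labels and PET are on different grids")
    vv = voxel_volume_ml(labels.grid)
    arr = labels.labels
    out = {}
    for lab in labels.present_labels():
        out[lab] = float(pet_suv.values[arr == lab].sum()) * vv
    return out
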