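"""Segmentation agreement metrics: Dice, recall, precision and aggregates.

All metrics derive from exact per-label voxel confusion counts between a
predicted and a reference label map.  Labels that were not annotated in a
study are excluded entirely, so sparse annotation never distorts the
numbers of other labels.  Two aggregation modes are provided because they
genuinely differ: the unweighted mean of per-organ metrics, and pooled
"foreground" metrics computed on the union of all labels against
background.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AnnotationMask, Group, LabelMap, LabelRegistry

__all__ = [
    "confusion_counts",
    "dice_recall_precision",
    "foreground_metrics",
    "metrics_table",
    "aggregate",
    "case_dispersion",
    "interobserver",
]

METRIC_COLUMNS = ["label", "name", "dice", "recall", "precision", "tp", "fp", "fn"]


def _as_arrays(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    p = pred.labels if isinstance(pred, LabelMap) else np.asarray(pred)
    t = truth.labels if isinstance(truth, LabelMap) else np.asarray(truth)
    if isinstance(pred, LabelMap) and isinstance(truth, LabelMap) \
            and pred.grid != truth.grid:
        raise ValueError("prediction and reference are on different grids")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return p.ravel(), t.ravel()


def confusion_counts(pred, truth, annotation: AnnotationMask | None = None
                     ) -> dict[int, tuple[int, int, int]]:
    """Exact per-label (TP, FP, FN) voxel counts.

    Labels are the union of nonzero values in either map, restricted to the
    annotated set when an :class:`AnnotationMask` is given.
    """
    p, t = _as_arrays(pred, truth)
    K = int(max(p.max(initial=0), t.max(initial=0))) + 1
    tp = np.bincount(t[p == t], minlength=K)
    n_truth = np.bincount(t, minlength=K)
    n_pred = np.bincount(p, minlength=K)
    labels = sorted(set(np.unique(p)) | set(np.unique(t)))
    out = {}
    for lab in labels:
        lab = int(lab)
        if lab == 0:
            continue
        if annotation is not None and not annotation.includes(lab):
            continue
        out[lab] = (int(tp[lab]), int(n_pred[lab] - tp[lab]), int(n_truth[lab] - tp[lab]))
    return out


def dice_recall_precision(counts: tuple[int, int, int],
                          empty_value: float | None = 1.0
                          ) -> tuple[float, float, float]:
    """(dice, recall, precision) from a (TP, FP, FN) triple.

    Dice = 2TP/(2TP+FP+FN), recall = TP/(TP+FN), precision = TP/(TP+FP).
    When both masks are empty (TP=FP=FN=0) all three default to
    ``empty_value`` (agreement on absence); pass ``empty_value=None`` to
    get NaN instead.
    """
    tp, fp, fn = (int(c) for c in counts)
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp == fp == fn == 0:
        v = np.nan if empty_value is None else float(empty_value)
        return (v, v, v)
    dice = 2 * tp / (2 * tp + fp + fn)
    recall = tp / (tp + fn) if tp + fn else (np.nan if empty_value is None else float(empty_value))
    precision = tp / (tp + fp) if tp + fp else (np.nan if empty_value is None else float(empty_value))
    return (float(dice), float(recall), float(precision))


def foreground_metrics(pred, truth) -> tuple[float, float, float]:
    """Dice/recall/precision of all foreground voxels pooled, label-blind."""
    p, t = _as_arrays(pred, truth)
    pf, tf = p > 0, t > 0
    tp = int(np.count_nonzero(pf & tf))
    fp = int(np.count_nonzero(pf & ~tf))
    fn = int(np.count_nonzero(~pf & tf))
    return dice_recall_precision((tp, fp, fn))


def metrics_table(pred, truth, annotation: AnnotationMask | None = None,
                  registry: LabelRegistry | None = None,
                  empty_value: float | None = 1.0) -> pd.DataFrame:
    """Per-label metrics rows (one per annotated label present anywhere)."""
    counts = confusion_counts(pred, truth, annotation)
    rows = []
    for lab, c in counts.items():
        d, r, pr = dice_recall_precision(c, empty_value)
        name = registry[lab].name if registry is not None and lab in registry else str(lab)
        rows.append((lab, name, d, r, pr, *c))
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def aggregate(table: pd.DataFrame, registry: LabelRegistry | None = None,
              grouping: str = "group") -> pd.DataFrame:
    """Unweighted group means of the per-label metrics.

    ``grouping='group'`` aggregates by bone / soft-tissue (requires a
    registry) plus an overall row; ``grouping='all'`` yields the overall
    row only.  The mean is over label entries, not voxels — pooled-voxel
    foreground metrics are a deliberately separate computation
    (:func:`foreground_metrics`).
    """
    if table.empty:
        raise ValueError("cannot aggregate an empty metrics table")
    rows = []

    def mean_row(name, sub):
        return (name, len(sub), float(sub.dice.mean()),
                float(sub.recall.mean()), float(sub.precision.mean()))

    if grouping == "group":
        if registry is None:
            raise ValueError("group aggregation requires a registry")
        groups = {g: [] for g in (Group.BONE, Group.SOFT_TISSUE)}
        for _, row in table.iterrows():
            if int(row.label) in registry:
                groups[registry[int(row.label)].group].append(row)
        for g, members in groups.items():
            if members:
                rows.append(mean_row(g.value, pd.DataFrame(members)))
    elif grouping != "all":
        raise ValueError(f"unknown grouping {grouping!r}")
    rows.append(mean_row("all", table))
    return pd.DataFrame(rows, columns=["group", "n_labels", "dice", "recall", "precision"])


def case_dispersion(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Per-label mean and standard deviation of Dice across cases."""
    if not tables:
        raise ValueError("no cases given")
    cat = pd.concat(tables, ignore_index=True)
    g = cat.groupby("label")["dice"]
    out = pd.DataFrame({"label": g.mean().index,
                        "dice_mean": g.mean().values,
                        "dice_sd": g.std(ddof=0).values,
                        "n_cases": g.count().values})
    return out.reset_index(drop=True)


def interobserver(reader1, reader2, registry: LabelRegistry | None = None,
                  annotation: AnnotationMask | None = None) -> pd.DataFrame:
    """Agreement between two readers, treating reader2 as the reference.

    Dice is symmetric under argument exchange; recall and precision swap.
    """
    return metrics_table(reader1, reader2, annotation, registry)
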