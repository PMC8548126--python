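"""Pixel-wise evaluation of probability maps against ground-truth lesion masks.

Metrics are pooled ("micro") over all test pixels, matching the single
optimal sensitivity/specificity pair reported for a whole test set: ROC/AUC,
the Youden-optimal operating point (maximizing sensitivity + specificity - 1,
ties broken toward higher sensitivity), accuracy, and the Dice similarity
coefficient 2TP/(2TP+FP+FN) evaluated at the Youden-optimal threshold.
Predictions are positive when probability >= threshold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as sk_roc_curve

from .fundus_io import ProbabilityMap


class EvaluationError(ValueError):
    pass


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else float("nan")


@dataclass
class RocResult:
    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    youden_optimal: tuple[float, float, float, float]  # (threshold, sens, spec, acc)


def _pool(maps: Sequence[ProbabilityMap], truths: Sequence[np.ndarray]):
    if len(maps) != len(truths):
        raise EvaluationError(f"{len(maps)} maps vs {len(truths)} truths")
    scores, labels = [], []
    for pmap, truth in zip(maps, truths):
        truth = np.asarray(truth)
        if pmap.values.shape != truth.shape:
            raise EvaluationError(
                f"map {pmap.id!r} shape {pmap.values.shape} != truth shape {truth.shape}"
            )
        scores.append(pmap.values.ravel())
        labels.append(truth.ravel().astype(np.int8))
    return np.concatenate(scores), np.concatenate(labels)


def confusion_at(
    maps: Sequence[ProbabilityMap],
    truths: Sequence[np.ndarray],
    threshold: float,
) -> ConfusionCounts:
    """Pooled pixel confusion counts at a probability threshold (positive iff >=)."""
    scores, labels = _pool(maps, truths)
    pred = scores >= threshold
    pos = labels == 1
    tp = int(np.count_nonzero(pred & pos))
    fp = int(np.count_nonzero(pred & ~pos))
    fn = int(np.count_nonzero(~pred & pos))
    tn = int(np.count_nonzero(~pred & ~pos))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def roc(maps: Sequence[ProbabilityMap], truths: Sequence[np.ndarray]) -> RocResult:
    """Pooled ROC curve, trapezoidal AUC, and the Youden-optimal operating point."""
    scores, labels = _pool(maps, truths)
    if labels.min() == labels.max():
        raise EvaluationError("ground truth contains a single class; ROC undefined")
    fpr, tpr, thresholds = sk_roc_curve(labels, scores, drop_intermediate=False)
    sens, spec = tpr, 1.0 - fpr
    auc = float(np.trapezoid(tpr, fpr))
    youden = sens + spec - 1.0
    best_j = youden.max()
    candidates = np.flatnonzero(youden >= best_j - 1e-12)
    best = candidates[np.argmax(sens[candidates])]  # ties: higher sensitivity
    thr = float(min(thresholds[best], 1.0))  # sk uses inf sentinel above max score
    counts = confusion_at(maps, truths, thr)
    return RocResult(
        thresholds=thresholds,
        sens=sens,
        spec=spec,
        auc=auc,
        youden_optimal=(thr, float(sens[best]), float(spec[best]), counts.accuracy),
    )


def youden_index(sensitivity: float, specificity: float) -> float:
    """Youden's J statistic: sensitivity + specificity - 1."""
    return sensitivity + specificity - 1.0


def dsc(counts: ConfusionCounts) -> float:
    """Dice similarity coefficient 2TP/(2TP+FP+FN).

    When prediction and truth are both empty the overlap is vacuously perfect:
    returns 1.0 with a warning.
    """
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        warnings.warn("DSC undefined (both prediction and truth empty); returning 1.0")
        return 1.0
    return 2 * counts.tp / denom


VARIANTS = ("raw", "macula_masked", "od_masked", "both_masked")


def evaluate_run(
    variant_maps: dict[str, list[ProbabilityMap]],
    truths: Sequence[np.ndarray],
) -> pd.DataFrame:
    """Per-variant report: AUC, Youden-optimal sens/spec/accuracy, and DSC.

    ``variant_maps`` maps each pipeline variant name (see :data:`VARIANTS`:
    raw / +macula mask / +OD mask / +both) to its probability maps.  DSC is
    computed at each variant's own Youden-optimal threshold.
    """
    rows = []
    for variant in VARIANTS:
        if variant not in variant_maps:
            raise EvaluationError(f"missing variant {variant!r}")
        maps = variant_maps[variant]
        r = roc(maps, truths)
        thr, sens, spec, acc = r.youden_optimal
        counts = confusion_at(maps, truths, thr)
        rows.append(
            {
                "variant": variant,
                "auc": r.auc,
                "sensitivity": sens,
                "specificity": spec,
                "accuracy": acc,
                "dsc": dsc(counts),
                "threshold": thr,
            }
        )
    return pd.DataFrame(rows)


def save_report(report: pd.DataFrame, csv_path: str | Path, json_path: str | Path | None = None):
    report.to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(report.to_dict(orient="records"), indent=2))


def save_roc_points(result: RocResult, csv_path: str | Path) -> None:
    """Export the ROC curve (threshold, sensitivity, specificity) for plotting."""
    pd.DataFrame(
        {"threshold": result.thresholds, "sensitivity": result.sens,
         "specificity": result.spec}
    ).to_csv(csv_path, index=False)
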