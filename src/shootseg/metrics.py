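"""Evaluation protocol: per-class precision, recall and IoU with flower exclusion.

Predictions are binary (leaf/stem).  Points whose ground truth is any other
class — flower, pot, tag, background — are excluded from the confusion counts
and tallied separately, so a method is neither rewarded nor punished for what
it predicts on flowers.

Per class: precision = TP/(TP+FP), recall = TP/(TP+FN),
IoU = TP/(TP+FN+FP).  A zero denominator makes the metric *undefined* (NaN),
which is distinct from 0 and excluded from averages with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .core import DatasetManifest, OrganLabel
from .errors import ValidationError

__all__ = [
    "SegmentationReport",
    "confusion_counts",
    "metrics_from_confusion",
    "evaluate_labels",
    "evaluate_manifest",
    "summarize_reports",
]

_CLASSES = (int(OrganLabel.LEAF), int(OrganLabel.STEM))
_CLASS_NAMES = {int(OrganLabel.LEAF): "leaf", int(OrganLabel.STEM): "stem"}


@dataclass
class SegmentationReport:
    """Confusion counts over {leaf, stem} plus the derived metrics.

    ``confusion[i, j]`` counts points with ground truth class ``i`` predicted
    as class ``j``, rows/columns ordered (leaf, stem).
    """

    confusion: np.ndarray
    n_ignored: int
    precision: dict[str, float]
    recall: dict[str, float]
    iou: dict[str, float]

    @property
    def mean_iou(self) -> float:
        vals = np.array(list(self.iou.values()), dtype=float)
        defined = vals[~np.isnan(vals)]
        if len(defined) < len(vals):
            warnings.warn("mean IoU excludes undefined per-class values")
        return float(defined.mean()) if len(defined) else float("nan")

    def as_row(self) -> dict[str, float]:
        return {
            "R_leaf": self.recall["leaf"],
            "R_stem": self.recall["stem"],
            "P_leaf": self.precision["leaf"],
            "P_stem": self.precision["stem"],
            "IoU_leaf": self.iou["leaf"],
            "IoU_stem": self.iou["stem"],
        }


def confusion_counts(gt_labels: np.ndarray, pred_labels: np.ndarray) -> tuple[np.ndarray, int]:
    """2x2 confusion over (leaf, stem) plus the count of ignored points."""
    gt = np.asarray(gt_labels, dtype=np.int64)
    pred = np.asarray(pred_labels, dtype=np.int64)
    if gt.shape != pred.shape:
        raise ValidationError(f"gt length {gt.shape} != pred length {pred.shape}")
    if not np.isin(pred, _CLASSES).all():
        bad = np.setdiff1d(np.unique(pred), _CLASSES)
        raise ValidationError(f"predictions must be leaf/stem codes, got also {bad.tolist()}")
    scored = np.isin(gt, _CLASSES)
    n_ignored = int((~scored).sum())
    conf = np.zeros((2, 2), dtype=np.int64)
    for i, ci in enumerate(_CLASSES):
        for j, cj in enumerate(_CLASSES):
            conf[i, j] = int(((gt == ci) & (pred == cj) & scored).sum())
    return conf, n_ignored


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metrics_from_confusion(confusion: np.ndarray) -> tuple[dict, dict, dict]:
    """Per-class precision, recall and IoU from a 2x2 confusion matrix."""
    conf = np.asarray(confusion, dtype=np.int64)
    if conf.shape != (2, 2) or (conf < 0).any():
        raise ValidationError("confusion must be a non-negative 2x2 matrix")
    precision, recall, iou = {}, {}, {}
    for i, code in enumerate(_CLASSES):
        name = _CLASS_NAMES[code]
        tp = conf[i, i]
        fn = conf[i].sum() - tp
        fp = conf[:, i].sum() - tp
        precision[name] = _safe_div(tp, tp + fp)
        recall[name] = _safe_div(tp, tp + fn)
        iou[name] = _safe_div(tp, tp + fn + fp)
    return precision, recall, iou


def evaluate_labels(gt_labels: np.ndarray, pred_labels: np.ndarray) -> SegmentationReport:
    """Full report for one model's ground truth and predictions."""
    conf, n_ignored = confusion_counts(gt_labels, pred_labels)
    precision, recall, iou = metrics_from_confusion(conf)
    return SegmentationReport(conf, n_ignored, precision, recall, iou)


def summarize_reports(reports: dict[str, SegmentationReport]) -> pd.DataFrame:
    """Per-model rows plus a mean and sd row over the models.

    NaN (undefined) metrics are excluded from the aggregates; pandas mean/std
    skip NaN, and a warning is emitted when any are present.
    """
    rows = {mid: rep.as_row() for mid, rep in reports.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    if df.isna().any().any():
        warnings.warn("some per-class metrics are undefined and excluded from averages")
    mean = df.mean()
    sd = df.std(ddof=1) if len(df) > 1 else df.iloc[0] * 0.0
    df.loc["mean"] = mean
    df.loc["sd"] = sd
    df.index.name = "model_id"
    return df


def evaluate_manifest(
    manifest: DatasetManifest,
    predictions: dict[str, np.ndarray],
    ground_truth: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Evaluate per-model predictions over the manifest's test entries."""
    reports = {}
    for entry in manifest.test:
        if entry.model_id not in predictions:
            raise ValidationError(f"no predictions for test model {entry.model_id}")
        reports[entry.model_id] = evaluate_labels(
            ground_truth[entry.model_id], predictions[entry.model_id]
        )
    return summarize_reports(reports)
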