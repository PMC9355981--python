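"""Segmentation agreement metrics.

For each muscle label (one-vs-rest) seven metrics are computed from the
voxel confusion counts:

====================  =========================================
Sørensen-Dice         2 TP / (2 TP + FP + FN)
Jaccard               TP / (TP + FP + FN)
Conformity            1 - (FP + FN) / TP           (<= 1, unbounded below)
True positive rate    TP / (TP + FN)
True negative rate    TN / (TN + FP)
Positive pred. value  TP / (TP + FP)
Volume ratio          |SM| / |GT|
====================  =========================================

plus absolute volumes in ml (voxel count x voxel volume / 1000). Metrics
are computed on whole volumes, not per slice. Degenerate conventions: a
label empty in both masks scores 1.0 throughout; a label with TP = 0 but
positives present gets NaN conformity, and a prediction over an empty
ground truth gets NaN volume ratio — both flagged in the ``degenerate``
column so aggregates stay finite and auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume import LABEL_NAMES, MUSCLE_LABELS, LabelMask, _check_geometry

METRIC_COLUMNS = ("dice", "jaccard", "conformity", "tpr", "tnr", "ppv", "volume_ratio")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(pred: LabelMask, gt: LabelMask, label: int) -> ConfusionCounts:
    """One-vs-rest voxel confusion counts for ``label``."""
    _check_geometry(pred, gt)
    p = pred.data == label
    g = gt.data == label
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(p.size - tp - fp - fn)
    return ConfusionCounts(tp, fp, fn, tn)


def metrics_from_counts(c: ConfusionCounts) -> dict:
    """The seven agreement metrics from one-vs-rest counts."""
    tp, fp, fn, tn = c.tp, c.fp, c.fn, c.tn
    n_pred = tp + fp
    n_gt = tp + fn
    degenerate = False
    if n_pred == 0 and n_gt == 0:
        vals = {m: 1.0 for m in METRIC_COLUMNS}
        vals["tnr"] = tn / (tn + fp) if tn + fp else 1.0
        return {**vals, "degenerate": False}
    dice = 2.0 * tp / (2.0 * tp + fp + fn)
    jaccard = tp / (tp + fp + fn)
    if tp > 0:
        conformity = 1.0 - (fp + fn) / tp
    else:
        conformity, degenerate = np.nan, True
    tpr = tp / n_gt if n_gt else np.nan
    tnr = tn / (tn + fp) if tn + fp else 1.0
    ppv = tp / n_pred if n_pred else np.nan
    if n_gt:
        volume_ratio = n_pred / n_gt
    else:
        volume_ratio, degenerate = np.nan, True
    if n_gt == 0 or n_pred == 0:
        degenerate = True
    return {"dice": dice, "jaccard": jaccard, "conformity": conformity,
            "tpr": tpr, "tnr": tnr, "ppv": ppv, "volume_ratio": volume_ratio,
            "degenerate": degenerate}


def compute_metrics(pred: LabelMask, gt: LabelMask, spacing=None,
                    subject: str = "") -> pd.DataFrame:
    """MetricReport rows: one per muscle label, with volumes in ml."""
    _check_geometry(pred, gt)
    if spacing is None:
        spacing = gt.spacing
    vv_ml = float(np.prod(spacing)) / 1000.0
    rows = []
    for lab in MUSCLE_LABELS:
        c = confusion_counts(pred, gt, lab)
        vals = metrics_from_counts(c)
        rows.append({"subject": subject, "label": lab,
                     "label_name": LABEL_NAMES[lab], **vals,
                     "volume_sm_ml": (c.tp + c.fp) * vv_ml,
                     "volume_gt_ml": (c.tp + c.fn) * vv_ml})
    return pd.DataFrame(rows)


def evaluate_manifest(pred_masks: dict, gt_manifest) -> pd.DataFrame:
    """Batch evaluation: ``pred_masks`` maps subject_id -> LabelMask."""
    from .volume import read_manifest, read_mask

    df = read_manifest(gt_manifest) if not isinstance(gt_manifest, pd.DataFrame) else gt_manifest
    reports = []
    for _, row in df.iterrows():
        sid = row["subject_id"]
        if sid not in pred_masks:
            continue
        gt = read_mask(row["mask"])
        reports.append(compute_metrics(pred_masks[sid], gt, subject=sid))
    return pd.concat(reports, ignore_index=True) if reports else pd.DataFrame()
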