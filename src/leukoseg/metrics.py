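"""Pixelwise segmentation metrics.

Six standard measures derived from the confusion counts of a predicted binary
mask against a ground-truth mask: accuracy, precision, recall, specificity,
Dice similarity coefficient (DSC / F1) and intersection-over-union (IoU /
Jaccard).  DSC and IoU are linked by the identity DSC = 2·IoU / (1 + IoU).

Ratios with a zero denominator (e.g. precision of an empty prediction) are
reported as 0.0 and flagged in ``MetricReport.undefined``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DimensionError

METRIC_NAMES = ("accuracy", "precision", "recall", "specificity", "dsc", "iou")


@dataclass
class MetricReport:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    specificity: float
    dsc: float
    iou: float
    undefined: tuple[str, ...] = field(default_factory=tuple)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["undefined"] = list(self.undefined)
        return d


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> tuple[int, int, int, int]:
    """Exhaustive pixelwise (TP, TN, FP, FN) tally of two boolean masks."""
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise DimensionError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    tp = int(np.count_nonzero(pred & gt))
    tn = int(np.count_nonzero(~pred & ~gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    return tp, tn, fp, fn


def report_from_counts(tp: int, tn: int, fp: int, fn: int) -> MetricReport:
    """Build a :class:`MetricReport` from confusion counts."""
    undefined: list[str] = []

    def ratio(name: str, num: float, den: float) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    total = tp + tn + fp + fn
    accuracy = ratio("accuracy", tp + tn, total)
    precision = ratio("precision", tp, tp + fp)
    recall = ratio("recall", tp, tp + fn)
    specificity = ratio("specificity", tn, tn + fp)
    dsc = ratio("dsc", 2 * tp, 2 * tp + fp + fn)
    iou = ratio("iou", tp, tp + fp + fn)
    return MetricReport(tp, tn, fp, fn, accuracy, precision, recall,
                        specificity, dsc, iou, tuple(undefined))


def evaluate(pred: np.ndarray, gt: np.ndarray) -> MetricReport:
    """Evaluate a predicted mask against ground truth with all six metrics."""
    return report_from_counts(*confusion_counts(pred, gt))


def aggregate(reports: list[MetricReport]) -> dict[str, float]:
    """Unweighted per-image mean of each metric (dataset-level summary)."""
    if not reports:
        raise ValueError("no reports to aggregate")
    return {name: float(np.mean([getattr(r, name) for r in reports]))
            for name in METRIC_NAMES}


def evaluate_directory(
    pred_dir: str | Path,
    gt_dir: str | Path,
    out_csv: str | Path | None = None,
    out_json: str | Path | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Batch evaluation of (pred, gt) PNG mask pairs matched by filename.

    Returns the per-image table and the aggregate means; optionally writes
    them as CSV and JSON.
    """
    from .io import read_mask

    pred_dir, gt_dir = Path(pred_dir), Path(gt_dir)
    names = sorted(p.name for p in pred_dir.iterdir() if p.suffix.lower() == ".png")
    if not names:
        raise FileNotFoundError(f"no PNG masks found in {pred_dir}")
    rows = []
    for name in names:
        gt_path = gt_dir / name
        if not gt_path.exists():
            raise FileNotFoundError(f"no ground-truth mask for {name} in {gt_dir}")
        rep = evaluate(read_mask(pred_dir / name), read_mask(gt_path))
        rows.append({"image": name, **{k: v for k, v in rep.as_dict().items()
                                       if k != "undefined"}})
    table = pd.DataFrame(rows)
    agg = {name: float(table[name].mean()) for name in METRIC_NAMES}
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    if out_json is not None:
        Path(out_json).write_text(json.dumps(agg, indent=2))
    return table, agg
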