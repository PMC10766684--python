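"""Per-structure segmentation evaluation: DSC, precision, recall.

For each structure, A is the binarized automatic segmentation and B the
binarized ground truth:

    DSC(A, B)       = 2 |A n B| / (|A| + |B|)
    precision(A, B) = |A n B| / |A|
    recall(A, B)    = |A n B| / |B|

Empty-mask conventions (the formulas' 0/0 cases): both masks empty scores 1
on all three metrics, so a structure legitimately absent from a slice does
not poison the aggregates; such rows are flagged. An empty prediction
against a nonempty truth scores precision 1 / recall 0 and vice versa.

Aggregation mirrors per-structure reporting over test slices: mean and
sample standard deviation over slices within a structure, then the
unweighted mean of structure means as the grand score.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Sequence

import numpy as np
import pandas as pd

from .stack_io import LabelVolume

__all__ = [
    "StructureScore",
    "score_structure",
    "evaluate_volume",
    "summarize",
    "export_report",
]


@dataclasses.dataclass(frozen=True)
class StructureScore:
    structure_id: int
    dsc: float
    precision: float
    recall: float
    n_pred_px: int
    n_gt_px: int
    n_overlap_px: int


def score_structure(pred_mask: np.ndarray, gt_mask: np.ndarray,
                    structure_id: int = 0) -> StructureScore:
    """Score one binary prediction against one binary ground-truth mask."""
    pred_mask = np.asarray(pred_mask, dtype=bool)
    gt_mask = np.asarray(gt_mask, dtype=bool)
    if pred_mask.shape != gt_mask.shape:
        raise ValueError(
            f"mask shapes differ: {pred_mask.shape} vs {gt_mask.shape}")
    n_pred = int(pred_mask.sum())
    n_gt = int(gt_mask.sum())
    n_overlap = int((pred_mask & gt_mask).sum())
    dsc = 2 * n_overlap / (n_pred + n_gt) if n_pred + n_gt > 0 else 1.0
    precision = n_overlap / n_pred if n_pred > 0 else 1.0
    recall = n_overlap / n_gt if n_gt > 0 else 1.0
    return StructureScore(structure_id, dsc, precision, recall,
                          n_pred, n_gt, n_overlap)


def evaluate_volume(pred: LabelVolume, gt: LabelVolume,
                    slices: Sequence[int]) -> pd.DataFrame:
    """Per-(structure, slice) scores on the listed test slices.

    Returns a tidy frame with one row per structure and slice; rows where
    the structure is absent from both masks are flagged ``absent``.
    """
    if pred.labels.shape != gt.labels.shape:
        raise ValueError("prediction and ground-truth volumes are misaligned")
    slices = list(slices)
    if not slices:
        raise ValueError("need at least one slice to evaluate")
    rows = []
    for s in range(1, gt.scheme.c + 1):
        for z in slices:
            sc = score_structure(pred.labels[z] == s, gt.labels[z] == s, s)
            rows.append({
                "structure_id": s,
                "structure": gt.scheme.name_of(s),
                "slice": z,
                "dsc": sc.dsc,
                "precision": sc.precision,
                "recall": sc.recall,
                "n_pred_px": sc.n_pred_px,
                "n_gt_px": sc.n_gt_px,
                "n_overlap_px": sc.n_overlap_px,
                "absent": sc.n_pred_px == 0 and sc.n_gt_px == 0,
            })
    return pd.DataFrame(rows)


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-structure mean +/- sd over slices plus an overall row.

    Single-slice groups report sd = 0 (flagged via ``n_slices``); the
    overall row is the unweighted mean of the structure means.
    """
    def _sd(x: pd.Series) -> float:
        return float(x.std(ddof=1)) if len(x) > 1 else 0.0

    per = (table.groupby(["structure_id", "structure"], as_index=False)
           .agg(dsc_mean=("dsc", "mean"), dsc_sd=("dsc", _sd),
                precision_mean=("precision", "mean"), precision_sd=("precision", _sd),
                recall_mean=("recall", "mean"), recall_sd=("recall", _sd),
                n_slices=("slice", "count")))
    overall = {
        "structure_id": 0, "structure": "OVERALL",
        "dsc_mean": per["dsc_mean"].mean(),
        "dsc_sd": _sd(per["dsc_mean"]),
        "precision_mean": per["precision_mean"].mean(),
        "precision_sd": _sd(per["precision_mean"]),
        "recall_mean": per["recall_mean"].mean(),
        "recall_sd": _sd(per["recall_mean"]),
        "n_slices": int(per["n_slices"].iloc[0]) if len(per) else 0,
    }
    return pd.concat([per, pd.DataFrame([overall])], ignore_index=True)


def export_report(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """CSV report: detail rows, then a summary block, floats to 6 decimals."""
    detail = table.copy()
    detail.insert(0, "kind", "detail")
    summary = summarize(table)
    summary.insert(0, "kind", "summary")
    out = pd.concat([detail, summary], ignore_index=True)
    out.to_csv(path, index=False, float_format="%.6f")
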