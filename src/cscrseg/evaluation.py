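"""Pixelwise evaluation against ground truth and the ablation harness.

Four indicators over the binary confusion counts:

    Sensitivity = TP / (TP + FN)
    F1-score    = 2 TP / (2 TP + FN + FP)
    Accuracy    = (TP + TN) / (TP + FN + TN + FP)
    Specificity = TN / (TN + FP)

A 0/0 ratio is reported as NaN (an explicit "undefined" marker) and
excluded from averages, never raised. Metrics are counted over the ROI by
default: the full frame is dominated by true-negative background, which
inflates accuracy and specificity without saying anything about the
segmentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig, T_GRID
from .io import ImagePair, ROIBox

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion",
    "metrics",
    "evaluate_masks",
    "ablation_study",
    "summarize_ablation",
]

VARIANTS = ("LR", "LRM", "LRM_to_R", "LRM_plus_R")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FN: int
    TN: int
    FP: int

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.TN + self.FP


@dataclass(frozen=True)
class MetricReport:
    sensitivity: float
    f1_score: float
    accuracy: float
    specificity: float

    def as_dict(self) -> dict[str, float]:
        return {"sensitivity": self.sensitivity, "f1_score": self.f1_score,
                "accuracy": self.accuracy, "specificity": self.specificity}


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.dtype != bool and not np.all(np.isin(np.unique(arr), (0, 1))):
        raise ValueError(f"{name} must be binary")
    return arr.astype(bool)


def confusion(pred: np.ndarray, truth: np.ndarray,
              scope: str = "full", box: ROIBox | None = None
              ) -> ConfusionCounts:
    """Pixelwise confusion counts, over the whole frame or an ROI box."""
    pred = _check_binary(pred, "pred")
    truth = _check_binary(truth, "truth")
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    if scope == "roi":
        if box is None:
            raise ValueError("scope='roi' needs a box")
        sl = (slice(box.r0, box.r1), slice(box.c0, box.c1))
        pred, truth = pred[sl], truth[sl]
    elif scope != "full":
        raise ValueError("scope must be 'roi' or 'full'")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionCounts(TP=tp, FN=fn, TN=tn, FP=fp)


def _ratio(num: int, den: int) -> float:
    return num / den if den else math.nan


def metrics(counts: ConfusionCounts) -> MetricReport:
    """The four indicators; 0/0 cases come back as NaN, never an error."""
    c = counts
    return MetricReport(
        sensitivity=_ratio(c.TP, c.TP + c.FN),
        f1_score=_ratio(2 * c.TP, 2 * c.TP + c.FN + c.FP),
        accuracy=_ratio(c.TP + c.TN, c.total),
        specificity=_ratio(c.TN, c.TN + c.FP),
    )


def evaluate_masks(pred: np.ndarray, truth: np.ndarray,
                   scope: str = "full", box: ROIBox | None = None
                   ) -> MetricReport:
    return metrics(confusion(pred, truth, scope=scope, box=box))


def ablation_study(phantoms: list, T_grid: tuple[float, ...] = T_GRID,
                   config: RunConfig | None = None,
                   boxes: list[ROIBox] | None = None) -> pd.DataFrame:
    """Run all four variants over the threshold grid on a phantom batch.

    ``phantoms`` is a list of (ImagePair, PhantomTruth); the ROI for each
    phantom defaults to a box enclosing its blobs (the phantom analogue of
    the operator's manual selection). The decomposition stage is computed
    once per phantom and modality setting and shared across thresholds; the
    decomposition-only variants carry no T dependence, so their rows are
    identical across the grid.

    Returns a tidy DataFrame with one row per (phantom, variant, T).
    """
    from .phantom import roi_covering_blobs
    from .pipeline import threshold_grid_masks

    if not phantoms:
        raise ValueError("need at least one phantom")
    if not T_grid:
        raise ValueError("empty threshold grid")
    cfg = config or RunConfig()
    rows = []
    for i, (pair, truth) in enumerate(phantoms):
        box = boxes[i] if boxes is not None else roi_covering_blobs(
            truth, pair.shape, patch_size=cfg.patch_size)
        masks = threshold_grid_masks(pair, box, cfg, T_grid)
        for variant in VARIANTS:
            for T in T_grid:
                full_mask = masks[variant][T if variant in
                                           ("LRM_to_R", "LRM_plus_R")
                                           else None]
                rep = evaluate_masks(full_mask, truth.blob_mask,
                                     scope=cfg.metric_scope, box=box)
                rows.append({"phantom": i, "variant": variant, "T": T,
                             **rep.as_dict()})
    return pd.DataFrame(rows)


def summarize_ablation(table: pd.DataFrame) -> pd.DataFrame:
    """Mean of each indicator over phantoms, by variant and threshold.

    NaN (undefined) metrics are excluded per cell; the 'n_defined' columns
    record how many phantoms contributed to each mean.
    """
    metric_cols = ["f1_score", "sensitivity", "accuracy", "specificity"]
    grouped = table.groupby(["variant", "T"])[metric_cols]
    out = grouped.mean()                      # pandas mean skips NaN
    counts = grouped.count()
    counts.columns = [f"n_defined_{c}" for c in metric_cols]
    return out.join(counts).reset_index()
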