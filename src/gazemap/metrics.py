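"""Evaluation metrics for heatmap reconstruction and ROI segmentation.

Heatmap similarity is measured with per-pixel MSE and the structural
similarity index (SSIM); binarized heatmaps are scored with pixel-level
precision, recall, F1 and intersection-over-union; multi-class diagnosis is
scored with micro-averaged sensitivity/specificity/F1 (one-vs-rest counts
summed across classes).

SSIM follows the standard windowed form

    SSIM = mean over windows of  l^alpha * c^beta * s^gamma

with an 11x11 Gaussian window (sigma 1.5) and stabilization constants
C1=(K1*L)^2, C2=(K2*L)^2; the component exponents default to 1 and are
configurable through :class:`SsimParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .heatmap_builder import BinaryMask, Heatmap, binarize_heatmap

__all__ = [
    "SsimParams",
    "ConfusionCounts",
    "EvalReport",
    "mse",
    "ssim",
    "segmentation_scores",
    "micro_sensitivity_specificity",
    "evaluate_test_set",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = (0.4, 0.45, 0.5, 0.6, 0.7)


@dataclass(frozen=True)
class SsimParams:
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    k1: float = 0.01
    k2: float = 0.03
    data_range: float = 1.0
    win_size: int = 11
    sigma: float = 1.5

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("stabilization constants must be positive")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be nonnegative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


@dataclass
class EvalReport:
    """Per-threshold evaluation of a test set of heatmaps."""

    threshold: float
    avg_mse: float
    avg_ssim: float
    precision: float
    recall: float
    f1: float
    iou: float
    counts: ConfusionCounts
    per_case: dict[str, dict] = field(default_factory=dict)
    #: case-macro averages of the segmentation scores (pooled ones above)
    macro: dict[str, float] = field(default_factory=dict)


def _as_array(grid) -> np.ndarray:
    if isinstance(grid, Heatmap):
        return grid.values
    if isinstance(grid, BinaryMask):
        return grid.values
    return np.asarray(grid)


def mse(a, b) -> float:
    """Mean squared per-pixel difference."""
    a, b = _as_array(a).astype(np.float64), _as_array(b).astype(np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(((a - b) ** 2).mean())


def ssim(a, b, params: SsimParams = SsimParams()) -> float:
    """Structural similarity index; 1.0 for identical inputs."""
    a, b = _as_array(a).astype(np.float64), _as_array(b).astype(np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    c1 = (params.k1 * params.data_range) ** 2
    c2 = (params.k2 * params.data_range) ** 2
    c3 = c2 / 2.0

    truncate = (params.win_size - 1) / 2 / params.sigma

    def gwin(x):
        return ndimage.gaussian_filter(x, sigma=params.sigma, truncate=truncate,
                                       mode="reflect")

    mu_a, mu_b = gwin(a), gwin(b)
    var_a = np.maximum(gwin(a * a) - mu_a**2, 0.0)
    var_b = np.maximum(gwin(b * b) - mu_b**2, 0.0)
    cov = gwin(a * b) - mu_a * mu_b
    sd_a, sd_b = np.sqrt(var_a), np.sqrt(var_b)

    lum = (2 * mu_a * mu_b + c1) / (mu_a**2 + mu_b**2 + c1)
    con = (2 * sd_a * sd_b + c2) / (var_a + var_b + c2)
    struct = (cov + c3) / (sd_a * sd_b + c3)
    smap = (np.sign(lum) * np.abs(lum) ** params.alpha
            * np.sign(con) * np.abs(con) ** params.beta
            * np.sign(struct) * np.abs(struct) ** params.gamma)
    # crop the filter's edge effects, as windowed SSIM implementations do
    pad = (params.win_size - 1) // 2
    if min(smap.shape) > 2 * pad:
        smap = smap[pad:-pad, pad:-pad]
    return float(smap.mean())


def _confusion(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    pred, gt = pred.astype(bool), gt.astype(bool)
    return ConfusionCounts(
        tp=int((pred & gt).sum()),
        fp=int((pred & ~gt).sum()),
        fn=int((~pred & gt).sum()),
        tn=int((~pred & ~gt).sum()),
    )


def _scores_from_counts(c: ConfusionCounts) -> tuple[float, float, float, float]:
    if c.tp == 0 and c.fp == 0 and c.fn == 0:
        # both masks empty: perfect (vacuous) agreement
        return 1.0, 1.0, 1.0, 1.0
    precision = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    recall = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    iou = c.tp / (c.tp + c.fp + c.fn)
    return precision, recall, f1, iou


def segmentation_scores(pred: BinaryMask | np.ndarray, gt: BinaryMask | np.ndarray
                        ) -> tuple[float, float, float, float, ConfusionCounts]:
    """Pixel precision, recall, F1 (harmonic mean) and IoU of two binary masks."""
    p, g = _as_array(pred), _as_array(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {g.shape}")
    counts = _confusion(p, g)
    return (*_scores_from_counts(counts), counts)


def micro_sensitivity_specificity(
    per_class_counts: Sequence[ConfusionCounts],
) -> tuple[float, float, float]:
    """Micro-average one-vs-rest counts across classes.

    Returns (sensitivity, specificity, micro F1).  Sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP), computed on the summed counts.
    """
    if len(per_class_counts) < 2:
        raise ValueError("need counts for at least 2 classes")
    total = ConfusionCounts()
    for c in per_class_counts:
        total = total + c
    sens = total.tp / (total.tp + total.fn) if total.tp + total.fn else 0.0
    spec = total.tn / (total.tn + total.fp) if total.tn + total.fp else 0.0
    precision = total.tp / (total.tp + total.fp) if total.tp + total.fp else 0.0
    f1 = 2 * precision * sens / (precision + sens) if precision + sens else 0.0
    return sens, spec, f1


def confusion_counts_from_labels(
    true: Sequence[int], pred: Sequence[int], classes: Sequence[int]
) -> list[ConfusionCounts]:
    """One-vs-rest confusion counts per class for label vectors."""
    true = np.asarray(true)
    pred = np.asarray(pred)
    out = []
    for cls in classes:
        t, p = true == cls, pred == cls
        out.append(_confusion(p, t))
    return out


def evaluate_test_set(
    pred_heatmaps: Mapping[str, Heatmap | np.ndarray],
    gt_heatmaps: Mapping[str, Heatmap | np.ndarray],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    ssim_params: SsimParams = SsimParams(),
) -> dict[float, EvalReport]:
    """Evaluate predicted against ground-truth heatmaps, per threshold.

    MSE and SSIM are averaged over cases; precision/recall/F1/IoU are
    computed from pixel counts pooled over all cases (case-macro averages
    are reported alongside).
    """
    if set(pred_heatmaps) != set(gt_heatmaps):
        raise ValueError("prediction and ground-truth case sets differ")
    case_ids = sorted(pred_heatmaps)
    if not case_ids:
        raise ValueError("no cases to evaluate")
    mses = {cid: mse(pred_heatmaps[cid], gt_heatmaps[cid]) for cid in case_ids}
    ssims = {cid: ssim(pred_heatmaps[cid], gt_heatmaps[cid], ssim_params) for cid in case_ids}

    reports: dict[float, EvalReport] = {}
    for thr in thresholds:
        pooled = ConfusionCounts()
        per_case: dict[str, dict] = {}
        macro_acc = np.zeros(4)
        for cid in case_ids:
            pm = binarize_heatmap(_as_array(pred_heatmaps[cid]), thr)
            gm = binarize_heatmap(_as_array(gt_heatmaps[cid]), thr)
            p, r, f1, iou, counts = segmentation_scores(pm, gm)
            pooled = pooled + counts
            macro_acc += (p, r, f1, iou)
            per_case[cid] = {
                "mse": mses[cid], "ssim": ssims[cid],
                "precision": p, "recall": r, "f1": f1, "iou": iou,
            }
        p, r, f1, iou = _scores_from_counts(pooled)
        macro = macro_acc / len(case_ids)
        reports[thr] = EvalReport(
            threshold=thr,
            avg_mse=float(np.mean([mses[c] for c in case_ids])),
            avg_ssim=float(np.mean([ssims[c] for c in case_ids])),
            precision=p, recall=r, f1=f1, iou=iou,
            counts=pooled,
            per_case=per_case,
            macro={"precision": macro[0], "recall": macro[1],
                   "f1": macro[2], "iou": macro[3]},
        )
    return reports
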