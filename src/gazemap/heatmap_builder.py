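"""Duration-weighted viewing heatmaps.

For each case, the dwell durations of all viewing ROIs from every qualifying
interpretation (those within one diagnostic class of the consensus) are
accumulated per pixel and the result is divided by its maximum, giving a
grid in [0, 1] where 1 marks the most-viewed pixel.  These heatmaps serve
as regression targets: brighter means longer viewed, hence more important
to the diagnosis.

Accumulation is O(#ROIs) using a 2-D difference array (summed-area trick)
rather than per-pixel rasterization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .roi_extraction import ViewingROI
from .viewport_log import Interpretation

__all__ = [
    "Heatmap",
    "BinaryMask",
    "select_interpretations",
    "build_case_heatmap",
    "binarize_heatmap",
    "save_heatmap_png16",
    "load_heatmap_png16",
    "save_mask_png",
    "load_mask_png",
]


@dataclass
class Heatmap:
    """A [0,1] float grid on the 10x reference frame (rows=y, cols=x)."""

    values: np.ndarray
    case_id: str = ""
    magnification: float = 10.0
    #: True when no ROI with positive duration contributed (all-zero grid).
    empty: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("heatmap values must be a 2-D grid")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("heatmap values must lie in [0, 1]")

    @property
    def frame(self) -> tuple[int, int]:
        """(width, height) of the reference frame."""
        h, w = self.values.shape
        return (w, h)


@dataclass
class BinaryMask:
    values: np.ndarray
    threshold_used: float = 0.5

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("mask values must be 0/1")
        self.values = self.values.astype(np.uint8)


def select_interpretations(
    interps: Iterable[Interpretation], consensus_class: int, max_error: int = 1
) -> list[Interpretation]:
    """Keep interpretations within ``max_error`` classes of the consensus.

    Restricting the heatmap to near-accurate readings suppresses viewing
    behavior from misdiagnoses, which tends to dwell on distracting regions.
    """
    return [
        it
        for it in interps
        if it.diagnosis_class is not None
        and abs(it.diagnosis_class - consensus_class) <= max_error
    ]


def _accumulate_rects(
    rects: Sequence[tuple[int, int, int, int]],
    weights: Sequence[float],
    frame: tuple[int, int],
) -> np.ndarray:
    """Sum weight over each half-open rect via a difference array."""
    width, height = frame
    diff = np.zeros((height + 1, width + 1), dtype=np.float64)
    for (x, y, w, h), wt in zip(rects, weights):
        x0, y0 = max(x, 0), max(y, 0)
        x1, y1 = min(x + w, width), min(y + h, height)
        if x1 <= x0 or y1 <= y0:
            continue
        diff[y0, x0] += wt
        diff[y0, x1] -= wt
        diff[y1, x0] -= wt
        diff[y1, x1] += wt
    acc = diff.cumsum(axis=0).cumsum(axis=1)[:height, :width]
    # cancellation in the cumsums leaves ~1e-13 residue where the true sum is 0
    return np.clip(acc, 0.0, None)


def build_case_heatmap(
    rois_by_interpretation: Mapping[str, Sequence[ViewingROI]] | Sequence[Sequence[ViewingROI]],
    frame: tuple[int, int],
    case_id: str = "",
    downscale: int = 1,
) -> Heatmap:
    """Accumulate ROI dwell durations per pixel and max-normalize.

    Parameters
    ----------
    rois_by_interpretation
        Viewing ROIs of each qualifying interpretation (mapping keyed by
        pathologist, or a plain sequence of ROI lists).
    frame
        (width, height) of the 10x reference frame.
    downscale
        Integer factor for building the map on a coarser grid; ROI
        coordinates are divided accordingly.

    Returns the all-zero heatmap with ``empty=True`` when no ROI has
    positive duration.
    """
    if isinstance(rois_by_interpretation, Mapping):
        roi_lists: Iterable[Sequence[ViewingROI]] = rois_by_interpretation.values()
    else:
        roi_lists = rois_by_interpretation
    rects, weights = [], []
    for rois in roi_lists:
        for roi in rois:
            if case_id and roi.case_id and roi.case_id != case_id:
                raise ValueError(
                    f"ROI case_id {roi.case_id!r} does not match heatmap case {case_id!r}"
                )
            x, y, w, h = roi.rect
            if downscale > 1:
                x, y = x // downscale, y // downscale
                w, h = max(1, round(w / downscale)), max(1, round(h / downscale))
            rects.append((x, y, w, h))
            weights.append(roi.duration)

    grid_frame = (frame[0] // downscale, frame[1] // downscale) if downscale > 1 else frame
    raw = _accumulate_rects(rects, weights, grid_frame)
    peak = raw.max() if raw.size else 0.0
    if peak <= 0:
        return Heatmap(np.zeros(grid_frame[::-1]), case_id=case_id, empty=True)
    return Heatmap(raw / peak, case_id=case_id)


def binarize_heatmap(hm: Heatmap | np.ndarray, threshold: float = 0.5) -> BinaryMask:
    """Threshold a heatmap: strictly above -> ROI (1), at or below -> 0."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    values = hm.values if isinstance(hm, Heatmap) else np.asarray(hm)
    return BinaryMask((values > threshold).astype(np.uint8), threshold_used=threshold)


# ---------------------------------------------------------------------------
# persistence: 16-bit grayscale PNG for heatmaps, 8-bit {0,255} PNG for masks

def save_heatmap_png16(hm: Heatmap, path: str | Path) -> None:
    from PIL import Image

    arr = np.round(hm.values * 65535).astype(np.uint16)
    Image.fromarray(arr).save(str(path))


def load_heatmap_png16(path: str | Path, case_id: str = "") -> Heatmap:
    from PIL import Image

    arr = np.asarray(Image.open(str(path)), dtype=np.float64) / 65535.0
    return Heatmap(arr, case_id=case_id)


def save_mask_png(mask: BinaryMask, path: str | Path) -> None:
    from PIL import Image

    Image.fromarray(mask.values * np.uint8(255), mode="L").save(str(path))


def load_mask_png(path: str | Path, threshold_used: float = 0.5) -> BinaryMask:
    from PIL import Image

    arr = np.asarray(Image.open(str(path)))
    return BinaryMask((arr > 127).astype(np.uint8), threshold_used=threshold_used)
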