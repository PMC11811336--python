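"""Viewing-behavior detection: zoom peaks, slow pannings, and fixations.

Three viewing behaviors mark a viewport as diagnostically interesting:

* **zoom peak** — the magnification strictly exceeds both neighbours: the
  pathologist intentionally zoomed in to look closer.
* **slow panning** — the magnification is unchanged from the previous entry
  and the viewport center moved less than ``panning_max_displacement`` pixels:
  local exploration of a slightly larger area.
* **fixation** — the dwell duration exceeds ``fixation_min_s`` (entries longer
  than ``fixation_max_s`` are discarded as inactive time).

Only viewports at magnification strictly above ``min_zoom`` yield viewing
ROIs, which keeps the extracted regions small enough to be informative.
All threshold comparisons are strict.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .viewport_log import Interpretation, ViewportRecord

__all__ = [
    "Behavior",
    "BehaviorConfig",
    "ViewingROI",
    "detect_zoom_peaks",
    "detect_slow_pannings",
    "detect_fixations",
    "extract_viewing_rois",
    "write_roi_csv",
    "read_roi_csv",
]

ROI_CSV_HEADER = [
    "case_id", "pathologist_id", "behavior", "x", "y",
    "width", "height", "duration_s", "source_index",
]

#: zoom values are rounded to this many decimals before equality comparison;
#: logged zoom levels are discrete viewer states, not free floats.
ZOOM_DECIMALS = 3


class Behavior(str, Enum):
    zoom_peak = "zoom_peak"
    slow_panning = "slow_panning"
    fixation = "fixation"


@dataclass(frozen=True)
class BehaviorConfig:
    """Thresholds of the three behavior detectors (reference-frame pixels, seconds)."""

    panning_max_displacement: float = 100.0
    fixation_min_s: float = 2.0
    fixation_max_s: float = 60.0
    min_zoom: float = 5.0

    def __post_init__(self) -> None:
        if min(self.panning_max_displacement, self.fixation_min_s,
               self.fixation_max_s, self.min_zoom) <= 0:
            raise ValueError("all thresholds must be positive")
        if self.fixation_min_s >= self.fixation_max_s:
            raise ValueError("fixation_min_s must be < fixation_max_s")


@dataclass(frozen=True)
class ViewingROI:
    """A behavior-flagged viewport: the unit that accumulates into heatmaps."""

    rect: tuple[int, int, int, int]  # (x, y, w, h), half-open, clipped to frame
    behavior: Behavior
    duration: float
    source_index: int
    pathologist_id: str = ""
    case_id: str = ""

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("duration must be >= 0")


def _round_zoom(z: float) -> float:
    return round(z, ZOOM_DECIMALS)


def detect_zoom_peaks(records: Sequence[ViewportRecord]) -> list[int]:
    """Indices whose zoom strictly exceeds both neighbours (endpoints never qualify)."""
    return [
        i
        for i in range(1, len(records) - 1)
        if records[i].zoom > records[i - 1].zoom and records[i].zoom > records[i + 1].zoom
    ]


def detect_slow_pannings(
    records: Sequence[ViewportRecord], config: BehaviorConfig = BehaviorConfig()
) -> list[int]:
    """Indices i>=1 with zoom unchanged and center displacement < threshold."""
    out = []
    for i in range(1, len(records)):
        if _round_zoom(records[i].zoom) != _round_zoom(records[i - 1].zoom):
            continue
        (cx0, cy0), (cx1, cy1) = records[i - 1].center, records[i].center
        if math.hypot(cx1 - cx0, cy1 - cy0) < config.panning_max_displacement:
            out.append(i)
    return out


def detect_fixations(
    records: Sequence[ViewportRecord], config: BehaviorConfig = BehaviorConfig()
) -> list[int]:
    """Indices dwelled on longer than ``fixation_min_s`` and at most ``fixation_max_s``."""
    return [
        i
        for i, r in enumerate(records)
        if config.fixation_min_s < r.duration <= config.fixation_max_s
    ]


def _clip_rect(rect: tuple[int, int, int, int],
               frame: tuple[int, int] | None) -> tuple[int, int, int, int] | None:
    if frame is None:
        return rect
    x, y, w, h = rect
    fw, fh = frame
    x0, y0 = max(x, 0), max(y, 0)
    x1, y1 = min(x + w, fw), min(y + h, fh)
    if x1 <= x0 or y1 <= y0:
        return None
    return (x0, y0, x1 - x0, y1 - y0)


def extract_viewing_rois(
    interp: Interpretation,
    config: BehaviorConfig = BehaviorConfig(),
    frame: tuple[int, int] | None = None,
) -> list[ViewingROI]:
    """Union of the three behavior detectors, restricted to zoom > ``min_zoom``.

    An entry flagged by k behaviors yields k ROIs with distinct behavior tags;
    de-duplication of overlapping regions is the heatmap builder's concern.
    ``frame`` (width, height) clips the rects; ROIs entirely off-frame are
    dropped.
    """
    records = interp.records
    if not records:
        return []
    flagged: list[tuple[int, Behavior]] = []
    flagged += [(i, Behavior.zoom_peak) for i in detect_zoom_peaks(records)]
    flagged += [(i, Behavior.slow_panning) for i in detect_slow_pannings(records, config)]
    flagged += [(i, Behavior.fixation) for i in detect_fixations(records, config)]

    rois = []
    for i, behavior in sorted(flagged, key=lambda t: (t[0], t[1].value)):
        rec = records[i]
        if not rec.zoom > config.min_zoom:
            continue
        rect = _clip_rect(rec.rect, frame)
        if rect is None:
            continue
        rois.append(
            ViewingROI(
                rect=rect,
                behavior=behavior,
                duration=rec.duration,
                source_index=i,
                pathologist_id=interp.pathologist_id,
                case_id=interp.case_id,
            )
        )
    return rois


def write_roi_csv(rois: Iterable[ViewingROI]) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(ROI_CSV_HEADER)
    for r in rois:
        x, y, w, h = r.rect
        writer.writerow(
            [r.case_id, r.pathologist_id, r.behavior.value, x, y, w, h,
             repr(r.duration), r.source_index]
        )
    return buf.getvalue()


def read_roi_csv(stream: io.TextIOBase | str) -> list[ViewingROI]:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out = []
    for row in csv.DictReader(stream):
        out.append(
            ViewingROI(
                rect=(int(row["x"]), int(row["y"]), int(row["width"]), int(row["height"])),
                behavior=Behavior(row["behavior"]),
                duration=float(row["duration_s"]),
                source_index=int(row["source_index"]),
                pathologist_id=row["pathologist_id"],
                case_id=row["case_id"],
            )
        )
    return out
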