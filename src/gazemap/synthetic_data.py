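"""Synthetic slides and simulated viewing sessions.

Real viewport-tracking cohorts of pathologists are essentially never public,
so this module fabricates a complete testbed: H&E-looking slides (white
glass, one elliptical pink tissue blob, darker high-frequency lesion
ellipses inside it) together with per-pathologist viewing sessions scripted
to contain the three detectable behaviors — a low-zoom scan, then for each
visited lesion a high-zoom approach dwell (fixation), a deeper zoom peek
(zoom peak) and one or more small same-zoom moves (slow pannings).

Every planted behavior is recoverable by the extraction rules by
construction, and the generator returns its plan, so detector recall and
heatmap placement can be verified against exact ground truth.  Everything
is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .heatmap_builder import BinaryMask
from .roi_extraction import Behavior
from .slide_tiling import SlideImage, write_slide
from .viewport_log import (
    CaseMeta,
    Interpretation,
    ViewportRecord,
    assign_durations,
    serialize_viewport_log,
    write_case_table,
    write_interpretation_table,
)

__all__ = [
    "SyntheticCase",
    "SessionProfile",
    "SessionPlan",
    "VIEWER_BASE_PX",
    "generate_slide",
    "plan_session",
    "simulate_viewing_session",
    "generate_cohort",
]

#: reference-frame extent of the viewer screen at 1x; a viewport at zoom z
#: covers VIEWER_BASE_PX / z pixels per side.
VIEWER_BASE_PX = 768.0

TISSUE_RGB = np.array([231, 177, 203], dtype=np.float64)  # eosin pink
LESION_RGB = np.array([126, 87, 156], dtype=np.float64)   # hematoxylin purple


@dataclass
class SyntheticCase:
    slide: SlideImage
    tissue_mask: BinaryMask
    lesion_mask: BinaryMask
    lesion_centers: list[tuple[float, float]]
    consensus_class: int
    seed: int

    @property
    def case_id(self) -> str:
        return self.slide.case_id


@dataclass(frozen=True)
class SessionProfile:
    """Knobs of the scripted viewing behavior."""

    n_lesion_visits: int | None = None  # None = visit every lesion
    dwell_s: tuple[float, float] = (3.0, 10.0)
    scan_zoom: tuple[float, float] = (2.0, 4.0)
    inspect_zoom: tuple[float, float] = (8.0, 20.0)
    pan_step_px: tuple[float, float] = (15.0, 60.0)
    n_pans: int = 1
    distractor_visit_prob: float = 0.0
    diagnosis_error_prob: float = 0.2

    def __post_init__(self) -> None:
        if self.inspect_zoom[0] <= 5.0:
            raise ValueError("inspect_zoom must stay above the 5x viewing-ROI cutoff")
        if not (2.0 < self.dwell_s[0] <= self.dwell_s[1] < 60.0):
            raise ValueError("dwell_s must lie within the (2, 60) s fixation band")


@dataclass
class SessionPlan:
    """A simulated session plus its ground truth."""

    interpretation: Interpretation
    #: (record index, behavior) pairs planted at zoom > 5x
    planted: list[tuple[int, Behavior]] = field(default_factory=list)
    visited_lesions: list[int] = field(default_factory=list)
    distractor_indices: list[int] = field(default_factory=list)


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  axes: tuple[float, float], angle: float) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[:h, :w]
    ca, sa = np.cos(angle), np.sin(angle)
    dx, dy = xx - center[0], yy - center[1]
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def generate_slide(width: int = 384, height: int = 384, n_lesions: int = 2,
                   seed: int = 0, case_id: str = "", n_distractors: int = 0) -> SyntheticCase:
    """Fabricate one slide with exact tissue and lesion masks.

    White background; one rotated elliptical tissue blob with smooth pink
    texture noise; ``n_lesions`` darker purple ellipses with high-frequency
    texture planted fully inside the tissue.  ``n_distractors`` additional
    blobs with the same visual signature are placed but excluded from the
    lesion mask — regions that look suspicious yet carry no diagnostic
    weight, which only the viewing heatmap can rule out.  Raises when the
    requested regions cannot be placed.
    """
    if width < 256 or height < 256:
        raise ValueError("slide dimensions must be at least 256")
    if n_lesions < 0:
        raise ValueError("n_lesions must be >= 0")
    rng = np.random.default_rng(seed)
    shape = (height, width)

    center = (width / 2 + rng.uniform(-0.05, 0.05) * width,
              height / 2 + rng.uniform(-0.05, 0.05) * height)
    axes = (rng.uniform(0.36, 0.44) * width, rng.uniform(0.30, 0.40) * height)
    angle = rng.uniform(0, np.pi)
    tissue = _ellipse_mask(shape, center, axes, angle)

    from scipy.ndimage import gaussian_filter

    img = np.full((height, width, 3), 255.0)
    smooth_noise = gaussian_filter(rng.normal(0, 1, (height, width, 3)), (3, 3, 0)) * 28
    img[tissue] = np.clip(TISSUE_RGB + smooth_noise, 0, 255)[tissue]

    lesion = np.zeros(shape, dtype=bool)
    occupied = np.zeros(shape, dtype=bool)
    centers: list[tuple[float, float]] = []
    min_r = min(width, height) * 0.06
    max_r = min(width, height) * 0.11
    attempts = 0
    placed_distractors = 0
    while len(centers) < n_lesions or placed_distractors < n_distractors:
        attempts += 1
        if attempts > 600:
            raise ValueError(
                f"could not place {n_lesions} lesions + {n_distractors} distractors"
            )
        is_lesion = len(centers) < n_lesions
        r1, r2 = rng.uniform(min_r, max_r, size=2)
        ang = rng.uniform(0, np.pi)
        cx = rng.uniform(r1, width - r1)
        cy = rng.uniform(r1, height - r1)
        cand = _ellipse_mask(shape, (cx, cy), (r1, r2), ang)
        # blobs must sit fully in tissue and keep clear of each other
        if not (cand & ~tissue).any() and not (cand & occupied).any() and cand.any():
            sharp_noise = rng.normal(0, 1, (height, width, 3)) * 26
            img[cand] = np.clip(LESION_RGB + sharp_noise, 0, 255)[cand]
            occupied |= cand
            if is_lesion:
                lesion |= cand
                centers.append((cx, cy))
            else:
                placed_distractors += 1

    slide = SlideImage(np.round(img).astype(np.uint8), case_id=case_id or f"case{seed:04d}")
    return SyntheticCase(
        slide=slide,
        tissue_mask=BinaryMask(tissue.astype(np.uint8)),
        lesion_mask=BinaryMask(lesion.astype(np.uint8)),
        lesion_centers=centers,
        consensus_class=1,
        seed=seed,
    )


def _viewport_at(cx: float, cy: float, zoom: float,
                 frame: tuple[int, int]) -> tuple[int, int, int, int]:
    extent = max(8, int(round(VIEWER_BASE_PX / zoom)))
    x = int(round(cx - extent / 2))
    y = int(round(cy - extent / 2))
    return (x, y, extent, extent)


def plan_session(case: SyntheticCase, profile: SessionProfile = SessionProfile(),
                 seed: int = 0, pathologist_id: str = "P0") -> SessionPlan:
    """Script a session and report exactly which entries carry which behavior."""
    rng = np.random.default_rng(seed)
    frame = case.slide.frame
    width, height = frame

    entries: list[tuple[float, float, float, float]] = []  # (cx, cy, zoom, dwell)
    planted: list[tuple[int, Behavior]] = []
    distractor_indices: list[int] = []

    scan_zoom = round(float(rng.uniform(*profile.scan_zoom)), 1)
    n_scan = int(rng.integers(3, 6))
    for _ in range(n_scan):
        cx = rng.uniform(0.2, 0.8) * width
        cy = rng.uniform(0.2, 0.8) * height
        entries.append((cx, cy, scan_zoom, float(rng.uniform(0.4, 1.5))))

    n_lesions = len(case.lesion_centers)
    if profile.n_lesion_visits is None:
        visited = list(range(n_lesions))
    else:
        visited = list(rng.permutation(n_lesions)[: profile.n_lesion_visits])

    def _dwell() -> float:
        return float(rng.uniform(*profile.dwell_s))

    def _visit(cx: float, cy: float, distractor: bool) -> None:
        z1 = round(float(rng.uniform(*profile.inspect_zoom)), 1)
        z2 = round(min(z1 * 1.5, 60.0), 1)
        jx, jy = rng.uniform(-8, 8, size=2)
        i0 = len(entries)
        # approach: high-zoom dwell on the target -> fixation
        entries.append((cx + jx, cy + jy, z1, _dwell()))
        planted.append((i0, Behavior.fixation))
        # peek: strictly higher zoom than both neighbours -> zoom peak
        entries.append((cx, cy, z2, float(rng.uniform(0.5, 1.5))))
        planted.append((i0 + 1, Behavior.zoom_peak))
        # return to z1, then small same-zoom moves -> slow pannings (and
        # fixations, since they dwell)
        px, py = cx + jx, cy + jy
        entries.append((px, py, z1, _dwell()))
        planted.append((i0 + 2, Behavior.fixation))
        for p in range(profile.n_pans):
            step = rng.uniform(*profile.pan_step_px)
            theta = rng.uniform(0, 2 * np.pi)
            px = float(np.clip(px + step * np.cos(theta), 0, width))
            py = float(np.clip(py + step * np.sin(theta), 0, height))
            idx = len(entries)
            entries.append((px, py, z1, _dwell()))
            planted.append((idx, Behavior.slow_panning))
            planted.append((idx, Behavior.fixation))
        if distractor:
            distractor_indices.extend(range(i0, len(entries)))

    for li in visited:
        cx, cy = case.lesion_centers[li]
        _visit(cx, cy, distractor=False)

    if rng.random() < profile.distractor_visit_prob:
        # dwell somewhere on tissue away from every lesion
        ys, xs = np.nonzero(case.tissue_mask.values & ~case.lesion_mask.values.astype(bool))
        if len(xs):
            j = int(rng.integers(len(xs)))
            _visit(float(xs[j]), float(ys[j]), distractor=True)

    # zoom back out; final entry gets duration 0 (no successor)
    entries.append((width / 2, height / 2, scan_zoom, 0.0))

    t = 0.0
    records = []
    for cx, cy, zoom, dwell in entries:
        x, y, w, h = _viewport_at(cx, cy, zoom, frame)
        records.append(ViewportRecord(x=x, y=y, width=w, height=h, zoom=zoom, timestamp=t))
        t += max(dwell, 1e-3)
    records = assign_durations(records)

    diagnosis = case.consensus_class
    if rng.random() < profile.diagnosis_error_prob:
        options = [c for c in (diagnosis - 1, diagnosis + 1) if 1 <= c <= 4]
        diagnosis = int(rng.choice(options))

    interp = Interpretation(
        case_id=case.case_id,
        pathologist_id=pathologist_id,
        records=records,
        diagnosis_class=diagnosis,
    )
    return SessionPlan(
        interpretation=interp,
        planted=planted,
        visited_lesions=visited,
        distractor_indices=distractor_indices,
    )


def simulate_viewing_session(case: SyntheticCase,
                             profile: SessionProfile = SessionProfile(),
                             seed: int = 0,
                             pathologist_id: str = "P0") -> Interpretation:
    return plan_session(case, profile, seed, pathologist_id).interpretation


def generate_cohort(
    n_cases: int,
    pathologists_per_case: int = 5,
    profile: SessionProfile = SessionProfile(),
    seed: int = 0,
    width: int = 384,
    height: int = 384,
    lesions_per_case: tuple[int, int] = (1, 3),
    class_from_lesions: bool = False,
    distractors_per_case: tuple[int, int] = (0, 0),
    out_dir: str | Path | None = None,
) -> tuple[list[SyntheticCase], list[SessionPlan], list[CaseMeta]]:
    """Generate a multi-case, multi-pathologist synthetic study.

    Consensus classes are drawn near-uniformly over 1..4 (or, with
    ``class_from_lesions``, set to the lesion count so that diagnosis is
    learnable from the image).  When ``out_dir`` is given, the viewport-log
    CSV, interpretation table, case table and slide PNGs are written in the
    package's standard dialects.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    rng = np.random.default_rng(seed)
    classes = [1 + i % 4 for i in range(n_cases)]
    rng.shuffle(classes)

    cases: list[SyntheticCase] = []
    plans: list[SessionPlan] = []
    metas: list[CaseMeta] = []
    for i in range(n_cases):
        case_seed = int(rng.integers(0, 2**31 - 1))
        if class_from_lesions:
            n_lesions = classes[i]
        else:
            n_lesions = int(rng.integers(lesions_per_case[0], lesions_per_case[1] + 1))
        n_distr = int(rng.integers(distractors_per_case[0], distractors_per_case[1] + 1))
        case = generate_slide(width, height, n_lesions, seed=case_seed,
                              case_id=f"case{i:03d}", n_distractors=n_distr)
        case.consensus_class = classes[i]
        cases.append(case)
        for p in range(pathologists_per_case):
            sess_seed = int(rng.integers(0, 2**31 - 1))
            plans.append(plan_session(case, profile, seed=sess_seed,
                                      pathologist_id=f"P{p:02d}"))
        metas.append(
            CaseMeta(
                case_id=case.case_id,
                consensus_class=classes[i],
                slide_path=f"slides/{case.case_id}.png",
                frame_width=width,
                frame_height=height,
            )
        )

    if out_dir is not None:
        out = Path(out_dir)
        (out / "slides").mkdir(parents=True, exist_ok=True)
        for case in cases:
            write_slide(case.slide, out / "slides" / f"{case.case_id}.png")
        interps = [p.interpretation for p in plans]
        (out / "viewport_log.csv").write_text(serialize_viewport_log(interps))
        (out / "cases.csv").write_text(write_case_table(metas))
        (out / "interpretations.csv").write_text(write_interpretation_table(interps))
    return cases, plans, metas
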