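"""Slide reading, tissue filtering, patch extraction, splits, and stitching.

Slides are analyzed at the 10x reference frame and cut into non-overlapping
square patches anchored at (0, 0); trailing partial patches are dropped so
every patch has the full size.  Patches whose tissue fraction is below a
cutoff are discarded — viewport rectangles inevitably include white
background, and training on empty glass wastes capacity.

Case-level stratified splitting keeps every patch of a case in one split,
preventing leakage of near-duplicate texture between train and test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .heatmap_builder import BinaryMask, Heatmap
from .viewport_log import CaseMeta

__all__ = [
    "SlideImage",
    "PatchPair",
    "DatasetSplit",
    "read_slide",
    "write_slide",
    "compute_tissue_mask",
    "tile_case",
    "split_cases",
    "stitch_patches",
]


@dataclass
class SlideImage:
    """RGB pixel grid (H, W, 3) uint8 at the 10x reference frame."""

    pixels: np.ndarray
    case_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("slide must be an (H, W, 3) RGB grid")

    @property
    def frame(self) -> tuple[int, int]:
        h, w = self.pixels.shape[:2]
        return (w, h)


@dataclass(frozen=True)
class PatchPair:
    """Aligned (image patch, heatmap patch) cut from the same slide window."""

    image: np.ndarray  # (p, p, 3) uint8
    target: np.ndarray  # (p, p) float in [0, 1]
    origin: tuple[int, int]  # (x, y) reference-frame px
    case_id: str = ""


@dataclass
class DatasetSplit:
    train: set[str] = field(default_factory=set)
    val: set[str] = field(default_factory=set)
    test: set[str] = field(default_factory=set)

    def split_of(self, case_id: str) -> str:
        for name in ("train", "val", "test"):
            if case_id in getattr(self, name):
                return name
        raise KeyError(case_id)


def read_slide(path: str | Path, case_id: str = "") -> SlideImage:
    """Read an RGB slide from TIFF (first/base level) or PNG."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(str(path))
    else:
        from PIL import Image

        arr = np.asarray(Image.open(str(path)).convert("RGB"))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return SlideImage(arr[..., :3].astype(np.uint8), case_id=case_id or path.stem)


def write_slide(slide: SlideImage, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(str(path), slide.pixels, photometric="rgb")
    else:
        from PIL import Image

        Image.fromarray(slide.pixels).save(str(path))


def compute_tissue_mask(
    slide: SlideImage | np.ndarray,
    sat_threshold: float = 0.07,
    val_threshold: float = 0.95,
    smooth: int = 5,
) -> BinaryMask:
    """Tissue = saturated, non-white pixels; background = bright glass.

    Pixels with HSV saturation > ``sat_threshold`` and value < ``val_threshold``
    count as tissue, followed by ``smooth`` x ``smooth`` majority smoothing to
    remove speckle.
    """
    from skimage.color import rgb2hsv

    pixels = slide.pixels if isinstance(slide, SlideImage) else np.asarray(slide)
    hsv = rgb2hsv(pixels)
    raw = (hsv[..., 1] > sat_threshold) & (hsv[..., 2] < val_threshold)
    if smooth > 1:
        frac = ndimage.uniform_filter(raw.astype(np.float64), size=smooth)
        raw = frac > 0.5
    return BinaryMask(raw.astype(np.uint8))


def tile_case(
    slide: SlideImage,
    heatmap: Heatmap,
    patch_size: int = 256,
    min_tissue_frac: float = 0.05,
    tissue_mask: BinaryMask | None = None,
) -> list[PatchPair]:
    """Cut aligned image/heatmap patches on the non-overlapping grid.

    The grid is anchored at (0, 0); partial border patches are dropped.
    Patches whose tissue fraction is below ``min_tissue_frac`` are excluded
    (pass 0 to keep everything).
    """
    if slide.frame != heatmap.frame:
        raise ValueError(f"slide frame {slide.frame} != heatmap frame {heatmap.frame}")
    if tissue_mask is None and min_tissue_frac > 0:
        tissue_mask = compute_tissue_mask(slide)
    h, w = slide.pixels.shape[:2]
    pairs = []
    for y in range(0, h - patch_size + 1, patch_size):
        for x in range(0, w - patch_size + 1, patch_size):
            if min_tissue_frac > 0:
                frac = tissue_mask.values[y : y + patch_size, x : x + patch_size].mean()
                if frac < min_tissue_frac:
                    continue
            pairs.append(
                PatchPair(
                    image=slide.pixels[y : y + patch_size, x : x + patch_size].copy(),
                    target=heatmap.values[y : y + patch_size, x : x + patch_size].copy(),
                    origin=(x, y),
                    case_id=slide.case_id,
                )
            )
    return pairs


def split_cases(
    cases: Sequence[CaseMeta],
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> DatasetSplit:
    """Stratified case-level 60/20/20 split by consensus class.

    Per class of size n: ``n_val = round(r_val*n)``, ``n_test = round(r_test*n)``,
    remainder to train.  Classes with fewer than 3 cases go entirely to train.
    Deterministic for a given seed.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    split = DatasetSplit()
    by_class: dict[int, list[str]] = {}
    for c in cases:
        by_class.setdefault(c.consensus_class, []).append(c.case_id)
    for cls in sorted(by_class):
        ids = sorted(by_class[cls])
        n = len(ids)
        if n < 3:
            import warnings

            warnings.warn(f"class {cls} has only {n} case(s); assigning all to train")
            split.train.update(ids)
            continue
        n_val = int(round(ratios[1] * n))
        n_test = int(round(ratios[2] * n))
        order = rng.permutation(n)
        ids = [ids[i] for i in order]
        split.val.update(ids[:n_val])
        split.test.update(ids[n_val : n_val + n_test])
        split.train.update(ids[n_val + n_test :])
    return split


def stitch_patches(
    patch_grids: Iterable[np.ndarray],
    origins: Iterable[tuple[int, int]],
    frame: tuple[int, int],
    case_id: str = "",
) -> Heatmap:
    """Paint patch predictions back onto the slide frame; uncovered pixels are 0."""
    width, height = frame
    out = np.zeros((height, width), dtype=np.float64)
    covered = np.zeros((height, width), dtype=bool)
    for patch, (x, y) in zip(patch_grids, origins):
        patch = np.asarray(patch)
        ph, pw = patch.shape
        if x < 0 or y < 0 or x + pw > width or y + ph > height:
            raise ValueError(f"patch at {(x, y)} exceeds frame {frame}")
        if covered[y : y + ph, x : x + pw].any():
            raise ValueError(f"overlapping patch origin {(x, y)}")
        out[y : y + ph, x : x + pw] = patch
        covered[y : y + ph, x : x + pw] = True
    return Heatmap(np.clip(out, 0.0, 1.0), case_id=case_id)
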