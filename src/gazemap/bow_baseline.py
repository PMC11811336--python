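"""Bag-of-visual-words ROI detection baseline.

The hand-crafted baseline against which the encoder-decoder models are
compared.  A sliding window cuts the slide into overlapping square *bags*
(default 1024 px, stride 512); each bag splits into an 8x8 grid of
non-overlapping *words* (default 128 px).  Every word is described by a Lab
color histogram (8 bins per channel) concatenated with a uniform
local-binary-pattern texture histogram (radius 1, 8 neighbours, 10 bins),
each block L1-normalized.  K-means (k=40) over all training words yields a
codebook; each bag becomes the frequency histogram of its words' cluster
assignments, a random forest classifies bags as ROI / non-ROI, and the
per-bag ROI probabilities are painted back onto the slide (averaged where
bags overlap) to form a heatmap comparable with the deep models'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .heatmap_builder import Heatmap
from .roi_extraction import ViewingROI
from .slide_tiling import SlideImage

__all__ = [
    "BagConfig",
    "Bag",
    "Codebook",
    "BowModel",
    "DESK_SCALE_BAGS",
    "featurize_slide",
    "fit_codebook",
    "bag_histogram",
    "assign_words",
    "label_bags",
    "fit_predict_bow",
    "paint_bag_heatmap",
]


@dataclass(frozen=True)
class BagConfig:
    """Bag/word geometry and feature parameters."""

    bag_size: int = 1024
    stride: int = 512
    word_size: int = 128
    lab_bins: int = 8
    lbp_radius: int = 1
    lbp_points: int = 8

    def __post_init__(self) -> None:
        if self.bag_size % self.word_size:
            raise ValueError("bag_size must be a multiple of word_size")

    @property
    def words_per_side(self) -> int:
        return self.bag_size // self.word_size

    @property
    def lbp_bins(self) -> int:
        # uniform LBP with P points has P+2 output codes
        return self.lbp_points + 2


#: proportionally shrunk geometry for small synthetic slides (same 8x8 words/bag)
DESK_SCALE_BAGS = BagConfig(bag_size=128, stride=64, word_size=16)


@dataclass
class Bag:
    rect: tuple[int, int, int, int]  # (x, y, w, h)
    word_indices: np.ndarray  # indices into the slide's word-feature matrix
    histogram: np.ndarray | None = None
    label: int | None = None  # 1 = roi, 0 = non_roi


@dataclass(frozen=True)
class Codebook:
    centers: np.ndarray  # (k, feature_dim)

    @property
    def k(self) -> int:
        return self.centers.shape[0]


@dataclass
class BowModel:
    codebook: Codebook
    classifier: object  # sklearn RandomForestClassifier
    config: BagConfig = field(default_factory=BagConfig)
    rf_seed: int = 0


def _word_features(words: np.ndarray, config: BagConfig) -> np.ndarray:
    """Feature matrix for a stack of RGB words (n, s, s, 3) in uint8."""
    from skimage.color import rgb2gray, rgb2lab
    from skimage.feature import local_binary_pattern

    n = words.shape[0]
    feats = np.empty((n, 3 * config.lab_bins + config.lbp_bins), dtype=np.float64)
    lab = rgb2lab(words.astype(np.float64) / 255.0)
    ranges = ((0.0, 100.0), (-128.0, 127.0), (-128.0, 127.0))
    for i in range(n):
        parts = []
        for c, (lo, hi) in enumerate(ranges):
            hist, _ = np.histogram(lab[i, ..., c], bins=config.lab_bins, range=(lo, hi))
            hist = hist.astype(np.float64)
            parts.append(hist / max(hist.sum(), 1))
        gray = np.round(rgb2gray(words[i].astype(np.float64) / 255.0) * 255).astype(np.uint8)
        codes = local_binary_pattern(gray, config.lbp_points, config.lbp_radius,
                                     method="uniform")
        lbp_hist, _ = np.histogram(codes, bins=config.lbp_bins,
                                   range=(0, config.lbp_bins))
        lbp_hist = lbp_hist.astype(np.float64)
        parts.append(lbp_hist / max(lbp_hist.sum(), 1))
        feats[i] = np.concatenate(parts)
    return feats


def featurize_slide(
    slide: SlideImage, config: BagConfig = BagConfig()
) -> tuple[list[Bag], np.ndarray]:
    """Enumerate bags and compute the word-feature matrix of a slide.

    Slides smaller than one bag are padded with white on the right/bottom.
    Word features are computed once per unique grid cell and shared by the
    overlapping bags that contain the cell.
    """
    pixels = slide.pixels
    h, w = pixels.shape[:2]
    pad_h = max(config.bag_size - h, 0)
    pad_w = max(config.bag_size - w, 0)
    if pad_h or pad_w:
        pixels = np.pad(pixels, ((0, pad_h), (0, pad_w), (0, 0)), constant_values=255)
        h, w = pixels.shape[:2]

    s = config.word_size
    # word grid covering every position any bag can touch
    n_by = (h - config.bag_size) // config.stride + 1
    n_bx = (w - config.bag_size) // config.stride + 1
    max_y = (n_by - 1) * config.stride + config.bag_size
    max_x = (n_bx - 1) * config.stride + config.bag_size
    grid_h, grid_w = max_y // s, max_x // s
    words = (
        pixels[:grid_h * s, :grid_w * s]
        .reshape(grid_h, s, grid_w, s, 3)
        .transpose(0, 2, 1, 3, 4)
        .reshape(-1, s, s, 3)
    )
    features = _word_features(words, config)

    bags = []
    wps = config.words_per_side
    for by in range(n_by):
        for bx in range(n_bx):
            x, y = bx * config.stride, by * config.stride
            gy, gx = y // s, x // s
            rows = np.arange(gy, gy + wps)
            cols = np.arange(gx, gx + wps)
            idx = (rows[:, None] * grid_w + cols[None, :]).ravel()
            bags.append(Bag(rect=(x, y, config.bag_size, config.bag_size),
                            word_indices=idx))
    return bags, features


def fit_codebook(word_features: np.ndarray, k: int = 40, seed: int = 0) -> Codebook:
    """Seeded k-means codebook over word features."""
    from sklearn.cluster import KMeans

    if word_features.shape[0] < k:
        raise ValueError(f"need at least {k} word vectors, got {word_features.shape[0]}")
    km = KMeans(n_clusters=k, random_state=seed, n_init=4)
    km.fit(word_features)
    return Codebook(centers=km.cluster_centers_.astype(np.float64))


def assign_words(features: np.ndarray, codebook: Codebook) -> np.ndarray:
    """Nearest-center assignment (Euclidean, lowest index wins ties)."""
    d2 = ((features[:, None, :] - codebook.centers[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def bag_histogram(bag: Bag, codebook: Codebook,
                  word_features: np.ndarray | None = None,
                  assignments: np.ndarray | None = None) -> np.ndarray:
    """Frequency histogram of the bag's word cluster assignments (sums to 1)."""
    if assignments is None:
        if word_features is None:
            raise ValueError("need word_features or precomputed assignments")
        assignments = assign_words(word_features[bag.word_indices], codebook)
    else:
        assignments = assignments[bag.word_indices]
    hist = np.bincount(assignments, minlength=codebook.k).astype(np.float64)
    return hist / hist.sum()


def label_bags(
    bags: Sequence[Bag],
    viewing_rois: Iterable[ViewingROI],
    frame: tuple[int, int],
    min_overlap_frac: float = 0.5,
) -> list[Bag]:
    """Label a bag positive when the ROI union covers >= ``min_overlap_frac`` of it.

    Coverage is computed against the rasterized union of ROI rects, so
    overlapping ROIs are not double counted.
    """
    width, height = frame
    covered = np.zeros((height, width), dtype=bool)
    for roi in viewing_rois:
        x, y, w, h = roi.rect
        covered[max(y, 0) : y + h, max(x, 0) : x + w] = True
    integral = np.pad(covered.cumsum(0).cumsum(1), ((1, 0), (1, 0)))
    for bag in bags:
        x, y, w, h = bag.rect
        x1, y1 = min(x + w, width), min(y + h, height)
        x0, y0 = min(x, width), min(y, height)
        inter = int(integral[y1, x1] - integral[y0, x1] - integral[y1, x0]
                    + integral[y0, x0])
        bag.label = int(inter / (w * h) >= min_overlap_frac)
    return list(bags)


def paint_bag_heatmap(bags: Sequence[Bag], scores: Sequence[float],
                      frame: tuple[int, int], case_id: str = "") -> Heatmap:
    """Average per-bag ROI probabilities onto the slide frame."""
    width, height = frame
    acc = np.zeros((height, width), dtype=np.float64)
    cnt = np.zeros((height, width), dtype=np.float64)
    for bag, score in zip(bags, scores):
        x, y, w, h = bag.rect
        acc[y : min(y + h, height), x : min(x + w, width)] += score
        cnt[y : min(y + h, height), x : min(x + w, width)] += 1
    with np.errstate(invalid="ignore"):
        out = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
    return Heatmap(np.clip(out, 0, 1), case_id=case_id)


def fit_predict_bow(
    train_slides: Sequence[tuple[SlideImage, Sequence[ViewingROI]]],
    test_slides: Sequence[SlideImage],
    config: BagConfig = BagConfig(),
    k: int = 40,
    n_trees: int = 100,
    min_overlap_frac: float = 0.5,
    seed: int = 0,
) -> tuple[BowModel, list[Heatmap]]:
    """Full baseline: codebook, histograms, RF classifier, test heatmaps.

    ``train_slides`` pairs each slide with the viewing ROIs that define its
    positive regions.  Raises when the training bags collapse to one class.
    """
    from sklearn.ensemble import RandomForestClassifier

    all_feats = []
    per_slide: list[tuple[list[Bag], np.ndarray]] = []
    for slide, rois in train_slides:
        bags, feats = featurize_slide(slide, config)
        label_bags(bags, rois, slide.frame, min_overlap_frac)
        per_slide.append((bags, feats))
        all_feats.append(feats)
    codebook = fit_codebook(np.vstack(all_feats), k=k, seed=seed)

    X, y = [], []
    for bags, feats in per_slide:
        assignments = assign_words(feats, codebook)
        for bag in bags:
            X.append(bag_histogram(bag, codebook, assignments=assignments))
            y.append(bag.label)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training bags contain a single class; cannot fit a classifier")
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    clf.fit(np.asarray(X), y)
    model = BowModel(codebook=codebook, classifier=clf, config=config, rf_seed=seed)

    heatmaps = []
    pos_col = int(np.where(clf.classes_ == 1)[0][0])
    for slide in test_slides:
        bags, feats = featurize_slide(slide, config)
        assignments = assign_words(feats, codebook)
        hists = np.asarray(
            [bag_histogram(b, codebook, assignments=assignments) for b in bags]
        )
        scores = clf.predict_proba(hists)[:, pos_col]
        heatmaps.append(paint_bag_heatmap(bags, scores, slide.frame, slide.case_id))
    return model, heatmaps
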