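"""Heatmap-channel fusion for computer-aided diagnosis.

The viewing heatmap is appended to the downscaled RGB slide as a fourth
input plane and matched classifiers — identical except for the first-layer
channel count — are trained with and without it, over several seeds, to
measure whether the attention signal improves diagnosis.  Metrics are
micro-averaged F1, sensitivity and specificity over the four diagnostic
classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import nn
from .heatmap_builder import Heatmap
from .metrics import confusion_counts_from_labels, micro_sensitivity_specificity
from .slide_tiling import DatasetSplit, SlideImage

__all__ = [
    "FusedInput",
    "ClassifierConfig",
    "fuse_heatmap_channel",
    "train_diagnosis_classifier",
    "compare_fusion",
]

CLASSES = (1, 2, 3, 4)


@dataclass
class FusedInput:
    """(4, H, W) float grid: RGB planes in [0,1] plus the raw heatmap plane."""

    channels: np.ndarray
    label: int
    case_id: str = ""

    def __post_init__(self) -> None:
        if self.channels.ndim != 3 or self.channels.shape[0] != 4:
            raise ValueError("fused input must have 4 leading channel planes")
        if self.label not in CLASSES:
            raise ValueError(f"label must be in 1..4, got {self.label}")


@dataclass(frozen=True)
class ClassifierConfig:
    input_size: int = 64
    width: int = 8
    depth: int = 3
    epochs: int = 20
    lr: float = 0.001
    batch_size: int = 8
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    input_mode: str = "wsi"  # or "wsi_plus_heatmap"


def _resize_plane(arr: np.ndarray, size: int) -> np.ndarray:
    from skimage.transform import resize

    return resize(arr.astype(np.float64), (size, size), order=1,
                  preserve_range=True, anti_aliasing=True)


def fuse_heatmap_channel(slide: SlideImage, heatmap: Heatmap,
                         size: int | None = None, label: int = 1) -> FusedInput:
    """Stack the heatmap as channel 4 below the RGB planes.

    The heatmap plane is carried raw in [0, 1]; with ``size=None`` no
    resampling happens and channel 4 equals the heatmap bit-exactly.
    """
    if slide.frame != heatmap.frame:
        raise ValueError(f"slide frame {slide.frame} != heatmap frame {heatmap.frame}")
    rgb = slide.pixels.astype(np.float64) / 255.0
    hm = heatmap.values
    if size is not None and (slide.frame != (size, size)):
        rgb = np.stack([_resize_plane(rgb[..., c], size) for c in range(3)], axis=-1)
        hm = np.clip(_resize_plane(hm, size), 0.0, 1.0)
    planes = np.concatenate([rgb.transpose(2, 0, 1), hm[None]], axis=0)
    return FusedInput(channels=planes.astype(np.float32), label=label,
                      case_id=slide.case_id)


def _fit_one(
    inputs: list[FusedInput], labels: np.ndarray,
    test_inputs: list[FusedInput],
    in_channels: int, config: ClassifierConfig, seed: int,
) -> np.ndarray:
    model = nn.ConvClassifier(in_channels, n_classes=len(CLASSES),
                              width=config.width, depth=config.depth, seed=seed)
    opt = nn.Adam(model.parameters(), lr=config.lr)
    rng = np.random.default_rng(seed)
    X = np.stack([f.channels[:in_channels] for f in inputs])
    Xt = np.stack([f.channels[:in_channels] for f in test_inputs])
    y = labels - 1  # 1..4 -> 0..3
    for _ in range(config.epochs):
        order = rng.permutation(len(X))
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            opt.zero_grad()
            loss = nn.softmax_cross_entropy(model(nn.Tensor(X[idx])), y[idx])
            loss.backward()
            opt.step()
    with nn.no_grad():
        logits = model(nn.Tensor(Xt)).data
    return logits.argmax(axis=1) + 1


def train_diagnosis_classifier(
    cohort: Sequence[FusedInput],
    split: DatasetSplit | Mapping[str, str],
    config: ClassifierConfig = ClassifierConfig(),
) -> list[dict]:
    """Train per-seed classifiers in the configured input mode.

    ``cohort`` holds fused inputs for every case; the split decides train
    vs test membership (validation cases are folded into train for these
    small-cohort experiments).  Returns one metrics dict per seed.
    """
    def _split_of(cid: str) -> str:
        if isinstance(split, DatasetSplit):
            return split.split_of(cid)
        return split[cid]

    train = [f for f in cohort if _split_of(f.case_id) in ("train", "val")]
    test = [f for f in cohort if _split_of(f.case_id) == "test"]
    if not train or not test:
        raise ValueError("both train and test splits must be non-empty")
    y_train = np.array([f.label for f in train])
    if set(np.unique(y_train)) != set(CLASSES):
        raise ValueError("every diagnostic class must appear in the training split")
    y_test = np.array([f.label for f in test])
    in_channels = 4 if config.input_mode == "wsi_plus_heatmap" else 3

    results = []
    for seed in config.seeds:
        pred = _fit_one(train, y_train, test, in_channels, config, seed)
        counts = confusion_counts_from_labels(y_test, pred, CLASSES)
        sens, spec, f1 = micro_sensitivity_specificity(counts)
        results.append(
            {"seed": seed, "input_mode": config.input_mode,
             "micro_f1": f1, "sensitivity": sens, "specificity": spec}
        )
    return results


def compare_fusion(per_seed_metrics: Mapping[str, Sequence[dict]]) -> dict:
    """Per-mode means and per-seed deltas of the fusion experiment.

    ``per_seed_metrics`` maps input mode -> list of per-seed metric dicts
    (as returned by :func:`train_diagnosis_classifier`).  Modes must share
    the same seed set.
    """
    modes = sorted(per_seed_metrics)
    if not modes:
        raise ValueError("no metrics to compare")
    seed_sets = {m: tuple(r["seed"] for r in per_seed_metrics[m]) for m in modes}
    if len(set(seed_sets.values())) != 1:
        raise ValueError(f"seed sets differ across modes: {seed_sets}")
    report: dict = {"means": {}, "deltas": {}}
    keys = ("micro_f1", "sensitivity", "specificity")
    for m in modes:
        report["means"][m] = {
            k: float(np.mean([r[k] for r in per_seed_metrics[m]])) for k in keys
        }
    if len(modes) == 2:
        a, b = modes
        report["deltas"] = {
            k: [rb[k] - ra[k]
                for ra, rb in zip(per_seed_metrics[a], per_seed_metrics[b])]
            for k in keys
        }
    return report
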