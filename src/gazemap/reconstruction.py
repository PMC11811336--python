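"""Heatmap regression with encoder-decoder networks.

An encoder compresses an RGB slide patch into a latent representation and a
decoder reconstructs the viewing heatmap for that patch; training minimizes
per-pixel mean squared error against the duration-weighted viewing heatmap.
Inputs are normalized with ImageNet statistics; targets stay in raw [0, 1]
heatmap space.

Three architectures are available (``convae``, ``unet``, ``attention_unet``),
each with a sigmoid output head so predictions always lie in (0, 1).
Training stops early once the validation loss has not improved for
``early_stopping_patience`` epochs and the best-validation weights are
restored.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from . import nn
from .slide_tiling import PatchPair

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "AugmentationPolicy",
    "IMAGENET_MEAN",
    "IMAGENET_STD",
    "build_model",
    "augment_pair",
    "train_model",
    "predict_heatmaps",
    "save_checkpoint",
    "load_checkpoint",
]

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)

ARCHS = ("convae", "unet", "attention_unet")
ALL_AUG_OPS = (
    "hflip", "vflip", "random_crop", "sharpen", "emboss",
    "brightness", "hue_saturation", "grayscale", "contrast",
)
GEOMETRIC_OPS = frozenset({"hflip", "vflip", "random_crop"})


@dataclass(frozen=True)
class ModelSpec:
    """Architecture selection; width scales the whole channel ladder."""

    arch: str = "unet"
    encoder_width: int = 64
    pretrained: bool = False
    pretrained_path: str | None = None
    in_channels: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arch not in ARCHS:
            raise ValueError(f"unknown arch {self.arch!r}; expected one of {ARCHS}")


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 0.001
    batch_size: int = 64  # the 512-px experiments use 32
    max_epochs: int = 50
    early_stopping_patience: int = 5
    seed: int = 0
    normalization_mean: tuple[float, float, float] = (0.485, 0.456, 0.406)
    normalization_std: tuple[float, float, float] = (0.229, 0.224, 0.225)

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.early_stopping_patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass(frozen=True)
class AugmentationPolicy:
    """Which augmentations to draw from, applied in randomized order.

    Geometric ops act identically on image and target; photometric ops never
    touch the target.
    """

    ops: tuple[str, ...] = ALL_AUG_OPS
    p: float = 0.5
    crop_frac: float = 0.875

    def __post_init__(self) -> None:
        unknown = set(self.ops) - set(ALL_AUG_OPS)
        if unknown:
            raise ValueError(f"unknown augmentation ops: {sorted(unknown)}")


def build_model(spec: ModelSpec) -> nn.Module:
    """Construct a model per spec; random init is seeded, so builds replay."""
    cls = {"convae": nn.ConvAE, "unet": nn.UNet, "attention_unet": nn.AttentionUNet}[spec.arch]
    model = cls(in_channels=spec.in_channels, width=spec.encoder_width, seed=spec.seed)
    if spec.pretrained:
        if not spec.pretrained_path:
            raise ValueError(
                "pretrained=True requires pretrained_path (a checkpoint with encoder weights)"
            )
        _, arrays = _read_checkpoint(spec.pretrained_path)
        model.load_state_arrays(arrays)
    return model


# ---------------------------------------------------------------------------
# augmentation

def _resize2d(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    from skimage.transform import resize

    return resize(arr, shape, order=1, preserve_range=True, anti_aliasing=False)


def _apply_op(op: str, img: np.ndarray, tgt: np.ndarray, rng: np.random.Generator,
              policy: AugmentationPolicy) -> tuple[np.ndarray, np.ndarray]:
    """img: float (H, W, 3) in [0,1]; tgt: float (H, W) in [0,1]."""
    if op == "hflip":
        return img[:, ::-1], tgt[:, ::-1]
    if op == "vflip":
        return img[::-1], tgt[::-1]
    if op == "random_crop":
        h, w = tgt.shape
        ch, cw = max(1, int(round(h * policy.crop_frac))), max(1, int(round(w * policy.crop_frac)))
        y = int(rng.integers(0, h - ch + 1))
        x = int(rng.integers(0, w - cw + 1))
        img_c = _resize2d(img[y : y + ch, x : x + cw], (h, w))
        tgt_c = _resize2d(tgt[y : y + ch, x : x + cw], (h, w))
        return img_c, np.clip(tgt_c, 0.0, 1.0)
    if op == "sharpen":
        from scipy.ndimage import gaussian_filter

        blurred = gaussian_filter(img, sigma=(1, 1, 0))
        amount = rng.uniform(0.5, 1.5)
        return np.clip(img + amount * (img - blurred), 0, 1), tgt
    if op == "emboss":
        from scipy.ndimage import convolve

        kernel = np.array([[-1, -1, 0], [-1, 1, 1], [0, 1, 1]], dtype=np.float64)
        strength = rng.uniform(0.2, 0.6)
        embossed = np.stack(
            [convolve(img[..., c], kernel, mode="nearest") for c in range(3)], axis=-1
        )
        return np.clip((1 - strength) * img + strength * embossed, 0, 1), tgt
    if op == "brightness":
        return np.clip(img * rng.uniform(0.8, 1.2), 0, 1), tgt
    if op == "hue_saturation":
        from skimage.color import hsv2rgb, rgb2hsv

        hsv = rgb2hsv(img)
        hsv[..., 0] = (hsv[..., 0] + rng.uniform(-0.05, 0.05)) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] * rng.uniform(0.8, 1.2), 0, 1)
        return np.clip(hsv2rgb(hsv), 0, 1), tgt
    if op == "grayscale":
        luma = img @ np.array([0.299, 0.587, 0.114])
        return np.repeat(luma[..., None], 3, axis=-1), tgt
    if op == "contrast":
        factor = rng.uniform(0.8, 1.2)
        return np.clip(0.5 + factor * (img - 0.5), 0, 1), tgt
    raise ValueError(op)  # pragma: no cover


def augment_pair(pair: PatchPair, policy: AugmentationPolicy,
                 rng: np.random.Generator) -> PatchPair:
    """Apply the policy's ops in a randomized sequence, each with probability p."""
    img = pair.image.astype(np.float64) / 255.0
    tgt = pair.target.astype(np.float64)
    order = rng.permutation(len(policy.ops))
    for idx in order:
        if rng.random() < policy.p:
            img, tgt = _apply_op(policy.ops[idx], img, tgt, rng, policy)
    return PatchPair(
        image=np.round(np.ascontiguousarray(img) * 255).astype(np.uint8),
        target=np.ascontiguousarray(tgt),
        origin=pair.origin,
        case_id=pair.case_id,
    )


# ---------------------------------------------------------------------------
# training / inference

def _to_batch(pairs: Sequence[PatchPair], config: TrainConfig) -> tuple[np.ndarray, np.ndarray]:
    mean = np.asarray(config.normalization_mean, dtype=np.float32)
    std = np.asarray(config.normalization_std, dtype=np.float32)
    imgs = np.stack([p.image for p in pairs]).astype(np.float32) / 255.0
    imgs = (imgs - mean) / std
    x = imgs.transpose(0, 3, 1, 2)  # NHWC -> NCHW
    y = np.stack([p.target for p in pairs]).astype(np.float32)[:, None]
    return x, y


def _forward_loss(model: nn.Module, x: np.ndarray, y: np.ndarray) -> nn.Tensor:
    pred = model(nn.Tensor(x))
    diff = pred - nn.Tensor(y)
    return (diff * diff).mean()


def _eval_loss(model: nn.Module, pairs: Sequence[PatchPair], config: TrainConfig) -> float:
    total, count = 0.0, 0
    with nn.no_grad():
        for i in range(0, len(pairs), config.batch_size):
            chunk = pairs[i : i + config.batch_size]
            x, y = _to_batch(chunk, config)
            pred = model(nn.Tensor(x)).data
            total += float(((pred - y) ** 2).mean()) * len(chunk)
            count += len(chunk)
    return total / count


def train_model(
    model: nn.Module,
    train_pairs: Sequence[PatchPair],
    val_pairs: Sequence[PatchPair],
    config: TrainConfig = TrainConfig(),
    augmentation: AugmentationPolicy | None = None,
    progress: Callable[[int, float, float], None] | None = None,
) -> tuple[nn.Module, list[dict]]:
    """Minimize per-pixel MSE with Adam; early-stop on validation loss.

    Returns the model (with best-validation weights restored) and a history
    of ``{"epoch", "train_loss", "val_loss"}`` records.  Fully deterministic
    given ``config.seed``.
    """
    if not train_pairs or not val_pairs:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.lr)
    history: list[dict] = []
    best_val = np.inf
    best_state: list[np.ndarray] | None = None
    stale = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_pairs))
        running, seen = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            chunk = [train_pairs[j] for j in order[i : i + config.batch_size]]
            if augmentation is not None:
                chunk = [augment_pair(p, augmentation, rng) for p in chunk]
            x, y = _to_batch(chunk, config)
            opt.zero_grad()
            loss = _forward_loss(model, x, y)
            loss.backward()
            opt.step()
            running += float(loss.data) * len(chunk)
            seen += len(chunk)
        val_loss = _eval_loss(model, val_pairs, config)
        history.append(
            {"epoch": epoch, "train_loss": running / seen, "val_loss": val_loss}
        )
        if progress is not None:
            progress(epoch, running / seen, val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = [a.copy() for a in model.state_arrays()]
            stale = 0
        else:
            stale += 1
            if stale >= config.early_stopping_patience:
                break
    if best_state is not None:
        model.load_state_arrays(best_state)
    return model, history


def predict_heatmaps(
    model: nn.Module,
    patches: Sequence[PatchPair] | Sequence[np.ndarray],
    config: TrainConfig = TrainConfig(),
) -> list[np.ndarray]:
    """Predict one (0,1) heatmap grid per input patch (order-preserving)."""
    imgs = [p.image if isinstance(p, PatchPair) else np.asarray(p) for p in patches]
    out: list[np.ndarray] = []
    mean = np.asarray(config.normalization_mean, dtype=np.float32)
    std = np.asarray(config.normalization_std, dtype=np.float32)
    with nn.no_grad():
        for i in range(0, len(imgs), config.batch_size):
            chunk = np.stack(imgs[i : i + config.batch_size]).astype(np.float32) / 255.0
            x = ((chunk - mean) / std).transpose(0, 3, 1, 2)
            pred = model(nn.Tensor(x)).data
            out.extend(pred[j, 0].astype(np.float64) for j in range(pred.shape[0]))
    return out


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(path: str | Path, model: nn.Module, spec: ModelSpec,
                    config: TrainConfig | None = None) -> None:
    meta = {"spec": asdict(spec), "config": asdict(config) if config else None}
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(str(path), __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def _read_checkpoint(path: str | Path) -> tuple[dict, list[np.ndarray]]:
    with np.load(str(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = [data[f"arr_{i}"] for i in range(len(data.files) - 1)]
    return meta, arrays


def load_checkpoint(path: str | Path) -> tuple[nn.Module, ModelSpec, TrainConfig | None]:
    meta, arrays = _read_checkpoint(path)
    spec = ModelSpec(**{k: tuple(v) if isinstance(v, list) else v
                        for k, v in meta["spec"].items()})
    model = build_model(replace(spec, pretrained=False))
    model.load_state_arrays(arrays)
    cfgdict = meta.get("config")
    config = None
    if cfgdict:
        cfgdict = {k: tuple(v) if isinstance(v, list) else v for k, v in cfgdict.items()}
        config = TrainConfig(**cfgdict)
    return model, spec, config
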