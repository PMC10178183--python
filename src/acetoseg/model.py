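"""Dual-input U-Net segmenter for acetowhite epithelium.

The network takes either six channels (after-image RGB stacked with the
aligned before-image RGB; the "proposed" arm) or three channels (after-image
only; the "control" arm) and returns a per-pixel lesion probability.
Training minimizes soft dice loss with Adam, with one random geometric
augmentation (scale, translate, horizontal flip) sampled per case per epoch
and applied identically to every input channel and the mask.

All randomness — weight initialization, batch order, augmentation — derives
from ``UNetConfig.seed``, so a run is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
from numba import njit

from . import evaluate as _evaluate
from ._net import Adam, NumpyUNet, batch_dice_loss_and_grad
from .errors import ValidationError
from .preprocess import CasePair

__all__ = [
    "Arm",
    "UNetConfig",
    "AugmentParams",
    "TrainingHistory",
    "stack_inputs",
    "dice_loss",
    "augment",
    "build_unet",
    "train",
    "predict",
]

Arm = Literal["proposed", "control"]


@dataclass
class UNetConfig:
    """Architecture and optimisation settings.

    ``in_channels`` selects the arm: 6 stacks the aligned before-image onto
    the after-image, 3 uses the after-image alone.  The small encoder keeps
    the method exercisable on one CPU; ``vgg16_style`` reproduces the
    13-convolution VGG16 layout.
    """

    in_channels: int = 6
    depth: int = 3
    base_channels: int = 3
    encoder_kind: str = "small"
    pretrained_adaptation: str = "random"
    epochs: int = 40
    batch_size: int = 5
    learning_rate: float = 1e-3
    seed: int = 0
    smooth: float = 1.0
    threshold: float = 0.5

    def __post_init__(self):
        if self.in_channels not in (3, 6):
            raise ValidationError(f"in_channels must be 3 or 6, got {self.in_channels}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be >= 1")

    @property
    def arm(self) -> Arm:
        return "proposed" if self.in_channels == 6 else "control"

    @classmethod
    def for_arm(cls, arm: Arm, **kwargs) -> "UNetConfig":
        if arm not in ("proposed", "control"):
            raise ValidationError(f"unknown arm {arm!r}")
        return cls(in_channels=6 if arm == "proposed" else 3, **kwargs)


@dataclass
class AugmentParams:
    """Random scaling 0.5-1.5x, +/-10% translation per axis, horizontal flip
    with probability 0.5 — resampled once per case per epoch."""

    scale_range: tuple[float, float] = (0.5, 1.5)
    translate_frac: float = 0.10
    hflip_prob: float = 0.5

    def __post_init__(self):
        lo, hi = self.scale_range
        if not (0 < lo <= hi):
            raise ValidationError(f"scale_range must be positive, got {self.scale_range}")
        if not 0 <= self.translate_frac <= 1:
            raise ValidationError("translate_frac must lie in [0, 1]")


@dataclass
class TrainingHistory:
    """Per-epoch record for one training run (one LOOCV fold).

    Metrics are computed on the validation case(s) after every epoch at the
    configured binarization threshold; undefined ratios (no predicted or no
    true positives) are stored as NaN.  ``val_probs[e]`` holds the epoch-e
    validation probability maps, kept so the ROC AUC at the minimum-loss
    epoch can be computed after training.
    """

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    recall: list[float] = field(default_factory=list)
    precision: list[float] = field(default_factory=list)
    f1: list[float] = field(default_factory=list)
    val_probs: list[list[np.ndarray]] = field(default_factory=list)
    case_id: str = ""
    n_train: int = 0

    def __len__(self) -> int:
        return len(self.train_loss)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self) + 1),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "accuracy": self.accuracy,
                "recall": self.recall,
                "precision": self.precision,
                "f1": self.f1,
            }
        )


# ---------------------------------------------------------------- stacking

def stack_inputs(case: CasePair, arm: Arm) -> np.ndarray:
    """Build the network input for one case: float32 (C,H,W) in [0,1].

    proposed -> 6 channels [after R,G,B, aligned-before R,G,B];
    control  -> 3 channels [after R,G,B].
    """
    after = np.asarray(case.after_img)
    if arm == "proposed":
        before = np.asarray(case.before_img_aligned)
        if before.shape != after.shape:
            raise ValidationError(
                f"after {after.shape} and aligned-before {before.shape} shapes differ"
            )
        stacked = np.concatenate([after, before], axis=-1)
    elif arm == "control":
        stacked = after
    else:
        raise ValidationError(f"unknown arm {arm!r}")
    return np.ascontiguousarray(stacked.transpose(2, 0, 1)).astype(np.float32) / 255.0


# --------------------------------------------------------------- dice loss

def dice_loss(pred_prob: np.ndarray, target: np.ndarray, smooth: float = 1.0) -> float:
    """Soft dice loss 1 - (2*sum(p*t)+s) / (sum(p)+sum(t)+s), in [0, 1]."""
    pred_prob = np.asarray(pred_prob, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred_prob.shape != target.shape:
        raise ValidationError(
            f"shape mismatch: pred {pred_prob.shape} vs target {target.shape}"
        )
    if pred_prob.min() < 0 or pred_prob.max() > 1:
        raise ValidationError("predictions must lie in [0, 1]")
    num = 2.0 * float((pred_prob * target).sum()) + smooth
    den = float(pred_prob.sum()) + float(target.sum()) + smooth
    return 1.0 - num / den


# ------------------------------------------------------------ augmentation

@njit(fastmath=True, cache=True)
def _affine_sample_kernel(src, out, sy, sx, oy, ox, flip, nearest):
    """Inverse-mapped affine resample of (C,H,W): output (i,j) samples the
    source at (sy*i+oy, sx*j'+ox) with j' horizontally flipped when asked;
    out-of-range samples are 0."""
    C, H, W = src.shape
    for c in range(C):
        for i in range(H):
            yi = sy * i + oy
            for j in range(W):
                jj = W - 1 - j if flip else j
                xi = sx * jj + ox
                if nearest:
                    yn = int(np.rint(yi))
                    xn = int(np.rint(xi))
                    if 0 <= yn < H and 0 <= xn < W:
                        out[c, i, j] = src[c, yn, xn]
                    else:
                        out[c, i, j] = 0.0
                else:
                    y0 = int(np.floor(yi))
                    x0 = int(np.floor(xi))
                    fy = yi - y0
                    fx = xi - x0
                    v = 0.0
                    for dy2 in range(2):
                        yy = y0 + dy2
                        if yy < 0 or yy >= H:
                            continue
                        wy = fy if dy2 == 1 else 1.0 - fy
                        for dx2 in range(2):
                            xx = x0 + dx2
                            if xx < 0 or xx >= W:
                                continue
                            wx = fx if dx2 == 1 else 1.0 - fx
                            v += wy * wx * src[c, yy, xx]
                    out[c, i, j] = v


def _apply_geom(arr: np.ndarray, scale: float, ty: float, tx: float,
                flip: bool, nearest: bool) -> np.ndarray:
    """Resample about the image center, translate by (ty, tx) pixels, then
    optionally flip horizontally; output keeps the input size (zero fill)."""
    squeeze = arr.ndim == 2
    src = np.ascontiguousarray(arr[None] if squeeze else arr, dtype=np.float32)
    C, H, W = src.shape
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    # inverse map of "scale about center then translate"
    sy = sx = 1.0 / scale
    oy = cy - (cy + ty) / scale
    ox = cx - (cx + tx) / scale
    out = np.empty_like(src)
    _affine_sample_kernel(src, out, sy, sx, oy, ox, flip, nearest)
    return out[0] if squeeze else out


def augment(case_tensor: np.ndarray, mask: np.ndarray, params: AugmentParams,
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Sample ONE geometric transform and apply it to all channels and the
    mask.  The image channels are resampled bilinearly, the mask by nearest
    neighbour (so it stays binary); the canvas size is unchanged, with zero
    fill where the transform leaves the frame."""
    lo, hi = params.scale_range
    scale = float(rng.uniform(lo, hi))
    H, W = mask.shape
    ty = float(rng.uniform(-params.translate_frac, params.translate_frac) * H)
    tx = float(rng.uniform(-params.translate_frac, params.translate_frac) * W)
    flip = bool(rng.random() < params.hflip_prob)
    out_t = _apply_geom(case_tensor, scale, ty, tx, flip, nearest=False)
    out_m = _apply_geom(mask.astype(np.float32), scale, ty, tx, flip, nearest=True)
    return out_t, out_m


# ----------------------------------------------------------------- training

def build_unet(config: UNetConfig) -> NumpyUNet:
    """Instantiate the network with weights drawn from ``config.seed``."""
    return NumpyUNet(
        in_channels=config.in_channels,
        depth=config.depth,
        base_channels=config.base_channels,
        encoder_kind=config.encoder_kind,
        pretrained_adaptation=config.pretrained_adaptation,
        rng=np.random.default_rng(config.seed),
    )


def _case_mask(case: CasePair) -> np.ndarray:
    return np.asarray(case.mask, dtype=np.float32)


def train(
    train_cases: Sequence[CasePair],
    val_cases: CasePair | Sequence[CasePair],
    config: UNetConfig,
    augment_params: AugmentParams | None = None,
) -> tuple[NumpyUNet, TrainingHistory]:
    """Train one model and record per-epoch validation metrics.

    Returns the trained network and its :class:`TrainingHistory` (one record
    per epoch; validation probability maps retained).
    """
    if len(train_cases) == 0:
        raise ValidationError("empty training set")
    if isinstance(val_cases, CasePair):
        val_cases = [val_cases]
    train_ids = {c.case_id for c in train_cases}
    for v in val_cases:
        if v.case_id in train_ids:
            raise ValidationError(f"validation case {v.case_id!r} appears in training set")
    if augment_params is None:
        augment_params = AugmentParams()
    arm = config.arm

    rng = np.random.default_rng(config.seed)
    model = NumpyUNet(
        in_channels=config.in_channels,
        depth=config.depth,
        base_channels=config.base_channels,
        encoder_kind=config.encoder_kind,
        pretrained_adaptation=config.pretrained_adaptation,
        rng=rng,
    )
    opt = Adam(model.params, lr=config.learning_rate)

    xs = [stack_inputs(c, arm) for c in train_cases]
    ms = [_case_mask(c) for c in train_cases]
    val_x = np.stack([stack_inputs(c, arm) for c in val_cases])
    val_m = np.stack([_case_mask(c) for c in val_cases])

    history = TrainingHistory(
        case_id=",".join(c.case_id for c in val_cases),
        n_train=len(train_cases),
    )
    n = len(xs)
    bs = config.batch_size
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, bs):
            batch_idx = order[start:start + bs]
            bx, bm = [], []
            for i in batch_idx:
                ax, am = augment(xs[i], ms[i], augment_params, rng)
                bx.append(ax)
                bm.append(am)
            bx = np.stack(bx)
            bm = np.stack(bm)
            prob, cache = model.forward(bx, keep_cache=True)
            loss, dp = batch_dice_loss_and_grad(prob, bm, config.smooth)
            grads = model.backward(cache, dp)
            opt.step(grads)
            epoch_losses.append(loss)
        # validation at the end of the epoch, no augmentation
        vprob = model.forward(val_x)
        vloss = float(
            np.mean(
                [dice_loss(vprob[k], val_m[k], config.smooth) for k in range(len(val_cases))]
            )
        )
        counts = _evaluate.ConfusionCounts(0, 0, 0, 0)
        for k in range(len(val_cases)):
            counts = counts + _evaluate.confusion(
                (vprob[k] >= config.threshold).astype(np.uint8),
                val_m[k].astype(np.uint8),
            )
        rec = _evaluate.metrics(counts)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(vloss)
        history.accuracy.append(rec.accuracy if rec.accuracy is not None else np.nan)
        history.recall.append(rec.recall if rec.recall is not None else np.nan)
        history.precision.append(rec.precision if rec.precision is not None else np.nan)
        history.f1.append(rec.f1 if rec.f1 is not None else np.nan)
        history.val_probs.append([vprob[k].copy() for k in range(len(val_cases))])
    return model, history


def save_model(model: NumpyUNet, config: UNetConfig, path) -> None:
    """Checkpoint: weights as .npz with a JSON sidecar of the config."""
    import json
    from pathlib import Path

    path = Path(path)
    np.savez(path, **model.params)
    path.with_suffix(".json").write_text(json.dumps(asdict(config), indent=2))


def load_model(path) -> tuple[NumpyUNet, UNetConfig]:
    import json
    from pathlib import Path

    path = Path(path)
    config = UNetConfig(**json.loads(path.with_suffix(".json").read_text()))
    model = build_unet(config)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        for k in model.params:
            model.params[k] = data[k].copy()
    return model, config


def predict(model: NumpyUNet, case: CasePair, arm: Arm) -> np.ndarray:
    """Per-pixel lesion probability for one case (no augmentation)."""
    x = stack_inputs(case, arm)
    if x.shape[0] != model.in_channels:
        raise ValidationError(
            f"arm {arm!r} produces {x.shape[0]} channels but the model "
            f"expects {model.in_channels}"
        )
    return model.forward(x[None])[0]
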