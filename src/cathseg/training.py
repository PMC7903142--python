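"""Training objectives and the two-stage transfer-learning protocol.

Two cost functions are implemented for the catheter/background
segmentation task:

* a smoothed negative Dice overlap,
  ``L = -(2 * sum(w t p) + c) / (sum(w t) + sum(w p) + c)``,
  evaluated per image and per output channel, and

* a weighted categorical cross-entropy,
  ``L = -(1/N) * sum(w_k log p_k[true class])``.

Both objectives carry a background:catheter weight ratio of 1/10 to
address the extreme class imbalance of thin curvilinear structures.
For the cross-entropy the ratio weights each pixel's term (the sum
stays normalized by the pixel count N).  For the Dice objective the
ratio is interpreted as a global scalar on the loss by default - which
leaves gradient directions, and therefore Adam's updates, unchanged -
with a per-pixel variant (weights inside all three sums) available
through :class:`LossSpec`.

Inputs are standardized per channel with mean/std computed once over
the entire training set.  Stage one trains end-to-end with Adam
(lr=0.001, beta1=0.9, beta2=0.999), batch 30, 12 epochs; stage two
freezes everything but a named selection of deepest layers and
fine-tunes with batch 10 for 50 epochs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .eval import dice_coefficient, threshold_mask
from .model import build_model, select_finetune_layers
from .nn import Adam, LightUNet

__all__ = [
    "NormalizationStats",
    "LossSpec",
    "TrainConfig",
    "compute_norm_stats",
    "normalize",
    "denormalize",
    "dice_loss",
    "weighted_cross_entropy",
    "train_end_to_end",
    "finetune",
    "fit_arrays",
    "load_manifest_arrays",
]

PROB_FLOOR = 1e-7  # numeric floor on probabilities inside logarithms


# --------------------------------------------------------------------- types
@dataclass(frozen=True)
class NormalizationStats:
    """Per-channel intensity mean/std of the entire training set."""

    mean: float
    std: float

    def __post_init__(self):
        if not self.std > 0:
            raise ValueError("normalization std must be positive")

    def to_dict(self) -> dict:
        return {"mean": self.mean, "std": self.std}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationStats":
        return cls(mean=float(d["mean"]), std=float(d["std"]))


@dataclass(frozen=True)
class LossSpec:
    """Objective selection and its constants.

    ``class_weight_ratio`` is the background weight relative to the
    catheter weight (1/10 by default); ``smoothing_c`` is the Dice
    smoothing constant guarding the empty-empty division.

    ``dice_weighting`` chooses how the ratio enters the Dice
    objective: as a global scalar on the loss ("scalar", the default),
    which leaves gradient directions - and hence Adam's updates -
    unchanged and keeps the loss in [-1, 0); or as per-pixel weights
    inside all three sums ("per_pixel"), which softens false-positive
    suppression by the same ratio.  The cross-entropy always applies
    the ratio per pixel.
    """

    kind: str = "dice"  # "dice" | "cross_entropy"
    smoothing_c: float = 1.0
    class_weight_ratio: float = 0.1
    dice_weighting: str = "scalar"  # "scalar" | "per_pixel"

    def __post_init__(self):
        if self.kind not in ("dice", "cross_entropy"):
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if not self.smoothing_c > 0:
            raise ValueError("smoothing_c must be positive")
        if self.dice_weighting not in ("scalar", "per_pixel"):
            raise ValueError(f"unknown dice_weighting {self.dice_weighting!r}")

    def dice_pixel_ratio(self) -> float:
        """Effective per-pixel background weight for the Dice sums."""
        return self.class_weight_ratio if self.dice_weighting == "per_pixel" else 1.0


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule for one training stage."""

    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 30
    epochs: int = 12
    stage: str = "end_to_end"  # or "finetune"
    finetune_layers: str = "7-layers"
    validation_fraction: float = 0.1
    threshold: float = 0.01
    seed: int = 0

    @classmethod
    def finetune_defaults(cls, **overrides) -> "TrainConfig":
        base = dict(batch_size=10, epochs=50, stage="finetune", validation_fraction=0.0)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown train config keys: {sorted(unknown)}")
        return cls(**d)


# ------------------------------------------------------------- normalization
def compute_norm_stats(training_images) -> NormalizationStats:
    """Mean and (population) standard deviation over all pixels of all
    training images; raises on an empty or constant-intensity set."""
    imgs = list(training_images)
    if not imgs:
        raise ValueError("cannot compute normalization stats from an empty set")
    flat = np.concatenate([np.asarray(im, dtype=np.float64).ravel() for im in imgs])
    mean = float(flat.mean())
    std = float(flat.std())
    if std == 0:
        raise ValueError("training set has zero intensity variance")
    return NormalizationStats(mean=mean, std=std)


def normalize(image: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Standardize pixel intensities with the training-set statistics."""
    return ((np.asarray(image, dtype=np.float32) - stats.mean) / stats.std).astype(np.float32)


def denormalize(image: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    return np.asarray(image, dtype=np.float32) * stats.std + stats.mean


# --------------------------------------------------------------------- losses
def _pixel_weights(target: np.ndarray, ratio: float, dtype=np.float64) -> np.ndarray:
    """Per-pixel weights: 1 on catheter pixels, ``ratio`` on background."""
    return np.where(target > 0, dtype(1.0), dtype(ratio))


def _as_channel_pairs(prediction, target):
    """Validate a prediction/target pair for the reference losses.

    Accepts a single catheter probability map with a binary mask (2-D)
    or a stack of them (3-D); shapes must agree.  Reference losses are
    evaluated in float64.
    """
    pred = np.asarray(prediction, dtype=np.float64)
    targ = np.asarray(target, dtype=np.float64)
    if pred.shape != targ.shape:
        raise ValueError(f"prediction shape {pred.shape} != target shape {targ.shape}")
    return pred, targ


def dice_loss(prediction, target, spec: LossSpec | None = None) -> float:
    """Negative smoothed Dice overlap, in [-1, 0).

    Equals -1 exactly for a perfect binary match, including the
    empty-empty case (-c/c).  With ``dice_weighting="per_pixel"`` the
    class weights (1 catheter, ``ratio`` background) enter all three
    sums; the default scalar interpretation keeps the sums unweighted.
    """
    spec = spec or LossSpec()
    pred, targ = _as_channel_pairs(prediction, target)
    w = _pixel_weights(targ, spec.dice_pixel_ratio())
    c = spec.smoothing_c
    if pred.ndim == 2:
        pred, targ, w = pred[None], targ[None], w[None]
    num = 2.0 * (w * targ * pred).sum(axis=(1, 2)) + c
    den = (w * targ).sum(axis=(1, 2)) + (w * pred).sum(axis=(1, 2)) + c
    return float(-(num / den).mean())


def _dice_loss_and_grad(pred, targ, w, c):
    """Per-image, per-channel smoothed Dice; returns (loss, dL/dpred).

    ``pred``/``targ``/``w`` are (N, H, W, C); sums run over H, W.
    """
    axes = (1, 2)
    num = 2.0 * (w * targ * pred).sum(axis=axes, dtype=np.float64) + c  # (N, C)
    den = (
        (w * targ).sum(axis=axes, dtype=np.float64)
        + (w * pred).sum(axis=axes, dtype=np.float64)
        + c
    )
    loss = float(-(num / den).mean())
    scale = 1.0 / (pred.shape[0] * pred.shape[3])
    coef_t = (2.0 / den * scale).astype(np.float32)[:, None, None, :]
    coef_p = (num / den**2 * scale).astype(np.float32)[:, None, None, :]
    grad = -w * (targ * coef_t - coef_p)
    return loss, grad.astype(np.float32)


def weighted_cross_entropy(prediction, target, spec: LossSpec | None = None) -> float:
    """Mean over pixels of ``-w_k log p_k`` for the true-class probability.

    ``prediction`` is a catheter probability map (H, W), or a stack of
    them (N, H, W) scored as the mean of per-image losses.  The
    probability assigned to the true class is the map value on catheter
    pixels and its complement on background pixels.  Catheter pixels
    weigh 1, background pixels ``spec.class_weight_ratio``; the sum is
    normalized by the pixel count N.  (During training, where the two
    output channels are free sigmoids rather than exact complements,
    the channels are normalized per pixel first; see
    :func:`_cross_entropy_loss_and_grad`.)
    """
    spec = spec or LossSpec()
    pred, targ = _as_channel_pairs(prediction, target)
    w = _pixel_weights(targ, spec.class_weight_ratio)
    p_true = np.where(targ > 0, pred, 1.0 - pred)
    if pred.ndim == 2:
        n, batch = pred.size, 1
    else:  # (batch, H, W): mean of per-image losses
        n, batch = pred.shape[-2] * pred.shape[-1], pred.shape[0]
    return float(-(w * np.log(np.maximum(p_true, PROB_FLOOR))).sum() / (n * batch))


def _cross_entropy_loss_and_grad(pred, targ, w):
    """Batch weighted categorical cross-entropy; N = pixels per image.

    The two sigmoid output channels are not intrinsically a probability
    distribution, so they are normalized per pixel, p_c = S_c / (S1+S2),
    before taking the true-class log-probability (the convention of
    categorical cross-entropy on non-logit outputs).  This couples the
    channels: raising the true channel necessarily lowers the other,
    which is what drives the two maps toward complementarity.

    With t summing to 1 over channels, per pixel
    ``L = -w (sum_c t_c log S_c - log sum_c S_c)`` and
    ``dL/dS_j = -w (t_j / S_j - 1 / sum_c S_c)``.
    """
    n_pix = pred.shape[1] * pred.shape[2]
    scale = 1.0 / (pred.shape[0] * n_pix)
    p = np.maximum(pred, PROB_FLOOR)
    s = p.sum(axis=-1, keepdims=True)
    w_pix = w[..., :1]  # weight follows the pixel's true class
    loss = float(
        (-(w * targ * np.log(p)).sum(dtype=np.float64)
         + (w_pix * np.log(s)).sum(dtype=np.float64)) * scale
    )
    grad = (w_pix / s - w * targ / p) * np.float32(scale)
    return loss, grad.astype(np.float32, copy=False)


# ------------------------------------------------------------ training loops
def _predict_batched(model, images_u8, stats, batch_size=30, training=False):
    out = []
    for i in range(0, len(images_u8), batch_size):
        x = normalize(images_u8[i : i + batch_size], stats)[..., None]
        out.append(model.forward(x, training=training))
    return np.concatenate(out, axis=0)


def fit_arrays(
    model: LightUNet,
    images: np.ndarray,
    masks: np.ndarray,
    config: TrainConfig,
    spec: LossSpec | None = None,
    stats: NormalizationStats | None = None,
    val_images: np.ndarray | None = None,
    val_masks: np.ndarray | None = None,
) -> tuple[NormalizationStats, pd.DataFrame]:
    """Core optimisation loop over in-memory arrays.

    ``images`` are raw 8-bit intensities (n, H, W); ``masks`` binary
    (n, H, W).  Normalization stats are computed here from the training
    images unless supplied (the fine-tuning stage reuses the stats the
    base model was trained with).  Returns the stats and a per-epoch
    history frame (epoch, train_loss, train_dice, val_loss, val_dice).
    """
    spec = spec or LossSpec()
    pixel_ratio = (
        spec.dice_pixel_ratio() if spec.kind == "dice" else spec.class_weight_ratio
    )
    if stats is None:
        stats = compute_norm_stats(images)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model, lr=config.learning_rate, beta1=config.beta1, beta2=config.beta2)
    n = len(images)
    has_val = val_images is not None and len(val_images) > 0
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_dice = 0.0
        n_batches = 0
        n_seen = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            x = normalize(images[idx], stats)[..., None]
            t1 = np.asarray(masks[idx], dtype=np.float32)[..., None]
            targ = np.concatenate([t1, 1.0 - t1], axis=-1)  # complementary channels
            w = _pixel_weights(t1, pixel_ratio, dtype=np.float32)
            w = np.concatenate([w, w], axis=-1)  # weight follows the true class
            pred = model.forward(x, training=True)
            if spec.kind == "dice":
                loss, grad = _dice_loss_and_grad(pred, targ, w, spec.smoothing_c)
            else:
                loss, grad = _cross_entropy_loss_and_grad(pred, targ, w)
            # running train accuracy from the predictions of this pass
            epoch_dice += sum(
                dice_coefficient(
                    threshold_mask(pred[i, :, :, 0], config.threshold), masks[idx[i]]
                )
                for i in range(len(idx))
            )
            n_seen += len(idx)
            model.backward(grad)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        row = {
            "epoch": epoch + 1,
            "train_loss": epoch_loss / max(n_batches, 1),
            "train_dice": epoch_dice / max(n_seen, 1),
        }
        if has_val:
            vp = _predict_batched(model, val_images, stats, config.batch_size)
            vt1 = np.asarray(val_masks, dtype=np.float32)[..., None]
            vtarg = np.concatenate([vt1, 1.0 - vt1], axis=-1)
            vw = _pixel_weights(vt1, pixel_ratio, dtype=np.float32)
            vw = np.concatenate([vw, vw], axis=-1)
            if spec.kind == "dice":
                vloss, _ = _dice_loss_and_grad(vp, vtarg, vw, spec.smoothing_c)
            else:
                vloss, _ = _cross_entropy_loss_and_grad(vp, vtarg, vw)
            row["val_loss"] = vloss
            row["val_dice"] = float(
                np.mean(
                    [
                        dice_coefficient(
                            threshold_mask(vp[i, :, :, 0], config.threshold), val_masks[i]
                        )
                        for i in range(len(val_masks))
                    ]
                )
            )
        else:
            row["val_loss"] = np.nan
            row["val_dice"] = np.nan
        history.append(row)
    return stats, pd.DataFrame(
        history, columns=["epoch", "train_loss", "train_dice", "val_loss", "val_dice"]
    )


def load_manifest_arrays(manifest: pd.DataFrame | str | Path, root: str | Path | None = None):
    """Load the image/mask pairs a dataset manifest points to."""
    if not isinstance(manifest, pd.DataFrame):
        path = Path(manifest)
        root = root or path.parent
        manifest = pd.read_csv(path)
    root = Path(root) if root is not None else Path(".")
    images, masks = [], []
    for _, row in manifest.iterrows():
        img = np.asarray(iio.imread(root / row["image_path"]))
        msk = np.asarray(iio.imread(root / row["mask_path"]))
        if img.shape != msk.shape:
            raise ValueError(f"image/mask shape mismatch for {row['sample_id']}")
        images.append(img)
        masks.append((msk > 127).astype(np.uint8))
    return np.stack(images), np.stack(masks)


def _split_validation(n, fraction, rng):
    idx = rng.permutation(n)
    n_val = int(round(n * fraction))
    return idx[n_val:], idx[:n_val]


def train_end_to_end(
    model: LightUNet | None,
    manifest,
    config: TrainConfig | None = None,
    spec: LossSpec | None = None,
    root=None,
    checkpoint_path=None,
    history_path=None,
):
    """Stage one: train the full network on a generated dataset.

    Shuffles and standardizes the training images, runs the Adam
    schedule (defaults: lr 0.001, batch 30, 12 epochs) with a seeded
    90/10 train/validation split, and optionally writes a checkpoint
    (with the normalization stats embedded) and a history CSV.
    Returns (model, stats, history).
    """
    from .model import save_checkpoint  # local import to avoid cycle at module load

    config = config or TrainConfig()
    spec = spec or LossSpec()
    if model is None:
        model = build_model(rng_seed=config.seed)
    images, masks = load_manifest_arrays(manifest, root)
    split_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    tr, va = _split_validation(len(images), config.validation_fraction, split_rng)
    stats, history = fit_arrays(
        model,
        images[tr],
        masks[tr],
        config,
        spec,
        val_images=images[va] if len(va) else None,
        val_masks=masks[va] if len(va) else None,
    )
    if history_path:
        history.to_csv(history_path, index=False)
    if checkpoint_path:
        save_checkpoint(
            checkpoint_path,
            model,
            extra={"stage": "end_to_end", "norm_stats": stats.to_dict(), "loss": spec.kind},
        )
    return model, stats, history


def finetune(
    model: LightUNet,
    manifest,
    config: TrainConfig | None = None,
    spec: LossSpec | None = None,
    stats: NormalizationStats | None = None,
    root=None,
    checkpoint_path=None,
    history_path=None,
):
    """Stage two: refine only the deepest layers on a small labelled set.

    Freezes every layer outside the named selection (default
    "7-layers"); frozen weights and batch-norm buffers are bit-identical
    before and after.  Defaults: batch 10, 50 epochs, same Adam.  The
    base stage's normalization stats should be passed so inputs keep the
    distribution the transferred features were learned on; otherwise
    stats are recomputed on the fine-tuning set.
    """
    from .model import save_checkpoint

    config = config or TrainConfig.finetune_defaults()
    spec = spec or LossSpec()
    selection = select_finetune_layers(model, config.finetune_layers)
    images, masks = load_manifest_arrays(manifest, root)
    if config.validation_fraction > 0:
        split_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
        tr, va = _split_validation(len(images), config.validation_fraction, split_rng)
        val_im, val_ma = images[va], masks[va]
        images, masks = images[tr], masks[tr]
    else:
        val_im = val_ma = None
    stats, history = fit_arrays(
        model, images, masks, config, spec, stats=stats, val_images=val_im, val_masks=val_ma
    )
    if history_path:
        history.to_csv(history_path, index=False)
    if checkpoint_path:
        save_checkpoint(
            checkpoint_path,
            model,
            extra={
                "stage": "finetune",
                "finetune_layers": config.finetune_layers,
                "selection": selection,
                "norm_stats": stats.to_dict(),
                "loss": spec.kind,
            },
        )
    return model, stats, history
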