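"""Scikit-learn style estimator facade over the light U-Net.

``UNetSegmenter`` wraps model construction, input standardization,
training, optional deep-layer fine-tuning and thresholded prediction
behind the familiar ``fit`` / ``predict`` / ``score`` surface, so the
segmenter composes with sklearn pipelines and model selection.  The
lower-level modules (:mod:`cathseg.model`, :mod:`cathseg.training`,
:mod:`cathseg.eval`) remain the functional interface.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .eval import DEFAULT_THRESHOLD, dice_coefficient, threshold_mask
from .model import ArchitectureConfig, build_model, count_parameters
from .training import (
    LossSpec,
    NormalizationStats,
    TrainConfig,
    _predict_batched,
    compute_norm_stats,
    fit_arrays,
)

__all__ = ["UNetSegmenter"]


class UNetSegmenter(BaseEstimator):
    """Catheter/guidewire segmenter for grayscale fluoroscopy frames.

    Parameters
    ----------
    channels_per_level:
        Feature maps per resolution level, full resolution first and the
        bottleneck last.  The default reproduces the light architecture
        (687,634 trainable parameters, 55 layers).
    loss:
        "dice" (negative smoothed Dice overlap) or "cross_entropy"
        (weighted categorical cross-entropy).
    class_weight_ratio:
        Background pixel weight relative to the catheter weight.
    dice_weighting:
        How the ratio enters the Dice objective: "scalar" (default; a
        global factor, equivalent to the unweighted loss under Adam)
        or "per_pixel" (weights inside the Dice sums).
    smoothing_c:
        Dice smoothing constant.
    epochs, batch_size, learning_rate, beta1, beta2:
        Adam schedule; defaults follow the end-to-end stage (12 epochs,
        batch 30, lr 0.001).
    validation_fraction:
        Seeded random fraction held out for per-epoch validation scores.
    threshold:
        Probability cut for :meth:`predict` (strict greater-than).
    random_state:
        Seed for weight init, shuffling and the validation split.

    Attributes
    ----------
    model_ : LightUNet
        The trained network.
    norm_stats_ : NormalizationStats
        Training-set intensity mean/std applied to all later inputs.
    history_ : pandas.DataFrame
        Per-epoch train/validation loss and thresholded Dice.
    n_parameters_ : int
        Trainable parameter count.

    Examples
    --------
    >>> seg = UNetSegmenter(epochs=2, random_state=0)
    >>> seg.fit(images, masks)          # (n, H, W) uint8, (n, H, W) {0,1}
    >>> pred = seg.predict(images[:4])  # binary masks
    >>> seg.score(images, masks)        # mean Dice
    """

    def __init__(
        self,
        channels_per_level=(8, 16, 32, 44, 64, 156),
        loss="dice",
        class_weight_ratio=0.1,
        dice_weighting="scalar",
        smoothing_c=1.0,
        epochs=12,
        batch_size=30,
        learning_rate=0.001,
        beta1=0.9,
        beta2=0.999,
        validation_fraction=0.1,
        threshold=DEFAULT_THRESHOLD,
        random_state=0,
    ):
        self.channels_per_level = channels_per_level
        self.loss = loss
        self.class_weight_ratio = class_weight_ratio
        self.dice_weighting = dice_weighting
        self.smoothing_c = smoothing_c
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.validation_fraction = validation_fraction
        self.threshold = threshold
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def _loss_spec(self):
        return LossSpec(
            kind=self.loss,
            smoothing_c=self.smoothing_c,
            class_weight_ratio=self.class_weight_ratio,
            dice_weighting=self.dice_weighting,
        )

    def _validate_xy(self, X, y=None):
        X = np.asarray(X)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3:
            raise ValueError("X must be (n_images, height, width) grayscale")
        if y is not None:
            y = np.asarray(y)
            if y.ndim == 2:
                y = y[None]
            if y.shape != X.shape:
                raise ValueError(f"mask shape {y.shape} does not match images {X.shape}")
            uniq = np.unique(y)
            if not np.all(np.isin(uniq, [0, 1])):
                raise ValueError("masks must be binary {0, 1}")
        return X, y

    def fit(self, X, y):
        """Train end-to-end on images ``X`` and binary masks ``y``."""
        X, y = self._validate_xy(X, y)
        arch = ArchitectureConfig(
            input_size=X.shape[1], channels_per_level=tuple(self.channels_per_level)
        )
        self.model_ = build_model(arch, rng_seed=self.random_state)
        config = TrainConfig(
            learning_rate=self.learning_rate,
            beta1=self.beta1,
            beta2=self.beta2,
            batch_size=self.batch_size,
            epochs=self.epochs,
            validation_fraction=self.validation_fraction,
            threshold=self.threshold,
            seed=self.random_state,
        )
        split_rng = np.random.default_rng(np.random.SeedSequence([self.random_state, 0x5EED]))
        idx = split_rng.permutation(len(X))
        n_val = int(round(len(X) * self.validation_fraction))
        va, tr = idx[:n_val], idx[n_val:]
        self.norm_stats_, self.history_ = fit_arrays(
            self.model_,
            X[tr],
            y[tr],
            config,
            self._loss_spec(),
            val_images=X[va] if n_val else None,
            val_masks=y[va] if n_val else None,
        )
        self.n_parameters_ = count_parameters(self.model_, trainable_only=True)
        return self

    def finetune(self, X, y, layers="7-layers", epochs=50, batch_size=10):
        """Refine only the named deepest-layer selection on new data.

        Reuses the normalization statistics from the end-to-end stage;
        all frozen weights are bit-identical before and after.
        """
        self._check_fitted()
        from .model import select_finetune_layers

        X, y = self._validate_xy(X, y)
        select_finetune_layers(self.model_, layers)
        config = TrainConfig.finetune_defaults(
            learning_rate=self.learning_rate,
            beta1=self.beta1,
            beta2=self.beta2,
            batch_size=batch_size,
            epochs=epochs,
            finetune_layers=layers,
            threshold=self.threshold,
            seed=self.random_state,
        )
        _, self.finetune_history_ = fit_arrays(
            self.model_, X, y, config, self._loss_spec(), stats=self.norm_stats_
        )
        return self

    # -------------------------------------------------------------- predict
    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("this UNetSegmenter instance is not fitted yet")

    def predict_proba(self, X):
        """Per-pixel catheter probability maps, shape (n, H, W)."""
        self._check_fitted()
        X, _ = self._validate_xy(X)
        probs = _predict_batched(self.model_, X, self.norm_stats_, self.batch_size)
        return probs[..., 0]

    def predict(self, X):
        """Binary catheter masks obtained by thresholding the catheter
        probability map (strictly greater than ``threshold``)."""
        return threshold_mask(self.predict_proba(X), self.threshold)

    def score(self, X, y):
        """Mean Dice coefficient of thresholded predictions against ``y``."""
        X, y = self._validate_xy(X, y)
        pred = self.predict(X)
        return float(np.mean([dice_coefficient(pred[i], y[i]) for i in range(len(y))]))
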