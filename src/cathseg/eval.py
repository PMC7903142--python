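"""Thresholding and segmentation accuracy metrics.

Predicted per-pixel catheter probabilities are binarized with a
strict-greater threshold (default 0.01) and scored against ground
truth with the Dice overlap coefficient and the percentage of pixels
misclassified as false positives (normalized by the total pixel count,
which for thin curvilinear structures yields the familiar low
single-digit percentages).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_THRESHOLD",
    "EvalReport",
    "threshold_mask",
    "dice_coefficient",
    "false_positive_percent",
    "evaluate_dataset",
    "evaluate_arrays",
]

DEFAULT_THRESHOLD = 0.01


@dataclass
class EvalReport:
    """Per-image scores plus dataset aggregates."""

    per_image: pd.DataFrame  # columns: image_id, subset, dice, fp_percent
    aggregates: dict

    def save(self, csv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.per_image.to_csv(csv_path, index=False)
        if json_path is not None:
            Path(json_path).write_text(json.dumps(self.aggregates, indent=2))


def threshold_mask(s1: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Binarize a probability map: 1 where strictly greater than the
    threshold, 0 at or below it."""
    s1 = np.asarray(s1)
    return (s1 > threshold).astype(np.uint8)


def _check_binary_pair(prediction, truth):
    p = np.asarray(prediction)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {t.shape}")
    return p.astype(bool), t.astype(bool)


def dice_coefficient(prediction: np.ndarray, truth: np.ndarray) -> float:
    """Overlap score 2|P∩T| / (|P|+|T|); 1.0 when both masks are empty."""
    p, t = _check_binary_pair(prediction, truth)
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(p, t).sum()) / denom


def false_positive_percent(prediction: np.ndarray, truth: np.ndarray) -> float:
    """Percentage of all pixels predicted catheter where truth is
    background: 100 * |P \\ T| / total pixels."""
    p, t = _check_binary_pair(prediction, truth)
    return 100.0 * int(np.logical_and(p, ~t).sum()) / p.size


def evaluate_arrays(
    model,
    stats,
    images: np.ndarray,
    masks: np.ndarray,
    image_ids=None,
    subset="all",
    threshold: float = DEFAULT_THRESHOLD,
    batch_size: int = 30,
) -> EvalReport:
    """Normalize, predict, threshold and score a stack of images.

    ``subset`` may be one label for the whole stack or one per image;
    aggregates are reported overall and per subset (mean over images
    within a subset, plus the mean of subset means).
    """
    from .training import _predict_batched  # deferred: modules are siblings

    if image_ids is None:
        image_ids = [f"img_{i:05d}" for i in range(len(images))]
    subsets = [subset] * len(images) if isinstance(subset, str) else list(subset)
    probs = _predict_batched(model, images, stats, batch_size)
    rows = []
    for i in range(len(images)):
        pred = threshold_mask(probs[i, :, :, 0], threshold)
        rows.append(
            {
                "image_id": image_ids[i],
                "subset": subsets[i],
                "dice": dice_coefficient(pred, masks[i]),
                "fp_percent": false_positive_percent(pred, masks[i]),
            }
        )
    per_image = pd.DataFrame(rows, columns=["image_id", "subset", "dice", "fp_percent"])
    aggregates = {
        "n_images": len(per_image),
        "mean_dice": float(per_image["dice"].mean()),
        "mean_fp_percent": float(per_image["fp_percent"].mean()),
        "threshold": threshold,
    }
    by_subset = {
        name: {
            "mean_dice": float(g["dice"].mean()),
            "mean_fp_percent": float(g["fp_percent"].mean()),
            "n_images": len(g),
        }
        for name, g in per_image.groupby("subset")
    }
    aggregates["by_subset"] = by_subset
    aggregates["mean_of_subset_means"] = float(
        np.mean([v["mean_dice"] for v in by_subset.values()])
    )
    return EvalReport(per_image=per_image, aggregates=aggregates)


def render_overlay(image: np.ndarray, prediction: np.ndarray, out_path=None) -> np.ndarray:
    """Qualitative review image: prediction contour drawn on the input.

    Returns an RGB uint8 array (and optionally writes it as PNG) with
    the predicted mask boundary in red.
    """
    from skimage.segmentation import find_boundaries

    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a grayscale image")
    rgb = np.repeat(np.clip(img, 0, 255).astype(np.uint8)[..., None], 3, axis=-1)
    edge = find_boundaries(np.asarray(prediction).astype(bool), mode="outer")
    rgb[edge] = (255, 40, 40)
    if out_path is not None:
        import imageio.v3 as iio

        iio.imwrite(out_path, rgb)
    return rgb


def evaluate_dataset(
    model,
    stats,
    manifest,
    threshold: float = DEFAULT_THRESHOLD,
    root=None,
    batch_size: int = 30,
) -> EvalReport:
    """Score every image listed in a dataset manifest."""
    from .training import load_manifest_arrays

    if not isinstance(manifest, pd.DataFrame):
        path = Path(manifest)
        root = root or path.parent
        manifest = pd.read_csv(path)
    images, masks = load_manifest_arrays(manifest, root)
    subset = list(manifest["subset"]) if "subset" in manifest.columns else "all"
    ids = list(manifest["sample_id"]) if "sample_id" in manifest.columns else None
    return evaluate_arrays(
        model,
        stats,
        images,
        masks,
        image_ids=ids,
        subset=subset,
        threshold=threshold,
        batch_size=batch_size,
    )
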