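"""Synthetic X-ray fluoroscopy images with exact catheter ground truth.

Real annotated fluoroscopy is scarce, so training data are composited:
a textured background patch (procedurally generated here, or loaded
from user-supplied image files) is paired with a catheter shape given
as a 2-D polyline, the shape is randomly rotated / zoomed / shifted /
flipped in coordinate space, rasterized to a binary mask, and overlaid
by setting every catheter pixel to the background's mean intensity
plus a random offset drawn from [-50, 50].  The offset is drawn per
pixel by default, which mimics the discontinuous, beaded appearance of
catheters under X-ray; a per-image mode is available.

Every operation is a pure function of its seed, so a dataset can be
regenerated bit-identically from the manifest alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import interpolate, ndimage
from skimage.transform import resize as _sk_resize

__all__ = [
    "TextureSpec",
    "BackgroundPatch",
    "CatheterShape",
    "TransformParams",
    "SyntheticSample",
    "SynthgenConfig",
    "generate_background",
    "resize_patch",
    "load_background",
    "generate_catheter_shape",
    "sample_transform",
    "apply_transform",
    "rasterize_catheter",
    "overlay_catheter",
    "generate_dataset",
]

MANIFEST_COLUMNS = [
    "sample_id",
    "image_path",
    "mask_path",
    "background_id",
    "shape_id",
    "rotation_deg",
    "zoom",
    "shift_v",
    "shift_h",
    "flip_h",
    "flip_v",
    "offset_seed",
]


# --------------------------------------------------------------------- types
@dataclass(frozen=True)
class TextureSpec:
    """Procedural background texture parameters.

    ``base_level`` is the mean gray level; ``contrast`` the amplitude
    of the large-scale intensity structure (bone/organ silhouettes);
    ``roughness`` the relative strength of finer band-limited noise;
    ``n_blobs`` the number of smooth dark silhouettes.  With
    ``contrast=0`` and ``roughness=0`` the patch is constant.
    """

    base_level: float = 130.0
    contrast: float = 55.0
    roughness: float = 0.45
    n_blobs: int = 3

    def __post_init__(self):
        if not 0 <= self.base_level <= 255:
            raise ValueError("base_level must lie in [0, 255]")


@dataclass
class BackgroundPatch:
    """A catheter-free image sub-area used as compositing background."""

    pixels: np.ndarray  # float32 in [0, 255]
    source: str = "procedural"  # or "file"
    id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("background intensities must lie in [0, 255]")


@dataclass
class CatheterShape:
    """Open curve in continuous (row, col) image coordinates."""

    points: np.ndarray  # (m, 2) float
    width_px: float = 3.0
    id: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 2:
            raise ValueError("a catheter shape needs at least two 2-D points")
        if np.any(np.all(np.diff(self.points, axis=0) == 0, axis=1)):
            raise ValueError("consecutive points must be distinct")

    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass(frozen=True)
class TransformParams:
    """Random augmentation applied to catheter coordinates."""

    rotation_deg: float = 0.0
    zoom: float = 1.0
    shift_frac: tuple[float, float] = (0.0, 0.0)  # (vertical, horizontal)
    flip_h: bool = False
    flip_v: bool = False


@dataclass
class SyntheticSample:
    """One composited image with its exact mask and full provenance."""

    image: np.ndarray  # uint8 (H, W)
    mask: np.ndarray  # uint8 {0, 1}
    transform: TransformParams = field(default_factory=TransformParams)
    intensity_offsets: np.ndarray | None = None  # offsets actually applied
    offset_seed: int = 0
    background_id: str = ""
    shape_id: str = ""


@dataclass
class SynthgenConfig:
    """Generator settings; defaults mirror the reference study conditions
    (32 background patches, ~640 catheter shapes, 256 px frames)."""

    n_samples: int = 9000
    frame_size: int = 256
    stroke_width_px: float = 3.0
    offset_range: tuple[float, float] = (-50.0, 50.0)
    zoom_range: tuple[float, float] = (0.6, 1.4)
    rotation_range: tuple[float, float] = (0.0, 90.0)
    shift_range: tuple[float, float] = (-0.2, 0.2)
    offset_mode: str = "per_pixel"  # or "per_image"
    seed: int = 0
    n_backgrounds: int = 32
    n_shapes: int = 640
    n_control_points: int = 6
    texture: TextureSpec = field(default_factory=TextureSpec)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthgenConfig":
        d = dict(d)
        if "texture" in d and isinstance(d["texture"], dict):
            d["texture"] = TextureSpec(**d["texture"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown synthgen config keys: {sorted(unknown)}")
        for key in ("offset_range", "zoom_range", "rotation_range", "shift_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------- operations
def generate_background(
    size: int, texture_spec: TextureSpec | None = None, rng_seed: int = 0
) -> BackgroundPatch:
    """Procedural stand-in for a catheter-free fluoroscopy patch.

    Layers smooth large-scale gradients, a few dark elliptical
    silhouettes (organs, bones, the echo probe) and band-limited noise
    on a flat base level, then clips to the 8-bit range.  Deterministic
    given ``rng_seed``.
    """
    if size <= 0:
        raise ValueError("size must be positive")
    spec = texture_spec or TextureSpec()
    rng = np.random.default_rng(rng_seed)
    img = np.full((size, size), spec.base_level, dtype=np.float64)

    if spec.contrast > 0:
        # large-scale illumination / anatomy gradient
        coarse = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma=size / 4)
        coarse /= max(np.abs(coarse).max(), 1e-12)
        img += spec.contrast * coarse

        # smooth dark silhouettes (anisotropic gaussian bumps)
        rr, cc = np.mgrid[0:size, 0:size]
        for _ in range(spec.n_blobs):
            c0 = rng.uniform(0.1 * size, 0.9 * size, size=2)
            ax = rng.uniform(0.12 * size, 0.45 * size, size=2)
            theta = rng.uniform(0, np.pi)
            depth = rng.uniform(0.3, 1.0) * spec.contrast
            dr, dc = rr - c0[0], cc - c0[1]
            u = dr * np.cos(theta) + dc * np.sin(theta)
            v = -dr * np.sin(theta) + dc * np.cos(theta)
            img -= depth * np.exp(-0.5 * ((u / ax[0]) ** 2 + (v / ax[1]) ** 2))

        if spec.roughness > 0:
            mid = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma=size / 24)
            mid /= max(np.abs(mid).max(), 1e-12)
            fine = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma=1.5)
            fine /= max(np.abs(fine).max(), 1e-12)
            img += spec.contrast * spec.roughness * (0.7 * mid + 0.3 * fine)

    return BackgroundPatch(
        pixels=np.clip(img, 0, 255).astype(np.float32),
        source="procedural",
        id=f"bg-{rng_seed}",
    )


def resize_patch(patch: BackgroundPatch, size: int) -> BackgroundPatch:
    """Bilinearly resize a patch to the network input resolution."""
    if patch.pixels.shape == (size, size):
        return patch
    px = _sk_resize(patch.pixels, (size, size), order=1, preserve_range=True, anti_aliasing=True)
    return BackgroundPatch(np.clip(px, 0, 255).astype(np.float32), patch.source, patch.id)


def load_background(path: str | Path, size: int | None = None) -> BackgroundPatch:
    """Load a user-supplied background patch from an 8-bit image file."""
    px = np.asarray(iio.imread(path), dtype=np.float32)
    if px.ndim == 3:
        px = px.mean(axis=-1)
    patch = BackgroundPatch(px, source="file", id=Path(path).stem)
    return resize_patch(patch, size) if size else patch


def generate_catheter_shape(
    frame_size: int,
    n_control_points: int = 6,
    rng_seed: int = 0,
    width_px: float = 3.0,
) -> CatheterShape:
    """Random smooth open curve spanning the frame.

    Control points advance monotonically along a random direction with
    random lateral offsets, so the spline crosses most of the frame
    without self-tangling; a cubic parametric spline is then sampled at
    roughly 2-px spacing.
    """
    if n_control_points < 3:
        raise ValueError("need at least 3 control points")
    rng = np.random.default_rng(rng_seed)
    theta = rng.uniform(0, 2 * np.pi)
    d = np.array([np.cos(theta), np.sin(theta)])
    perp = np.array([-d[1], d[0]])
    t = np.sort(rng.uniform(-0.42, 0.42, size=n_control_points))
    lateral = rng.uniform(-0.25, 0.25, size=n_control_points)
    center = np.array([frame_size / 2.0, frame_size / 2.0])
    ctrl = center + np.outer(t * frame_size, d) + np.outer(lateral * frame_size, perp)
    pts = _spline_through(ctrl, frame_size)
    return CatheterShape(points=pts, width_px=width_px, id=f"shape-{rng_seed}")


def _spline_through(ctrl: np.ndarray, frame_size: int) -> np.ndarray:
    keep = np.ones(len(ctrl), dtype=bool)
    keep[1:] = np.any(np.diff(ctrl, axis=0) != 0, axis=1)
    ctrl = ctrl[keep]
    k = min(3, len(ctrl) - 1)
    tck, _ = interpolate.splprep([ctrl[:, 0], ctrl[:, 1]], k=k, s=0)
    chord = np.linalg.norm(np.diff(ctrl, axis=0), axis=1).sum()
    n_eval = max(32, int(np.ceil(chord / 2.0)))
    u = np.linspace(0, 1, n_eval)
    rows, cols = interpolate.splev(u, tck)
    pts = np.column_stack([rows, cols])
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(np.diff(pts, axis=0) != 0, axis=1)
    return pts[keep]


def sample_transform(rng_seed: int, config: SynthgenConfig | None = None) -> TransformParams:
    """Draw one augmentation uniformly from the configured ranges."""
    cfg = config or SynthgenConfig()
    rng = np.random.default_rng(rng_seed)
    return TransformParams(
        rotation_deg=float(rng.uniform(*cfg.rotation_range)),
        zoom=float(rng.uniform(*cfg.zoom_range)),
        shift_frac=(
            float(rng.uniform(*cfg.shift_range)),
            float(rng.uniform(*cfg.shift_range)),
        ),
        flip_h=bool(rng.random() < 0.5),
        flip_v=bool(rng.random() < 0.5),
    )


def apply_transform(
    shape: CatheterShape, params: TransformParams, frame_size: int
) -> CatheterShape:
    """Transform catheter *coordinates* (no pixel interpolation).

    Order: rotation about the frame center, zoom about the center,
    shifts as fractions of the frame size, then flips (mirror about the
    center axes).  Points may leave the frame; rasterization clips.
    """
    c = frame_size / 2.0
    pts = shape.points - [c, c]
    th = np.deg2rad(params.rotation_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    pts = pts @ rot.T
    pts = pts * params.zoom
    pts = pts + [params.shift_frac[0] * frame_size, params.shift_frac[1] * frame_size]
    if params.flip_h:  # mirror left-right: negate column offsets
        pts[:, 1] = -pts[:, 1]
    if params.flip_v:  # mirror top-bottom: negate row offsets
        pts[:, 0] = -pts[:, 0]
    return CatheterShape(points=pts + [c, c], width_px=shape.width_px, id=shape.id)


def rasterize_catheter(shape: CatheterShape, frame_size: int) -> np.ndarray:
    """Exact stroke rasterization: mask of pixels whose center lies
    within ``width_px / 2`` of the polyline (out-of-frame parts clipped).
    """
    r = shape.width_px / 2.0
    mask = np.zeros((frame_size, frame_size), dtype=np.uint8)
    p = shape.points[:-1]
    q = shape.points[1:]
    for a, b in zip(p, q):
        lo = np.floor(np.minimum(a, b) - r).astype(int)
        hi = np.ceil(np.maximum(a, b) + r).astype(int)
        lo = np.clip(lo, 0, frame_size - 1)
        hi = np.clip(hi, 0, frame_size - 1)
        if np.any(hi < lo):
            continue
        rr, cc = np.mgrid[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1]
        d = b - a
        L2 = float(d @ d)
        if L2 == 0:
            dist2 = (rr - a[0]) ** 2 + (cc - a[1]) ** 2
        else:
            t = ((rr - a[0]) * d[0] + (cc - a[1]) * d[1]) / L2
            t = np.clip(t, 0.0, 1.0)
            dist2 = (rr - (a[0] + t * d[0])) ** 2 + (cc - (a[1] + t * d[1])) ** 2
        sub = mask[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1]
        sub[dist2 <= r * r] = 1
    return mask


def overlay_catheter(
    background: BackgroundPatch,
    mask: np.ndarray,
    rng_seed: int = 0,
    offset_range: tuple[float, float] = (-50.0, 50.0),
    offset_mode: str = "per_pixel",
) -> SyntheticSample:
    """Composite the catheter onto a background.

    Every mask-1 pixel is set to the global mean background intensity
    plus a random offset from ``offset_range`` (one draw per pixel, or
    one per image with ``offset_mode="per_image"``), clipped to
    [0, 255].  Mask-0 pixels are untouched.
    """
    mask = np.asarray(mask)
    if background.pixels.shape != mask.shape:
        raise ValueError("background and mask shapes differ")
    if offset_mode not in ("per_pixel", "per_image"):
        raise ValueError(f"unknown offset_mode {offset_mode!r}")
    rng = np.random.default_rng(rng_seed)
    n_cath = int(mask.sum())
    n_draw = n_cath if offset_mode == "per_pixel" else 1
    offsets = rng.uniform(offset_range[0], offset_range[1], size=n_draw)
    if offset_mode == "per_image":
        offsets = np.repeat(offsets, n_cath)
    bg_mean = float(background.pixels.mean())
    image = np.rint(background.pixels).clip(0, 255).astype(np.uint8)
    values = np.clip(bg_mean + offsets, 0, 255)
    image[mask.astype(bool)] = np.rint(values).astype(np.uint8)
    return SyntheticSample(
        image=image,
        mask=mask.astype(np.uint8),
        intensity_offsets=offsets,
        offset_seed=rng_seed,
        background_id=background.id,
    )


def _make_sample(
    background: BackgroundPatch,
    shape: CatheterShape,
    transform: TransformParams,
    offset_seed: int,
    config: SynthgenConfig,
) -> SyntheticSample:
    moved = apply_transform(shape, transform, config.frame_size)
    mask = rasterize_catheter(moved, config.frame_size)
    sample = overlay_catheter(
        background, mask, offset_seed, config.offset_range, config.offset_mode
    )
    sample.transform = transform
    sample.shape_id = shape.id
    return sample


def generate_dataset(
    n_samples: int,
    config: SynthgenConfig | None = None,
    rng_seed: int | None = None,
    out_dir: str | Path = ".",
    backgrounds: list[BackgroundPatch] | None = None,
    shapes: list[CatheterShape] | None = None,
) -> pd.DataFrame:
    """Write ``n_samples`` image/mask PNG pairs plus a provenance manifest.

    Backgrounds and shapes default to procedural pools of
    ``config.n_backgrounds`` / ``config.n_shapes`` members; pre-loaded
    pools (e.g. real patches) may be passed instead.  Pairing, the
    per-pair transform and the overlay offsets all derive from the root
    seed, so re-running writes bit-identical files.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    cfg = config or SynthgenConfig()
    seed = cfg.seed if rng_seed is None else rng_seed
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(seed)
    bg_ss, shape_ss, pair_ss, tf_ss, off_ss = ss.spawn(5)
    if backgrounds is None:
        backgrounds = [
            generate_background(cfg.frame_size, cfg.texture, int(s.generate_state(1)[0] >> 1))
            for s in bg_ss.spawn(cfg.n_backgrounds)
        ]
    else:
        backgrounds = [resize_patch(b, cfg.frame_size) for b in backgrounds]
    if shapes is None:
        shapes = [
            generate_catheter_shape(
                cfg.frame_size, cfg.n_control_points, int(s.generate_state(1)[0] >> 1),
                cfg.stroke_width_px,
            )
            for s in shape_ss.spawn(cfg.n_shapes)
        ]

    pair_rng = np.random.default_rng(pair_ss)
    tf_seeds = [int(s.generate_state(1)[0] >> 1) for s in tf_ss.spawn(n_samples)]
    off_seeds = [int(s.generate_state(1)[0] >> 1) for s in off_ss.spawn(n_samples)]
    bg_idx = pair_rng.integers(0, len(backgrounds), size=n_samples)
    sh_idx = pair_rng.integers(0, len(shapes), size=n_samples)

    rows = []
    for i in range(n_samples):
        transform = sample_transform(tf_seeds[i], cfg)
        sample = _make_sample(
            backgrounds[bg_idx[i]], shapes[sh_idx[i]], transform, off_seeds[i], cfg
        )
        img_path = out_dir / "images" / f"sample_{i:05d}.png"
        mask_path = out_dir / "masks" / f"sample_{i:05d}.png"
        iio.imwrite(img_path, sample.image)
        iio.imwrite(mask_path, sample.mask * np.uint8(255))
        rows.append(
            {
                "sample_id": f"sample_{i:05d}",
                "image_path": str(img_path.relative_to(out_dir)),
                "mask_path": str(mask_path.relative_to(out_dir)),
                "background_id": sample.background_id,
                "shape_id": sample.shape_id,
                "rotation_deg": transform.rotation_deg,
                "zoom": transform.zoom,
                "shift_v": transform.shift_frac[0],
                "shift_h": transform.shift_frac[1],
                "flip_h": transform.flip_h,
                "flip_v": transform.flip_v,
                "offset_seed": sample.offset_seed,
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
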