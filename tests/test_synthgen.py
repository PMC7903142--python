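"""Synthetic fluoroscopy generator: determinism, ranges, exactness."""

import hashlib
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pytest

from cathseg.synthgen import (
    BackgroundPatch,
    CatheterShape,
    SynthgenConfig,
    TextureSpec,
    apply_transform,
    generate_background,
    generate_catheter_shape,
    generate_dataset,
    overlay_catheter,
    rasterize_catheter,
    resize_patch,
    sample_transform,
)


class TestBackground:
    def test_zero_noise_spec_is_constant(self):
        patch = generate_background(64, TextureSpec(base_level=120, contrast=0.0), rng_seed=3)
        assert np.all(patch.pixels == 120)

    def test_deterministic_given_seed(self):
        a = generate_background(128, rng_seed=5)
        b = generate_background(128, rng_seed=5)
        assert np.array_equal(a.pixels, b.pixels)
        c = generate_background(128, rng_seed=6)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_default_texture_has_wide_histogram(self):
        patch = generate_background(256, rng_seed=1)
        levels = np.unique(np.rint(patch.pixels))
        assert len(levels) >= 50

    def test_intensities_in_8bit_range(self):
        for seed in range(5):
            px = generate_background(96, rng_seed=seed).pixels
            assert px.min() >= 0 and px.max() <= 255

    def test_invalid_size_rejected(self):
        with pytest.raises(ValueError):
            generate_background(0)

    def test_resize_patch_to_network_resolution(self):
        patch = generate_background(100, rng_seed=2)
        resized = resize_patch(patch, 64)
        assert resized.pixels.shape == (64, 64)
        assert 0 <= resized.pixels.min() and resized.pixels.max() <= 255


class TestCatheterShape:
    def test_deterministic_given_seed(self):
        a = generate_catheter_shape(256, 6, rng_seed=7)
        b = generate_catheter_shape(256, 6, rng_seed=7)
        assert np.array_equal(a.points, b.points)

    def test_spans_at_least_half_the_frame(self):
        shape = generate_catheter_shape(256, 6, rng_seed=7)
        assert shape.arc_length() >= 128

    def test_collinear_control_points_give_straight_line(self):
        ctrl = np.array([[10.0, 10.0], [20.0, 20.0], [30.0, 30.0]])
        from cathseg.synthgen import _spline_through

        pts = _spline_through(ctrl, 64)
        # all points on the diagonal row == col
        assert np.allclose(pts[:, 0], pts[:, 1], atol=1e-8)

    def test_too_few_control_points_rejected(self):
        with pytest.raises(ValueError):
            generate_catheter_shape(256, 2, rng_seed=0)

    def test_degenerate_repeated_points_rejected(self):
        with pytest.raises(ValueError):
            CatheterShape(points=np.array([[1.0, 1.0], [1.0, 1.0]]))


class TestTransforms:
    def test_sampled_parameters_within_ranges(self):
        cfg = SynthgenConfig()
        for seed in range(500):
            p = sample_transform(seed, cfg)
            assert 0 <= p.rotation_deg <= 90
            assert 0.6 <= p.zoom <= 1.4
            assert -0.2 <= p.shift_frac[0] <= 0.2
            assert -0.2 <= p.shift_frac[1] <= 0.2

    def test_sampling_deterministic(self):
        assert sample_transform(123) == sample_transform(123)

    def test_identity_transform_is_noop(self):
        shape = generate_catheter_shape(128, 5, rng_seed=1)
        from cathseg.synthgen import TransformParams

        moved = apply_transform(shape, TransformParams(), 128)
        assert np.allclose(moved.points, shape.points)

    def test_center_is_fixed_point_of_rotation(self):
        from cathseg.synthgen import TransformParams

        shape = CatheterShape(points=np.array([[64.0, 64.0], [64.0, 65.0]]))
        moved = apply_transform(shape, TransformParams(rotation_deg=37.0), 128)
        assert np.allclose(moved.points[0], [64.0, 64.0])

    def test_zoom_about_center_hand_example(self):
        # point (64, 64) in a 256 frame, zoom 2 about (128, 128) -> (0, 0)
        from cathseg.synthgen import TransformParams

        shape = CatheterShape(points=np.array([[64.0, 64.0], [65.0, 64.0]]))
        moved = apply_transform(shape, TransformParams(zoom=2.0), 256)
        assert np.allclose(moved.points[0], [0.0, 0.0])

    def test_flips_are_involutions(self):
        from cathseg.synthgen import TransformParams

        shape = generate_catheter_shape(128, 5, rng_seed=3)
        p = TransformParams(flip_h=True, flip_v=True)
        twice = apply_transform(apply_transform(shape, p, 128), p, 128)
        assert np.allclose(twice.points, shape.points)


def _brute_force_segment_mask(points, width, frame):
    """Naive oracle: per-pixel distance to every segment."""
    mask = np.zeros((frame, frame), dtype=np.uint8)
    r = width / 2.0
    for i in range(frame):
        for j in range(frame):
            for a, b in zip(points[:-1], points[1:]):
                a, b = np.asarray(a, float), np.asarray(b, float)
                d = b - a
                L2 = d @ d
                t = 0.0 if L2 == 0 else np.clip(((i, j) - a) @ d / L2, 0, 1)
                if np.hypot(*((i, j) - (a + t * d))) <= r:
                    mask[i, j] = 1
                    break
    return mask


class TestRasterize:
    def test_outside_frame_gives_empty_mask(self):
        shape = CatheterShape(points=np.array([[-50.0, -50.0], [-10.0, -60.0]]))
        assert rasterize_catheter(shape, 64).sum() == 0

    def test_unit_width_horizontal_segment_is_single_row(self):
        shape = CatheterShape(
            points=np.array([[128.0, 10.0], [128.0, 245.0]]), width_px=1.0
        )
        mask = rasterize_catheter(shape, 256)
        rows = np.nonzero(mask.any(axis=1))[0]
        assert list(rows) == [128]
        cols = np.nonzero(mask[128])[0]
        assert cols.min() == 10 and cols.max() == 245 and len(cols) == 236

    def test_values_are_binary(self):
        shape = generate_catheter_shape(64, 5, rng_seed=9)
        mask = rasterize_catheter(shape, 64)
        assert set(np.unique(mask)) <= {0, 1}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_distance_oracle(self, seed, rng):
        r = np.random.default_rng(seed)
        pts = r.uniform(-5, 45, size=(3, 2))
        shape = CatheterShape(points=pts, width_px=r.uniform(1, 5))
        fast = rasterize_catheter(shape, 40)
        slow = _brute_force_segment_mask(shape.points, shape.width_px, 40)
        assert np.array_equal(fast, slow)


class TestOverlay:
    def test_forced_offset_on_constant_background(self):
        bg = BackgroundPatch(np.full((32, 32), 100.0), id="bg")
        mask = np.zeros((32, 32), dtype=np.uint8)
        mask[10:12, 5:20] = 1
        sample = overlay_catheter(bg, mask, rng_seed=0, offset_range=(30, 30))
        assert np.all(sample.image[mask == 1] == 130)
        assert np.all(sample.image[mask == 0] == 100)

    def test_clipping_at_8bit_ceiling(self):
        bg = BackgroundPatch(np.full((16, 16), 240.0))
        mask = np.eye(16, dtype=np.uint8)
        sample = overlay_catheter(bg, mask, rng_seed=1, offset_range=(50, 50))
        assert np.all(sample.image[mask == 1] == 255)

    def test_offsets_recorded_and_in_range(self):
        bg = generate_background(64, rng_seed=4)
        shape = generate_catheter_shape(64, 5, rng_seed=4)
        mask = rasterize_catheter(shape, 64)
        sample = overlay_catheter(bg, mask, rng_seed=2)
        assert len(sample.intensity_offsets) == int(mask.sum())
        assert np.all(sample.intensity_offsets >= -50)
        assert np.all(sample.intensity_offsets <= 50)

    def test_per_image_mode_uses_single_offset(self):
        bg = generate_background(32, rng_seed=0)
        mask = np.zeros((32, 32), np.uint8)
        mask[4:8, 4:8] = 1
        sample = overlay_catheter(bg, mask, rng_seed=3, offset_mode="per_image")
        assert len(np.unique(sample.intensity_offsets)) == 1

    def test_shape_mismatch_rejected(self):
        bg = BackgroundPatch(np.full((16, 16), 100.0))
        with pytest.raises(ValueError):
            overlay_catheter(bg, np.zeros((8, 8)))

    def test_overlay_rule_on_textured_background(self):
        """Catheter pixels follow mean+offset; background pixels untouched."""
        bg = generate_background(64, rng_seed=8)
        mask = rasterize_catheter(generate_catheter_shape(64, 5, rng_seed=8), 64)
        sample = overlay_catheter(bg, mask, rng_seed=9)
        untouched = np.rint(bg.pixels).clip(0, 255).astype(np.uint8)
        assert np.array_equal(sample.image[mask == 0], untouched[mask == 0])
        expected = np.rint(
            np.clip(bg.pixels.mean() + sample.intensity_offsets, 0, 255)
        ).astype(np.uint8)
        assert np.array_equal(sample.image[mask == 1], expected)


class TestDataset:
    def test_single_sample_dataset(self, tmp_path):
        cfg = SynthgenConfig(n_samples=1, frame_size=64, n_backgrounds=2, n_shapes=2)
        manifest = generate_dataset(1, cfg, 5, tmp_path)
        assert len(manifest) == 1
        assert len(list((tmp_path / "images").glob("*.png"))) == 1
        assert len(list((tmp_path / "masks").glob("*.png"))) == 1
        mask = iio.imread(tmp_path / manifest.iloc[0]["mask_path"])
        assert set(np.unique(mask)) <= {0, 255}

    def test_regeneration_is_bit_identical(self, tmp_path):
        cfg = SynthgenConfig(n_samples=4, frame_size=64, n_backgrounds=3, n_shapes=4)

        def digest(root: Path) -> str:
            h = hashlib.sha256()
            for p in sorted(root.rglob("*.png")) + [root / "manifest.csv"]:
                h.update(p.read_bytes())
            return h.hexdigest()

        a, b = tmp_path / "a", tmp_path / "b"
        generate_dataset(4, cfg, 21, a)
        generate_dataset(4, cfg, 21, b)
        assert digest(a) == digest(b)

    def test_manifest_schema_and_ranges(self, tiny_dataset):
        _, manifest = tiny_dataset
        from cathseg.synthgen import MANIFEST_COLUMNS

        assert list(manifest.columns) == MANIFEST_COLUMNS
        assert manifest["rotation_deg"].between(0, 90).all()
        assert manifest["zoom"].between(0.6, 1.4).all()
        assert manifest["shift_v"].between(-0.2, 0.2).all()
        assert manifest["shift_h"].between(-0.2, 0.2).all()

    def test_invalid_sample_count_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_dataset(0, SynthgenConfig(), 1, tmp_path)
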