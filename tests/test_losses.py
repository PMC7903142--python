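"""Loss functions and input normalization: hand-worked oracles and
invariants, plus numeric checks of the training gradients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from cathseg.training import (
    LossSpec,
    NormalizationStats,
    _cross_entropy_loss_and_grad,
    _dice_loss_and_grad,
    compute_norm_stats,
    denormalize,
    dice_loss,
    normalize,
    weighted_cross_entropy,
)


class TestNormalization:
    def test_two_constant_images_hand_example(self):
        stats = compute_norm_stats([np.zeros((8, 8)), np.full((8, 8), 200.0)])
        assert stats.mean == pytest.approx(100.0)
        assert stats.std == pytest.approx(100.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            compute_norm_stats([])

    def test_constant_set_rejected(self):
        with pytest.raises(ValueError):
            compute_norm_stats([np.full((4, 4), 7.0)])

    def test_order_invariance(self, rng):
        imgs = [rng.uniform(0, 255, (6, 6)) for _ in range(5)]
        a = compute_norm_stats(imgs)
        b = compute_norm_stats(imgs[::-1])
        assert a.mean == pytest.approx(b.mean) and a.std == pytest.approx(b.std)

    def test_centering_and_unit_scaling(self):
        stats = NormalizationStats(mean=50.0, std=10.0)
        assert normalize(np.array([[50.0]]), stats)[0, 0] == pytest.approx(0.0)
        assert normalize(np.array([[60.0]]), stats)[0, 0] == pytest.approx(1.0)

    def test_affine_closed_form(self, rng):
        """Stats of a*x+b are (a*m+b, |a|*s), so normalized values match."""
        imgs = [rng.uniform(0, 255, (8, 8)) for _ in range(3)]
        a, b = 0.5, 20.0
        scaled = [a * im + b for im in imgs]
        s0, s1 = compute_norm_stats(imgs), compute_norm_stats(scaled)
        assert s1.mean == pytest.approx(a * s0.mean + b)
        assert s1.std == pytest.approx(a * s0.std)
        np.testing.assert_allclose(
            normalize(scaled[0], s1), normalize(imgs[0], s0), rtol=1e-4, atol=1e-4
        )

    def test_round_trip(self, rng):
        stats = NormalizationStats(mean=123.4, std=55.0)
        img = rng.uniform(0, 255, (16, 16)).astype(np.float32)
        np.testing.assert_allclose(
            denormalize(normalize(img, stats), stats), img, atol=1e-3
        )

    def test_nonpositive_std_rejected(self):
        with pytest.raises(ValueError):
            NormalizationStats(mean=0.0, std=0.0)


class TestDiceLoss:
    @pytest.mark.parametrize("c", [0.5, 1.0, 10.0])
    def test_perfect_binary_overlap_is_minus_one(self, c, rng):
        mask = (rng.random((16, 16)) > 0.8).astype(np.float32)
        mask[0, 0] = 1  # nonzero mask
        spec = LossSpec(smoothing_c=c)
        assert dice_loss(mask, mask, spec) == pytest.approx(-1.0)

    @pytest.mark.parametrize("c", [0.5, 1.0, 10.0])
    def test_empty_empty_is_minus_one(self, c):
        z = np.zeros((8, 8))
        assert dice_loss(z, z, LossSpec(smoothing_c=c)) == pytest.approx(-1.0)

    def test_hand_worked_example_minus_five_sixths(self):
        """3 catheter pixels, prediction 1.0 on 2 of them, c=1:
        -(2*2+1)/(3+2+1) = -5/6."""
        target = np.zeros((4, 4))
        target[0, 0] = target[0, 1] = target[0, 2] = 1
        pred = np.zeros((4, 4))
        pred[0, 0] = pred[0, 1] = 1.0
        got = dice_loss(pred, target, LossSpec(smoothing_c=1.0))
        assert got == pytest.approx(-5.0 / 6.0, abs=1e-10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        pred=hnp.arrays(np.float64, (6, 6), elements=st.floats(0, 1)),
        targ=hnp.arrays(np.int8, (6, 6), elements=st.integers(0, 1)),
        c=st.floats(0.1, 10),
        ratio=st.floats(0.05, 1.0),
    )
    def test_bounded_in_minus_one_zero(self, pred, targ, c, ratio):
        val = dice_loss(pred, targ, LossSpec(smoothing_c=c, class_weight_ratio=ratio))
        assert -1.0 <= val < 0.0 or val == pytest.approx(-1.0)

    def test_permutation_invariance(self, rng):
        pred = rng.random((8, 8))
        targ = (rng.random((8, 8)) > 0.7).astype(float)
        perm = rng.permutation(64)
        a = dice_loss(pred, targ)
        b = dice_loss(pred.ravel()[perm].reshape(8, 8), targ.ravel()[perm].reshape(8, 8))
        assert a == pytest.approx(b)

    def test_small_c_recovers_negative_dice_coefficient(self, rng):
        from cathseg.eval import dice_coefficient

        pred = (rng.random((12, 12)) > 0.6).astype(float)
        targ = (rng.random((12, 12)) > 0.6).astype(float)
        spec = LossSpec(smoothing_c=1e-9, class_weight_ratio=1.0)
        assert dice_loss(pred, targ, spec) == pytest.approx(
            -dice_coefficient(pred, targ), abs=1e-6
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((4, 4)), np.zeros((5, 5)))


class TestWeightedCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        targ = np.zeros((4, 4))
        targ[1, 1] = 1
        pred = targ.copy()  # probability 1 for the true class everywhere
        assert weighted_cross_entropy(pred, targ) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_half_unweighted_is_log_two(self):
        targ = (np.arange(16).reshape(4, 4) % 2).astype(float)
        pred = np.full((4, 4), 0.5)
        spec = LossSpec(kind="cross_entropy", class_weight_ratio=1.0)
        assert weighted_cross_entropy(pred, targ, spec) == pytest.approx(np.log(2))

    def test_hand_worked_weighted_example(self):
        """Catheter pixel predicted 0.8, background pixel 0.6 for
        background, weights {1, 0.1}: -(log .8 + 0.1 log .6)/2."""
        targ = np.array([[1.0, 0.0]])
        pred = np.array([[0.8, 0.4]])  # catheter-class probabilities
        want = -(np.log(0.8) + 0.1 * np.log(0.6)) / 2.0
        got = weighted_cross_entropy(pred, targ, LossSpec(kind="cross_entropy"))
        assert got == pytest.approx(want, abs=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_cross_entropy(np.zeros((2, 2)), np.zeros((3, 3)))


class TestTrainingGradients:
    """The analytic gradients used by the optimizer, against central
    differences on the public loss values."""

    @staticmethod
    def _batchify(rng):
        pred = rng.uniform(0.05, 0.95, (2, 5, 5, 2)).astype(np.float32)
        t1 = (rng.random((2, 5, 5, 1)) > 0.7).astype(np.float32)
        targ = np.concatenate([t1, 1 - t1], axis=-1)
        w = np.where(t1 > 0, 1.0, 0.1).astype(np.float32)
        w = np.concatenate([w, w], axis=-1)
        return pred, targ, w

    @pytest.mark.parametrize("kind", ["dice", "cross_entropy"])
    def test_gradient_matches_central_difference(self, kind, rng):
        pred, targ, w = self._batchify(rng)
        if kind == "dice":
            loss, grad = _dice_loss_and_grad(pred, targ, w, c=1.0)

            def f(p):
                return _dice_loss_and_grad(p, targ, w, c=1.0)[0]

        else:
            loss, grad = _cross_entropy_loss_and_grad(pred, targ, w)

            def f(p):
                return _cross_entropy_loss_and_grad(p, targ, w)[0]

        eps = 1e-3
        idxs = [(0, 0, 0, 0), (1, 2, 3, 1), (0, 4, 4, 0), (1, 1, 1, 1)]
        for idx in idxs:
            p2 = pred.copy()
            p2[idx] += eps
            up = f(p2)
            p2[idx] -= 2 * eps
            dn = f(p2)
            assert grad[idx] == pytest.approx((up - dn) / (2 * eps), rel=2e-2, abs=1e-7)

    def test_batch_dice_loss_matches_public_mean(self, rng):
        """Batch loss equals the mean of per-image, per-channel values."""
        pred, targ, w = self._batchify(rng)
        # only meaningful with weights derived from each channel's own mask
        loss, _ = _dice_loss_and_grad(pred, targ, w, c=1.0)
        manual = []
        for i in range(pred.shape[0]):
            for ch in range(2):
                c = 1.0
                num = 2 * (w[i, :, :, ch] * targ[i, :, :, ch] * pred[i, :, :, ch]).sum() + c
                den = (
                    (w[i, :, :, ch] * targ[i, :, :, ch]).sum()
                    + (w[i, :, :, ch] * pred[i, :, :, ch]).sum()
                    + c
                )
                manual.append(-num / den)
        assert loss == pytest.approx(np.mean(manual), rel=1e-5)
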