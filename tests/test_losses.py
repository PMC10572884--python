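"""Dice / focal Tversky losses against independent scalar-loop oracles."""

import numpy as np
import pytest

from scintiseg.losses import (
    LossConfig,
    LossConfigError,
    UndefinedLossError,
    dice_loss,
    focal_tversky_loss,
    masked_multiclass_loss,
)
from scintiseg.nn import Tensor


def brute_force_dice(y, p, c, smooth=0.0):
    """Elementwise python-loop evaluation of the Dice loss on channel c."""
    num = den = 0.0
    yc, pc = y[c], p[c]
    for i in range(yc.shape[0]):
        for j in range(yc.shape[1]):
            num += yc[i, j] * pc[i, j]
            den += yc[i, j] + pc[i, j]
    return 1.0 - (2.0 * num + smooth) / (den + smooth)


def brute_force_ftl(y, p, c, alpha, beta, gamma, smooth=0.0):
    """Elementwise python-loop evaluation of the focal Tversky loss."""
    tp = fp = fn = 0.0
    yc, pc = y[c], p[c]
    for i in range(yc.shape[0]):
        for j in range(yc.shape[1]):
            tp += yc[i, j] * pc[i, j]
            fp += (1.0 - yc[i, j]) * pc[i, j]
            fn += yc[i, j] * (1.0 - pc[i, j])
    ti = (tp + smooth) / (tp + alpha * fp + beta * fn + smooth)
    return (1.0 - ti) ** gamma


def random_maps(rng, n_classes=3, size=4):
    classes = rng.integers(0, n_classes, size=(size, size))
    y = np.eye(n_classes)[classes].transpose(2, 0, 1)
    p = rng.random((n_classes, size, size))
    p /= p.sum(axis=0, keepdims=True)
    return y.astype(np.float64), p.astype(np.float64)


EXACT = LossConfig(smooth=0.0)


class TestAgainstOracles:
    @pytest.mark.parametrize("case", range(20))
    def test_dice_matches_scalar_loop(self, case):
        rng = np.random.default_rng(1000 + case)
        y, p = random_maps(rng)
        for c in (1, 2):
            got = dice_loss(y, p, EXACT, class_index=c)
            want = brute_force_dice(y, p, c)
            assert got == pytest.approx(want, rel=1e-10)

    @pytest.mark.parametrize("case", range(20))
    def test_focal_tversky_matches_scalar_loop(self, case):
        rng = np.random.default_rng(2000 + case)
        y, p = random_maps(rng)
        for c in (1, 2):
            got = focal_tversky_loss(y, p, EXACT, class_index=c)
            want = brute_force_ftl(y, p, c, 0.3, 0.7, 0.75)
            assert got == pytest.approx(want, rel=1e-10)

    def test_uniform_prediction_closed_form(self):
        # y one-hot on class M over k pixels, p uniform 1/3: closed form
        y = np.zeros((3, 8, 8))
        y[2, :2, :4] = 1.0  # k = 8
        y[0] = 1.0 - y[2]
        p = np.full((3, 8, 8), 1.0 / 3.0)
        k, n = 8.0, 64.0
        want = 1.0 - 2.0 * (k / 3.0) / (k + n / 3.0)
        assert dice_loss(y, p, EXACT, class_index=2) == pytest.approx(want, rel=1e-12)


class TestIdentitiesAndLimits:
    def test_perfect_prediction_gives_zero(self):
        rng = np.random.default_rng(3)
        y, _ = random_maps(rng)
        assert dice_loss(y, y.copy(), EXACT, class_index=2) == 0.0
        assert focal_tversky_loss(y, y.copy(), EXACT, class_index=2) == 0.0
        assert masked_multiclass_loss(y, y.copy(), EXACT, base="focal_tversky") == 0.0

    def test_disjoint_supports_give_one(self):
        y = np.zeros((3, 4, 4))
        y[1] = 1.0  # all NM
        p = np.zeros((3, 4, 4))
        p[2] = 1.0  # all M
        assert dice_loss(y, p, EXACT, class_index=1) == pytest.approx(1.0)
        assert focal_tversky_loss(y, p, EXACT, class_index=1) == pytest.approx(1.0)

    def test_ftl_with_symmetric_half_weights_equals_dice(self):
        # alpha = beta = 0.5, gamma = 1: Tversky index reduces to Dice
        cfg = LossConfig(alpha=0.5, beta=0.5, gamma=1.0, smooth=0.0)
        rng = np.random.default_rng(4)
        for _ in range(10):
            y, p = random_maps(rng)
            assert focal_tversky_loss(y, p, cfg, class_index=2) == pytest.approx(
                dice_loss(y, p, cfg, class_index=2), rel=1e-10
            )

    def test_losses_bounded_unit_interval(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            y, p = random_maps(rng)
            assert 0.0 <= dice_loss(y, p, EXACT, class_index=2) <= 1.0
            assert 0.0 <= focal_tversky_loss(y, p, EXACT, class_index=2) <= 1.0


class TestInvariances:
    def test_pixel_permutation_invariance(self):
        rng = np.random.default_rng(6)
        y, p = random_maps(rng, size=6)
        perm = rng.permutation(36)
        yp = y.reshape(3, -1)[:, perm].reshape(3, 6, 6)
        pp = p.reshape(3, -1)[:, perm].reshape(3, 6, 6)
        for fn in (dice_loss, focal_tversky_loss):
            assert fn(y, p, EXACT, class_index=2) == pytest.approx(
                fn(yp, pp, EXACT, class_index=2), rel=1e-12
            )

    def test_more_overlap_means_less_loss(self):
        # increase sum(y*p) holding sum(y), sum(p) fixed
        y = np.zeros((3, 4, 4))
        y[2, 0, :2] = 1.0
        y[0] = 1.0 - y[2]
        p_low = np.zeros((3, 4, 4))
        p_low[2, 3, :2] = 0.8  # mass off target
        p_low[0] = 1.0 - p_low[2]
        p_high = np.zeros((3, 4, 4))
        p_high[2, 0, :2] = 0.8  # same mass, on target
        p_high[0] = 1.0 - p_high[2]
        for fn in (dice_loss, focal_tversky_loss):
            assert fn(y, p_high, EXACT, class_index=2) < fn(y, p_low, EXACT, class_index=2)


class TestBackgroundExclusion:
    def test_bg_channel_receives_no_gradient(self):
        rng = np.random.default_rng(7)
        y, p0 = random_maps(rng)
        p = Tensor(p0, requires_grad=True)
        loss = masked_multiclass_loss(y, p, LossConfig(smooth=0.0), base="dice")
        loss.backward()
        assert np.all(p.grad[0] == 0.0)  # excluded BG channel: exactly zero
        assert np.any(p.grad[1] != 0.0) and np.any(p.grad[2] != 0.0)

    def test_bg_perturbation_leaves_loss_unchanged(self):
        rng = np.random.default_rng(8)
        y, p = random_maps(rng)
        base = masked_multiclass_loss(y, p, EXACT, base="focal_tversky")
        p2 = p.copy()
        p2[0] += 0.1  # off-simplex on purpose: only the BG channel moves
        assert masked_multiclass_loss(y, p2, EXACT, base="focal_tversky") == base

    def test_no_exclusions_equals_plain_class_mean(self):
        rng = np.random.default_rng(9)
        y, p = random_maps(rng)
        cfg = LossConfig(excluded_classes=frozenset(), smooth=0.0)
        got = masked_multiclass_loss(y, p, cfg, base="dice")
        want = np.mean([dice_loss(y, p, cfg, class_index=c) for c in range(3)])
        assert got == pytest.approx(want, rel=1e-12)

    def test_all_excluded_raises(self):
        y, p = random_maps(np.random.default_rng(10))
        with pytest.raises(LossConfigError):
            masked_multiclass_loss(y, p, LossConfig(excluded_classes=frozenset({0, 1, 2})))


class TestErrorsAndBatching:
    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((3, 4, 4)), np.zeros((3, 4, 5)), class_index=1)

    def test_empty_masks_without_smoothing(self):
        y = np.zeros((3, 4, 4))
        p = np.zeros((3, 4, 4))
        with pytest.raises(UndefinedLossError):
            dice_loss(y, p, EXACT, class_index=2)

    def test_batch_mean_equals_mean_of_singles(self):
        rng = np.random.default_rng(11)
        pairs = [random_maps(rng) for _ in range(3)]
        yb = np.stack([y for y, _ in pairs])
        pb = np.stack([p for _, p in pairs])
        got = dice_loss(yb, pb, EXACT, class_index=2)
        want = np.mean([dice_loss(y, p, EXACT, class_index=2) for y, p in pairs])
        assert got == pytest.approx(want, rel=1e-12)

    def test_invalid_config(self):
        with pytest.raises(LossConfigError):
            LossConfig(alpha=0.0)
        with pytest.raises(LossConfigError):
            LossConfig(smooth=-1.0)
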