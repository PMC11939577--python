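"""Boundary-aware Dice loss: closed-form cases, invariants, gradient sanity."""

import math

import numpy as np
import pytest

from lusseg.autograd import Tensor
from lusseg.losses import (LossConfig, batch_boundary_aware_dice_loss,
                           boundary_aware_dice_loss, boundary_loss, dice_loss,
                           extract_boundary)


class TestDiceLoss:
    def test_perfect_overlap_is_zero(self, rng):
        target = (rng.random((8, 8)) < 0.4).astype(float)
        assert dice_loss(target, target) == pytest.approx(0.0, abs=1e-9)

    def test_empty_empty_is_zero(self):
        z = np.zeros((5, 5))
        assert dice_loss(z, z) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_halves_near_one(self):
        target = np.zeros((4, 4))
        target[:, :2] = 1
        pred = np.zeros((4, 4))
        pred[:, 2:] = 1
        eps = 1e-6
        expected = 1 - eps / (16 + eps)
        assert dice_loss(pred, target) == pytest.approx(expected, rel=1e-9)

    def test_bounded_and_symmetric_for_binary(self, rng):
        for _ in range(20):
            a = (rng.random((6, 6)) < 0.5).astype(float)
            b = (rng.random((6, 6)) < 0.5).astype(float)
            v = dice_loss(a, b)
            assert 0.0 <= v <= 1.0
            assert v == pytest.approx(dice_loss(b, a), rel=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((3, 3)), np.zeros((4, 4)))


class TestBoundaryExtraction:
    def test_empty_target(self):
        assert extract_boundary(np.zeros((6, 6))).sum() == 0

    def test_single_pixel_is_its_own_boundary(self):
        t = np.zeros((5, 5))
        t[2, 2] = 1
        np.testing.assert_array_equal(extract_boundary(t), t.astype(np.uint8))

    def test_square_perimeter(self):
        t = np.zeros((8, 8))
        t[2:6, 2:6] = 1  # 4x4 solid square: 12 rim pixels, 4 interior
        b = extract_boundary(t)
        assert b.sum() == 12
        assert b[3:5, 3:5].sum() == 0  # interior excluded

    def test_boundary_subset_of_target(self, rng):
        for _ in range(25):
            t = (rng.random((12, 12)) < 0.35).astype(np.uint8)
            b = extract_boundary(t)
            assert np.all(b <= t)
            assert b.sum() <= t.sum()

    def test_thickness(self):
        t = np.zeros((12, 12))
        t[2:10, 2:10] = 1  # 8x8 square
        b2 = extract_boundary(t, LossConfig(boundary_thickness=2))
        assert b2.sum() == 64 - 16  # two rims: 8x8 minus the 4x4 core


class TestBoundaryLoss:
    def test_empty_boundary_mask(self):
        p = np.full((4, 4), 0.7)
        t = np.ones((4, 4))
        assert boundary_loss(p, t, np.zeros((4, 4))) == 0.0

    def test_perfect_prediction_vanishes(self):
        t = np.zeros((5, 5))
        t[2, 2] = 1
        bm = extract_boundary(t)
        assert boundary_loss(t.astype(float), t, bm) < 1e-5

    def test_half_probability_single_pixel(self):
        t = np.zeros((3, 3))
        t[1, 1] = 1
        p = np.zeros((3, 3))
        p[1, 1] = 0.5
        bm = extract_boundary(t)
        assert boundary_loss(p, t, bm) == pytest.approx(math.log(2), rel=1e-6)


class TestCombinedLoss:
    def test_lambda_zero_reduces_to_dice(self, rng):
        p = rng.random((6, 6))
        t = (rng.random((6, 6)) < 0.4).astype(float)
        cfg = LossConfig(lambda_boundary=0.0)
        assert boundary_aware_dice_loss(p, t, cfg) == pytest.approx(
            dice_loss(p, t, cfg), rel=1e-12)

    def test_perfect_prediction_is_zero(self):
        t = np.zeros((6, 6))
        t[2:4, 1:5] = 1
        assert boundary_aware_dice_loss(t.astype(float), t) < 1e-4

    def test_monotone_in_lambda(self, rng):
        p = np.clip(rng.random((8, 8)), 0.05, 0.95)
        t = (rng.random((8, 8)) < 0.4).astype(float)
        vals = [boundary_aware_dice_loss(p, t, LossConfig(lambda_boundary=lam))
                for lam in (0.5, 1.0, 2.0)]
        assert vals[0] < vals[1] < vals[2]

    def test_batch_form_matches_per_image_mean(self, rng):
        probs = rng.random((4, 10, 10)).astype(np.float32)
        targets = (rng.random((4, 10, 10)) < 0.3).astype(np.float32)
        batch = float(batch_boundary_aware_dice_loss(
            Tensor(probs), targets).data)
        per_image = np.mean([boundary_aware_dice_loss(probs[i], targets[i])
                             for i in range(4)])
        assert batch == pytest.approx(per_image, rel=1e-5)

    def test_loss_decreases_along_gradient(self):
        """One-step gradient descent on a toy problem reduces the loss."""
        t = np.zeros((5, 5), dtype=np.float32)
        t[1:4, 1:4] = 1
        logits = Tensor(np.zeros((1, 5, 5), dtype=np.float32),
                        requires_grad=True)
        loss = batch_boundary_aware_dice_loss(logits.sigmoid(), t[None])
        loss.backward()
        before = float(loss.data)
        stepped = Tensor(logits.data - 1.0 * logits.grad)
        after = float(batch_boundary_aware_dice_loss(
            stepped.sigmoid(), t[None]).data)
        assert after < before
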