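"""Evaluation metrics: hand-enumerated cases, algebraic identities, HD oracle."""

import math

import numpy as np
import pytest

from lusseg.metrics import (ConfusionCounts, aggregate_reports,
                            confusion_counts, evaluate_pair,
                            hausdorff_distance, overlap_metrics)


def brute_force_hausdorff(a_pts: np.ndarray, b_pts: np.ndarray) -> float:
    """O(|A| x |B|) double loop over the point sets (independent oracle)."""
    d = np.sqrt(((a_pts[:, None, :] - b_pts[None, :, :]) ** 2).sum(-1))
    return max(d.min(axis=1).max(), d.min(axis=0).max())


class TestConfusion:
    def test_all_ones(self):
        m = np.ones((2, 2), dtype=np.uint8)
        assert confusion_counts(m, m) == ConfusionCounts(4, 0, 0, 0)

    def test_all_wrong(self):
        p = np.ones((2, 2), dtype=np.uint8)
        t = np.zeros((2, 2), dtype=np.uint8)
        assert confusion_counts(p, t) == ConfusionCounts(0, 4, 0, 0)

    def test_row_vs_column(self):
        t = np.zeros((3, 3), dtype=np.uint8)
        t[0, :] = 1           # top row
        p = np.zeros((3, 3), dtype=np.uint8)
        p[:, 0] = 1           # left column
        assert confusion_counts(p, t) == ConfusionCounts(1, 2, 2, 4)

    def test_counts_sum_to_total(self, rng):
        p = (rng.random((7, 9)) < 0.5).astype(np.uint8)
        t = (rng.random((7, 9)) < 0.5).astype(np.uint8)
        assert confusion_counts(p, t).total == 63

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(np.full((2, 2), 0.5), np.zeros((2, 2)))


class TestOverlapMetrics:
    def test_identical_masks_all_one(self, rng):
        m = (rng.random((10, 10)) < 0.4).astype(np.uint8)
        m[0, 0] = 1  # non-empty
        r = overlap_metrics(m, m)
        for name in ("dice", "sensitivity", "specificity", "precision",
                     "f1", "iou"):
            assert getattr(r, name) == pytest.approx(1.0)

    def test_hand_computed_counts(self):
        t = np.zeros((3, 3), dtype=np.uint8)
        t[0, :] = 1
        p = np.zeros((3, 3), dtype=np.uint8)
        p[:, 0] = 1
        r = overlap_metrics(p, t)  # tp=1 fp=2 fn=2 tn=4
        assert r.dice == pytest.approx(2 / 6)
        assert r.iou == pytest.approx(1 / 5)
        assert r.precision == pytest.approx(1 / 3)
        assert r.sensitivity == pytest.approx(1 / 3)
        assert r.specificity == pytest.approx(4 / 6)
        assert r.f1 == pytest.approx(1 / 3)

    def test_dice_f1_iou_identities(self, rng):
        for _ in range(30):
            p = (rng.random((8, 8)) < 0.5).astype(np.uint8)
            t = (rng.random((8, 8)) < 0.5).astype(np.uint8)
            r = overlap_metrics(p, t)
            assert r.dice == pytest.approx(r.f1, abs=1e-12)
            assert r.dice == pytest.approx(2 * r.iou / (1 + r.iou), abs=1e-12)
            assert r.iou <= r.dice + 1e-12

    def test_padding_invariance_of_foreground_metrics(self, rng):
        p = (rng.random((6, 6)) < 0.5).astype(np.uint8)
        t = (rng.random((6, 6)) < 0.5).astype(np.uint8)
        r0 = overlap_metrics(p, t)
        r1 = overlap_metrics(np.pad(p, 4), np.pad(t, 4))
        for name in ("dice", "sensitivity", "precision", "f1", "iou"):
            assert getattr(r0, name) == pytest.approx(getattr(r1, name))

    def test_both_empty_scores_one(self):
        z = np.zeros((4, 4), dtype=np.uint8)
        r = overlap_metrics(z, z)
        assert r.dice == 1.0 and r.iou == 1.0 and r.degenerate


class TestHausdorff:
    def test_identical_masks_zero(self, rng):
        m = (rng.random((10, 10)) < 0.3).astype(np.uint8)
        m[4, 4] = 1
        assert hausdorff_distance(m, m) == 0.0

    def test_three_four_five(self):
        a = np.zeros((6, 6), dtype=np.uint8)
        a[0, 0] = 1
        b = np.zeros((6, 6), dtype=np.uint8)
        b[3, 4] = 1
        assert hausdorff_distance(a, b) == pytest.approx(5.0)

    def test_max_of_min_asymmetry(self):
        a = np.zeros((12, 12), dtype=np.uint8)
        a[0, 0] = a[10, 0] = 1   # A = {(0,0), (10,0)}
        b = np.zeros((12, 12), dtype=np.uint8)
        b[0, 0] = 1              # B = {(0,0)}
        assert hausdorff_distance(a, b) == pytest.approx(10.0)
        assert hausdorff_distance(b, a) == pytest.approx(10.0)  # symmetric

    def test_empty_mask_gives_nan_with_warning(self):
        m = np.zeros((4, 4), dtype=np.uint8)
        n = m.copy()
        n[1, 1] = 1
        with pytest.warns(UserWarning):
            assert math.isnan(hausdorff_distance(m, n))

    def test_matches_brute_force_on_random_masks(self, rng):
        """Exact agreement with the double-loop oracle on random mask pairs."""
        for _ in range(40):
            shape = (int(rng.integers(4, 33)), int(rng.integers(4, 33)))
            p = (rng.random(shape) < 0.25).astype(np.uint8)
            t = (rng.random(shape) < 0.25).astype(np.uint8)
            if not p.any() or not t.any():
                continue
            got = hausdorff_distance(p, t, on_boundary=False)
            want = brute_force_hausdorff(np.argwhere(p).astype(float),
                                         np.argwhere(t).astype(float))
            assert got == pytest.approx(want, abs=0)


def test_aggregate_skips_undefined_hausdorff(rng):
    m = (rng.random((8, 8)) < 0.4).astype(np.uint8)
    m[3, 3] = 1
    z = np.zeros((8, 8), dtype=np.uint8)
    reports = [evaluate_pair(m, m), evaluate_pair(z, m)]
    # evaluate_pair never computes HD for the empty pred; it stays NaN
    assert math.isnan(reports[1].hausdorff)
    agg = aggregate_reports(reports)
    assert agg["n_hausdorff_defined"] == 1
    assert agg["hausdorff_mean"] == 0.0
    assert agg["dice_mean"] == pytest.approx(0.5)
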