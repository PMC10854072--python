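"""Objective and metric arithmetic against closed forms and set oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mducnn.metrics import (SegmentationSample, aggregate_folds, batch_loss,
                            binarize, comparative_increase, jaccard, pixel_bce)


class TestPixelBCE:
    def test_perfect_prediction_is_tiny(self):
        b = (np.random.default_rng(0).random((16, 16)) > 0.5).astype(float)
        loss = pixel_bce(b, b)
        assert 0.0 <= loss <= 10 * 1e-7 * b.size

    def test_single_pixel_half_confidence(self):
        assert pixel_bce(np.array([1.0]), np.array([0.5])) == pytest.approx(
            math.log(2), abs=1e-9)

    def test_two_pixel_additivity(self):
        loss = pixel_bce(np.array([1.0, 0.0]), np.array([0.5, 0.5]), "sum")
        assert loss == pytest.approx(2 * math.log(2), abs=1e-9)

    def test_sum_equals_mean_times_pixels(self, rng):
        b = (rng.random((7, 9)) > 0.5).astype(float)
        p = rng.random((7, 9))
        assert pixel_bce(b, p, "sum") == pytest.approx(
            pixel_bce(b, p, "mean") * b.size, rel=1e-12)

    def test_monotone_toward_truth(self):
        """Loss strictly decreases as the prediction approaches the label."""
        for b in (0.0, 1.0):
            preds = np.linspace(0.05, 0.95, 10)
            losses = [pixel_bce(np.array([b]), np.array([p])) for p in preds]
            diffs = np.diff(losses)
            assert np.all(diffs < 0) if b == 1.0 else np.all(diffs > 0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            pixel_bce(np.zeros((2, 2)), np.zeros((2, 3)))

    def test_accepts_sample(self, rng):
        mask = (rng.random((4, 4)) > 0.5).astype(np.uint8)
        s = SegmentationSample(image=rng.random((4, 4, 1)).astype(np.float32),
                               mask=mask)
        p = rng.random((4, 4))
        assert pixel_bce(s, p) == pixel_bce(mask, p)


class TestBatchLoss:
    def test_singleton_equals_pixel_bce(self, rng):
        b = (rng.random((5, 5)) > 0.5).astype(float)
        p = rng.random((5, 5))
        assert batch_loss([b], [p]) == pixel_bce(b, p)

    def test_mean_of_losses(self, rng):
        bs = [(rng.random((6, 6)) > 0.5).astype(float) for _ in range(4)]
        ps = [rng.random((6, 6)) for _ in range(4)]
        expected = np.mean([pixel_bce(b, p) for b, p in zip(bs, ps)])
        assert batch_loss(bs, ps) == pytest.approx(expected, rel=1e-12)

    def test_duplicated_batch_invariance(self, rng):
        bs = [(rng.random((4, 4)) > 0.5).astype(float) for _ in range(3)]
        ps = [rng.random((4, 4)) for _ in range(3)]
        assert batch_loss(bs + bs, ps + ps) == pytest.approx(
            batch_loss(bs, ps), rel=1e-12)

    def test_empty_batch(self):
        with pytest.raises(ValueError):
            batch_loss([], [])


class TestBinarize:
    def test_above_below_and_tie(self):
        assert binarize(np.full((3, 3), 0.7)).all()
        assert not binarize(np.full((3, 3), 0.3)).any()
        assert binarize(np.full((3, 3), 0.5)).all()  # ties to foreground

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((2, 2)), threshold=0.0)


def jaccard_set_oracle(x, y):
    xs = {tuple(i) for i in np.argwhere(x)}
    ys = {tuple(i) for i in np.argwhere(y)}
    if not xs and not ys:
        return 1.0
    return len(xs & ys) / len(xs | ys)


class TestJaccard:
    def test_identity_and_disjoint(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        a[:2] = 1
        b = np.zeros((4, 4), dtype=np.uint8)
        b[2:] = 1
        assert jaccard(a, a) == 1.0
        assert jaccard(a, b) == 0.0

    def test_counting_example(self):
        x = np.zeros(10, dtype=np.uint8)
        y = np.zeros(10, dtype=np.uint8)
        x[:6] = 1
        y[3:7] = 1  # overlap 3, union 7
        assert jaccard(x, y) == pytest.approx(3 / 7)

    def test_both_empty_convention(self):
        z = np.zeros((3, 3), dtype=np.uint8)
        assert jaccard(z, z) == 1.0

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.integers(0, 2 ** 16 - 1), st.integers(0, 2 ** 16 - 1))
    def test_matches_set_oracle(self, seed_x, seed_y):
        x = (np.random.default_rng(seed_x).random((4, 4)) > 0.6).astype(np.uint8)
        y = (np.random.default_rng(seed_y).random((4, 4)) > 0.6).astype(np.uint8)
        assert jaccard(x, y) == pytest.approx(jaccard_set_oracle(x, y), abs=1e-12)
        assert jaccard(x, y) == jaccard(y, x)
        assert 0.0 <= jaccard(x, y) <= 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            jaccard(np.zeros((2, 2)), np.zeros((3, 2)))


class TestReportArithmetic:
    def test_constant_folds(self):
        assert aggregate_folds([80, 80, 80]) == (80.0, 0.0)

    @pytest.mark.parametrize("folds,mean", [
        ([74.11, 72.67, 73.89, 75.22, 76.07], 74.392),
        ([82.25, 79.43, 83.16, 81.02, 85.08], 82.188),
    ])
    def test_published_fold_means(self, folds, mean):
        m, s = aggregate_folds(folds)
        assert m == pytest.approx(mean, abs=1e-9)
        assert s == pytest.approx(np.std(folds, ddof=1), rel=1e-12)

    def test_needs_two_folds(self):
        with pytest.raises(ValueError):
            aggregate_folds([80.0])

    @pytest.mark.parametrize("proposed,traditional,expected", [
        (83.1567, 72.9190, 10.2377),
        (81.3188, 76.1256, 5.1932),
        (55.5, 55.5, 0.0),
    ])
    def test_comparative_increase(self, proposed, traditional, expected):
        assert comparative_increase(proposed, traditional) == pytest.approx(
            expected, abs=1e-9)


class TestSegmentationSample:
    def test_rejects_nonbinary_mask(self, rng):
        with pytest.raises(ValueError):
            SegmentationSample(image=rng.random((4, 4, 1)),
                               mask=rng.random((4, 4)))

    def test_rejects_mismatched_extents(self, rng):
        with pytest.raises(ValueError):
            SegmentationSample(image=rng.random((4, 4, 1)),
                               mask=np.zeros((4, 5), dtype=np.uint8))
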