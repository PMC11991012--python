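"""Masked pooling, anomaly scoring, soft thresholding and the Dice metric."""

import numpy as np
import pytest

from dcopnet.autodiff import Tensor
from dcopnet.errors import DegeneratePrototype, EmptyMask, ShapeMismatch
from dcopnet.protomath import (anomaly_score_map, dice_score,
                               downsample_mask_nearest, masked_average_pool,
                               soft_threshold_mask, upsample_bilinear)


def pool_oracle(F, M):
    """Explicit double-loop weighted mean."""
    C, H, W = F.shape
    num = np.zeros(C)
    den = 0.0
    for h in range(H):
        for w in range(W):
            num += F[:, h, w] * M[h, w]
            den += M[h, w]
    return num / den


class TestMaskedAveragePool:
    def test_matches_double_loop_oracle_on_random_draws(self, rng):
        for _ in range(100):
            F = rng.normal(size=(5, 6, 7))
            M = rng.random((6, 7))
            got = masked_average_pool(Tensor(F), Tensor(M)).data
            np.testing.assert_allclose(got, pool_oracle(F, M), atol=1e-6)

    def test_constant_features_pool_to_the_constant(self, rng):
        c = np.array([1.5, -2.0, 0.25])
        F = np.broadcast_to(c[:, None, None], (3, 4, 4)).copy()
        M = (rng.random((4, 4)) > 0.5).astype(float)
        M[0, 0] = 1.0
        np.testing.assert_allclose(
            masked_average_pool(Tensor(F), Tensor(M)).data, c)

    def test_known_weighted_mean(self):
        F = np.array([[[1.0, 3.0], [5.0, 7.0]]])
        M = np.array([[1.0, 1.0], [0.0, 0.0]])
        assert masked_average_pool(Tensor(F), Tensor(M)).data == \
            pytest.approx(2.0)

    def test_all_ones_mask_is_spatial_mean(self, rng):
        F = rng.normal(size=(4, 5, 5))
        got = masked_average_pool(Tensor(F), Tensor(np.ones((5, 5)))).data
        np.testing.assert_allclose(got, F.mean(axis=(1, 2)))

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMask):
            masked_average_pool(Tensor(np.ones((2, 3, 3))),
                                Tensor(np.zeros((3, 3))))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ShapeMismatch):
            masked_average_pool(Tensor(np.ones((2, 3, 3))),
                                Tensor(np.ones((4, 4))))

    def test_differentiable_in_features_and_mask(self, rng):
        F = Tensor(rng.normal(size=(3, 4, 4)), requires_grad=True)
        M = Tensor(rng.random((4, 4)), requires_grad=True)
        masked_average_pool(F, M).sum().backward()
        assert np.isfinite(F.grad).all() and np.isfinite(M.grad).all()


class TestAnomalyScore:
    def test_identical_antiparallel_orthogonal(self):
        p = np.array([1.0, 2.0, 2.0])
        F = np.stack([p, -p, np.array([2.0, -1.0, 0.0])], axis=1)[:, :, None]
        S = anomaly_score_map(Tensor(F), Tensor(p)).data.ravel()
        np.testing.assert_allclose(S, [-20.0, 20.0, 0.0], atol=1e-5)

    def test_bounded_by_alpha(self, rng):
        S = anomaly_score_map(Tensor(rng.normal(size=(8, 5, 5))),
                              Tensor(rng.normal(size=8)), alpha=20.0)
        assert np.abs(S.data).max() <= 20.0 + 1e-12

    def test_prototype_scale_invariance(self, rng):
        F = Tensor(rng.normal(size=(6, 4, 4)))
        p = rng.normal(size=6)
        a = anomaly_score_map(F, Tensor(p)).data
        b = anomaly_score_map(F, Tensor(37.5 * p)).data
        np.testing.assert_allclose(a, b, atol=1e-5)

    def test_zero_norm_pixels_score_zero_not_nan(self):
        F = np.zeros((3, 2, 2))
        S = anomaly_score_map(Tensor(F), Tensor(np.ones(3))).data
        assert np.isfinite(S).all()
        np.testing.assert_allclose(S, 0.0)

    def test_degenerate_prototype_raises(self):
        with pytest.raises(DegeneratePrototype):
            anomaly_score_map(Tensor(np.ones((3, 2, 2))),
                              Tensor(np.zeros(3)))


class TestSoftThreshold:
    def test_half_at_threshold_and_closed_form(self):
        S = Tensor(np.array([[0.0, -10.0]]))
        M = soft_threshold_mask(S, 0.0, steepness=0.5).data
        assert M[0, 0] == pytest.approx(0.5)
        assert M[0, 1] == pytest.approx(0.99330714907, abs=1e-5)

    def test_strictly_decreasing_and_saturating(self):
        # strict decrease over the anomaly-score range; saturation beyond
        S = np.linspace(-20, 20, 201)
        M = soft_threshold_mask(Tensor(S[None]), -10.0).data.ravel()
        assert (np.diff(M) < 0).all()
        far = soft_threshold_mask(Tensor([[1e4, -1e4]]), 0.0).data.ravel()
        assert far[0] == pytest.approx(0.0, abs=1e-12)
        assert far[1] == pytest.approx(1.0, abs=1e-12)

    def test_chain_with_anomaly_score_is_differentiable(self, rng):
        F = Tensor(rng.normal(size=(4, 3, 3)), requires_grad=True)
        p = Tensor(rng.normal(size=4), requires_grad=True)
        S = anomaly_score_map(F, p)
        soft_threshold_mask(S, -10.0).sum().backward()
        assert np.isfinite(F.grad).all() and np.isfinite(p.grad).all()
        assert np.abs(F.grad).sum() > 0


class TestDice:
    def test_basic_cases(self):
        a = np.zeros((4, 4)); a[:2] = 1
        assert dice_score(a, a) == 100.0
        b = np.zeros((4, 4)); b[3:] = 1
        assert dice_score(a, b) == 0.0
        assert dice_score(np.zeros((3, 3)), np.zeros((3, 3))) == 100.0

    def test_partial_overlap_2_2_1(self):
        a = np.array([[1, 1, 0, 0]])
        b = np.array([[0, 1, 1, 0]])
        assert dice_score(a, b) == pytest.approx(50.0)

    def test_symmetric_and_matches_set_count_oracle(self, rng):
        for _ in range(100):
            a = rng.random((8, 8)) > 0.6
            b = rng.random((8, 8)) > 0.6
            d = dice_score(a, b)
            assert d == dice_score(b, a)
            inter = np.sum(a & b)
            expect = 100.0 if a.sum() + b.sum() == 0 else \
                200.0 * inter / (a.sum() + b.sum())
            assert d == pytest.approx(expect)


class TestResampling:
    def test_nearest_downsample_preserves_binaryness(self, rng):
        m = (rng.random((64, 64)) > 0.5).astype(float)
        d = downsample_mask_nearest(m, (8, 8))
        assert set(np.unique(d)) <= {0.0, 1.0}
        assert d.shape == (8, 8)

    def test_bilinear_upsample_is_differentiable_and_bounded(self, rng):
        m = Tensor(rng.random((8, 8)), requires_grad=True)
        up = upsample_bilinear(m, (64, 64))
        assert up.shape == (64, 64)
        assert up.data.min() >= 0.0 and up.data.max() <= 1.0
        up.sum().backward()
        assert np.isfinite(m.grad).all()

    def test_upsample_of_constant_is_constant(self):
        up = upsample_bilinear(Tensor(np.full((4, 4), 0.3)), (16, 16))
        np.testing.assert_allclose(up.data, 0.3)
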