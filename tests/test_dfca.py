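"""Dual-filter cross attention: prior mask, fusion, score filter, FCA."""

import numpy as np
import pytest

from dcopnet.autodiff import Tensor
from dcopnet.dfca import (DFCAModule, FusionConv, ProjectionWeights,
                          fca_enhance, filter_scores, fuse_features,
                          generate_prior_mask)
from dcopnet.nn import masked_softmax


class TestPriorMaskGeneration:
    def test_closed_form_chain_for_prototype_matching_pixel(self, rng):
        # a query pixel whose feature equals the pooled prototype scores
        # -alpha, and the shifted sigmoid at Ta=-10 gives ~0.9933
        F = rng.normal(size=(6, 4, 4))
        M = np.zeros((4, 4)); M[1, 2] = 1.0
        proto, prior = generate_prior_mask(Tensor(F), Tensor(M), Tensor(F))
        np.testing.assert_allclose(proto.data, F[:, 1, 2])
        assert prior.data[1, 2] == pytest.approx(0.99330714907, abs=1e-4)

    def test_score_at_threshold_gives_half(self, rng):
        F = rng.normal(size=(3, 2, 2))
        M = np.ones((2, 2))
        proto, _ = generate_prior_mask(Tensor(F), Tensor(M), Tensor(F))
        from dcopnet.protomath import anomaly_score_map, soft_threshold_mask
        S = anomaly_score_map(Tensor(F), proto)
        mask = soft_threshold_mask(S, float(S.data[0, 0]))
        assert mask.data[0, 0] == pytest.approx(0.5)


class TestFuseFeatures:
    def test_identity_selection_projection_recovers_features(self, rng):
        C = 5
        fusion = FusionConv(C, rng)
        # 1x1 conv weight (C, 2C+1): select the first C input channels
        fusion.conv.weight.data = np.eye(C, 2 * C + 1)
        fusion.conv.bias.data[:] = 0.0
        F = rng.normal(size=(C, 3, 3))
        out = fuse_features(Tensor(F), Tensor(rng.normal(size=C)),
                            Tensor(rng.random((3, 3))), fusion)
        np.testing.assert_allclose(out.data, F)

    def test_preserves_geometry_and_is_deterministic(self, rng):
        C = 4
        fusion = FusionConv(C, rng)
        F = Tensor(rng.normal(size=(C, 5, 7)))
        p = Tensor(rng.normal(size=C))
        M = Tensor(rng.random((5, 7)))
        a = fuse_features(F, p, M, fusion)
        b = fuse_features(F, p, M, fusion)
        assert a.shape == (C, 5, 7)
        assert np.array_equal(a.data, b.data)


class TestFilterScores:
    def test_known_example_only_max_survives(self):
        raw = Tensor(np.array([[1.0, 2.0, 3.0, 10.0]]))
        fs = filter_scores(raw)
        assert fs.v_filter == pytest.approx(7.0)
        np.testing.assert_array_equal(fs.keep,
                                      [[False, False, False, True]])

    def test_constant_matrix_fallback_keeps_everything(self):
        fs = filter_scores(Tensor(np.full((3, 4), 2.5)))
        assert fs.keep.all()

    def test_global_max_always_survives(self, rng):
        for _ in range(50):
            data = rng.normal(size=(6, 6))
            if np.ptp(data) == 0:
                continue
            fs = filter_scores(Tensor(data))
            assert fs.keep.ravel()[data.argmax()]

    def test_v_filter_matches_brute_force_and_rows_never_starve(self, rng):
        # fuzz including constant and single-element matrices
        cases = [rng.normal(size=(rng.integers(1, 8), rng.integers(1, 8)))
                 for _ in range(1000)]
        cases += [np.zeros((3, 3)), np.full((2, 2), -4.0), np.array([[7.0]])]
        for data in cases:
            fs = filter_scores(Tensor(data))
            assert fs.v_filter == pytest.approx(
                (data.max() + data.mean()) / 2.0, abs=1e-6)
            sm = masked_softmax(Tensor(data), fs.keep, axis=1).data
            assert np.isfinite(sm).all()
            np.testing.assert_allclose(sm.sum(axis=1), 1.0, atol=1e-12)
            # every survivor exceeds the filter value, except tie fallback
            starved_rows = ~((data > fs.v_filter).any(axis=1))
            survivors = fs.keep & ~starved_rows[:, None]
            assert (data[survivors] > fs.v_filter).all()


class TestFCAEnhance:
    def _inputs(self, rng, C=4, hw=3):
        Fs = Tensor(rng.normal(size=(C, hw, hw)))
        Fq = Tensor(rng.normal(size=(C, hw, hw)))
        Ms = (rng.random((hw, hw)) > 0.4).astype(float)
        Ms[0, 0] = 1.0
        Mq = rng.random((hw, hw)) * 0.9 + 0.05
        return Fs, Ms, Fq, Mq

    def test_background_pixels_keep_fused_features(self, rng):
        Fs, Ms, Fq, Mq = self._inputs(rng)
        ws, wq = ProjectionWeights(4, rng), ProjectionWeights(4, rng)
        s_enh, _ = fca_enhance(Fs, Ms, Fq, Mq, ws, wq)
        bg = Ms == 0.0
        np.testing.assert_allclose(s_enh.data[:, bg], Fs.data[:, bg])

    def test_symmetry_under_identical_inputs_and_shared_weights(self, rng):
        Fs, _, _, Mq = self._inputs(rng)
        shared = ProjectionWeights(4, rng)
        s_enh, q_enh = fca_enhance(Fs, Mq, Fs, Mq, shared, shared)
        np.testing.assert_allclose(s_enh.data, q_enh.data)

    def test_zero_mask_key_tokens_cannot_influence_output(self, rng):
        # first-filter guarantee: a support pixel with mask weight 0
        # contributes nothing to the query-enhancing attention
        Fs, Ms, Fq, Mq = self._inputs(rng)
        ws, wq = ProjectionWeights(4, rng), ProjectionWeights(4, rng)
        Ms[1, 1] = 0.0
        _, q1 = fca_enhance(Fs, Ms, Fq, Mq, ws, wq)
        Fs2 = Tensor(Fs.data.copy())
        Fs2.data[:, 1, 1] = 123.0   # arbitrary junk behind the zero mask
        _, q2 = fca_enhance(Fs2, Ms, Fq, Mq, ws, wq)
        np.testing.assert_allclose(q1.data, q2.data, atol=1e-10)


class TestDFCAForward:
    def test_output_shapes_and_determinism(self, rng, episode, model):
        fs = model.encoder(episode.support_images[0])
        fq = model.encoder(episode.query_images[0])
        from dcopnet.protomath import downsample_mask_nearest
        ms = downsample_mask_nearest(episode.support_masks[0], (8, 8))
        dfca = DFCAModule(64, np.random.default_rng(0))
        s1, q1, prior1, _ = dfca(fs, ms, fq)
        s2, q2, prior2, _ = dfca(fs, ms, fq)
        assert s1.shape == q1.shape == (64, 8, 8)
        assert prior1.shape == (8, 8)
        assert np.array_equal(s1.data, s2.data)
        assert np.array_equal(prior1.data, prior2.data)

    def test_gradients_reach_encoder_parameters(self, episode, model):
        model.zero_grad()
        out = model(episode.support_images[0], episode.support_masks[0],
                    episode.query_images[0])
        out.pred_mask_feat.sum().backward()
        g = model.encoder.conv1.weight.grad
        assert g is not None and np.isfinite(g).all() and np.abs(g).sum() > 0
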