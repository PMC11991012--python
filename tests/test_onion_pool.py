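"""Onion pooling: erosion oracle, nesting, prototypes, self-attention mixing."""

import numpy as np
import pytest

from dcopnet.autodiff import Tensor
from dcopnet.dfca import ProjectionWeights
from dcopnet.errors import EmptyMask
from dcopnet.onion_pool import (build_onion_masks, erode_mask,
                                extract_prototypes, mix_prototypes)
from dcopnet.protomath import masked_average_pool


def erosion_oracle(mask):
    """Brute-force 2x2 erosion, top-left anchor, out-of-bounds = background."""
    m = np.asarray(mask) > 0.5
    H, W = m.shape
    out = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            ok = True
            for di in (0, 1):
                for dj in (0, 1):
                    ii, jj = i + di, j + dj
                    if ii >= H or jj >= W or not m[ii, jj]:
                        ok = False
            out[i, j] = 1.0 if ok else 0.0
    return out


class TestErodeMask:
    def test_matches_brute_force_oracle_bit_for_bit(self, rng):
        for _ in range(200):
            m = (rng.random((32, 32)) > rng.uniform(0.3, 0.7)).astype(float)
            np.testing.assert_array_equal(erode_mask(m), erosion_oracle(m))

    def test_all_ones_4x4_erodes_to_3x3_block(self):
        out = erode_mask(np.ones((4, 4)))
        expect = np.zeros((4, 4))
        expect[:3, :3] = 1.0
        np.testing.assert_array_equal(out, expect)

    def test_empty_and_single_pixel(self):
        np.testing.assert_array_equal(erode_mask(np.zeros((5, 5))),
                                      np.zeros((5, 5)))
        single = np.zeros((5, 5)); single[2, 2] = 1.0
        np.testing.assert_array_equal(erode_mask(single), np.zeros((5, 5)))

    def test_top_left_bias_on_interior_square(self):
        # a solid square away from the last row/col loses exactly its
        # bottom/right boundary under the top-left anchor convention
        m = np.zeros((8, 8)); m[1:5, 1:5] = 1.0
        out = erode_mask(m)
        np.testing.assert_array_equal(out, erosion_oracle(m))
        assert out[1:4, 1:4].all() and out.sum() == 9


class TestBuildOnionMasks:
    def test_20px_square_on_32_grid_hits_the_layer_cap(self):
        m = np.zeros((32, 32)); m[5:25, 5:25] = 1.0
        layers = build_onion_masks(m, n_max=4)
        assert len(layers) == 4
        np.testing.assert_array_equal(layers[0], m)

    def test_single_pixel_yields_one_layer(self):
        m = np.zeros((8, 8)); m[3, 3] = 1.0
        assert len(build_onion_masks(m)) == 1

    def test_nesting_nonemptiness_and_cap_on_random_masks(self, rng):
        for _ in range(100):
            m = (rng.random((16, 16)) > 0.5).astype(float)
            if m.sum() == 0:
                m[0, 0] = 1.0
            layers = build_onion_masks(m, n_max=4)
            assert 1 <= len(layers) <= 4
            for j in range(len(layers) - 1):
                inner, outer = layers[j + 1], layers[j]
                assert inner.sum() > 0
                assert np.all(outer[inner > 0] > 0)   # strict nesting
                assert inner.sum() <= outer.sum()

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMask):
            build_onion_masks(np.zeros((8, 8)))

    def test_exclude_base_layer_starts_from_first_erosion(self):
        m = np.zeros((8, 8)); m[1:6, 1:6] = 1.0
        layers = build_onion_masks(m, include_base_layer=False)
        np.testing.assert_array_equal(layers[0], erosion_oracle(m))


class TestExtractPrototypes:
    def test_matches_per_layer_pooling_oracle(self, rng):
        F = Tensor(rng.normal(size=(5, 16, 16)))
        m = np.zeros((16, 16)); m[2:12, 3:13] = 1.0
        layers = build_onion_masks(m)
        protos = extract_prototypes(F, layers)
        assert len(protos) == len(layers)
        for p, layer in zip(protos, layers):
            expect = masked_average_pool(F, Tensor(layer)).data
            np.testing.assert_allclose(p.data, expect, atol=1e-6)

    def test_constant_features_give_identical_prototypes(self):
        F = Tensor(np.full((3, 8, 8), 2.5))
        m = np.zeros((8, 8)); m[1:7, 1:7] = 1.0
        for p in extract_prototypes(F, build_onion_masks(m)):
            np.testing.assert_allclose(p.data, 2.5)

    def test_single_layer_reduces_to_plain_map(self, rng):
        F = Tensor(rng.normal(size=(4, 8, 8)))
        m = np.zeros((8, 8)); m[4, 4] = 1.0
        protos = extract_prototypes(F, build_onion_masks(m))
        np.testing.assert_allclose(protos[0].data, F.data[:, 4, 4])


class TestMixPrototypes:
    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_count_preserved(self, rng, n):
        proj = ProjectionWeights(6, rng)
        protos = [Tensor(rng.normal(size=6)) for _ in range(n)]
        assert len(mix_prototypes(protos, proj)) == n

    def test_singleton_equals_value_projection(self, rng):
        proj = ProjectionWeights(6, rng)
        p = Tensor(rng.normal(size=6))
        out = mix_prototypes([p], proj)[0]
        np.testing.assert_allclose(out.data, proj.v(p).data, atol=1e-12)

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_permutation_equivariance(self, rng, n):
        proj = ProjectionWeights(5, rng)
        protos = [Tensor(rng.normal(size=5)) for _ in range(n)]
        perm = list(rng.permutation(n))
        mixed = mix_prototypes(protos, proj)
        mixed_perm = mix_prototypes([protos[i] for i in perm], proj)
        for k, i in enumerate(perm):
            np.testing.assert_allclose(mixed_perm[k].data, mixed[i].data,
                                       atol=1e-6)
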