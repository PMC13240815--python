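import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from treeparse3d.io_formats import CrownAnnotationSet, ValidationError
from treeparse3d.mde import (
    MDEConfig, MDEncoder, annotation_descriptor, entangle, fuse,
    trilinear_weights,
)


@pytest.fixture(scope="module")
def encoder():
    return MDEncoder(MDEConfig(seed=7))


def _square(cx, cy, r=1.0):
    return np.array([[cx - r, cy - r], [cx + r, cy - r],
                     [cx + r, cy + r], [cx - r, cy + r]])


@pytest.fixture(scope="module")
def two_crown_ann():
    return CrownAnnotationSet(
        polygons=[(1, _square(0, 0)), (2, _square(5, 0, 1.5))],
        class_labels={1: "crown", 2: "crown"})


class TestTrilinear:
    @pytest.mark.parametrize("coord,hot", [
        ((0, 0, 0), 0), ((1, 0, 0), 1), ((0, 1, 0), 2), ((1, 1, 0), 3),
        ((0, 0, 1), 4), ((1, 0, 1), 5), ((0, 1, 1), 6), ((1, 1, 1), 7),
    ])
    def test_corner_one_hot(self, coord, hot):
        w = trilinear_weights(np.array([coord], dtype=float))[0]
        expected = np.zeros(8)
        expected[hot] = 1.0
        np.testing.assert_allclose(w, expected)

    def test_center_uniform(self):
        w = trilinear_weights(np.array([[0.5, 0.5, 0.5]]))[0]
        np.testing.assert_allclose(w, 1 / 8)

    def test_nan_rejected(self):
        with pytest.raises(ValidationError):
            trilinear_weights(np.array([[0.1, np.nan, 0.2]]))

    def test_outside_cube_clamped(self):
        w = trilinear_weights(np.array([[-0.5, 2.0, 0.5]]))
        np.testing.assert_allclose(w.sum(), 1.0)

    @settings(derandomize=True, max_examples=50)
    @given(hnp.arrays(np.float64, (20, 3),
                      elements=st.floats(0, 1, allow_nan=False)))
    def test_partition_of_unity(self, coords):
        w = trilinear_weights(coords)
        assert (w >= 0).all() and (w <= 1).all()
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-6)


class TestFuse:
    def test_corner_reproduces_vertex(self, rng):
        h = rng.normal(size=(8, 16))
        w = trilinear_weights(np.array([[0.0, 0.0, 0.0]]))
        np.testing.assert_allclose(fuse(h, w)[0], h[0])

    def test_center_is_vertex_mean(self, rng):
        h = rng.normal(size=(8, 16))
        w = trilinear_weights(np.array([[0.5, 0.5, 0.5]]))
        np.testing.assert_allclose(fuse(h, w)[0], h.mean(axis=0), atol=1e-12)

    def test_matches_loop_oracle(self, rng):
        h = rng.normal(size=(8, 5))
        coords = rng.uniform(size=(30, 3))
        w = trilinear_weights(coords)
        oracle = np.array([[sum(w[n, v] * h[v, d] for v in range(8))
                            for d in range(5)] for n in range(30)])
        np.testing.assert_allclose(fuse(h, w), oracle, atol=1e-6)

    def test_linear_in_template(self, rng):
        h1 = rng.normal(size=(8, 4))
        h2 = rng.normal(size=(8, 4))
        w = trilinear_weights(rng.uniform(size=(10, 3)))
        np.testing.assert_allclose(fuse(h1 + h2, w), fuse(h1, w) + fuse(h2, w),
                                   atol=1e-6)


class TestEncodeJson:
    def test_deterministic(self, encoder, two_crown_ann):
        np.testing.assert_array_equal(encoder.encode_json(two_crown_ann),
                                      encoder.encode_json(two_crown_ann))

    def test_empty_set_zero_descriptor(self):
        assert not annotation_descriptor(None).any()
        assert not annotation_descriptor(CrownAnnotationSet()).any()

    def test_polygon_order_invariance(self, encoder):
        polys = [(i + 1, _square(3 * i, 0, 0.5 + 0.2 * i)) for i in range(4)]
        base = encoder.encode_json(CrownAnnotationSet(
            polygons=polys, class_labels={i + 1: "crown" for i in range(4)}))
        from itertools import permutations
        for perm in list(permutations(range(4)))[:8]:
            ann = CrownAnnotationSet(
                polygons=[polys[i] for i in perm],
                class_labels={i + 1: "crown" for i in range(4)})
            np.testing.assert_allclose(encoder.encode_json(ann), base,
                                       atol=1e-9)


class TestTemplate:
    def test_shape_contract(self, encoder, two_crown_ann):
        h = encoder.build_template(encoder.encode_json(two_crown_ann))
        assert h.shape == (8, encoder.config.d_feat)

    def test_zero_weight_mlp_zero_template(self, two_crown_ann):
        enc = MDEncoder(MDEConfig(seed=0))
        enc.mlp_hypercube.zero_()
        enc.refine.zero_()
        h = enc.build_template(enc.encode_json(two_crown_ann))
        np.testing.assert_array_equal(h, 0.0)

    def test_finite_difference_sensitivity(self, encoder, two_crown_ann):
        """Template entries respond to F_s perturbations (nonzero gradient)."""
        f_s = encoder.encode_json(two_crown_ann)
        h0 = encoder.build_template(f_s)
        eps = 1e-6
        bumped = f_s.copy()
        bumped[0] += eps
        grad = (encoder.build_template(bumped) - h0) / eps
        assert np.abs(grad).max() > 1e-3


class TestBranchesAndGate:
    def test_zero_logits_uniform(self, rng):
        enc = MDEncoder(MDEConfig(seed=0))
        enc.mlp_b.zero_()
        bw = enc.select_branches(rng.normal(size=(9, 64)))
        np.testing.assert_allclose(bw, 1 / 3)

    def test_rows_sum_to_one(self, encoder, rng):
        bw = encoder.select_branches(rng.normal(size=(40, 64)))
        np.testing.assert_allclose(bw.sum(axis=1), 1.0, atol=1e-6)

    def test_softmax_shift_invariance(self, encoder, rng):
        x = rng.normal(size=(12, 64))
        base = encoder.select_branches(x)
        enc2 = MDEncoder(MDEConfig(seed=7))
        enc2.mlp_b.l2.b += 3.7          # constant added to every logit
        np.testing.assert_allclose(enc2.select_branches(x), base, atol=1e-9)

    def test_zero_gate_at_half_threshold_retains_nothing(self, rng):
        enc = MDEncoder(MDEConfig(seed=0))
        enc.mlp_g.zero_()
        mask, g = enc.sparse_gate(rng.uniform(size=(20, 3)), np.zeros(64),
                                  tau_g=0.5)
        np.testing.assert_allclose(g, 0.5)
        assert not mask.any()           # strict inequality in the indicator

    def test_tau_to_zero_retains_all(self, encoder, rng):
        coords = rng.uniform(size=(30, 3))
        f_s = rng.normal(size=64)
        mask, _ = encoder.sparse_gate(coords, f_s, tau_g=1e-9)
        assert mask.all()

    def test_retained_count_monotone_in_tau(self, encoder, rng):
        coords = rng.uniform(size=(200, 3))
        f_s = rng.normal(size=64)
        counts = [encoder.sparse_gate(coords, f_s, tau_g=t)[0].sum()
                  for t in np.linspace(0.05, 0.95, 19)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestEntangle:
    def test_single_point_basis_state(self):
        q = np.zeros((1, 4, 3))
        q[0, :, 0] = 1.0
        out = entangle(q)
        e11 = np.zeros((3, 3))
        e11[0, 0] = 1.0
        for j in range(4):
            np.testing.assert_allclose(out[j], e11)

    def test_zero_states_zero_matrices(self):
        np.testing.assert_array_equal(entangle(np.zeros((5, 4, 8))), 0.0)

    def test_psd_and_symmetric(self, rng):
        out = entangle(rng.normal(size=(60, 4, 8)))
        for j in range(4):
            np.testing.assert_allclose(out[j], out[j].T, atol=1e-12)
            assert np.linalg.eigvalsh(out[j]).min() >= -1e-9

    def test_point_order_invariance(self, rng):
        q = rng.normal(size=(40, 4, 8))
        perm = rng.permutation(40)
        np.testing.assert_allclose(entangle(q), entangle(q[perm]), atol=1e-7)

    def test_dim_not_divisible_rejected(self):
        with pytest.raises(ValidationError, match="4"):
            MDEConfig(d_feat=60, subspace_k=16).validate()


class TestDynamicConv:
    def test_residual_only_with_zero_kernel(self, rng):
        enc = MDEncoder(MDEConfig(seed=1))
        enc.mlp_kernel.zero_()
        coords = rng.uniform(size=(15, 3))
        q = rng.normal(size=(15, 4, enc.config.subspace_k))
        out = enc.dynamic_conv_out(coords, np.ones(15, bool), entangle(q), q)
        np.testing.assert_allclose(out, enc.w_skip(coords), atol=1e-12)

    def test_output_shape(self, encoder, rng):
        coords = rng.uniform(size=(25, 3))
        q = rng.normal(size=(25, 4, encoder.config.subspace_k))
        out = encoder.dynamic_conv_out(coords, np.zeros(25, bool),
                                       entangle(q), q)
        assert out.shape == (25, encoder.config.d_out)

    def test_mean_entangle_matches_loop_oracle(self, rng):
        q_ent = entangle(rng.normal(size=(30, 4, 6)))
        oracle = sum(q_ent[j] for j in range(4)) / 4.0
        np.testing.assert_allclose(q_ent.mean(axis=0), oracle, atol=1e-7)


def test_whole_block_deterministic(encoder, two_crown_ann, rng):
    coords = rng.uniform(size=(100, 3))
    a = encoder(coords, two_crown_ann)
    b = encoder(coords, two_crown_ann)
    np.testing.assert_array_equal(a, b)
    assert a.shape == (100, encoder.config.d_out)
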