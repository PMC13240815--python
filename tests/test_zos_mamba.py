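import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from treeparse3d._nn import softplus
from treeparse3d.io_formats import PointCloud, ValidationError
from treeparse3d.zos_mamba import (
    SSMBlock, ZOSConfig, ZOSMambaEncoder, build_zorder_sequence, restore,
    rmsnorm, selective_scan, serialize, voxelize, zorder_encode,
)


def interleave_oracle(x: int, y: int, z: int, b: int) -> int:
    """Brute-force bit interleave: x -> bits 3i, y -> 3i+1, z -> 3i+2."""
    out = 0
    for i in range(b):
        out |= ((x >> i) & 1) << (3 * i)
        out |= ((y >> i) & 1) << (3 * i + 1)
        out |= ((z >> i) & 1) << (3 * i + 2)
    return out


class TestVoxelize:
    def test_one_voxel(self):
        pc = PointCloud(np.array([[0.1, 0.1, 0.1], [0.9, 0.9, 0.9]]))
        grid = voxelize(pc, 1.0)
        assert grid.n_voxels == 1

    def test_two_voxels(self):
        pc = PointCloud(np.array([[0.1, 0.1, 0.1], [0.9, 0.9, 0.9]]))
        grid = voxelize(pc, 0.5)
        assert grid.n_voxels == 2
        assert {tuple(v) for v in grid.voxel_coords} == {(0, 0, 0), (1, 1, 1)}

    def test_every_point_assigned(self, rng):
        pc = PointCloud(rng.uniform(0, 10, size=(500, 3)))
        grid = voxelize(pc, 0.7)
        counts = np.bincount(grid.point_to_voxel, minlength=grid.n_voxels)
        assert counts.sum() == 500
        assert (counts > 0).all()

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValidationError):
            voxelize(PointCloud(np.zeros((1, 3))), 0.0)


class TestZOrder:
    def test_origin_is_zero(self):
        assert zorder_encode(np.array([[0, 0, 0]]), 3)[0] == 0

    @pytest.mark.parametrize("coord,code", [
        ((1, 0, 0), 1), ((0, 1, 0), 2), ((0, 0, 1), 4)])
    def test_single_bit_axes(self, coord, code):
        assert zorder_encode(np.array([coord]), 3)[0] == code

    def test_worked_example(self):
        assert zorder_encode(np.array([[3, 5, 1]]), 3)[0] == 143

    def test_out_of_range_names_axis(self):
        with pytest.raises(ValidationError, match="y-coordinate"):
            zorder_encode(np.array([[0, 8, 0]]), 3)

    def test_exhaustive_against_oracle_b3(self):
        n = 8
        grid = np.array([(x, y, z) for x in range(n) for y in range(n)
                         for z in range(n)])
        codes = zorder_encode(grid, 3)
        oracle = np.array([interleave_oracle(x, y, z, 3) for x, y, z in grid])
        np.testing.assert_array_equal(codes, oracle)
        assert len(np.unique(codes)) == len(grid)      # injective

    def test_recursive_octant_order_4x4x4(self):
        """Morton order visits octants recursively: each half of the sorted
        sequence stays inside one octant of the cube."""
        grid = np.array([(x, y, z) for x in range(4) for y in range(4)
                         for z in range(4)])
        seq = build_zorder_sequence(grid)
        ordered = grid[seq.perm]
        # first 8 entries = first octant (all coords < 2) in 2x2x2 suborder
        first = ordered[:8]
        assert (first < 2).all()
        oracle_sub = sorted(map(tuple, first),
                            key=lambda c: interleave_oracle(*c, 1))
        assert list(map(tuple, first)) == oracle_sub


class TestSerializeRestore:
    def test_sorted_input_identity(self):
        grid = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        seq = build_zorder_sequence(grid)
        np.testing.assert_array_equal(seq.perm, [0, 1, 2])

    def test_roundtrip_exact(self, rng):
        grid = rng.integers(0, 16, size=(200, 3))
        seq = build_zorder_sequence(grid)
        feats = rng.normal(size=(200, 6))
        np.testing.assert_array_equal(restore(serialize(feats, seq), seq),
                                      feats)

    def test_length_mismatch_rejected(self):
        seq = build_zorder_sequence(np.array([[0, 0, 0], [1, 1, 1]]))
        with pytest.raises(ValidationError):
            serialize(np.zeros((3, 2)), seq)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 2**31 - 1))
    def test_roundtrip_many_fixtures(self, seed):
        r = np.random.default_rng(seed)
        grid = np.unique(r.integers(0, 8, size=(30, 3)), axis=0)
        seq = build_zorder_sequence(grid)
        x = r.normal(size=(len(grid), 3))
        np.testing.assert_array_equal(restore(serialize(x, seq), seq), x)
        assert seq.inv_perm[seq.perm].tolist() == list(range(len(grid)))


class TestSelectiveScan:
    def test_softplus_zero_closed_form(self):
        np.testing.assert_allclose(softplus(np.array([0.0])), np.log(2.0),
                                   atol=1e-12)

    def test_sequential_matches_unrolled_three_steps(self):
        """Hand-unrolled recurrence x_t = e^{dt A} x_{t-1} + dt B u,
        y_t = C x_t + D u for T = 3 scalar features."""
        block = SSMBlock(d=1, n_state=2, seed=9)
        u = np.array([[0.5], [-1.2], [0.3]])
        dt, b, c = block.input_params(u)
        x = np.zeros((1, 2))
        expected = []
        for t in range(3):
            x = np.exp(dt[t][:, None] * block.A) * x + \
                (dt[t][:, None] * u[t][:, None]) * b[t][None, :]
            expected.append(x @ c[t] + block.d_skip * u[t])
        y = selective_scan(u, block, mode="sequential")
        np.testing.assert_allclose(y, np.array(expected), atol=1e-9)

    def test_modes_agree_when_A_zero(self, rng):
        block = SSMBlock(d=4, n_state=3, seed=2)
        block.A[:] = 0.0
        u = rng.normal(size=(20, 4))
        y_seq = selective_scan(u, block, mode="sequential")
        y_par = selective_scan(u, block, mode="parallel")
        np.testing.assert_allclose(y_seq, y_par, atol=1e-6)

    def test_modes_converge_as_A_shrinks(self, rng):
        u = rng.normal(size=(10, 2))
        divergences = []
        for scale in (1.0, 0.1, 0.01):
            block = SSMBlock(d=2, n_state=2, seed=3)
            block.A *= scale
            d = np.abs(selective_scan(u, block, "sequential")
                       - selective_scan(u, block, "parallel")).max()
            divergences.append(d)
        assert divergences[2] < divergences[0]

    def test_dt_positive(self, rng):
        block = SSMBlock(d=3, n_state=2, seed=5)
        dt, _, _ = block.input_params(rng.normal(size=(100, 3)) * 10)
        assert (dt > 0).all()

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValidationError):
            selective_scan(np.zeros((2, 1)), SSMBlock(1, 1), mode="magic")


class TestRMSNorm:
    def test_unit_vector_fixed_point(self):
        y = np.ones((1, 4))
        np.testing.assert_allclose(rmsnorm(y, 1.0, eps=0.0), y)

    def test_three_four_values(self):
        out = rmsnorm(np.array([[3.0, 4.0]]), 1.0, eps=0.0)
        np.testing.assert_allclose(out, [[0.848528, 1.131371]], atol=1e-6)

    def test_scale_invariance(self, rng):
        y = rng.normal(size=(6, 8))
        np.testing.assert_allclose(rmsnorm(7.3 * y, eps=0.0),
                                   rmsnorm(y, eps=0.0), atol=1e-6)

    def test_unit_rms_rows(self, rng):
        out = rmsnorm(rng.normal(size=(10, 16)), 1.0, eps=1e-12)
        rms = np.sqrt((out ** 2).mean(axis=1))
        np.testing.assert_allclose(rms, 1.0, atol=1e-6)


def test_encoder_preserves_point_count(small_plantation):
    pc = small_plantation[0]
    enc = ZOSMambaEncoder(d_in=3, config=ZOSConfig(voxel_size=0.5))
    out = enc(pc, pc.coords)
    assert out.shape == (len(pc), enc.config.d)
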