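import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from treeparse3d import aloc
from treeparse3d.io_formats import PointCloud, ValidationError
from treeparse3d.metrics import match_instances
from treeparse3d.synthetic import PlantationSpec, generate_plantation


class TestLevy:
    def test_sigma_matches_gamma_oracle(self):
        """Mantegna scale recomputed from the Gamma-function formula."""
        from math import gamma, sin, pi
        beta = 1.5
        oracle = ((gamma(1 + beta) * sin(pi * beta / 2))
                  / (gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2))
                  ) ** (1 / beta)
        assert abs(aloc.levy_sigma(1.5) - oracle) < 1e-12
        assert abs(aloc.levy_sigma(1.5) - 0.696575) < 1e-6

    def test_default_beta(self):
        assert aloc.LevySampler().beta == 1.5

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValidationError):
            aloc.LevySampler(beta=2.5)

    def test_steps_centered(self):
        sampler = aloc.LevySampler(rng=np.random.default_rng(0))
        steps = np.array([sampler.step(1)[0] for _ in range(100_000)])
        # heavy-tailed: compare a trimmed mean against 0 at 3 SE
        trimmed = steps[np.abs(steps) < np.quantile(np.abs(steps), 0.99)]
        se = trimmed.std() / np.sqrt(len(trimmed))
        assert abs(trimmed.mean()) < 3 * se


class TestControlFactor:
    def test_final_iteration_exactly_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert aloc.control_factor(10, 10, rng) == 0.0

    def test_initial_angle_is_half_pi(self):
        assert abs(aloc.angular_control(0, 7) - np.pi / 2) < 1e-12

    def test_expected_E_nonincreasing(self):
        ms = []
        for it in (0, 5, 10, 15, 20):
            rng = np.random.default_rng(99)
            ms.append(np.mean([aloc.control_factor(it, 20, rng)
                               for _ in range(10_000)]))
        assert all(a >= b - 1e-9 for a, b in zip(ms, ms[1:]))

    def test_nonnegative(self):
        rng = np.random.default_rng(1)
        assert all(aloc.control_factor(i, 30, rng) >= 0 for i in range(31))


class TestUpdates:
    def _state(self, best):
        return aloc.SearchState(max_iter=10, best_params=np.asarray(best),
                                best_score=0.5)

    @pytest.mark.parametrize("variant", ["ds", "gft"])
    def test_fixed_point_at_best(self, variant):
        bounds = np.array([[0.0, 10.0], [0.0, 10.0]])
        theta = np.array([3.0, 4.0])
        params = aloc.ClusterParams(theta.copy(), bounds)
        out = aloc.exploit_update(self._state(theta), params, variant,
                                  np.random.default_rng(0))
        np.testing.assert_array_equal(out.theta, theta)

    def test_gft_lands_on_best_when_step_is_unit(self):
        bounds = np.array([[0.0, 10.0], [0.0, 10.0]])
        state = self._state([8.0, 2.0])
        state.f_scale = 1.0
        params = aloc.ClusterParams(np.array([1.0, 6.0]), bounds)

        class UnitRng:
            def uniform(self):
                return 1.0
        out = aloc.exploit_update(state, params, "gft", UnitRng())
        np.testing.assert_allclose(out.theta, state.best_params)

    def test_gft_collinear_with_best_direction(self, rng):
        """GFT updates lie on the segment through theta_best/theta_current."""
        bounds = np.array([[-100.0, 100.0]] * 3)
        for _ in range(100):
            best = rng.normal(size=3)
            cur = rng.normal(size=3)
            out = aloc.exploit_update(
                self._state(best), aloc.ClusterParams(cur.copy(), bounds),
                "gft", np.random.default_rng(int(rng.integers(1 << 30))))
            d1 = out.theta - cur
            d2 = best - cur
            cross = np.linalg.norm(np.cross(d1, d2))
            assert cross < 1e-9 * max(1.0, np.linalg.norm(d2) ** 2)

    def test_spiral_fixed_point_at_best(self):
        bounds = np.array([[0.0, 10.0]] * 2)
        theta = np.array([5.0, 5.0])
        out = aloc.spiral_update(self._state(theta),
                                 aloc.ClusterParams(theta.copy(), bounds),
                                 np.random.default_rng(0))
        np.testing.assert_array_equal(out.theta, theta)

    def test_spiral_amplitude_bound(self, rng):
        """|spiral| <= radius * sqrt(2) for every r3."""
        for _ in range(200):
            r3 = rng.uniform()
            radius = rng.uniform(0, 5)
            spiral = radius * (np.sin(2 * np.pi * r3) + np.cos(2 * np.pi * r3))
            assert abs(spiral) <= radius * np.sqrt(2) + 1e-12

    def test_radius_matches_norm_oracle(self, rng):
        best = rng.normal(size=5)
        cur = rng.normal(size=5)
        oracle = np.sqrt(sum((b - c) ** 2 for b, c in zip(best, cur)))
        assert abs(np.linalg.norm(best - cur) - oracle) < 1e-9

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(0, 2**31 - 1))
    def test_updates_respect_bounds(self, seed):
        r = np.random.default_rng(seed)
        bounds = np.sort(r.normal(size=(3, 2)) * 5, axis=1)
        state = aloc.SearchState(
            max_iter=10,
            best_params=r.uniform(bounds[:, 0], bounds[:, 1]),
            best_score=0.5)
        params = aloc.ClusterParams(r.uniform(bounds[:, 0], bounds[:, 1]),
                                    bounds)
        for variant in ("ds", "gft"):
            out = aloc.exploit_update(state, params, variant, r)
            assert (out.theta >= bounds[:, 0] - 1e-12).all()
            assert (out.theta <= bounds[:, 1] + 1e-12).all()
        out = aloc.spiral_update(state, params, r)
        assert (out.theta >= bounds[:, 0] - 1e-12).all()
        assert (out.theta <= bounds[:, 1] + 1e-12).all()


class TestFeedback:
    def test_uniform_f1_fixed_point(self):
        assert aloc.feedback_score(np.full(5, 0.8)) == pytest.approx(0.8)

    def test_weighted_combination(self):
        # mean 0.7, max 0.9 at alpha 0.7 -> 0.76
        f1 = np.array([0.5, 0.7, 0.9])
        assert aloc.feedback_score(f1) == pytest.approx(0.76)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            aloc.feedback_score(np.array([]))

    def test_score_between_mean_and_max(self, rng):
        for _ in range(50):
            f1 = rng.uniform(size=rng.integers(1, 10))
            s = aloc.feedback_score(f1)
            assert f1.mean() - 1e-12 <= s <= f1.max() + 1e-12


class TestBackendSelection:
    def test_small_segment_knn(self):
        assert aloc.select_backend(10, 100) == "knn"

    def test_boundary_goes_to_meanshift(self):
        assert aloc.select_backend(100, 100) == "meanshift"

    def test_monotone_no_flip_back(self):
        labels = [aloc.select_backend(n, 500) for n in range(1, 2000, 37)]
        flipped = "".join("k" if l == "knn" else "m" for l in labels)
        assert "mk" not in flipped


class TestOptimize:
    def test_single_tree_one_instance(self):
        pc, _, _ = generate_plantation(PlantationSpec(
            rows=1, trees_per_row=1, growth_stage_mix=(0.0, 1.0), seed=2))
        scorer = aloc.make_supervised_scorer(pc.instance)
        seg = aloc.optimize(pc, val_fn=scorer, max_iter=10, seed=0)
        inst = seg.instance[pc.semantic == 1]
        assert len(np.unique(inst[inst > 0])) == 1

    def test_two_separated_trees_perfect_fscore(self, separated_pair):
        pc, _, _ = separated_pair
        scorer = aloc.make_supervised_scorer(pc.instance)
        seg = aloc.optimize(pc, val_fn=scorer, max_iter=30, seed=0)
        res = match_instances(seg.instance, pc.instance, tau=0.5)
        assert res.fscore == pytest.approx(1.0)

    def test_best_score_trajectory_nondecreasing(self, separated_pair):
        pc, _, _ = separated_pair
        scorer = aloc.make_supervised_scorer(pc.instance)
        seg = aloc.optimize(pc, val_fn=scorer, max_iter=15, seed=4,
                            stop_score=2.0)    # disable early stop
        h = seg.state.history
        assert all(a <= b + 1e-12 for a, b in zip(h, h[1:]))

    def test_deterministic_given_seed(self, separated_pair):
        pc, _, _ = separated_pair
        scorer = aloc.make_supervised_scorer(pc.instance)
        a = aloc.optimize(pc, val_fn=scorer, max_iter=8, seed=11)
        b = aloc.optimize(pc, val_fn=scorer, max_iter=8, seed=11)
        np.testing.assert_array_equal(a.instance, b.instance)
        np.testing.assert_array_equal(a.best_params, b.best_params)

    def test_empty_foreground_empty_segmentation(self):
        pc = PointCloud(np.random.default_rng(0).uniform(size=(50, 3)),
                        semantic=np.zeros(50, dtype=int))
        seg = aloc.optimize(pc, max_iter=3, seed=0)
        assert not seg.instance.any()

    def test_acceptance_monotone_random_sequences(self, rng):
        """Incumbent never decreases over random score sequences."""
        for _ in range(200):
            best = -np.inf
            history = []
            for s in rng.uniform(size=50):
                if s > best:
                    best = s
                history.append(best)
            assert all(a <= b for a, b in zip(history, history[1:]))
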