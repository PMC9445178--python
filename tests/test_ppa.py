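"""Spatial statistics: closed-form CSR means, exhaustive pair oracles, envelopes."""

import numpy as np
import pytest

from stereocol import (
    ColumnarParams,
    KGrid,
    PointPattern3D,
    Window3D,
    classify_pattern,
    csr_global_envelope,
    cylindrical_K,
    empty_space_F,
    nearest_neighbour_G,
    ripley_K3,
    simulate_columnar,
    simulate_csr,
    simulate_hardcore,
)
from stereocol.envelopes import global_rank_envelope
from stereocol.ppa import DIRECTIONS, cylindrical_K_csr_mean, k_all_directions


class TestCylindricalK:
    def test_degenerate_patterns_zero(self, cube100):
        grid = KGrid()
        for pts in (np.empty((0, 3)), np.array([[50.0, 50.0, 50.0]])):
            k = cylindrical_K(PointPattern3D(pts, cube100), "x", grid)
            assert k.degenerate
            assert np.all(k.khat == 0)

    def test_two_point_pair_oracle(self, cube100):
        """Brute-force pair indicator: nonzero iff the pair fits the cylinder."""
        pts = np.array([[10.0, 50.0, 50.0], [40.0, 50.0, 50.0]])
        pat = PointPattern3D(pts, cube100)
        grid = KGrid(radii=np.array([1.0, 5.0]), half_lengths=np.array([20.0, 30.0, 40.0]))
        k = cylindrical_K(pat, "x", grid)
        # separation (30,0,0): axial 30, perpendicular 0
        # K = |W|²/(n(n-1)) * 2 / |W ∩ W_shift|, |W∩W_shift| = 70*100*100
        expected_hit = 1e12 / 2 * 2 / (70.0 * 100.0 * 100.0)
        for i_r in range(2):
            for i_t, t in enumerate(grid.half_lengths):
                want = expected_hit if t >= 30.0 else 0.0
                assert k.khat[i_r, i_t] == pytest.approx(want)
        # perpendicular to the pair axis nothing is captured at small r
        k_y = cylindrical_K(pat, "y", grid)
        assert np.all(k_y.khat == 0.0)

    def test_csr_mean_matches_cylinder_volume(self, cube100):
        grid = KGrid(radii=np.array([10.0]), half_lengths=np.array([50.0]))
        vals = np.array([
            cylindrical_K(simulate_csr(cube100, n_points=200, seed=s), "x", grid).khat[0, 0]
            for s in range(500)
        ])
        expect = 2 * np.pi * 100.0 * 50.0
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - expect) <= 3 * se

    def test_translation_invariance(self, cube200):
        pat = simulate_csr(Window3D(100, 100, 100), n_points=60, seed=5)
        grid = KGrid(radii=np.array([5.0, 10.0]), half_lengths=np.array([20.0]))
        k0 = cylindrical_K(PointPattern3D(pat.points, cube200), "x", grid).khat
        k1 = cylindrical_K(PointPattern3D(pat.points + 40.0, cube200), "x", grid).khat
        np.testing.assert_allclose(k0, k1, rtol=1e-12)

    def test_reflection_invariance_along_direction(self, cube100):
        pat = simulate_csr(cube100, n_points=80, seed=6)
        grid = KGrid(radii=np.array([8.0]), half_lengths=np.array([30.0]))
        mirrored = pat.points.copy()
        mirrored[:, 0] = 100.0 - mirrored[:, 0]
        k0 = cylindrical_K(pat, "x", grid).khat
        k1 = cylindrical_K(PointPattern3D(mirrored, cube100), "x", grid).khat
        np.testing.assert_allclose(k0, k1, rtol=1e-12)

    def test_monotone_in_r_and_t(self, cube100):
        pat = simulate_csr(cube100, n_points=100, seed=8)
        grid = KGrid(radii=np.array([5.0, 10.0, 15.0]), half_lengths=np.array([10.0, 20.0, 40.0]))
        k = cylindrical_K(pat, "z", grid).khat
        assert np.all(np.diff(k, axis=0) >= 0)
        assert np.all(np.diff(k, axis=1) >= 0)

    def test_fast_path_matches_per_direction(self, cube100):
        pat = simulate_csr(cube100, n_points=70, seed=9)
        grid = KGrid()
        flat = k_all_directions(pat, grid, -1)
        nr = grid.radii.size
        for i, d in enumerate(DIRECTIONS):
            np.testing.assert_allclose(
                flat[i * nr:(i + 1) * nr],
                cylindrical_K(pat, d, grid).khat[:, -1],
                rtol=1e-10,
            )

    def test_grid_must_fit_window(self, cube100):
        with pytest.raises(ValueError, match="fit"):
            cylindrical_K(simulate_csr(cube100, n_points=10, seed=1), "x",
                          KGrid(half_lengths=np.array([60.0])))


class TestRipleyK3:
    def test_csr_mean_matches_ball_volume(self, cube100):
        vals = np.array([
            ripley_K3(simulate_csr(cube100, n_points=200, seed=s), np.array([10.0]))[0]
            for s in range(500)
        ])
        expect = 4 / 3 * np.pi * 1000.0
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - expect) <= 3 * se

    def test_hardcore_zero_below_radius(self, cube100):
        pat = simulate_hardcore(cube100, 5e-4, 10.0, seed=3)
        assert ripley_K3(pat, np.array([9.9]))[0] == 0.0

    def test_single_point_zero(self, cube100):
        pat = PointPattern3D(np.array([[1.0, 1.0, 1.0]]), cube100)
        assert np.all(ripley_K3(pat, np.array([5.0])) == 0.0)


class TestFG:
    RADII = np.array([5.0, 10.0])

    def test_csr_closed_form(self, cube100):
        lam = 1e-3
        F, G = [], []
        for s in range(500):
            pat = simulate_csr(cube100, intensity=lam, seed=s)
            if pat.n < 2:
                continue
            F.append(empty_space_F(pat, self.RADII))
            G.append(nearest_neighbour_G(pat, self.RADII))
        F, G = np.array(F), np.array(G)
        theory = 1.0 - np.exp(-lam * 4 / 3 * np.pi * self.RADII**3)
        for emp in (F, G):
            mean = np.nanmean(emp, axis=0)
            se = np.nanstd(emp, axis=0, ddof=1) / np.sqrt(emp.shape[0])
            assert np.all(np.abs(mean - theory) <= 3 * se + 1e-9)

    def test_cdf_properties(self, cube100):
        pat = simulate_csr(cube100, n_points=150, seed=4)
        radii = np.linspace(1.0, 20.0, 10)
        for curve in (empty_space_F(pat, radii), nearest_neighbour_G(pat, radii)):
            vals = curve[~np.isnan(curve)]
            assert np.all((vals >= 0) & (vals <= 1))
            assert np.all(np.diff(vals) >= -1e-12)

    def test_hardcore_G_zero_below_radius(self, cube100):
        pat = simulate_hardcore(cube100, 5e-4, 10.0, seed=7)
        assert nearest_neighbour_G(pat, np.array([9.0]))[0] == 0.0

    def test_empty_and_singleton_rejected(self, cube100):
        with pytest.raises(ValueError):
            empty_space_F(PointPattern3D(np.empty((0, 3)), cube100), self.RADII)
        with pytest.raises(ValueError):
            nearest_neighbour_G(PointPattern3D(np.array([[1.0, 1.0, 1.0]]), cube100), self.RADII)


class TestGlobalEnvelope:
    def test_too_few_simulations_rejected(self, cube100):
        pat = simulate_csr(cube100, n_points=50, seed=1)
        with pytest.raises(ValueError, match="too small"):
            csr_global_envelope(pat, n_sim=10, seed=1)

    def test_envelope_bounds_ordered_and_median_inside(self, cube100):
        pat = simulate_csr(cube100, n_points=100, seed=2)
        env = csr_global_envelope(pat, n_sim=199, seed=3)
        for d in DIRECTIONS:
            assert np.all(env.lo[d] <= env.hi[d])
        grid = env.grid
        theo = cylindrical_K_csr_mean(grid)[:, -1]
        # CSR theoretical curve is a mid-rank curve: inside the envelope
        for d in DIRECTIONS:
            assert np.all(theo >= env.lo[d] - 1e-9)
            assert np.all(theo <= env.hi[d] + 1e-9)

    def test_columnar_pattern_detected_in_x(self, cube200):
        params = ColumnarParams(5e-4, 20.0, 3.0)
        hits = 0
        for rep in range(10):
            pat = simulate_columnar(cube200, params, seed=100 + rep)
            env = csr_global_envelope(pat, n_sim=199, seed=rep)
            exits_above_x = bool(np.any(env.observed["x"] > env.hi["x"]))
            hits += exits_above_x and env.pattern_verdict == "clustered, columnar in x"
        assert hits >= 9

    def test_csr_patterns_mostly_inside(self, cube100):
        rejections = 0
        for rep in range(40):
            pat = simulate_csr(cube100, n_points=100, seed=500 + rep)
            env = csr_global_envelope(pat, n_sim=199, seed=rep)
            rejections += env.p_value < 0.05
        # expect ~2 of 40; allow generous MC slack
        assert rejections <= 8


class TestClassification:
    def _env(self, obs, lo, hi):
        from stereocol.ppa import EnvelopeResult

        r = np.array([5.0, 10.0])
        return EnvelopeResult(
            grid=KGrid(radii=r), observed=obs,
            lo={d: lo[d] for d in DIRECTIONS}, hi={d: hi[d] for d in DIRECTIONS},
            n_sim=99, level=0.95, p_value=0.5,
        )

    def test_all_inside_random(self):
        z = np.zeros(2)
        env = self._env({d: z for d in DIRECTIONS},
                        {d: z - 1 for d in DIRECTIONS}, {d: z + 1 for d in DIRECTIONS})
        env = classify_pattern(env)
        assert env.pattern_verdict == "random"
        assert all(v == "random" for v in env.verdicts.values())

    def test_only_x_above_is_columnar(self):
        z = np.zeros(2)
        obs = {"x": z + 2, "y": z, "z": z}
        env = classify_pattern(self._env(obs, {d: z - 1 for d in DIRECTIONS},
                                         {d: z + 1 for d in DIRECTIONS}))
        assert env.verdicts == {"x": "clustered", "y": "random", "z": "random"}
        assert env.pattern_verdict == "clustered, columnar in x"

    def test_x_highest_of_three_above_is_columnar_in_x(self):
        z = np.zeros(2)
        obs = {"x": z + 5, "y": z + 2, "z": z + 2}
        env = classify_pattern(self._env(obs, {d: z - 1 for d in DIRECTIONS},
                                         {d: z + 1 for d in DIRECTIONS}))
        assert env.pattern_verdict == "clustered, columnar in x"

    def test_all_below_is_repulsive(self):
        z = np.zeros(2)
        obs = {d: z - 2 for d in DIRECTIONS}
        env = classify_pattern(self._env(obs, {d: z - 1 for d in DIRECTIONS},
                                         {d: z + 1 for d in DIRECTIONS}))
        assert env.pattern_verdict == "repulsive"


class TestRankEnvelopeMachinery:
    def test_rank_count_and_p_value_range(self):
        rng = np.random.default_rng(1)
        curves = rng.normal(size=(100, 12))
        env = global_rank_envelope(curves, level=0.95)
        assert 0.0 < env.p_value <= 1.0
        assert np.all(env.lo <= env.hi)

    def test_null_p_values_roughly_uniform(self):
        """Under exchangeability the ERL p-value is uniform on its grid."""
        rng = np.random.default_rng(2)
        ps = []
        for _ in range(300):
            curves = rng.normal(size=(50, 6))
            ps.append(global_rank_envelope(curves, level=0.95).p_value)
        ps = np.array(ps)
        grid = np.linspace(0.05, 0.95, 10)
        emp = np.array([(ps <= q).mean() for q in grid])
        assert np.max(np.abs(emp - grid)) < 0.1

    def test_extreme_curve_gets_small_p(self):
        rng = np.random.default_rng(3)
        curves = rng.normal(size=(200, 8))
        curves[0] += 50.0
        env = global_rank_envelope(curves, level=0.95)
        assert env.p_value == pytest.approx(1 / 200)
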