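"""Particle swarm machinery: start points, velocity rules, Solis-Wets."""

import warnings

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import swarmdock as sd
from swarmdock.swarm import (DockingProblem, LocalSearchState, SearchSpace,
                             SwarmConfig, ring_neighbourhoods)


@pytest.fixture(scope="module")
def small_problem(binding_pair):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rec = sd.assign_params(binding_pair.receptor)
        lig = sd.assign_params(binding_pair.ligand_unbound)
    mr = sd.compute_modes(binding_pair.receptor, method="rtb")
    ml = sd.compute_modes(binding_pair.ligand_unbound, method="rtb")
    return DockingProblem(rec, lig, mr, ml, 5, 5)


class TestStartPoints:
    def test_single_point_is_pole(self, binding_pair):
        pts = sd.generate_start_points(binding_pair.receptor,
                                       binding_pair.ligand_unbound, n=1)
        centre = binding_pair.receptor.mass_center()
        d = pts[0] - centre
        assert d[0] == pytest.approx(0.0) and d[1] == pytest.approx(0.0)
        assert d[2] > 0

    def test_equal_radius(self, binding_pair):
        pts = sd.generate_start_points(binding_pair.receptor,
                                       binding_pair.ligand_unbound, n=64)
        centre = binding_pair.receptor.mass_center()
        radii = np.linalg.norm(pts - centre, axis=1)
        assert np.ptp(radii) < 1e-6

    def test_quasi_uniform_angular_separation(self, binding_pair):
        n = 120
        pts = sd.generate_start_points(binding_pair.receptor,
                                       binding_pair.ligand_unbound, n=n)
        centre = binding_pair.receptor.mass_center()
        u = pts - centre
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        cosines = np.clip(u @ u.T, -1, 1)
        np.fill_diagonal(cosines, -1)
        min_sep = np.min(np.arccos(np.max(cosines, axis=1)))
        ideal = np.sqrt(8 * np.pi / (np.sqrt(3) * n))  # hexagonal bound
        assert min_sep > 0.75 * ideal

    def test_filter_keeps_nearest(self, binding_pair):
        pts = sd.generate_start_points(binding_pair.receptor,
                                       binding_pair.ligand_unbound, n=120)
        ref = binding_pair.ligand_bound.mass_center()
        kept = sd.filter_start_points(pts, ref, n_keep=10)
        d_kept = np.sort(np.linalg.norm(kept - ref, axis=1))
        d_all = np.sort(np.linalg.norm(pts - ref, axis=1))
        assert np.allclose(d_kept, d_all[:10])


class TestInitialisation:
    def test_seeded_determinism(self, small_problem):
        cfg = SwarmConfig(population=20, neighbourhood_k=6)
        a = sd.initialize_swarm(small_problem, np.zeros(3), cfg,
                                np.random.default_rng(5))
        b = sd.initialize_swarm(small_problem, np.zeros(3), cfg,
                                np.random.default_rng(5))
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.energies, b.energies)

    def test_translation_statistics(self, small_problem):
        cfg = SwarmConfig(population=100_000, neighbourhood_k=10)
        start = np.array([40.0, -10.0, 5.0])   # far away: cheap energies
        swarm = sd.initialize_swarm(small_problem, start, cfg,
                                    np.random.default_rng(0))
        mean = swarm.positions[:, :3].mean(axis=0)
        assert np.all(np.abs(mean - start) < 0.2)   # sigma=10, n=1e5
        std = swarm.positions[:, :3].std(axis=0)
        assert np.all(np.abs(std - 10.0) < 0.2)

    def test_orientation_uniformity(self, small_problem):
        cfg = SwarmConfig(population=100_000, neighbourhood_k=10)
        swarm = sd.initialize_swarm(small_problem, np.array([60.0, 0, 0]), cfg,
                                    np.random.default_rng(1))
        sp = small_problem.space
        rotvecs = (swarm.positions[:, sp.axis]
                   * swarm.positions[:, sp.angle][:, None])
        mats = Rotation.from_rotvec(rotvecs).as_matrix()
        mean_mat = mats.mean(axis=0)
        assert np.linalg.norm(mean_mat, ord=2) < 0.02  # Haar mean is 0

    def test_velocities_zero_and_pbest_set(self, small_problem):
        cfg = SwarmConfig(population=10, neighbourhood_k=3)
        swarm = sd.initialize_swarm(small_problem, np.zeros(3), cfg,
                                    np.random.default_rng(2))
        assert np.all(swarm.velocities == 0.0)
        assert np.array_equal(swarm.pbest_energies, swarm.energies)


class TestDecode:
    def test_identity_decode(self, small_problem):
        sp = small_problem.space
        x = np.zeros(sp.dim)
        lig0 = small_problem.ligand.coords
        com = np.average(lig0, axis=0,
                         weights=small_problem.ligand.structure.masses)
        x[sp.translation] = com
        x[sp.axis] = (0, 0, 1)
        _, lig = small_problem.decode(x)
        assert np.allclose(lig, lig0, atol=1e-10)

    def test_rotation_matches_matrix_oracle(self, small_problem):
        sp = small_problem.space
        x = np.zeros(sp.dim)
        x[sp.angle] = np.pi / 2
        x[sp.axis] = (0, 0, 1)
        x[sp.translation] = (10.0, 0.0, 0.0)
        _, lig = small_problem.decode(x)
        lig0 = small_problem.ligand.coords
        com = np.average(lig0, axis=0,
                         weights=small_problem.ligand.structure.masses)
        R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        oracle = (lig0 - com) @ R.T + np.array([10.0, 0.0, 0.0])
        assert np.allclose(lig, oracle, atol=1e-10)

    def test_mode_deformation_is_linear(self, small_problem):
        sp = small_problem.space
        x = np.zeros(sp.dim)
        x[sp.axis] = (0, 0, 1)
        lig0 = small_problem.ligand.coords
        com = np.average(lig0, axis=0,
                         weights=small_problem.ligand.structure.masses)
        x[sp.translation] = com
        x[sp.ligand_modes] = (1.0, -2.0, 0.5, 0.0, 3.0)
        _, lig_plus = small_problem.decode(x)
        x[sp.ligand_modes] = -x[sp.ligand_modes]
        _, lig_minus = small_problem.decode(x)
        assert np.allclose((lig_plus + lig_minus) / 2, lig0, atol=1e-9)

    def test_dimension_mismatch_errors(self, small_problem):
        with pytest.raises(ValueError):
            small_problem.decode(np.zeros(3))

    def test_batch_decode_matches_scalar(self, small_problem):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, small_problem.space.dim))
        rec_b, lig_b = small_problem.decode_batch(X)
        for i in range(8):
            rec, lig = small_problem.decode(X[i])
            assert np.allclose(rec_b[i], rec, atol=1e-12)
            assert np.allclose(lig_b[i], lig, atol=1e-12)


class TestVelocityRules:
    def test_all_attractors_at_position_zero_velocity(self):
        cfg = SwarmConfig(population=10, neighbourhood_k=3, inertia=0.0)
        x = np.array([1.0, 2.0, 3.0])
        v = sd.update_velocity(x, np.zeros(3), x, x, x, cfg,
                               np.random.default_rng(0))
        assert np.allclose(v, 0.0)

    def test_hand_evaluated_1d_arithmetic(self):
        cfg = SwarmConfig(population=10, neighbourhood_k=3, inertia=0.5)
        x, v0 = np.array([2.0]), np.array([1.0])
        pbest, nbest, prand = np.array([4.0]), np.array([0.0]), np.array([6.0])
        v = sd.update_velocity(x, v0, pbest, nbest, prand, cfg,
                               np.random.default_rng(0),
                               r=(0.5, 0.5, 0.5))
        # 0.5*1 + 2.05*0.5*(4-2) + 2.05*0.5*(0-2) + 0.5*(6-2)
        expected = 0.5 + 2.05 * 0.5 * 2 + 2.05 * 0.5 * (-2) + 0.5 * 4
        assert v[0] == pytest.approx(expected)

    def test_at_best_known_position_only_random_pull(self):
        cfg = SwarmConfig(population=10, neighbourhood_k=3)
        x = np.array([1.0, 1.0, 1.0])
        prand = np.array([3.0, 1.0, 1.0])
        v = sd.update_velocity(x, np.zeros(3), x, x, prand, cfg,
                               np.random.default_rng(1), r=(0.7, 0.3, 0.6))
        assert np.allclose(v, 0.6 * (prand - x))

    def test_clamping_per_class(self):
        cfg = SwarmConfig(population=10, neighbourhood_k=3)
        sp = SearchSpace(2, 3)
        v = np.zeros(sp.dim)
        v[0], v[1] = 7.2, -6.0          # translation
        v[sp.angle] = 0.5               # angle
        v[4] = -1.0                     # quaternion spatial
        v[7], v[-1] = 50.0, -80.0       # mode coefficients
        out = sd.clamp_velocity(v, cfg, sp)
        assert out[0] == 5.0 and out[1] == -5.0
        assert out[sp.angle] == pytest.approx(0.2)
        assert out[4] == pytest.approx(-0.5)
        assert out[7] == 50.0 and out[-1] == -80.0   # never clamped

    def test_ring_neighbourhood_membership(self):
        neigh = ring_neighbourhoods(10, 4)
        assert set(neigh[0]) == {8, 9, 1, 2}      # wraparound, self excluded
        assert set(neigh[5]) == {3, 4, 6, 7}
        assert neigh.shape == (10, 4)


class TestSolisWets:
    def test_success_updates_bias_and_counters(self):
        sp = SearchSpace(0, 0)
        state = LocalSearchState.initial(sp)
        rng = np.random.default_rng(0)
        x = np.ones(sp.dim)
        # energy decreases along any step: first trial always succeeds
        new_x, new_e, state = sd.solis_wets_step(
            x, 100.0, state, lambda _: 0.0, rng)
        assert new_e == 0.0
        assert state.success_count == 1 and state.fail_count == 0
        assert not np.allclose(state.bias, 0.0)    # 0.6 b + 0.4 d

    def test_double_failure_halves_bias(self):
        sp = SearchSpace(0, 0)
        state = LocalSearchState.initial(sp)
        state.bias = np.ones(sp.dim)
        rng = np.random.default_rng(0)
        _, _, state = sd.solis_wets_step(np.zeros(sp.dim), -1.0, state,
                                         lambda _: 5.0, rng)
        assert state.fail_count == 1 and state.success_count == 0
        assert np.allclose(np.abs(state.bias), 0.5)

    def test_step_doubling_and_contraction(self):
        sp = SearchSpace(0, 0)
        state = LocalSearchState.initial(sp)
        rho0 = state.rho.copy()
        rng = np.random.default_rng(0)
        x, e = np.zeros(sp.dim), 1000.0
        for _ in range(5):
            x, e, state = sd.solis_wets_step(x, e, state,
                                             lambda y: -np.sum(y ** 2), rng)
        # five successes in a row double the step sizes  (energy keeps
        # decreasing along |y|^2 growth so every trial succeeds)
        assert np.allclose(state.rho, 2 * rho0)
        state2 = LocalSearchState.initial(sp)
        for _ in range(5):
            _, _, state2 = sd.solis_wets_step(np.zeros(sp.dim), -1.0, state2,
                                              lambda _: 5.0, rng)
        assert np.allclose(state2.rho, rho0 / 2)
        assert state2.consecutive_contractions == 1

    def test_quadratic_bowl_convergence(self):
        # 2-D bowl: 95% of seeds reach within 1e-3 of the minimum value
        # before the 5-consecutive-contractions termination
        sp = SearchSpace(0, 0)
        target = np.array([1.3, -0.7])

        def energy(x):
            return float(np.sum((x[:2] - target) ** 2))

        successes = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            state = LocalSearchState.initial(sp)
            x = np.zeros(sp.dim)
            e = energy(x)
            for _ in range(20_000):
                x, e, state = sd.solis_wets_step(x, e, state, energy, rng)
                if state.terminated:
                    break
            if e < 1e-3:
                successes += 1
        assert successes >= 19   # >= 95% of 20 seeds


class TestRunDocking:
    def test_zero_iterations_returns_initial_best(self, small_problem):
        cfg = SwarmConfig(population=15, neighbourhood_k=4, iterations=0,
                          repeats=1, final_local_search=False)
        runs = sd.run_docking(small_problem, np.array([[30.0, 0.0, 0.0]]),
                              cfg, seed=3)
        assert len(runs) == 1
        swarm = sd.initialize_swarm(
            small_problem, np.array([30.0, 0.0, 0.0]),
            cfg, np.random.default_rng(runs[0].seed))
        assert runs[0].best_energy == pytest.approx(
            np.min(swarm.energies), abs=1e-12)

    def test_bit_reproducible(self, small_problem):
        cfg = SwarmConfig(population=15, neighbourhood_k=4, iterations=8,
                          repeats=2)
        pts = np.array([[25.0, 0.0, 0.0]])
        a = sd.run_docking(small_problem, pts, cfg, seed=11)
        b = sd.run_docking(small_problem, pts, cfg, seed=11)
        assert len(a) == len(b) == 2
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.best_position, rb.best_position)
            assert ra.best_energy == rb.best_energy

    def test_global_best_monotone_and_trace_spread(self, small_problem):
        cfg = SwarmConfig(population=15, neighbourhood_k=4, iterations=15,
                          repeats=1)
        runs = sd.run_docking(small_problem, np.array([[25.0, 0.0, 0.0]]),
                              cfg, seed=7)
        energies = [t[0] for t in runs[0].trace]
        assert all(b <= a + 1e-12 for a, b in zip(energies, energies[1:]))
        spreads = [t[1] for t in runs[0].trace]
        assert all(s >= 0 for s in spreads)

    def test_funnel_landscape_finds_minimum(self, small_problem):
        # synthetic single-minimum landscape over translations only
        target = np.array([12.0, -4.0, 6.0])

        class Funnel(DockingProblem):
            def energy(self, x):
                return float(np.sum((x[:3] - target) ** 2))

            def energy_batch(self, X):
                return np.sum((X[:, :3] - target) ** 2, axis=1)

        funnel = Funnel(small_problem.receptor, small_problem.ligand,
                        None, None, 0, 0)
        cfg = SwarmConfig(population=40, neighbourhood_k=13, iterations=60,
                          repeats=1, local_search_steps=2)
        hits = 0
        for seed in range(20):
            runs = sd.run_docking(funnel, np.array([[0.0, 0.0, 0.0]]),
                                  cfg, seed=seed)
            if np.linalg.norm(runs[0].best_position[:3] - target) < 0.5:
                hits += 1
        assert hits >= 18   # >= 90% of 20 seeds

    def test_save_runs_writes_json_and_poses(self, small_problem, tmp_path,
                                             binding_pair):
        cfg = SwarmConfig(population=10, neighbourhood_k=3, iterations=2,
                          repeats=1, final_local_search=False)
        runs = sd.run_docking(small_problem, np.array([[25.0, 0.0, 0.0]]),
                              cfg, seed=4)
        sd.save_runs(runs, tmp_path / "out",
                     ligand_template=binding_pair.ligand_unbound)
        import json
        summary = json.loads((tmp_path / "out" / "runs.json").read_text())
        assert len(summary) == 1
        assert "best_energy" in summary[0]
        assert (tmp_path / "out" / "poses.pdb").exists()

    def test_positions_move_at_most_vmax_in_clamped_classes(self,
                                                            small_problem):
        # one manual propagation step: position change equals the clamped
        # velocity, so clamped classes can never move more than V_max
        cfg = SwarmConfig(population=12, neighbourhood_k=4)
        sp = small_problem.space
        rng = np.random.default_rng(0)
        swarm = sd.initialize_swarm(small_problem, np.zeros(3), cfg, rng)
        huge = rng.normal(scale=100.0, size=swarm.velocities.shape)
        clamped = sd.clamp_velocity(huge, cfg, sp)
        new_pos = swarm.positions + clamped
        delta = np.abs(new_pos - swarm.positions)
        tol = 1e-12
        assert np.all(delta[:, sp.translation] <= cfg.v_max_translation + tol)
        assert np.all(delta[:, sp.angle] <= cfg.v_max_angle + tol)
        assert np.all(delta[:, sp.axis] <= cfg.v_max_axis + tol)
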