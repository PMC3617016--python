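"""Generators: closed-form kinetics, long-run laws, reproducibility."""

import numpy as np
import pytest

from ppimsm.errors import DataError
from ppimsm.synthetic import (
    JumpModel,
    asymmetric_double_well,
    boltzmann_basin_probabilities,
    flat_potential,
    make_toy_structures,
    ppi_release_preset,
    simulate_jump,
    simulate_langevin,
    symmetric_double_well,
)


class TestCalibratedPreset:
    def test_closed_form_stationary_and_mfpt(self, preset_model):
        """Two-state exchange: π2 = k12/(k12+k21), MFPT(1→2) = 1/k12."""
        k12, k21 = 2.0000e-3, 2.8833e-4
        pi = preset_model.stationary()
        assert pi[1] == pytest.approx(k12 / (k12 + k21), abs=1e-12)
        M = preset_model.mfpt_matrix()
        assert M[0, 1] == pytest.approx(1.0 / k12, abs=1e-9)
        assert M[0, 0] == 0.0 and M[1, 1] == 0.0

    def test_matches_reported_state_populations(self, preset_model):
        """Bound/released populations calibrate to 12.6% / 87.4%, released
        ~7-fold more populated, release MFPT 500 ns (0.5 µs)."""
        pi = preset_model.stationary()
        assert round(100 * pi[0], 1) == 12.6
        assert round(100 * pi[1], 1) == 87.4
        assert pi[1] / pi[0] == pytest.approx(7.0, abs=0.1)
        assert preset_model.mfpt_matrix()[0, 1] == pytest.approx(500.0, rel=1e-9)

    def test_long_run_occupancy(self, preset_model):
        """Empirical occupancy over 10^6 frames converges to π within 3
        standard errors (se from the effective sample count at the
        relaxation time 1/(k12+k21) ≈ 437 ns)."""
        sim = simulate_jump(preset_model, 10_000, 1.0, 100, seed=3)
        occ = (sim.state_paths == 1).mean()
        n_eff = 1e6 / (2 * 437.0)
        se = np.sqrt(0.874 * 0.126 / n_eff)
        assert abs(occ - 0.874) < 3 * se

    def test_first_passage_brute_force(self, preset_model):
        """Averaged simulated escape times agree with 1/k12 = 500 ns."""
        sim = simulate_jump(preset_model, 3_000, 1.0, 1_000, seed=4, initial_state=0)
        fpts = []
        for path in sim.state_paths:
            hits = np.flatnonzero(path == 1)
            if hits.size:
                fpts.append(hits[0])
        fpts = np.asarray(fpts, float)
        assert fpts.size > 900
        sem = fpts.std(ddof=1) / np.sqrt(fpts.size)
        # truncation at 3000 ns biases the mean down by ~exp(-6)*3000 ≈ 7 ns
        assert abs(fpts.mean() - 500.0) < 3 * sem + 8.0

    def test_expected_transition_count(self, preset_model):
        """Poisson thinning: #(0→1 jumps) ≈ time in state 0 × k12."""
        sim = simulate_jump(preset_model, 10_000, 1.0, 100, seed=9)
        S = sim.state_paths
        jumps = int(((S[:, :-1] == 0) & (S[:, 1:] == 1)).sum())
        expected = (S == 0).sum() * 2.0e-3
        assert abs(jumps - expected) < 3 * np.sqrt(expected)


class TestSimulateJump:
    def test_absorbing_model_constant_path(self):
        model = JumpModel(2, np.array([[0.0, 0.0], [1e-3, 0.0]]),
                          np.array([4.0, 15.0]), np.array([0.8, 2.5]))
        with pytest.warns(UserWarning, match="never visited"):
            sim = simulate_jump(model, 500, 1.0, 3, seed=0, initial_state=0)
        assert np.all(sim.state_paths == 0)
        assert np.isinf(sim.truth.mfpt_matrix[0, 1])

    def test_symmetric_occupancy(self):
        model = JumpModel(2, np.array([[0.0, 0.01], [0.01, 0.0]]),
                          np.array([0.0, 1.0]), np.array([0.1, 0.1]))
        sim = simulate_jump(model, 100_000, 1.0, 10, seed=1)
        occ = (sim.state_paths == 0).mean()
        n_eff = 1e6 / (2 / 0.02)  # relaxation time 1/(k12+k21) = 50 frames
        assert abs(occ - 0.5) < 3 * np.sqrt(0.25 / n_eff)

    def test_bit_identical_under_seed(self, preset_model):
        a = simulate_jump(preset_model, 1_000, 1.0, 5, seed=42)
        b = simulate_jump(preset_model, 1_000, 1.0, 5, seed=42)
        assert np.array_equal(a.state_paths, b.state_paths)
        for fa, fb in zip(a.features, b.features):
            assert np.array_equal(fa.values, fb.values)

    def test_unvisited_state_warning_recorded(self):
        model = JumpModel(2, np.zeros((2, 2)),
                          np.array([0.0, 1.0]), np.array([0.1, 0.1]))
        with pytest.warns(UserWarning, match="never visited"):
            sim = simulate_jump(model, 10, 1.0, 2, seed=0, initial_state=0)
        assert sim.truth.warnings

    def test_rejects_bad_sizes(self, preset_model):
        with pytest.raises(DataError):
            simulate_jump(preset_model, 1, 1.0, 1, seed=0)
        with pytest.raises(DataError):
            simulate_jump(preset_model, 10, 0.0, 1, seed=0)


class TestLangevin:
    def test_flat_potential_free_diffusion(self):
        """Increments on U≡0 are i.i.d. normal with variance 2·kT·dt/γ."""
        pot = flat_potential(kT=1.0)
        traj = simulate_langevin(pot, 100_000, 1e-3, 1.0, seed=6, x0=0.0)
        inc = np.diff(np.concatenate([[0.0], traj.values[:, 0]]))
        var = 2 * 1.0 * 1e-3 / 1.0
        se = var * np.sqrt(2 / inc.size)
        assert abs(inc.var(ddof=1) - var) < 3 * se
        assert abs(inc.mean()) < 3 * np.sqrt(var / inc.size)

    def test_symmetric_double_well_occupancy(self):
        pot = symmetric_double_well()
        traj = simulate_langevin(pot, 400_000, 2e-3, 1.0, seed=7, x0=0.0)
        x = traj.values[:, 0]
        occ = (x < 0.5).mean()
        assert abs(occ - 0.5) < 0.06  # limited by the basin-hopping count

    def test_asymmetric_well_matches_boltzmann(self):
        """Basin occupancy ratio matches the quadrature of exp(-U/kT)
        over each basin within 5% relative."""
        pot = asymmetric_double_well()
        probs, split = boltzmann_basin_probabilities(pot)
        traj = simulate_langevin(pot, 1_000_000, 2e-3, 1.0, seed=5, x0=0.0)
        x = traj.values[:, 0]
        emp_ratio = (x < split).mean() / (x >= split).mean()
        assert emp_ratio == pytest.approx(probs[0] / probs[1], rel=0.05)

    def test_domain_exit_names_frame(self):
        pot = flat_potential(kT=1.0, bounds=(-0.05, 0.05))
        with pytest.raises(DataError, match="frame"):
            simulate_langevin(pot, 10_000, 1e-3, 1.0, seed=0, x0=0.0)

    def test_timestep_guard(self):
        with pytest.raises(DataError, match="time_step too large"):
            simulate_langevin(asymmetric_double_well(), 100, 0.1, 1.0, seed=0)


class TestToyStructures:
    def test_zero_displacement_identical_after_alignment(self):
        from ppimsm.geometry import metric_rmsd

        traj, labels = make_toy_structures(20, 0.0, seed=2, cluster_probability=0.0)
        assert np.all(labels == 0)
        for i in range(1, traj.n_frames):
            r = metric_rmsd(traj.coords[i], traj.coords[0],
                            traj.alignment_subset, traj.metric_subset)
            assert r < 1e-8

    def test_rigid_motion_invariance(self):
        """Random rigid motions leave the post-alignment RMSD unchanged."""
        from scipy.spatial.transform import Rotation

        from ppimsm.geometry import metric_rmsd

        traj, _ = make_toy_structures(6, 0.5, seed=3)
        rng = np.random.default_rng(8)
        a, b = traj.coords[0], traj.coords[1]
        base = metric_rmsd(a, b, traj.alignment_subset, traj.metric_subset)
        R = Rotation.random(rng=rng).as_matrix()
        moved = a @ R.T + rng.uniform(-5, 5, 3)
        after = metric_rmsd(moved, b, traj.alignment_subset, traj.metric_subset)
        assert after == pytest.approx(base, abs=1e-8)

    def test_planted_partition_recovered_by_kcenter(self, toy_structures):
        """10 Å separation ≫ 0.5 Å spread: greedy 2-center is exact."""
        from ppimsm.clustering import LigandRMSDMetric, kcenter

        traj, labels = toy_structures
        cl = kcenter(traj, 2, LigandRMSDMetric())
        agreement = (cl.labels == labels).mean()
        assert agreement in (0.0, 1.0)  # equal up to label swap
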