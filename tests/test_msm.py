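"""MSM estimation: counting rules, spectra, lumping, MFPT, bootstrap."""

import numpy as np
import pytest

from conftest import (
    best_metastability_partition,
    mc_first_passage,
    partitions_equal,
    sample_chain,
    sample_chains,
)
from ppimsm import msm
from ppimsm.errors import DataError, NumericalError, ReducibleMatrixError


def _model_from_T(T, lag=1, frame_interval=1.0):
    """Wrap an exact transition matrix as a TransitionModel (scaled counts)."""
    cm = msm.CountMatrix(np.asarray(T) * 1e6, lag, 1, True, np.arange(len(T)))
    return msm.transition_matrix(cm, frame_interval)


class TestCountTransitions:
    def test_hand_enumerated_sliding_windows(self):
        """Path [0,0,1,1] at lag 1: windows 0→0, 0→1, 1→1."""
        cm = msm.count_transitions([[0, 0, 1, 1]], 2, 1, 1, True)
        assert np.array_equal(cm.counts, [[1, 1], [0, 1]])

    def test_dwell_filter_rejects_recrossing(self):
        """Path [0,1,0,0], dwell 2: the 0→1 arrival lasts only one frame
        and is rejected; 1→0 and 0→0 (end-truncated dwell) count."""
        cm = msm.count_transitions([[0, 1, 0, 0]], 2, 1, 2, True)
        assert np.array_equal(cm.counts, [[1, 0], [1, 0]])

    def test_constant_path_only_diagonal(self):
        for lag in (1, 2, 4):
            cm = msm.count_transitions([[2] * 5], 3, lag, 1, True)
            off = cm.counts - np.diag(np.diag(cm.counts))
            assert off.sum() == 0
            assert cm.counts[2, 2] == 5 - lag

    def test_no_counts_across_trajectory_boundaries(self):
        joint = msm.count_transitions([[0, 0], [1, 1]], 2, 1, 1, True)
        assert joint.counts[0, 1] == 0 and joint.counts[1, 0] == 0

    def test_short_trajectory_contributes_nothing(self):
        cm = msm.count_transitions([[0, 1], [0] * 10], 2, 5, 1, True)
        assert cm.counts.sum() == 5  # only the long path's windows

    def test_non_sliding_strides_by_lag(self):
        cm = msm.count_transitions([[0, 1, 0, 1, 0]], 2, 2, 1, sliding=False)
        # starts at 0 and 2: 0→0 twice
        assert np.array_equal(cm.counts, [[2, 0], [0, 0]])

    @pytest.mark.parametrize("seed", range(3))
    def test_dwell_monotonicity(self, seed):
        """Off-diagonal counts never increase with the dwell window."""
        path = sample_chain([[0.7, 0.3], [0.4, 0.6]], 400, seed)
        off = []
        for dwell in (1, 2, 3, 5):
            N = msm.count_transitions([path], 2, 1, dwell, True).counts
            off.append(N.sum() - np.trace(N))
        assert all(a >= b for a, b in zip(off, off[1:]))


class TestErgodicSubset:
    def test_fully_connected_unchanged(self):
        cm = msm.CountMatrix(np.ones((3, 3)), 1, 1, True, np.arange(3))
        out = msm.largest_ergodic_subset(cm)
        assert np.array_equal(out.counts, cm.counts)
        assert list(out.state_labels) == [0, 1, 2]

    def test_block_diagonal_keeps_larger_block(self):
        N = np.zeros((5, 5))
        N[:3, :3] = 1.0
        N[3:, 3:] = 1.0
        cm = msm.CountMatrix(N, 1, 1, True, np.arange(5))
        out = msm.largest_ergodic_subset(cm)
        assert list(out.state_labels) == [0, 1, 2]

    def test_one_way_sink_removed(self):
        N = np.array([[5.0, 1.0], [0.0, 0.0]])  # counts into 1, none out
        out = msm.largest_ergodic_subset(
            msm.CountMatrix(N, 1, 1, True, np.arange(2))
        )
        assert list(out.state_labels) == [0]


class TestTransitionMatrix:
    def test_symmetric_counts(self):
        cm = msm.CountMatrix([[9, 1], [1, 9]], 1, 1, True, np.arange(2))
        model = msm.transition_matrix(cm)
        assert np.allclose(model.T, [[0.9, 0.1], [0.1, 0.9]])
        assert np.allclose(model.pi, [0.5, 0.5])

    def test_detailed_balance_example(self):
        """T = [[0.9,0.1],[0.05,0.95]] balances at π = (1/3, 2/3)."""
        cm = msm.CountMatrix([[90, 10], [5, 95]], 1, 1, True, np.arange(2))
        model = msm.transition_matrix(cm)
        assert np.allclose(model.pi, [1 / 3, 2 / 3], atol=1e-12)

    def test_zero_row_error_points_to_ergodic_trim(self):
        cm = msm.CountMatrix([[1, 1], [0, 0]], 1, 1, True, np.arange(2))
        with pytest.raises(DataError, match="largest_ergodic_subset"):
            msm.transition_matrix(cm)

    def test_eigenvalues_sorted_by_modulus(self):
        rng = np.random.default_rng(0)
        N = rng.integers(1, 50, size=(4, 4)).astype(float)
        model = msm.transition_matrix(msm.CountMatrix(N, 1, 1, True, np.arange(4)))
        mods = np.abs(model.eigenvalues)
        assert np.all(np.diff(mods) <= 1e-12)
        assert model.eigenvalues[0].real == pytest.approx(1.0, abs=1e-10)


class TestImpliedTimescales:
    T_TRUE = np.array([[0.9, 0.1], [0.1, 0.9]])
    TAU_TRUE = -1.0 / np.log(0.8)  # 4.4814 frames

    def test_known_eigenvalue_recovered(self):
        dtrajs = sample_chains(self.T_TRUE, 20, 5_000, seed=0)
        table = msm.implied_timescales(dtrajs, 2, [1], n_timescales=1)
        assert table.timescales[0, 0] == pytest.approx(self.TAU_TRUE, rel=0.08)

    def test_markovian_flatness_across_lags(self):
        """μ(nτ) = μ(τ)^n for an exact chain, so τ_2 is lag-independent."""
        dtrajs = sample_chains(self.T_TRUE, 20, 5_000, seed=1)
        table = msm.implied_timescales(dtrajs, 2, [1, 2, 4, 8], n_timescales=1)
        ts = table.timescales[:, 0]
        assert np.all(np.isfinite(ts))
        assert np.ptp(ts) / ts.mean() < 0.15

    def test_alternating_path_flagged_not_crashed(self):
        table = msm.implied_timescales([[0, 1] * 50], 2, [1], n_timescales=1)
        assert table.undefined[0, 0]
        assert np.isnan(table.timescales[0, 0])


class TestChooseMacrostateCount:
    def _table(self, ts):
        ts = np.asarray(ts, float)[None, :]
        return msm.ImpliedTimescaleTable(
            lags_frames=np.array([1]), lags_time=np.array([1.0]),
            timescales=ts, undefined=~np.isfinite(ts),
            time_unit="ns", n_requested=ts.shape[1],
        )

    def test_gap_after_second_timescale(self):
        m, ratios, flagged = msm.choose_macrostate_count(
            self._table([100.0, 90.0, 5.0, 4.0]), 1
        )
        assert m == 3 and not flagged
        assert np.argmax(ratios) == 1

    def test_dominant_first_gap(self):
        m, _, _ = msm.choose_macrostate_count(self._table([500.0, 5.0, 4.0]), 1)
        assert m == 2

    def test_single_timescale_convention(self):
        m, _, flagged = msm.choose_macrostate_count(
            self._table([42.0, np.nan, np.nan]), 1
        )
        assert m == 2 and flagged

    def test_all_undefined_errors(self):
        with pytest.raises(NumericalError):
            msm.choose_macrostate_count(self._table([np.nan, np.nan]), 1)


def _coupled_blocks(leak=0.01):
    T = np.array([
        [0.89, 0.10, leak / 2, leak / 2],
        [0.10, 0.89, leak / 2, leak / 2],
        [leak / 2, leak / 2, 0.89, 0.10],
        [leak / 2, leak / 2, 0.10, 0.89],
    ])
    return T / T.sum(axis=1, keepdims=True)


class TestPCCA:
    def test_two_blocks_crisp_and_sign_split(self):
        """Crisp lumping separates the blocks and coincides with the sign
        split of the second eigenvector, and with the exhaustive
        best-metastability 2-partition."""
        model = _model_from_T(_coupled_blocks())
        chi = msm.pcca_plus(model, 2)
        crisp = np.argmax(chi, axis=1)
        assert partitions_equal(crisp, np.array([0, 0, 1, 1]))
        vals, vecs = np.linalg.eig(model.T)
        psi2 = np.real(vecs[:, np.argsort(-vals.real)[1]])
        assert partitions_equal(crisp, (psi2 > 0).astype(int))
        best = best_metastability_partition(model.T, model.pi, 2)
        assert partitions_equal(crisp, best)

    def test_memberships_are_a_fuzzy_partition(self):
        model = _model_from_T(_coupled_blocks(0.04))
        chi = msm.pcca_plus(model, 2)
        assert np.all(chi >= -1e-12)
        assert np.allclose(chi.sum(axis=1), 1.0, atol=1e-9)

    def test_relabeling_equivariance(self):
        T = _coupled_blocks()
        perm = np.array([2, 0, 3, 1])
        Tp = T[np.ix_(perm, perm)]
        crisp = np.argmax(msm.pcca_plus(_model_from_T(T), 2), axis=1)
        crisp_p = np.argmax(msm.pcca_plus(_model_from_T(Tp), 2), axis=1)
        assert partitions_equal(crisp[perm], crisp_p)

    def test_m_equals_n_identity_lumping(self):
        model = _model_from_T(_coupled_blocks())
        chi = msm.pcca_plus(model, 4)
        crisp = np.argmax(chi, axis=1)
        assert len(set(crisp.tolist())) == 4


class TestLump:
    def test_identity_assignment_preserves_model(self):
        cm = msm.CountMatrix([[90, 10], [5, 95]], 1, 1, True, np.arange(2))
        model = msm.transition_matrix(cm)
        macro = msm.lump(cm, model, np.eye(2), lag_time=1.0)
        assert np.allclose(macro.macro_T, model.T)
        assert np.allclose(macro.populations, model.pi)

    def test_population_addition(self):
        """micro π = (0.25, 0.25, 0.5), macrostates {0,1},{2} → (0.5, 0.5)."""
        T = np.array([[0.5, 0.25, 0.25], [0.25, 0.5, 0.25], [0.125, 0.125, 0.75]])
        model = _model_from_T(T)
        assert np.allclose(model.pi, [0.25, 0.25, 0.5], atol=1e-9)
        chi = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        cm = msm.CountMatrix(T * 1e6, 1, 1, True, np.arange(3))
        macro = msm.lump(cm, model, chi, lag_time=1.0)
        assert np.allclose(macro.populations, [0.5, 0.5], atol=1e-9)

    def test_empty_macrostate_rejected(self):
        cm = msm.CountMatrix([[9, 1], [1, 9]], 1, 1, True, np.arange(2))
        model = msm.transition_matrix(cm)
        chi = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(NumericalError, match="no member"):
            msm.lump(cm, model, chi, lag_time=1.0)

    def test_planted_block_escape_probability(self):
        """Lumped off-diagonals match the generator's block-escape rates."""
        T = _coupled_blocks(0.02)
        dtrajs = sample_chains(T, 10, 20_000, seed=3)
        cm = msm.count_transitions(dtrajs, 4, 1)
        erg = msm.largest_ergodic_subset(cm)
        model = msm.transition_matrix(erg)
        chi = msm.pcca_plus(model, 2)
        macro = msm.lump(erg, model, chi, lag_time=1.0)
        off = macro.macro_T[0, 1]
        assert off == pytest.approx(0.02, rel=0.15)


class TestMFPT:
    def test_two_state_closed_form(self):
        """T = [[0.9,0.1],[0.1,0.9]] at lag 4.5 ns: MFPT = 4.5/0.1 = 45."""
        M = msm.mfpt(np.array([[0.9, 0.1], [0.1, 0.9]]), 4.5)
        assert M[0, 1] == pytest.approx(45.0, abs=1e-10)
        assert M[1, 0] == pytest.approx(45.0, abs=1e-10)

    def test_diagonal_zero(self):
        rng = np.random.default_rng(1)
        T = rng.random((4, 4)) + 0.1
        T /= T.sum(axis=1, keepdims=True)
        assert np.all(np.diag(msm.mfpt(T, 2.0)) == 0.0)

    def test_three_state_against_monte_carlo(self):
        rng = np.random.default_rng(5)
        T = rng.random((3, 3)) + 0.2
        T /= T.sum(axis=1, keepdims=True)
        M = msm.mfpt(T, 1.0)
        mc_mean, mc_se = mc_first_passage(T, 0, 2, n_paths=20_000, seed=6)
        assert abs(M[0, 2] - mc_mean) < 2 * mc_se

    def test_reducible_matrix_rejected(self):
        T = np.array([[1.0, 0.0], [0.5, 0.5]])
        with pytest.raises(ReducibleMatrixError):
            msm.mfpt(T, 1.0)

    def test_micro_level_cross_check_agrees_when_metastable(self):
        T = _coupled_blocks(0.005)
        model = _model_from_T(T)
        crisp = np.array([0, 0, 1, 1])
        micro = msm.mfpt_micro_to_macrostates(model, crisp, 1.0)
        cm = msm.CountMatrix(T * 1e6, 1, 1, True, np.arange(4))
        macro = msm.lump(cm, model, np.eye(2)[crisp], 1.0)
        lumped = msm.mfpt(macro.macro_T, 1.0)
        assert micro[0, 1] == pytest.approx(lumped[0, 1], rel=0.1)


class TestBootstrap:
    def _dtrajs(self, seed=0, different=False):
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        if different:
            return [sample_chain(T, 500, seed), sample_chain(T, 500, seed + 1),
                    np.array([0] * 200 + [1] * 300)]
        path = sample_chain(T, 500, seed)
        return [path.copy() for _ in range(5)]

    CRISP = np.array([0, 1])

    def test_identical_trajectories_zero_sd(self):
        boot = msm.bootstrap(self._dtrajs(), 2, self.CRISP, 1, n_replicates=20, seed=1)
        assert np.allclose(boot.populations_sd, 0.0, atol=1e-14)
        assert np.allclose(boot.mfpt_sd, 0.0, atol=1e-12)

    def test_default_replicate_count(self):
        import inspect

        sig = inspect.signature(msm.bootstrap)
        assert sig.parameters["n_replicates"].default == 100

    def test_nonzero_sd_and_seed_determinism(self):
        boot1 = msm.bootstrap(self._dtrajs(different=True), 2, self.CRISP, 1,
                              n_replicates=30, seed=9)
        boot2 = msm.bootstrap(self._dtrajs(different=True), 2, self.CRISP, 1,
                              n_replicates=30, seed=9)
        assert boot1.populations_sd[0] > 0
        assert np.array_equal(boot1.populations_mean, boot2.populations_mean)
        assert np.array_equal(boot1.mfpt_mean, boot2.mfpt_mean)


class TestResidence:
    def test_n_zero_is_exactly_one(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        dtrajs = sample_chains(T, 5, 500, seed=0)
        res = msm.validate_residence(T, np.array([0, 1]), np.arange(2),
                                     dtrajs, 1, [0])
        assert np.allclose(res.predicted[:, 0], 1.0)
        assert np.allclose(res.observed[:, 0], 1.0)

    def test_points_beyond_trajectory_flagged(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        res = msm.validate_residence(T, np.array([0, 1]), np.arange(2),
                                     [[0, 1, 0, 1]], 1, [0, 10])
        assert np.all(res.undefined[:, 1])
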