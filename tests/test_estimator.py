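import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from milekin import (
    CellStatistics,
    CombinedCounts,
    DisconnectedError,
    NumericalError,
    ValidationError,
    build_radial_model,
    build_rate_matrix,
    combine_counts,
    counts_from_jump_trace,
    estimate_kinetics,
    free_energy_profile,
    kinetics_from_counts,
    mfpt,
    replica_aggregate,
    simulate_confined_bd,
    simulate_ctmc,
    solve_cell_equilibrium,
    stationary_probabilities,
)
from milekin.estimator import RateMatrixResult, _local_maxima
from milekin.stats import collect_cell_statistics

from conftest import tridiagonal_generator


def birth_death_mfpt(q: np.ndarray) -> np.ndarray:
    """Independent closed-form oracle: nested-sum MFPT of a birth-death
    chain with absorbing top state (state 0 has no down rate)."""
    n = q.shape[0]
    lam = np.array([q[i, i + 1] for i in range(n - 1)])
    mu = np.array([q[i, i - 1] if i > 0 else 0.0 for i in range(n - 1)])
    d = np.zeros(n - 1)  # d[k] = mean time from k to first reach k+1
    d[0] = 1.0 / lam[0]
    for k in range(1, n - 1):
        d[k] = (1.0 + mu[k] * d[k - 1]) / lam[k]
    out = np.zeros(n)
    for i in range(n - 1):
        out[i] = d[i:].sum()
    return out


def cell_stats(cell, borders, N, R, N_boundary):
    s = CellStatistics(
        cell=cell, boundary_milestones=borders, N=dict(N), R=dict(R),
        T=sum(R.values()), N_boundary=dict(N_boundary),
    )
    s.validate()
    return s


class TestCellEquilibrium:
    def test_two_cell_flux_balance(self):
        # k_12 = 0.2, k_21 = 0.1 per unit time -> pi = (1/3, 2/3)
        a = cell_stats(0, (0,), {}, {0: 10.0}, {0: 2})
        b = cell_stats(1, (0, 1), {}, {0: 10.0, 1: 10.0}, {0: 2, 1: 5})
        pi = solve_cell_equilibrium([a, b])
        np.testing.assert_allclose(pi, [1 / 3, 2 / 3], atol=1e-12)

    def test_symmetric_cells_uniform(self):
        stats = [
            cell_stats(0, (0,), {}, {0: 5.0}, {0: 4}),
            cell_stats(1, (0, 1), {}, {0: 2.5, 1: 2.5}, {0: 4, 1: 4}),
            cell_stats(2, (1, 2), {}, {1: 2.5, 2: 2.5}, {1: 4, 2: 4}),
        ]
        pi = solve_cell_equilibrium(stats)
        np.testing.assert_allclose(pi, np.full(3, 1 / 3), atol=1e-12)

    def test_zero_collision_boundary_disconnects(self):
        stats = [
            cell_stats(0, (0,), {}, {0: 5.0}, {0: 4}),
            cell_stats(1, (0, 1), {}, {0: 2.5, 1: 2.5}, {0: 4, 1: 0}),
            cell_stats(2, (1, 2), {}, {1: 2.5, 2: 2.5}, {1: 4, 2: 4}),
        ]
        with pytest.raises(DisconnectedError, match="components"):
            solve_cell_equilibrium(stats)

    def test_zero_time_cell_rejected(self):
        s = CellStatistics(cell=0, boundary_milestones=(0,), T=0.0)
        with pytest.raises(NumericalError, match="cell 0"):
            solve_cell_equilibrium([s])

    def test_single_cell(self):
        s = cell_stats(0, (0,), {}, {0: 3.0}, {0: 7})
        np.testing.assert_array_equal(solve_cell_equilibrium([s]), [1.0])


class TestCombineCounts:
    def test_single_cell_reduces_to_raw(self):
        s = cell_stats(
            1, (0, 1), {(0, 1): 4, (1, 0): 3}, {0: 6.0, 1: 4.0},
            {0: 9, 1: 8},
        )
        counts = combine_counts([s], np.array([1.0]), n_milestones=2)
        np.testing.assert_allclose(counts.N, [[0, 4], [3, 0]])
        np.testing.assert_allclose(counts.R, [6.0, 4.0])
        assert counts.T == pytest.approx(10.0)

    def test_identical_cells_uniform_pi(self):
        # two replicas of the same cell statistics under uniform weights
        # leave the rate ratios N_ij / R_i unchanged
        template = dict(
            N={(0, 1): 4, (1, 0): 3}, R={0: 6.0, 1: 4.0},
            N_boundary={0: 9, 1: 8},
        )
        a = cell_stats(1, (0, 1), **template)
        b = cell_stats(2, (1, 2), {(1, 2): 4, (2, 1): 3},
                       {1: 6.0, 2: 4.0}, {1: 9, 2: 8})
        counts = combine_counts([a, b], np.array([0.5, 0.5]), n_milestones=3)
        # milestones fed by a single cell keep their raw rate ratios
        assert counts.N[0, 1] / counts.R[0] == pytest.approx(4 / 6.0)
        assert counts.N[2, 1] / counts.R[2] == pytest.approx(3 / 4.0)
        # identical cells under uniform weights contribute identically
        assert counts.N[0, 1] == pytest.approx(counts.N[1, 2])
        assert counts.R[0] == pytest.approx(counts.R[2] * 6.0 / 4.0)

    def test_time_rescaling_halves_rates(self):
        s = cell_stats(
            1, (0, 1), {(0, 1): 4, (1, 0): 3}, {0: 6.0, 1: 4.0},
            {0: 9, 1: 8},
        )
        s2 = cell_stats(
            1, (0, 1), {(0, 1): 4, (1, 0): 3}, {0: 12.0, 1: 8.0},
            {0: 9, 1: 8},
        )
        c1 = combine_counts([s], np.array([1.0]), n_milestones=2)
        c2 = combine_counts([s2], np.array([1.0]), n_milestones=2)
        assert c2.N[0, 1] / c2.R[0] == pytest.approx(
            0.5 * c1.N[0, 1] / c1.R[0]
        )

    def test_shape_mismatch(self):
        s = cell_stats(1, (0, 1), {}, {0: 1.0}, {0: 1})
        with pytest.raises(ValidationError, match="shape"):
            combine_counts([s], np.array([0.5, 0.5]))


class TestRateMatrix:
    def test_direct_arithmetic(self):
        counts = CombinedCounts(
            N=np.array([[0.0, 5.0], [3.0, 0.0]]), R=np.array([10.0, 6.0]),
            T=16.0,
        )
        rm = build_rate_matrix(counts, absorbing=1)
        np.testing.assert_allclose(rm.Q, [[-0.5, 0.5], [0.5, -0.5]])
        np.testing.assert_allclose(rm.Q_hat, [[-0.5]])

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(0)
        N = rng.integers(1, 50, (6, 6)).astype(float)
        np.fill_diagonal(N, 0.0)
        counts = CombinedCounts(N=N, R=rng.uniform(1, 5, 6), T=20.0)
        rm = build_rate_matrix(counts)
        np.testing.assert_allclose(rm.Q.sum(axis=1), 0.0, atol=1e-12)
        assert np.all(rm.Q - np.diag(np.diag(rm.Q)) >= 0)

    def test_zero_occupation_with_counts_rejected(self):
        counts = CombinedCounts(
            N=np.array([[0.0, 0.0], [2.0, 0.0]]), R=np.array([10.0, 0.0]),
            T=10.0,
        )
        with pytest.raises(NumericalError, match="zero"):
            build_rate_matrix(counts)

    def test_unsampled_milestone_rejected(self):
        counts = CombinedCounts(N=np.zeros((3, 3)), R=np.array([1.0, 1.0, 0.0]),
                                T=2.0)
        with pytest.raises(NumericalError, match="unsampled"):
            build_rate_matrix(counts)


class TestMFPT:
    def test_two_state(self):
        rm = RateMatrixResult(
            Q=np.array([[-0.5, 0.5], [0.5, -0.5]]),
            Q_hat=np.array([[-0.5]]), absorbing=1,
        )
        vec, residence = mfpt(rm)
        assert residence == pytest.approx(2.0, abs=1e-12)
        np.testing.assert_allclose(vec, [2.0, 0.0], atol=1e-12)

    def test_rate_scaling_halves_mfpt(self):
        q = tridiagonal_generator(5, np.random.default_rng(1))
        keep = np.ix_(range(4), range(4))
        rm1 = RateMatrixResult(Q=q, Q_hat=q[keep], absorbing=4)
        rm2 = RateMatrixResult(Q=2 * q, Q_hat=2 * q[keep], absorbing=4)
        v1, _ = mfpt(rm1)
        v2, _ = mfpt(rm2)
        np.testing.assert_allclose(v2, v1 / 2, rtol=1e-12)

    def test_birth_death_closed_form(self):
        q = tridiagonal_generator(5, np.random.default_rng(7))
        q[0, :] = 0.0
        q[0, 1] = 1.3
        q[0, 0] = -1.3  # no down rate from the bottom state
        rm = RateMatrixResult(
            Q=q, Q_hat=q[np.ix_(range(4), range(4))], absorbing=4
        )
        vec, _ = mfpt(rm)
        np.testing.assert_allclose(vec, birth_death_mfpt(q), rtol=1e-9)

    @given(seed=hst.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_milestone_index(self, seed):
        """Passage to the absorbing top milestone must pass through all
        intermediate milestones, so MFPT is non-increasing in index."""
        q = tridiagonal_generator(6, np.random.default_rng(seed))
        rm = RateMatrixResult(
            Q=q, Q_hat=q[np.ix_(range(5), range(5))], absorbing=5
        )
        vec, _ = mfpt(rm)
        assert np.all(np.diff(vec) <= 1e-12)

    def test_singular_system_raises(self):
        q = np.zeros((3, 3))
        q[0, 1] = q[1, 0] = 1.0
        np.fill_diagonal(q, -q.sum(axis=1))  # state 2 disconnected
        rm = RateMatrixResult(
            Q=q, Q_hat=q[np.ix_(range(2), range(2))], absorbing=2
        )
        with pytest.raises(NumericalError, match="absorbing"):
            mfpt(rm)


class TestStationary:
    def test_symmetric_two_state(self):
        rm = RateMatrixResult(
            Q=np.array([[-0.5, 0.5], [0.5, -0.5]]),
            Q_hat=np.array([[-0.5]]), absorbing=1,
        )
        np.testing.assert_allclose(
            stationary_probabilities(rm), [0.5, 0.5], atol=1e-12
        )

    def test_permutation_equivariance(self):
        q = tridiagonal_generator(5, np.random.default_rng(3))
        rm = RateMatrixResult(Q=q, Q_hat=q[:4, :4], absorbing=4)
        p = stationary_probabilities(rm)
        perm = np.array([2, 0, 4, 1, 3])
        qp = q[np.ix_(perm, perm)]
        rmp = RateMatrixResult(Q=qp, Q_hat=qp[:4, :4], absorbing=0)
        pp = stationary_probabilities(rmp)
        np.testing.assert_allclose(pp, p[perm], atol=1e-10)

    def test_recovers_known_generator_stationary(self):
        q = tridiagonal_generator(3, np.random.default_rng(5))
        tr = simulate_ctmc(q, 50_000, seed=6)
        counts = counts_from_jump_trace(tr, n_states=3)
        rm = build_rate_matrix(counts, absorbing=2)
        p = stationary_probabilities(rm)
        import scipy.linalg

        null = scipy.linalg.null_space(q.T).ravel()
        p_true = np.abs(null) / np.abs(null).sum()
        np.testing.assert_allclose(p, p_true, atol=0.02)

    def test_reducible_rejected(self):
        q = np.array([[-1.0, 1.0, 0.0], [1.0, -1.0, 0.0], [0.0, 1.0, -1.0]])
        rm = RateMatrixResult(Q=q, Q_hat=q[:2, :2], absorbing=2)
        with pytest.raises(NumericalError, match="reducible"):
            stationary_probabilities(rm)


class TestFreeEnergy:
    def test_equal_probability_zero(self):
        dG, _ = free_energy_profile(np.array([0.2, 0.2, 0.6]))
        assert dG[1] == 0.0

    def test_unit_log(self):
        p = np.array([0.5, 0.5 * np.exp(-1.0)])
        dG, _ = free_energy_profile(p / p.sum(), thermal_energy=1.0)
        assert dG[1] == pytest.approx(1.0, abs=1e-12)

    def test_two_barrier_topology(self):
        dG = np.array([0.0, 1.0, 0.5, 2.0, 1.2])
        _, ts = free_energy_profile(
            np.exp(-dG) / np.exp(-dG).sum(), thermal_energy=1.0
        )
        assert ts == (1, 3)

    def test_plateau_resolves_to_first_index(self):
        assert _local_maxima(np.array([0.0, 1.0, 1.0, 0.5, 2.0, 0.1])) == (1, 4)

    def test_zero_probability_inf_with_warning(self):
        with pytest.warns(RuntimeWarning, match="zero stationary"):
            dG, ts = free_energy_profile(np.array([0.5, 0.0, 0.25, 0.25]))
        assert np.isinf(dG[1])
        assert 1 not in ts

    def test_thermal_energy_scales(self):
        p = np.array([0.5, 0.5 * np.exp(-1.0)])
        dG, _ = free_energy_profile(p / p.sum(), thermal_energy=0.5961)
        assert dG[1] == pytest.approx(0.5961, abs=1e-12)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValidationError, match="reference"):
            free_energy_profile(np.array([0.0, 1.0]))


class TestReplicaAggregate:
    def _result(self, residence, n=4):
        from milekin.estimator import KineticsResult

        return KineticsResult(
            pi=np.full(n, 1 / n), p=np.full(n, 1 / n),
            mfpt=np.linspace(residence, 0, n), residence_time=residence,
            dG=np.zeros(n), ts_milestones=(), absorbing=n - 1, reference=0,
        )

    def test_identical_replicas(self):
        summary = replica_aggregate([self._result(2.0), self._result(2.0)])
        assert summary.residence_mean == 2.0
        assert summary.residence_sem == 0.0

    def test_two_point_formula(self):
        summary = replica_aggregate([self._result(2.0), self._result(4.0)])
        assert summary.residence_mean == pytest.approx(3.0, abs=1e-15)
        assert summary.residence_sem == pytest.approx(1.0, abs=1e-15)

    def test_permutation_invariant(self):
        rs = [self._result(v) for v in (1.0, 5.0, 2.5)]
        a = replica_aggregate(rs)
        b = replica_aggregate(rs[::-1])
        assert a.residence_mean == b.residence_mean
        assert a.residence_sem == b.residence_sem
        np.testing.assert_allclose(a.mfpt_mean, b.mfpt_mean)

    def test_mismatched_models_rejected(self):
        with pytest.raises(ValidationError, match="mismatch"):
            replica_aggregate([self._result(1.0, n=4), self._result(1.0, n=5)])

    def test_single_replica_rejected(self):
        with pytest.raises(ValidationError):
            replica_aggregate([self._result(1.0)])


class TestEndToEnd:
    def test_ctmc_oracle_recovery(self):
        """Statistics harvested from a known-generator jump process feed
        the estimator and recover the generator's bound-state MFPT."""
        q = tridiagonal_generator(6, np.random.default_rng(42))
        tr = simulate_ctmc(q, 100_000, seed=99)
        counts = counts_from_jump_trace(tr, n_states=6)
        result = kinetics_from_counts(counts, absorbing=5)
        true = np.linalg.solve(q[:5, :5], -np.ones(5))[0]
        assert result.residence_time == pytest.approx(true, rel=0.05)

    def test_estimator_invariant_to_segment_split(self, uniform_model, flat):
        traces = [
            simulate_confined_bd(
                uniform_model, flat, cell=c,
                start_cv=uniform_model.cell_bounds(c)[0] + 0.5,
                n_steps=150_000, dt=1e-3, seed=700 + c,
            )
            for c in range(uniform_model.n_cells)
        ]
        whole = [collect_cell_statistics(tr) for tr in traces]
        from milekin.dynamics import EventTrace
        from milekin.stats import merge_statistics

        split = []
        for tr in traces:
            k = tr.n_events // 3
            t_cut = float(tr.times[k])
            seg1 = EventTrace(
                cell=tr.cell, times=tr.times[: k + 1],
                milestones=tr.milestones[: k + 1], total_time=t_cut,
                boundary_milestones=tr.boundary_milestones,
            )
            seg2 = EventTrace(
                cell=tr.cell, times=tr.times[k + 1:] - t_cut,
                milestones=tr.milestones[k + 1:],
                total_time=tr.total_time - t_cut,
                boundary_milestones=tr.boundary_milestones,
            )
            split.append(
                merge_statistics(
                    [
                        collect_cell_statistics(seg1),
                        collect_cell_statistics(
                            seg2, initial_milestone=int(tr.milestones[k])
                        ),
                    ]
                )
            )
        a = estimate_kinetics(uniform_model, whole)
        b = estimate_kinetics(uniform_model, split)
        np.testing.assert_allclose(b.mfpt, a.mfpt, rtol=1e-12)
        np.testing.assert_allclose(b.dG, a.dG, atol=1e-12)
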