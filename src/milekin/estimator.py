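"""Milestone-level rate-matrix estimation, kinetics and thermodynamics.

From per-cell confined-sampling statistics the estimator

1. solves the cell-level flux balance for equilibrium weights ``pi``
   (boundary-collision rates ``k_ab = N_boundary / T_a`` between adjacent
   cells, normalized to sum to 1);
2. combines per-cell counts into milestone-level counts with the weighting
   time ``T = 1 / sum_a(pi_a / T_a)``::

       N[i][j] = T * sum_a pi_a * N_a[i][j] / T_a
       R[i]    = T * sum_a pi_a * R_a[i]    / T_a

3. builds the rate matrix ``Q_ij = N_ij / R_i`` (off-diagonal) with
   ``Q_ii = -sum_j Q_ij``;
4. solves ``Q_hat @ mfpt = -1`` with the absorbing milestone removed for
   mean first passage times (the bound milestone's entry is the residence
   time);
5. solves the stationary eigenproblem ``p @ Q = 0`` for milestone
   probabilities and converts them into a free-energy profile
   ``dG_i = -kT * ln(p_i / p_ref)`` with transition-state milestones at
   strict interior local maxima.

Linear solves are dense and direct with a pre-solve condition check;
badly conditioned systems fall back to least squares with a warning.
Unsampled transitions stay at rate zero — connectivity failures raise
rather than silently regularize.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.linalg

from .errors import DisconnectedError, NumericalError, ValidationError
from .model import MilestoningModel
from .stats import CellStatistics

__all__ = [
    "CombinedCounts",
    "RateMatrixResult",
    "KineticsResult",
    "ReplicaSummary",
    "solve_cell_equilibrium",
    "combine_counts",
    "build_rate_matrix",
    "mfpt",
    "stationary_probabilities",
    "free_energy_profile",
    "estimate_kinetics",
    "kinetics_from_counts",
    "replica_aggregate",
    "results_frame",
]

_COND_LIMIT = 1e12


# ---------------------------------------------------------------------------
# types


@dataclass(frozen=True)
class CombinedCounts:
    """Milestone-level weighted counts: ``N`` (zero diagonal), ``R``, and
    the weighting time ``T``."""

    N: np.ndarray
    R: np.ndarray
    T: float

    def __post_init__(self) -> None:
        N = np.asarray(self.N, dtype=float)
        R = np.asarray(self.R, dtype=float)
        object.__setattr__(self, "N", N)
        object.__setattr__(self, "R", R)
        if N.ndim != 2 or N.shape[0] != N.shape[1] or R.shape != (N.shape[0],):
            raise ValidationError("N must be square and R its matching vector")
        if np.any(N < 0) or np.any(R < 0) or self.T < 0:
            raise ValidationError("counts and times must be nonnegative")
        if np.any(np.diag(N) != 0):
            raise ValidationError("N must have a zero diagonal")

    @property
    def n_milestones(self) -> int:
        return int(self.R.size)


@dataclass(frozen=True)
class RateMatrixResult:
    """Rate matrix ``Q``, its submatrix ``Q_hat`` with the absorbing
    milestone's row and column removed, and the absorbing index."""

    Q: np.ndarray
    Q_hat: np.ndarray
    absorbing: int

    @property
    def n_milestones(self) -> int:
        return int(self.Q.shape[0])

    @property
    def kept(self) -> np.ndarray:
        """Milestone indices retained in ``Q_hat``."""
        return np.array(
            [i for i in range(self.n_milestones) if i != self.absorbing]
        )


@dataclass(frozen=True)
class KineticsResult:
    pi: np.ndarray                    # per-cell equilibrium weights
    p: np.ndarray                     # per-milestone stationary probabilities
    mfpt: np.ndarray                  # per-milestone MFPT, absorbing = 0
    residence_time: float             # MFPT of the bound milestone
    dG: np.ndarray                    # free energy, reference milestone = 0
    ts_milestones: tuple[int, ...]    # strict local maxima of dG
    absorbing: int
    reference: int


@dataclass(frozen=True)
class ReplicaSummary:
    """Mean +/- standard error over independent replicas."""

    n_replicas: int
    mfpt_mean: np.ndarray
    mfpt_sem: np.ndarray
    dG_mean: np.ndarray
    dG_sem: np.ndarray
    residence_mean: float
    residence_sem: float
    residence_samples: tuple[float, ...]


# ---------------------------------------------------------------------------
# cell equilibrium (flux balance between adjacent cells)


def solve_cell_equilibrium(stats: Sequence[CellStatistics]) -> np.ndarray:
    """Equilibrium cell weights ``pi`` from boundary-collision flux balance.

    Cells sharing a milestone exchange probability at rate
    ``k_ab = N_boundary_a[shared] / T_a``; ``pi`` solves
    ``sum_b pi_b k_ba = pi_a sum_b k_ab`` with ``sum pi = 1``, replacing
    one redundant balance row by the normalization.
    """
    if not stats:
        raise ValidationError("no cell statistics supplied")
    cells = [s.cell for s in stats]
    if len(set(cells)) != len(cells):
        raise ValidationError(f"duplicate cell statistics: {sorted(cells)}")
    for s in stats:
        if s.T <= 0:
            raise NumericalError(
                f"cell {s.cell} has zero attributable sampling time"
            )
    n = len(stats)
    if n == 1:
        return np.array([1.0])
    index = {c: k for k, c in enumerate(cells)}

    # adjacency through shared milestones
    by_milestone: dict[int, list[int]] = {}
    for s in stats:
        for m in s.boundary_milestones:
            by_milestone.setdefault(m, []).append(s.cell)

    K = np.zeros((n, n))  # K[a, b] = rate a -> b
    graph = nx.Graph()
    graph.add_nodes_from(cells)
    for m, members in by_milestone.items():
        if len(members) < 2:
            continue
        if len(members) > 2:
            raise ValidationError(
                f"milestone {m} claimed as boundary by cells {members}"
            )
        a, b = members
        sa, sb = stats[index[a]], stats[index[b]]
        k_ab = sa.N_boundary.get(m, 0) / sa.T
        k_ba = sb.N_boundary.get(m, 0) / sb.T
        K[index[a], index[b]] = k_ab
        K[index[b], index[a]] = k_ba
        if k_ab > 0 and k_ba > 0:
            graph.add_edge(a, b)

    if not nx.is_connected(graph):
        components = [sorted(c) for c in nx.connected_components(graph)]
        raise DisconnectedError(
            "cell graph is disconnected; components: "
            f"{sorted(components, key=lambda c: c[0])}"
        )

    # balance matrix: A[a, b] = K[b, a] for b != a, A[a, a] = -sum_b K[a, b]
    A = K.T - np.diag(K.sum(axis=1))
    A[-1, :] = 1.0  # normalization replaces one redundant balance row
    rhs = np.zeros(n)
    rhs[-1] = 1.0
    pi = _direct_solve(A, rhs, context="cell equilibrium")
    if np.any(pi < -1e-10):
        raise NumericalError("cell equilibrium produced negative weights")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# count combination


def combine_counts(
    stats: Sequence[CellStatistics],
    pi: np.ndarray,
    n_milestones: Optional[int] = None,
) -> CombinedCounts:
    """Weight per-cell statistics into milestone-level counts.

    ``T = 1 / sum_a(pi_a / T_a)``; each cell's counts and occupation times
    are scaled by ``pi_a * T / T_a``.  With a single cell this reduces to
    the raw statistics.
    """
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (len(stats),):
        raise ValidationError(
            f"pi has shape {pi.shape}, expected ({len(stats)},)"
        )
    if n_milestones is None:
        n_milestones = 1 + max(
            m for s in stats for m in s.boundary_milestones
        )
    T = 1.0 / sum(w / s.T for w, s in zip(pi, stats))
    N = np.zeros((n_milestones, n_milestones))
    R = np.zeros(n_milestones)
    for w, s in zip(pi, stats):
        scale = w * T / s.T
        for (i, j), c in s.N.items():
            N[i, j] += scale * c
        for i, r in s.R.items():
            R[i] += scale * r
    return CombinedCounts(N=N, R=R, T=T)


# ---------------------------------------------------------------------------
# rate matrix


def build_rate_matrix(
    counts: CombinedCounts, absorbing: Optional[int] = None
) -> RateMatrixResult:
    """``Q_ij = N_ij / R_i`` off-diagonal, rows summing to zero; ``Q_hat``
    drops the absorbing milestone's row and column."""
    n = counts.n_milestones
    if absorbing is None:
        absorbing = n - 1
    if not 0 <= absorbing < n:
        raise ValidationError(f"absorbing index {absorbing} outside 0..{n-1}")

    out_counts = counts.N.sum(axis=1)
    in_counts = counts.N.sum(axis=0)
    for i in range(n):
        if out_counts[i] > 0 and counts.R[i] <= 0:
            raise NumericalError(
                f"milestone {i} has outgoing transitions but zero "
                "occupation time"
            )
        if out_counts[i] == 0 and in_counts[i] == 0 and counts.R[i] <= 0:
            raise NumericalError(
                f"milestone {i} has no recorded statistics; it appears "
                "unsampled — extend the sampling"
            )

    Q = np.zeros((n, n))
    nonzero = counts.R > 0
    Q[nonzero, :] = counts.N[nonzero, :] / counts.R[nonzero, None]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    keep = [i for i in range(n) if i != absorbing]
    return RateMatrixResult(Q=Q, Q_hat=Q[np.ix_(keep, keep)], absorbing=absorbing)


# ---------------------------------------------------------------------------
# kinetics


def mfpt(rm: RateMatrixResult) -> tuple[np.ndarray, float]:
    """Mean first passage time to the absorbing milestone per milestone.

    Solves ``Q_hat @ t = -1``; the absorbing milestone's entry is fixed at
    zero.  Returns ``(mfpt_vector, residence_time)`` where the residence
    time is the bound (index 0) milestone's entry.
    """
    # semantic singularity check: every retained milestone must reach the
    # absorbing one through positive rates
    graph = nx.DiGraph(
        (rm.Q > 0) & ~np.eye(rm.n_milestones, dtype=bool)
    )
    reaching = nx.descendants(graph.reverse(copy=False), rm.absorbing)
    unreachable = [int(i) for i in rm.kept if i not in reaching]
    if unreachable:
        raise NumericalError(
            f"milestones {unreachable} cannot reach the absorbing "
            f"milestone {rm.absorbing}; the MFPT system is singular"
        )
    ones = np.ones(rm.Q_hat.shape[0])
    try:
        t_hat = _direct_solve(rm.Q_hat, -ones, context="MFPT")
    except NumericalError as err:
        raise NumericalError(
            "MFPT system is singular; some milestone is likely disconnected "
            f"from the absorbing milestone {rm.absorbing}"
        ) from err
    if np.any(t_hat < -1e-9 * max(1.0, np.abs(t_hat).max())):
        raise NumericalError("MFPT solve produced negative passage times")
    out = np.zeros(rm.n_milestones)
    out[rm.kept] = np.clip(t_hat, 0.0, None)
    bound = 0 if rm.absorbing != 0 else rm.kept[0]
    return out, float(out[bound])


def stationary_probabilities(rm: RateMatrixResult) -> np.ndarray:
    """Stationary milestone probabilities: the nonnegative, normalized
    solution of the eigenproblem ``p @ Q = 0`` for the full ``Q``."""
    Q = rm.Q
    graph = nx.DiGraph((np.abs(Q) > 0) & ~np.eye(Q.shape[0], dtype=bool))
    if not nx.is_strongly_connected(graph):
        raise NumericalError(
            "rate matrix is reducible; stationary probabilities are not "
            "unique — extend the sampling"
        )
    eigvals, eigvecs = scipy.linalg.eig(Q.T)
    k = int(np.argmin(np.abs(eigvals)))
    if abs(eigvals[k]) > 1e-8 * max(1.0, np.abs(Q).max()):
        raise NumericalError(
            f"no zero eigenvalue found (closest: {eigvals[k]:.3g})"
        )
    p = np.real(eigvecs[:, k])
    p = p * np.sign(p.sum() or 1.0)
    if np.any(p < -1e-8 * np.abs(p).max()):
        raise NumericalError("stationary eigenvector is not sign-definite")
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def free_energy_profile(
    p: np.ndarray,
    reference: int = 0,
    thermal_energy: float = 1.0,
) -> tuple[np.ndarray, tuple[int, ...]]:
    """``dG_i = -kT * ln(p_i / p_ref)`` plus transition-state milestones.

    Zero probabilities yield ``+inf`` with a warning and are excluded from
    the transition-state search.  Transition states are strict interior
    local maxima; a flat plateau that is a maximum resolves to its first
    index.
    """
    p = np.asarray(p, dtype=float)
    if not 0 <= reference < p.size:
        raise ValidationError(f"reference index {reference} out of range")
    if p[reference] <= 0:
        raise ValidationError("reference milestone has zero probability")
    with np.errstate(divide="ignore"):
        dG = -thermal_energy * np.log(p / p[reference])
    if np.any(np.isinf(dG)):
        warnings.warn(
            "zero stationary probability at milestones "
            f"{np.nonzero(np.isinf(dG))[0].tolist()}; dG reported as +inf",
            RuntimeWarning,
            stacklevel=2,
        )
    return dG, _local_maxima(dG)


def _local_maxima(dG: np.ndarray) -> tuple[int, ...]:
    finite = np.isfinite(dG)
    out = []
    i = 1
    n = dG.size
    while i < n - 1:
        if not finite[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and finite[j + 1] and dG[j + 1] == dG[i]:
            j += 1  # plateau [i..j]
        left_ok = finite[i - 1] and dG[i - 1] < dG[i]
        right_ok = j + 1 < n and finite[j + 1] and dG[j + 1] < dG[i]
        if left_ok and right_ok:
            out.append(i)
        i = j + 1
    return tuple(out)


# ---------------------------------------------------------------------------
# pipelines


def kinetics_from_counts(
    counts: CombinedCounts,
    absorbing: Optional[int] = None,
    reference: int = 0,
    thermal_energy: float = 1.0,
    pi: Optional[np.ndarray] = None,
) -> KineticsResult:
    rm = build_rate_matrix(counts, absorbing=absorbing)
    t_vec, residence = mfpt(rm)
    p = stationary_probabilities(rm)
    dG, ts = free_energy_profile(p, reference=reference,
                                 thermal_energy=thermal_energy)
    return KineticsResult(
        pi=np.array([1.0]) if pi is None else np.asarray(pi, dtype=float),
        p=p,
        mfpt=t_vec,
        residence_time=residence,
        dG=dG,
        ts_milestones=ts,
        absorbing=rm.absorbing,
        reference=reference,
    )


def estimate_kinetics(
    model: MilestoningModel, stats: Sequence[CellStatistics]
) -> KineticsResult:
    """Full pipeline: cell equilibrium, combined counts, rate matrix,
    MFPT/residence time, stationary probabilities, free-energy profile."""
    pi = solve_cell_equilibrium(stats)
    counts = combine_counts(stats, pi, n_milestones=model.n_milestones)
    return kinetics_from_counts(
        counts,
        absorbing=model.absorbing_milestone,
        reference=model.bound_milestone,
        thermal_energy=model.thermal_energy,
        pi=pi,
    )


# ---------------------------------------------------------------------------
# replica aggregation


def replica_aggregate(results: Sequence[KineticsResult]) -> ReplicaSummary:
    """Per-milestone arithmetic mean and standard error over replicas."""
    if len(results) < 2:
        raise ValidationError("need at least 2 replicas to aggregate")
    shapes = {r.mfpt.shape for r in results}
    absorbing = {r.absorbing for r in results}
    if len(shapes) != 1 or len(absorbing) != 1:
        raise ValidationError("replicas come from mismatched models")
    n = len(results)
    mfpts = np.vstack([r.mfpt for r in results])
    dGs = np.vstack([r.dG for r in results])
    residences = np.array([r.residence_time for r in results])

    def sem(arr, axis=0):
        return np.std(arr, axis=axis, ddof=1) / np.sqrt(n)

    return ReplicaSummary(
        n_replicas=n,
        mfpt_mean=mfpts.mean(axis=0),
        mfpt_sem=sem(mfpts),
        dG_mean=dGs.mean(axis=0),
        dG_sem=sem(dGs),
        residence_mean=float(residences.mean()),
        residence_sem=float(sem(residences)),
        residence_samples=tuple(residences.tolist()),
    )


def results_frame(
    model: MilestoningModel, summary: ReplicaSummary
) -> pd.DataFrame:
    """Per-milestone results table (CSV-ready)."""
    dG_mean = summary.dG_mean
    ts = set(_local_maxima(dG_mean))
    return pd.DataFrame(
        {
            "milestone": np.arange(model.n_milestones),
            "cv_value": model.milestone_values,
            "mfpt_mean": summary.mfpt_mean,
            "mfpt_sem": summary.mfpt_sem,
            "dG_mean": dG_mean,
            "dG_sem": summary.dG_sem,
            "is_TS": [i in ts for i in range(model.n_milestones)],
        }
    )


# ---------------------------------------------------------------------------
# linear algebra helper


def _direct_solve(A: np.ndarray, b: np.ndarray, context: str) -> np.ndarray:
    cond = np.linalg.cond(A)
    if not np.isfinite(cond):
        raise NumericalError(f"{context}: singular linear system")
    if cond > _COND_LIMIT:
        warnings.warn(
            f"{context}: condition number {cond:.3g} exceeds {_COND_LIMIT:g}; "
            "falling back to least squares",
            RuntimeWarning,
            stacklevel=2,
        )
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        return sol
    return np.linalg.solve(A, b)
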