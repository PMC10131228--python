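"""Multi-system orchestration: run the full pipeline per system, rank by
residence time, and test pairwise differences with Welch's t."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .dynamics import simulate_confined_bd, smd_standin
from .errors import MilekinError, ValidationError
from .estimator import (
    KineticsResult,
    ReplicaSummary,
    estimate_kinetics,
    replica_aggregate,
)
from .model import MilestoningModel
from .potentials import PotentialSpec
from .stats import collect_cell_statistics

__all__ = [
    "SystemSpec",
    "SystemResult",
    "run_system",
    "welch_ttest",
    "rank_systems",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SystemSpec:
    """One "inhibitor" system: model, potential, replica run matrix."""

    name: str
    model: MilestoningModel
    potential: PotentialSpec
    n_replicas: int = 3
    n_steps_per_cell: int = 200_000
    dt: float = 1e-3
    diffusion_coefficient: float = 1.0
    master_seed: int = 0
    include_bound_cell: bool = True  # sample all M cells (vs M-1)
    pull_speed: float = 0.05
    restraint_stiffness: float = 100.0

    def __post_init__(self) -> None:
        if self.n_replicas < 1:
            raise ValidationError("replica count must be >= 1")
        if self.n_steps_per_cell < 1 or self.dt <= 0:
            raise ValidationError("sampling budget must be positive")
        if self.diffusion_coefficient <= 0:
            raise ValidationError("diffusion coefficient must be positive")

    def cell_seed(self, replica: int, cell: int) -> np.random.SeedSequence:
        return np.random.SeedSequence(
            entropy=self.master_seed, spawn_key=(replica, cell + 1)
        )

    def smd_seed(self, replica: int) -> np.random.SeedSequence:
        return np.random.SeedSequence(
            entropy=self.master_seed, spawn_key=(replica, 0)
        )


@dataclass(frozen=True)
class SystemResult:
    spec: SystemSpec
    replicas: tuple[KineticsResult, ...]
    summary: ReplicaSummary


def _replica_summary_single(result: KineticsResult) -> ReplicaSummary:
    zeros = np.zeros_like(result.mfpt)
    return ReplicaSummary(
        n_replicas=1,
        mfpt_mean=result.mfpt.copy(),
        mfpt_sem=zeros,
        dG_mean=result.dG.copy(),
        dG_sem=zeros.copy(),
        residence_mean=result.residence_time,
        residence_sem=0.0,
        residence_samples=(result.residence_time,),
    )


def run_system(spec: SystemSpec) -> SystemResult:
    """Seed cells by pulling, sample every cell per replica, estimate
    kinetics, aggregate over replicas.  Deterministic for a fixed
    master seed; per-cell runs are independent (order-free reduction)."""
    model = spec.model
    cells = range(0 if spec.include_bound_cell else 1, model.n_cells)
    replicas: list[KineticsResult] = []
    for replica in range(spec.n_replicas):
        try:
            starts = smd_standin(
                model,
                spec.potential,
                pull_speed=spec.pull_speed,
                restraint_stiffness=spec.restraint_stiffness,
                dt=spec.dt,
                diffusion_coefficient=spec.diffusion_coefficient,
                seed=spec.smd_seed(replica),
            )
        except MilekinError as err:
            raise type(err)(
                f"system {spec.name!r} replica {replica}: seeding failed: {err}"
            ) from err
        stats = []
        for cell in cells:
            try:
                trace = simulate_confined_bd(
                    model,
                    spec.potential,
                    cell=cell,
                    start_cv=starts[cell],
                    n_steps=spec.n_steps_per_cell,
                    dt=spec.dt,
                    diffusion_coefficient=spec.diffusion_coefficient,
                    seed=spec.cell_seed(replica, cell),
                )
            except MilekinError as err:
                raise type(err)(
                    f"system {spec.name!r} replica {replica} cell {cell}: "
                    f"{err}"
                ) from err
            logger.info(
                "system=%s replica=%d cell=%d steps=%d collisions=%d",
                spec.name, replica, cell, spec.n_steps_per_cell,
                trace.n_events,
            )
            stats.append(collect_cell_statistics(trace))
        try:
            replicas.append(estimate_kinetics(model, stats))
        except MilekinError as err:
            raise type(err)(
                f"system {spec.name!r} replica {replica}: estimation "
                f"failed: {err}"
            ) from err
    if len(replicas) == 1:
        summary = _replica_summary_single(replicas[0])
    else:
        summary = replica_aggregate(replicas)
    return SystemResult(spec=spec, replicas=tuple(replicas), summary=summary)


# ---------------------------------------------------------------------------
# statistics


def welch_ttest(a: Sequence[float], b: Sequence[float]):
    """Welch's unequal-variance t-test (two-sided).

    Returns ``(t, df, p)`` with Welch-Satterthwaite degrees of freedom.
    If both samples have zero variance: p = 1 when the means are equal
    (by convention), p = 0 with infinite ``t`` otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        sign = np.sign(a.mean() - b.mean())
        return float(sign * np.inf), float(a.size + b.size - 2), 0.0
    res = scipy.stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def rank_systems(
    samples: dict[str, Sequence[float]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank systems by mean residence time (descending; alphabetical on
    exact ties, flagged) with all pairwise Welch p-values.

    ``samples`` maps system name to its per-replica residence times.
    Returns ``(ranking, pairwise)`` data frames.
    """
    if len(samples) < 2:
        raise ValidationError("need at least 2 systems to rank")
    means = {name: float(np.mean(vals)) for name, vals in samples.items()}
    sems = {
        name: (
            float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
            if len(vals) > 1
            else 0.0
        )
        for name, vals in samples.items()
    }
    order = sorted(means, key=lambda name: (-means[name], name))
    tied = {
        name
        for name in order
        if sum(1 for other in order if means[other] == means[name]) > 1
    }
    ranking = pd.DataFrame(
        {
            "system": order,
            "residence_mean": [means[name] for name in order],
            "residence_sem": [sems[name] for name in order],
            "rank": np.arange(1, len(order) + 1),
            "tied": [name in tied for name in order],
        }
    )
    rows = []
    for i, na in enumerate(order):
        for nb in order[i + 1:]:
            try:
                t, df, p = welch_ttest(samples[na], samples[nb])
            except ValidationError:
                t, df, p = np.nan, np.nan, np.nan
            rows.append(
                {"system_a": na, "system_b": nb, "t": t, "df": df, "p": p}
            )
    pairwise = pd.DataFrame(
        rows, columns=["system_a", "system_b", "t", "df", "p"]
    )
    return ranking, pairwise
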