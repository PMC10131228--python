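"""Synthetic confined dynamics along the CV.

This module replaces per-cell molecular dynamics with 1D overdamped
Brownian dynamics (Euler-Maruyama) under configurable potentials:

* :func:`simulate_confined_bd` — cell-confined sampling with reflective
  boundaries; each boundary-crossing attempt is one milestone collision.
  Position reflection of the offending step implements velocity reversal
  in the overdamped limit.
* :func:`simulate_unconfined_fpt` — brute-force first-passage times, the
  independent oracle for residence-time estimates.
* :func:`simulate_ctmc` — exact Gillespie simulation of a continuous-time
  Markov jump process with a known generator (estimator oracle).
* :func:`smd_standin` — a slow harmonic pull along the CV that records one
  starting value per cell, standing in for steered-MD seeding.

Collision times carry the time stamp of the end of the offending step
(O(dt) bias).  For a fixed seed every trace is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from . import _kernels
from .errors import TraceError, ValidationError
from .model import MilestoningModel
from .potentials import PotentialSpec

__all__ = [
    "EventTrace",
    "JumpTrace",
    "simulate_confined_bd",
    "simulate_unconfined_fpt",
    "simulate_ctmc",
    "smd_standin",
    "write_event_trace",
    "read_event_trace",
]

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]

_NOISE_CHUNK = 1 << 20


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# traces


@dataclass(frozen=True)
class EventTrace:
    """Boundary-touch events recorded in one confined-cell run.

    ``times`` and ``milestones`` are parallel arrays of collision times and
    milestone indices; ``boundary_milestones`` lists the milestones that
    border the cell (what a valid event may reference); ``total_time`` is
    the full simulated time.
    """

    cell: int
    times: np.ndarray
    milestones: np.ndarray
    total_time: float
    boundary_milestones: tuple[int, ...]
    seed: Optional[int] = None
    dt: Optional[float] = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        milestones = np.asarray(self.milestones, dtype=np.int64)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "milestones", milestones)
        if times.shape != milestones.shape or times.ndim != 1:
            raise TraceError("times and milestones must be parallel 1D arrays")
        if times.size:
            if np.any(np.diff(times) < 0):
                raise TraceError("event times must be non-decreasing")
            if times[-1] > self.total_time + 1e-12:
                raise TraceError("event time exceeds total simulated time")
            extra = set(np.unique(milestones)) - set(self.boundary_milestones)
            if extra:
                raise TraceError(
                    f"events reference milestones {sorted(extra)} that do "
                    f"not border cell {self.cell}"
                )

    @property
    def n_events(self) -> int:
        return int(self.times.size)

    def truncated(self, t_max: float) -> "EventTrace":
        """Prefix of the trace up to simulated time ``t_max``."""
        if not 0 < t_max <= self.total_time:
            raise ValidationError("t_max must be in (0, total_time]")
        keep = self.times <= t_max
        return EventTrace(
            cell=self.cell,
            times=self.times[keep],
            milestones=self.milestones[keep],
            total_time=t_max,
            boundary_milestones=self.boundary_milestones,
            seed=self.seed,
            dt=self.dt,
        )


@dataclass(frozen=True)
class JumpTrace:
    """A milestone-level jump sequence with exponential holding times.

    ``states[k]`` was occupied for ``holding_times[k]`` before jumping to
    ``states[k+1]``; if ``absorbed`` the final state was absorbing and its
    holding time is 0.
    """

    states: np.ndarray
    holding_times: np.ndarray
    absorbed: bool = False
    seed: Optional[int] = None

    @property
    def total_time(self) -> float:
        return float(self.holding_times.sum())


# ---------------------------------------------------------------------------
# confined BD


def simulate_confined_bd(
    model: MilestoningModel,
    potential: PotentialSpec,
    cell: int,
    start_cv: float,
    n_steps: int,
    dt: float,
    diffusion_coefficient: float = 1.0,
    seed: SeedLike = 0,
) -> EventTrace:
    """Sample one Voronoi cell with reflective boundaries.

    Overdamped updates ``x <- x - D*dt*d(beta*U)/dx + sqrt(2*D*dt)*xi``;
    a proposed step crossing a cell boundary is recorded as one collision
    with that milestone (time stamp = end of the offending step) and the
    position is reflected back inside.
    """
    lo, hi = model.cell_bounds(cell)
    lower_m, upper_m = model.cell_milestones(cell)
    if not lo < start_cv < hi:
        raise ValidationError(
            f"start_cv {start_cv} is not strictly inside cell {cell} "
            f"[{lo}, {hi})"
        )
    if dt <= 0 or diffusion_coefficient <= 0:
        raise ValidationError("dt and diffusion_coefficient must be positive")
    if n_steps < 1:
        raise ValidationError("n_steps must be >= 1")

    kind, params, aux = potential.packed()
    rng = _rng(seed)
    seed_val = seed if isinstance(seed, (int, np.integer)) else None

    cap = 2 * n_steps + 64
    event_step = np.empty(cap, dtype=np.int64)
    event_side = np.empty(cap, dtype=np.int8)
    all_steps = []
    all_sides = []
    x = float(start_cv)
    done = 0
    while done < n_steps:
        chunk = min(_NOISE_CHUNK, n_steps - done)
        noise = rng.standard_normal(chunk)
        n_ev, x = _kernels.bd_confined(
            x, lo, hi, dt, diffusion_coefficient, noise, kind, params, aux,
            lower_m is not None, event_step, event_side,
        )
        if n_ev == -1:
            raise ValidationError(
                f"non-finite force encountered near CV = {x!r}"
            )
        if n_ev == -2:
            raise TraceError("collision buffer exhausted; dt is too large")
        if n_ev:
            all_steps.append(event_step[:n_ev] + done)
            all_sides.append(event_side[:n_ev].copy())
        done += chunk

    if all_steps:
        steps = np.concatenate(all_steps)
        sides = np.concatenate(all_sides)
    else:
        steps = np.empty(0, dtype=np.int64)
        sides = np.empty(0, dtype=np.int8)
    times = (steps + 1) * dt
    milestones = np.where(sides == 1, upper_m, -1 if lower_m is None else lower_m)
    return EventTrace(
        cell=cell,
        times=times,
        milestones=milestones.astype(np.int64),
        total_time=n_steps * dt,
        boundary_milestones=tuple(
            m for m in (lower_m, upper_m) if m is not None
        ),
        seed=seed_val,
        dt=dt,
    )


# ---------------------------------------------------------------------------
# unconfined first-passage oracle


def simulate_unconfined_fpt(
    potential: PotentialSpec,
    start_cv: float,
    reflecting_at: float,
    absorbing_at: float,
    dt: float,
    diffusion_coefficient: float = 1.0,
    n_samples: int = 100,
    seed: SeedLike = 0,
    max_steps_per_sample: int = 1 << 28,
) -> np.ndarray:
    """Independent first-passage times from ``start_cv`` to the absorbing
    boundary with a reflecting lower wall (brute-force MFPT oracle)."""
    if not reflecting_at <= start_cv <= absorbing_at:
        raise ValidationError(
            "need reflecting_at <= start_cv <= absorbing_at, got "
            f"{reflecting_at}, {start_cv}, {absorbing_at}"
        )
    if reflecting_at >= absorbing_at:
        raise ValidationError("degenerate interval: reflecting >= absorbing")
    if dt <= 0 or diffusion_coefficient <= 0 or n_samples < 1:
        raise ValidationError("dt, D and n_samples must be positive")
    if start_cv >= absorbing_at:
        return np.zeros(n_samples)

    kind, params, aux = potential.packed()
    rng = _rng(seed)
    out = np.empty(n_samples)
    for i in range(n_samples):
        x = float(start_cv)
        steps = 0
        absorbed = False
        while not absorbed:
            if steps >= max_steps_per_sample:
                raise ValidationError(
                    "first-passage sample exceeded max_steps_per_sample"
                )
            noise = rng.standard_normal(_NOISE_CHUNK)
            x, used, absorbed = _kernels.bd_fpt_chunk(
                x, reflecting_at, absorbing_at, dt, diffusion_coefficient,
                noise, kind, params, aux,
            )
            steps += used
        out[i] = steps * dt
    return out


# ---------------------------------------------------------------------------
# CTMC oracle


def validate_generator(generator: np.ndarray) -> np.ndarray:
    q = np.asarray(generator, dtype=float)
    if q.ndim != 2 or q.shape[0] != q.shape[1] or q.shape[0] < 2:
        raise ValidationError("generator must be square with >= 2 states")
    off = q - np.diag(np.diag(q))
    for row in range(q.shape[0]):
        if np.any(off[row] < 0):
            raise ValidationError(
                f"generator row {row} has a negative off-diagonal rate"
            )
        if abs(q[row].sum()) > 1e-10 * max(1.0, np.abs(q[row]).max()):
            raise ValidationError(f"generator row {row} does not sum to zero")
    return q


def simulate_ctmc(
    generator_matrix: np.ndarray,
    total_jumps: int,
    seed: SeedLike = 0,
    start_state: int = 0,
) -> JumpTrace:
    """Exact Gillespie simulation: exponential holding with rate
    ``|Q_ii|``, jump to ``j`` with probability ``Q_ij / |Q_ii|``.  Stops
    early (reporting absorption) if an absorbing state is entered."""
    q = validate_generator(generator_matrix)
    if total_jumps < 1:
        raise ValidationError("total_jumps must be >= 1")
    n = q.shape[0]
    rates = -np.diag(q)
    probs = np.where(rates[:, None] > 0, q / np.where(rates == 0, 1, rates)[:, None], 0.0)
    np.fill_diagonal(probs, 0.0)

    rng = _rng(seed)
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    states = np.empty(total_jumps + 1, dtype=np.int64)
    holds = np.empty(total_jumps + 1, dtype=float)
    state = int(start_state)
    absorbed = False
    k = 0
    while k < total_jumps:
        states[k] = state
        if rates[state] <= 0:
            holds[k] = 0.0
            absorbed = True
            k += 1
            break
        holds[k] = rng.exponential(1.0 / rates[state])
        state = int(rng.choice(n, p=probs[state]))
        k += 1
    if not absorbed:
        states[k] = state
        holds[k] = 0.0
        k += 1
    return JumpTrace(
        states=states[:k], holding_times=holds[:k], absorbed=absorbed,
        seed=seed_val,
    )


# ---------------------------------------------------------------------------
# pulling stand-in for steered seeding


def smd_standin(
    model: MilestoningModel,
    potential: PotentialSpec,
    pull_speed: float,
    restraint_stiffness: float,
    dt: float,
    diffusion_coefficient: float = 1.0,
    seed: SeedLike = 0,
    pull_distance: Optional[float] = None,
) -> dict[int, float]:
    """Seed one starting CV value per cell with a slow harmonic pull.

    A moving restraint drags the walker from inside the bound cell to the
    outermost milestone; the first position observed strictly inside each
    cell is recorded.  Raises if the schedule leaves any cell unseeded.
    """
    if pull_speed <= 0 or restraint_stiffness <= 0:
        raise ValidationError("pull_speed and restraint_stiffness must be > 0")
    if dt <= 0 or diffusion_coefficient <= 0:
        raise ValidationError("dt and diffusion_coefficient must be positive")
    start = 0.5 * model.milestone_values[0]
    if pull_distance is None:
        pull_distance = float(model.milestone_values[-1] - start)
    n_steps = int(np.ceil(pull_distance / (pull_speed * dt)))
    edges = np.concatenate(([0.0], model.milestone_values))
    start_vals = np.full(model.n_cells, np.nan)
    start_vals[0] = start

    kind, params, aux = potential.packed()
    rng = _rng(seed)
    x = start
    done = 0
    while done < n_steps:
        chunk = min(_NOISE_CHUNK, n_steps - done)
        noise = rng.standard_normal(chunk)
        x = _kernels.bd_pulled(
            x, dt, diffusion_coefficient, noise, kind, params, aux,
            restraint_stiffness, start + pull_speed * dt * done,
            pull_speed, edges, start_vals,
        )
        done += chunk

    missing = [int(c) for c in np.nonzero(np.isnan(start_vals))[0]]
    if missing:
        raise ValidationError(
            f"pull schedule failed to seed cells {missing}; increase "
            "pull_distance or slow the pull"
        )
    return {cell: float(v) for cell, v in enumerate(start_vals)}


# ---------------------------------------------------------------------------
# JSON-lines trace serialization


def write_event_trace(trace: EventTrace, path) -> None:
    """Header record then one ``{"t": ..., "m": ...}`` object per event."""
    with open(path, "w") as fh:
        header = {
            "cell": trace.cell,
            "seed": trace.seed,
            "dt": trace.dt,
            "total_time": trace.total_time,
            "boundary_milestones": list(trace.boundary_milestones),
        }
        fh.write(json.dumps(header) + "\n")
        for t, m in zip(trace.times, trace.milestones):
            fh.write(json.dumps({"t": float(t), "m": int(m)}) + "\n")


def read_event_trace(path) -> EventTrace:
    with open(path) as fh:
        lines = [line for line in fh.read().split("\n") if line.strip()]
    if not lines:
        raise TraceError(f"empty trace file: {path}")
    header = json.loads(lines[0])
    times = np.empty(len(lines) - 1)
    milestones = np.empty(len(lines) - 1, dtype=np.int64)
    for i, line in enumerate(lines[1:]):
        rec = json.loads(line)
        times[i] = rec["t"]
        milestones[i] = rec["m"]
    return EventTrace(
        cell=int(header["cell"]),
        times=times,
        milestones=milestones,
        total_time=float(header["total_time"]),
        boundary_milestones=tuple(header["boundary_milestones"]),
        seed=header.get("seed"),
        dt=header.get("dt"),
    )
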