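"""Sufficient statistics harvested from confined-cell event traces.

For a cell ``alpha`` the estimator needs:

* ``N[i][j]`` — collisions with milestone ``j`` after having last touched
  milestone ``i`` (``i != j``),
* ``R[i]`` — simulation time spent having last touched milestone ``i``,
* ``T`` — total attributable time in the cell (``sum_i R[i]`` exactly),
* ``N_boundary[m]`` — total collisions with each bounding milestone,
  including same-milestone re-touches.

Time before the first touch cannot be attributed to any last-touched
milestone; it is tracked as ``excluded_time`` and excluded from ``T``.
Same-milestone re-touches enter ``N_boundary`` only, never ``N``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import TraceError, ValidationError
from .dynamics import EventTrace, JumpTrace

__all__ = [
    "CellStatistics",
    "collect_cell_statistics",
    "merge_statistics",
    "counts_from_jump_trace",
    "convergence_series",
    "write_statistics",
    "read_statistics",
    "statistics_frame",
]

SCHEMA = "mmvt_stats_v1"


@dataclass
class CellStatistics:
    """Milestoning sufficient statistics for one Voronoi cell."""

    cell: int
    boundary_milestones: tuple[int, ...]
    N: dict[tuple[int, int], int] = field(default_factory=dict)
    R: dict[int, float] = field(default_factory=dict)
    T: float = 0.0
    N_boundary: dict[int, int] = field(default_factory=dict)
    excluded_time: float = 0.0

    def validate(self) -> None:
        if any(v < 0 for v in self.N.values()):
            raise ValidationError("negative transition count")
        if any(v < 0 for v in self.R.values()) or self.T < 0:
            raise ValidationError("negative time")
        if self.T and abs(sum(self.R.values()) - self.T) > 1e-9 * self.T:
            raise ValidationError(
                f"cell {self.cell}: sum(R) = {sum(self.R.values())} does "
                f"not partition T = {self.T}"
            )
        borders = set(self.boundary_milestones)
        touched = (
            {i for pair in self.N for i in pair}
            | set(self.R)
            | set(self.N_boundary)
        )
        if touched - borders:
            raise ValidationError(
                f"cell {self.cell}: statistics reference milestones "
                f"{sorted(touched - borders)} outside its boundary set"
            )

    @property
    def total_collisions(self) -> int:
        return sum(self.N_boundary.values())


def collect_cell_statistics(
    trace: EventTrace, initial_milestone: Optional[int] = None
) -> CellStatistics:
    """Walk the event list of one confined run.

    Maintains the last-touched milestone; a touch of a different milestone
    increments ``N[last][new]``; every touch increments ``N_boundary``;
    occupation time between events accrues to ``R[last]``.  Time before
    the first touch goes to ``excluded_time``.

    ``initial_milestone`` carries a last-touched state into the segment
    (for continuation segments cut at an event): occupation then accrues
    from time zero with nothing excluded, and the virtual initial touch is
    not counted in ``N_boundary``.
    """
    borders = set(trace.boundary_milestones)
    stats = CellStatistics(
        cell=trace.cell, boundary_milestones=tuple(trace.boundary_milestones)
    )
    times = trace.times
    milestones = trace.milestones
    if initial_milestone is not None and initial_milestone not in borders:
        raise TraceError(
            f"initial milestone {initial_milestone} does not border cell "
            f"{trace.cell}"
        )
    if times.size == 0:
        if initial_milestone is None:
            stats.excluded_time = float(trace.total_time)
        else:
            stats.R[initial_milestone] = float(trace.total_time)
            stats.T = float(trace.total_time)
        return stats
    extra = set(np.unique(milestones)) - borders
    if extra:
        raise TraceError(
            f"trace for cell {trace.cell} references milestones "
            f"{sorted(extra)} that do not border it"
        )

    if initial_milestone is None:
        stats.excluded_time = float(times[0])
        last = int(milestones[0])
        prev_t = float(times[0])
        stats.N_boundary[last] = stats.N_boundary.get(last, 0) + 1
        start_idx = 1
    else:
        last = int(initial_milestone)
        prev_t = 0.0
        start_idx = 0
    for k in range(start_idx, times.size):
        t = float(times[k])
        m = int(milestones[k])
        stats.R[last] = stats.R.get(last, 0.0) + (t - prev_t)
        stats.N_boundary[m] = stats.N_boundary.get(m, 0) + 1
        if m != last:
            stats.N[(last, m)] = stats.N.get((last, m), 0) + 1
            last = m
        prev_t = t
    stats.R[last] = stats.R.get(last, 0.0) + (float(trace.total_time) - prev_t)
    stats.T = sum(stats.R.values())
    stats.validate()
    return stats


def merge_statistics(parts: Sequence[CellStatistics]) -> CellStatistics:
    """Component-wise sum of statistics segments for the same cell.

    Last-touched state does not carry across segments: each segment has
    already excluded its own pre-first-touch time.
    """
    if not parts:
        raise ValidationError("nothing to merge")
    cells = {p.cell for p in parts}
    if len(cells) != 1:
        raise ValidationError(f"cannot merge statistics of cells {sorted(cells)}")
    borders = tuple(sorted(set().union(*(p.boundary_milestones for p in parts))))
    out = CellStatistics(cell=parts[0].cell, boundary_milestones=borders)
    for p in parts:
        for key, v in p.N.items():
            out.N[key] = out.N.get(key, 0) + v
        for i, v in p.R.items():
            out.R[i] = out.R.get(i, 0.0) + v
        for m, v in p.N_boundary.items():
            out.N_boundary[m] = out.N_boundary.get(m, 0) + v
        out.T += p.T
        out.excluded_time += p.excluded_time
    out.validate()
    return out


def counts_from_jump_trace(trace: JumpTrace, n_states: Optional[int] = None):
    """Transition counts and occupation times of a milestone jump sequence.

    Returns a :class:`milekin.estimator.CombinedCounts` directly — a jump
    trace already lives at the milestone level, so no cell weighting
    applies (equivalently: one cell with unit weight).
    """
    from .estimator import CombinedCounts

    states = np.asarray(trace.states, dtype=np.int64)
    holds = np.asarray(trace.holding_times, dtype=float)
    if n_states is None:
        n_states = int(states.max()) + 1
    N = np.zeros((n_states, n_states))
    R = np.zeros(n_states)
    np.add.at(R, states, holds)
    if states.size > 1:
        np.add.at(N, (states[:-1], states[1:]), 1)
    np.fill_diagonal(N, 0.0)
    return CombinedCounts(N=N, R=R, T=float(holds.sum()))


def convergence_series(
    traces: Sequence[EventTrace],
    window_count: int,
    model,
) -> pd.DataFrame:
    """Cumulative-prefix MFPT estimates for convergence monitoring.

    Each trace is truncated to ``w / window_count`` of its total time for
    ``w = 1..window_count``; the full estimator runs on every prefix.
    Windows where estimation fails (e.g. disconnected statistics in a
    short prefix) are reported as NaN rather than raised.
    """
    from .errors import MilekinError
    from .estimator import estimate_kinetics

    if window_count < 2:
        raise ValidationError("need at least 2 windows")
    rows = []
    for w in range(1, window_count + 1):
        frac = w / window_count
        try:
            stats = [
                collect_cell_statistics(tr.truncated(frac * tr.total_time))
                for tr in traces
            ]
            result = estimate_kinetics(model, stats)
            residence = result.residence_time
        except MilekinError:
            residence = np.nan
        rows.append({"window": w, "time_fraction": frac, "mfpt": residence})
    frame = pd.DataFrame(rows)
    final, prev = frame["mfpt"].iloc[-1], frame["mfpt"].iloc[-2]
    frame.attrs["final_relative_change"] = (
        abs(final - prev) / abs(final) if np.isfinite(final) and final else np.nan
    )
    return frame


# ---------------------------------------------------------------------------
# serialization


def _cell_to_dict(s: CellStatistics) -> dict:
    return {
        "alpha": s.cell,
        "boundary_milestones": list(s.boundary_milestones),
        "N": [[i, j, c] for (i, j), c in sorted(s.N.items())],
        "R": [[i, t] for i, t in sorted(s.R.items())],
        "T": s.T,
        "N_boundary": [[m, c] for m, c in sorted(s.N_boundary.items())],
        "excluded_time": s.excluded_time,
    }


def _cell_from_dict(d: dict) -> CellStatistics:
    return CellStatistics(
        cell=int(d["alpha"]),
        boundary_milestones=tuple(d["boundary_milestones"]),
        N={(int(i), int(j)): int(c) for i, j, c in d["N"]},
        R={int(i): float(t) for i, t in d["R"]},
        T=float(d["T"]),
        N_boundary={int(m): int(c) for m, c in d["N_boundary"]},
        excluded_time=float(d.get("excluded_time", 0.0)),
    )


def write_statistics(stats: Sequence[CellStatistics], path) -> None:
    doc = {"schema": SCHEMA, "cells": [_cell_to_dict(s) for s in stats]}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_statistics(path) -> list[CellStatistics]:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema") != SCHEMA:
        raise ValidationError(
            f"unsupported statistics schema {doc.get('schema')!r}; "
            f"expected {SCHEMA!r}"
        )
    out = [_cell_from_dict(d) for d in doc["cells"]]
    for s in out:
        s.validate()
    return out


def statistics_frame(stats: Sequence[CellStatistics]) -> pd.DataFrame:
    """Flattened long-format table of all counts and times, for inspection."""
    rows = []
    for s in stats:
        for (i, j), c in sorted(s.N.items()):
            rows.append({"cell": s.cell, "kind": "N", "i": i, "j": j, "value": c})
        for i, t in sorted(s.R.items()):
            rows.append({"cell": s.cell, "kind": "R", "i": i, "j": -1, "value": t})
        for m, c in sorted(s.N_boundary.items()):
            rows.append(
                {"cell": s.cell, "kind": "N_boundary", "i": m, "j": -1, "value": c}
            )
        rows.append({"cell": s.cell, "kind": "T", "i": -1, "j": -1, "value": s.T})
        rows.append(
            {"cell": s.cell, "kind": "excluded_time", "i": -1, "j": -1,
             "value": s.excluded_time}
        )
    return pd.DataFrame(rows, columns=["cell", "kind", "i", "j", "value"])
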