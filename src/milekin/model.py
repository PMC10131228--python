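"""Tessellation of a scalar collective variable (CV) into cells and milestones.

The CV axis is partitioned by ``M`` strictly increasing milestone values
``m_0 < m_1 < ... < m_{M-1}`` into ``M`` half-open cells::

    cell 0 = [0, m_0)          (bound cell)
    cell k = [m_{k-1}, m_k)    for k = 1 .. M-1

so the cell count equals the milestone count.  Milestone ``i`` is the upper
boundary of cell ``i`` and the lower boundary of cell ``i + 1``; the
outermost milestone ``M - 1`` is the absorbing interface for unbinding
kinetics and bounds only cell ``M - 1`` from above.  A CV value exactly at a
milestone belongs to the cell above it (half-open convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .errors import ModelDefinitionError, OutOfDomainError, ValidationError

__all__ = [
    "MilestoningModel",
    "build_radial_model",
    "assign_cell",
    "milestone_between",
]


@dataclass(frozen=True)
class MilestoningModel:
    """Ordered milestone values along a scalar CV plus the thermal energy.

    Parameters
    ----------
    milestone_values
        Strictly increasing, positive CV values (e.g. COM-COM distances in
        angstroms).  Length ``M >= 2``.
    thermal_energy
        ``k_B * T`` in the energy units used for free-energy output.  The
        default of 1.0 reports free energies in units of ``k_B T``.
    cv_units, time_units
        Labels only; carried through serialization.
    """

    milestone_values: np.ndarray
    thermal_energy: float = 1.0
    cv_units: str = "angstrom"
    time_units: str = "ps"

    def __post_init__(self) -> None:
        values = np.asarray(self.milestone_values, dtype=float)
        object.__setattr__(self, "milestone_values", values)
        if values.ndim != 1 or values.size < 2:
            raise ModelDefinitionError(
                "at least two milestone values are required, got "
                f"{values.size}"
            )
        if not np.all(np.isfinite(values)):
            raise ModelDefinitionError("milestone values must be finite")
        bad = np.nonzero(values <= 0)[0]
        if bad.size:
            raise ModelDefinitionError(
                f"milestone values must be positive; entry {bad[0]} is "
                f"{values[bad[0]]!r}"
            )
        diffs = np.diff(values)
        bad = np.nonzero(diffs <= 0)[0]
        if bad.size:
            raise ModelDefinitionError(
                "milestones must be strictly increasing; entry "
                f"{bad[0] + 1} ({values[bad[0] + 1]!r}) does not exceed "
                f"entry {bad[0]} ({values[bad[0]]!r})"
            )
        if not self.thermal_energy > 0:
            raise ModelDefinitionError("thermal_energy must be positive")

    # -- structure ---------------------------------------------------------

    @property
    def n_milestones(self) -> int:
        return int(self.milestone_values.size)

    @property
    def n_cells(self) -> int:
        return self.n_milestones

    @property
    def bound_milestone(self) -> int:
        return 0

    @property
    def absorbing_milestone(self) -> int:
        return self.n_milestones - 1

    def cell_bounds(self, cell: int) -> tuple[float, float]:
        """Half-open interval ``[lo, hi)`` of ``cell``."""
        self._check_cell(cell)
        lo = 0.0 if cell == 0 else float(self.milestone_values[cell - 1])
        return lo, float(self.milestone_values[cell])

    def cell_milestones(self, cell: int) -> tuple[Optional[int], int]:
        """(lower, upper) milestone indices of ``cell``; lower is ``None``
        for the bound cell, whose lower edge is the hard wall at CV = 0."""
        self._check_cell(cell)
        return (None if cell == 0 else cell - 1), cell

    def _check_cell(self, cell: int) -> None:
        if not 0 <= cell < self.n_cells:
            raise ValidationError(
                f"cell index {cell} outside 0..{self.n_cells - 1}"
            )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "milestones": self.milestone_values.tolist(),
            "thermal_energy": self.thermal_energy,
            "units": {"cv": self.cv_units, "time": self.time_units},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "MilestoningModel":
        units = data.get("units", {})
        return cls(
            milestone_values=np.asarray(data["milestones"], dtype=float),
            thermal_energy=float(data.get("thermal_energy", 1.0)),
            cv_units=units.get("cv", "angstrom"),
            time_units=units.get("time", "ps"),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "MilestoningModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_radial_model(
    milestone_values: Sequence[float], thermal_energy: float = 1.0, **kwargs
) -> MilestoningModel:
    """Build a radial (1D) milestoning model from concentric milestone radii.

    The innermost milestone is the bound-state interface, the outermost the
    absorbing one.  Raises :class:`ModelDefinitionError` for non-monotone,
    duplicate, or non-positive radii.
    """
    return MilestoningModel(
        milestone_values=np.asarray(milestone_values, dtype=float),
        thermal_energy=thermal_energy,
        **kwargs,
    )


def assign_cell(
    model: MilestoningModel, cv_value: Union[float, np.ndarray]
) -> Union[int, np.ndarray]:
    """Map CV value(s) to the index of the containing cell.

    Boundary values belong to the cell above (half-open convention).
    Values outside ``[0, m_{M-1})`` raise :class:`OutOfDomainError`, which
    for the upper side signals escape past the absorbing milestone.
    """
    values = np.asarray(cv_value, dtype=float)
    outer = model.milestone_values[-1]
    if np.any(values < 0) or np.any(values >= outer) or not np.all(
        np.isfinite(values)
    ):
        raise OutOfDomainError(
            f"CV value {cv_value!r} outside the tessellated range "
            f"[0, {outer})"
        )
    cells = np.searchsorted(model.milestone_values, values, side="right")
    if np.isscalar(cv_value) or values.ndim == 0:
        return int(cells)
    return cells.astype(int)


def milestone_between(
    model: MilestoningModel, cell_a: int, cell_b: int
) -> Optional[int]:
    """Index of the milestone shared by two cells, or ``None`` if the cells
    are not adjacent.  Symmetric in its arguments."""
    model._check_cell(cell_a)
    model._check_cell(cell_b)
    if abs(cell_a - cell_b) != 1:
        return None
    return min(cell_a, cell_b)
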