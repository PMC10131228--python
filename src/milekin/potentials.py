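"""Configurable 1D potentials in units of thermal energy (beta * U).

These stand in for the molecular force field in the synthetic dynamics.
Four kinds are supported:

``flat``
    beta*U = 0 everywhere (free diffusion).
``harmonic``
    beta*U = 0.5 * stiffness * (x - center)**2.
``double_barrier``
    Two Gaussian barriers plus an optional Gaussian well, emulating an
    unbinding profile with a bound well and two transition states::

        beta*U(x) = h1*g(x; b1, w1) + h2*g(x; b2, w2) - d*g(x; c, wc)

    with ``g(x; m, s) = exp(-(x - m)**2 / (2 s**2))``.
``tabulated``
    Piecewise-linear interpolation of (cv, beta*U) knots; the energy is
    clamped to the end values outside the knot range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError

__all__ = ["PotentialSpec"]

_KIND_CODES = {"flat": 0, "harmonic": 1, "double_barrier": 2, "tabulated": 3}


@dataclass(frozen=True)
class PotentialSpec:
    kind: str = "flat"
    # harmonic
    stiffness: float = 1.0
    center: float = 0.0
    # double_barrier
    barrier_positions: Optional[tuple[float, float]] = None
    barrier_heights: Optional[tuple[float, float]] = None
    barrier_widths: tuple[float, float] = (1.0, 1.0)
    well_depth: float = 0.0
    well_center: float = 0.0
    well_width: float = 1.0
    # tabulated
    knots_cv: Optional[tuple[float, ...]] = None
    knots_beta_u: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.kind not in _KIND_CODES:
            raise ValidationError(
                f"unknown potential kind {self.kind!r}; expected one of "
                f"{sorted(_KIND_CODES)}"
            )
        if self.kind == "double_barrier":
            if self.barrier_positions is None or self.barrier_heights is None:
                raise ValidationError(
                    "double_barrier requires barrier_positions and "
                    "barrier_heights"
                )
            b1, b2 = self.barrier_positions
            if not b1 < b2:
                raise ValidationError(
                    "double_barrier positions must be strictly increasing; "
                    f"got {self.barrier_positions}"
                )
            if min(self.barrier_widths) <= 0 or self.well_width <= 0:
                raise ValidationError("Gaussian widths must be positive")
        if self.kind == "tabulated":
            if self.knots_cv is None or self.knots_beta_u is None:
                raise ValidationError(
                    "tabulated requires knots_cv and knots_beta_u"
                )
            xs = np.asarray(self.knots_cv, dtype=float)
            us = np.asarray(self.knots_beta_u, dtype=float)
            if xs.size != us.size or xs.size < 2:
                raise ValidationError("need >= 2 matching tabulated knots")
            if np.any(np.diff(xs) <= 0):
                raise ValidationError("tabulated knots_cv must increase")
            if not np.all(np.isfinite(us)):
                raise ValidationError("tabulated beta*U must be finite")

    # -- evaluation (vectorized numpy; kernels use the packed form) --------

    def beta_u(self, x):
        """beta * U at CV value(s) ``x``."""
        x = np.asarray(x, dtype=float)
        if self.kind == "flat":
            return np.zeros_like(x)
        if self.kind == "harmonic":
            return 0.5 * self.stiffness * (x - self.center) ** 2
        if self.kind == "double_barrier":
            (b1, b2) = self.barrier_positions
            (h1, h2) = self.barrier_heights
            (w1, w2) = self.barrier_widths
            u = h1 * np.exp(-((x - b1) ** 2) / (2 * w1**2))
            u = u + h2 * np.exp(-((x - b2) ** 2) / (2 * w2**2))
            if self.well_depth:
                u = u - self.well_depth * np.exp(
                    -((x - self.well_center) ** 2) / (2 * self.well_width**2)
                )
            return u
        xs = np.asarray(self.knots_cv, dtype=float)
        us = np.asarray(self.knots_beta_u, dtype=float)
        return np.interp(x, xs, us)

    def force(self, x):
        """-d(beta*U)/dx at CV value(s) ``x`` (units of 1/CV)."""
        x = np.asarray(x, dtype=float)
        if self.kind == "flat":
            return np.zeros_like(x)
        if self.kind == "harmonic":
            return -self.stiffness * (x - self.center)
        if self.kind == "double_barrier":
            (b1, b2) = self.barrier_positions
            (h1, h2) = self.barrier_heights
            (w1, w2) = self.barrier_widths
            f = h1 * (x - b1) / w1**2 * np.exp(-((x - b1) ** 2) / (2 * w1**2))
            f = f + h2 * (x - b2) / w2**2 * np.exp(
                -((x - b2) ** 2) / (2 * w2**2)
            )
            if self.well_depth:
                f = f - self.well_depth * (x - self.well_center) / (
                    self.well_width**2
                ) * np.exp(
                    -((x - self.well_center) ** 2) / (2 * self.well_width**2)
                )
            return f
        xs = np.asarray(self.knots_cv, dtype=float)
        us = np.asarray(self.knots_beta_u, dtype=float)
        slopes = np.diff(us) / np.diff(xs)
        idx = np.clip(np.searchsorted(xs, x, side="right") - 1, 0, xs.size - 2)
        f = -slopes[idx]
        f = np.where((x <= xs[0]) | (x >= xs[-1]), 0.0, f)
        return f

    # -- packing for the compiled kernels ----------------------------------

    def packed(self) -> tuple[int, np.ndarray, np.ndarray]:
        """(kind code, params, aux) for the numba integrators."""
        code = _KIND_CODES[self.kind]
        empty = np.empty(0, dtype=float)
        if self.kind == "flat":
            return code, empty, empty
        if self.kind == "harmonic":
            return code, np.array([self.stiffness, self.center]), empty
        if self.kind == "double_barrier":
            (b1, b2) = self.barrier_positions
            (h1, h2) = self.barrier_heights
            (w1, w2) = self.barrier_widths
            params = np.array(
                [
                    b1, h1, w1,
                    b2, h2, w2,
                    self.well_center, self.well_depth, self.well_width,
                ]
            )
            return code, params, empty
        xs = np.asarray(self.knots_cv, dtype=float)
        us = np.asarray(self.knots_beta_u, dtype=float)
        return code, xs, us

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        out = {"kind": self.kind}
        if self.kind == "harmonic":
            out.update(stiffness=self.stiffness, center=self.center)
        elif self.kind == "double_barrier":
            out.update(
                barrier_positions=list(self.barrier_positions),
                barrier_heights=list(self.barrier_heights),
                barrier_widths=list(self.barrier_widths),
                well_depth=self.well_depth,
                well_center=self.well_center,
                well_width=self.well_width,
            )
        elif self.kind == "tabulated":
            out.update(
                knots_cv=list(self.knots_cv),
                knots_beta_u=list(self.knots_beta_u),
            )
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "PotentialSpec":
        data = dict(data)
        kind = data.pop("kind", "flat")
        for key in ("barrier_positions", "barrier_heights", "barrier_widths",
                    "knots_cv", "knots_beta_u"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(kind=kind, **data)
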