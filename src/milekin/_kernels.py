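"""Compiled inner loops for the Brownian-dynamics integrators.

All kernels take the potential as ``(kind, params, aux)`` produced by
:meth:`milekin.potentials.PotentialSpec.packed` and a pre-drawn array of
standard-normal increments, so random-number generation stays with numpy
Generators in the calling code (bit-reproducible for a fixed seed).
"""

import numba
import numpy as np

KIND_FLAT = 0
KIND_HARMONIC = 1
KIND_DOUBLE_BARRIER = 2
KIND_TABULATED = 3


@numba.njit(cache=True, inline="always")
def _force(x, kind, params, aux):
    if kind == KIND_FLAT:
        return 0.0
    if kind == KIND_HARMONIC:
        return -params[0] * (x - params[1])
    if kind == KIND_DOUBLE_BARRIER:
        b1, h1, w1 = params[0], params[1], params[2]
        b2, h2, w2 = params[3], params[4], params[5]
        wc, d, ww = params[6], params[7], params[8]
        f = h1 * (x - b1) / (w1 * w1) * np.exp(
            -((x - b1) ** 2) / (2.0 * w1 * w1)
        )
        f += h2 * (x - b2) / (w2 * w2) * np.exp(
            -((x - b2) ** 2) / (2.0 * w2 * w2)
        )
        if d != 0.0:
            f -= d * (x - wc) / (ww * ww) * np.exp(
                -((x - wc) ** 2) / (2.0 * ww * ww)
            )
        return f
    # tabulated: params = knot CVs, aux = knot beta*U; clamped outside
    n = params.shape[0]
    if x <= params[0] or x >= params[n - 1]:
        return 0.0
    lo, hi = 0, n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if params[mid] <= x:
            lo = mid
        else:
            hi = mid
    return -(aux[lo + 1] - aux[lo]) / (params[lo + 1] - params[lo])


@numba.njit(cache=True)
def bd_confined(
    x0, lo, hi, dt, diffusion, noise, kind, params, aux,
    record_lower, event_step, event_side,
):
    """Overdamped Euler-Maruyama confined to [lo, hi] by reflection.

    A proposed step crossing a boundary records one collision event (step
    index + side: 0 lower / 1 upper) and is reflected back inside.  Returns
    (number of events, final position).  ``record_lower`` is False for the
    bound cell whose lower edge is a hard wall, not a milestone.
    """
    x = x0
    amp = np.sqrt(2.0 * diffusion * dt)
    n_events = 0
    n_steps = noise.shape[0]
    for step in range(n_steps):
        f = _force(x, kind, params, aux)
        if not np.isfinite(f):
            return -1, x  # caller raises, naming the CV value
        xn = x + diffusion * dt * f + amp * noise[step]
        # reflect until inside; each boundary crossing is one collision
        for _ in range(64):
            if n_events + 1 >= event_step.shape[0]:
                return -2, x  # event buffer exhausted; caller raises
            if xn < lo:
                if record_lower:
                    event_step[n_events] = step
                    event_side[n_events] = 0
                    n_events += 1
                xn = 2.0 * lo - xn
            elif xn > hi:
                event_step[n_events] = step
                event_side[n_events] = 1
                n_events += 1
                xn = 2.0 * hi - xn
            else:
                break
        else:
            # pathological step size; pin to the cell midpoint
            xn = 0.5 * (lo + hi)
        x = xn
    return n_events, x


@numba.njit(cache=True)
def bd_fpt_chunk(x0, reflecting, absorbing, dt, diffusion, noise, kind,
                 params, aux):
    """Run at most ``noise.shape[0]`` steps; stop at first passage of
    ``absorbing``.  Returns (final position, steps consumed, absorbed)."""
    x = x0
    amp = np.sqrt(2.0 * diffusion * dt)
    for step in range(noise.shape[0]):
        f = _force(x, kind, params, aux)
        xn = x + diffusion * dt * f + amp * noise[step]
        if xn >= absorbing:
            return xn, step + 1, True
        if xn < reflecting:
            xn = 2.0 * reflecting - xn
            if xn > absorbing:
                return xn, step + 1, True
        x = xn
    return x, noise.shape[0], False


@numba.njit(cache=True)
def bd_pulled(
    x0, dt, diffusion, noise, kind, params, aux,
    restraint_k, center0, pull_speed, edges, start_vals,
):
    """BD under the potential plus a moving harmonic restraint.

    ``edges`` are the cell boundaries (length n_cells + 1, edges[0] = 0);
    the first position observed strictly inside each cell is written into
    ``start_vals`` (pre-filled with NaN).  The walk reflects at CV = 0.
    """
    x = x0
    amp = np.sqrt(2.0 * diffusion * dt)
    n_cells = start_vals.shape[0]
    for step in range(noise.shape[0]):
        center = center0 + pull_speed * dt * step
        f = _force(x, kind, params, aux) - restraint_k * (x - center)
        x = x + diffusion * dt * f + amp * noise[step]
        if x < 0.0:
            x = -x
        # locate the containing cell (half-open upper assignment)
        if x < edges[n_cells]:
            lo, hi = 0, n_cells
            while hi - lo > 1:
                mid = (lo + hi) // 2
                if edges[mid] <= x:
                    lo = mid
                else:
                    hi = mid
            cell = lo
            if np.isnan(start_vals[cell]) and edges[cell] < x < edges[cell + 1]:
                start_vals[cell] = x
    return x
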