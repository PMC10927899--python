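"""Finite-difference core for the 1D diffusion equation.

A single θ = 1/2 (Crank–Nicolson) tridiagonal stepper serves both the
coarse fitting grid and the fine synthetic-data grid; the two callers use
different spatial/temporal resolutions, so inverse fits are never tested
against their own discretization.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.linalg import cho_solve_banded, cholesky_banded

__all__ = ["crank_nicolson_1d"]


def _factor(r: float, m: int):
    """Cholesky factor of the SPD tridiagonal (1 + r, -r/2) system, banded form."""
    ab = np.zeros((2, m))
    ab[0, 1:] = -r / 2.0
    ab[1, :] = 1.0 + r
    return (cholesky_banded(ab), False)


def crank_nicolson_1d(
    diffusivity: float,
    dy: float,
    n_nodes: int,
    dt: float,
    lower: Callable[[np.ndarray], np.ndarray],
    output_steps: Sequence[int],
    rannacher_substeps: int = 2,
    n_accumulate: int = 0,
):
    """Solve u_t = D u_yy with zero initial condition, Dirichlet data
    ``lower(t)`` at node 0 and 0 at the last node.

    Parameters
    ----------
    output_steps : step indices (multiples of ``dt``) at which the field is
        returned, in increasing order.
    rannacher_substeps : number of backward-Euler half-steps replacing the
        first CN step. CN is A-stable but not L-stable; with the large mesh
        ratios used here (D·dt/dy² ≫ 1) a non-smooth start (e.g. a step
        boundary) excites slowly-decaying ±1 oscillations. Implicit-Euler
        startup damps them without affecting second-order accuracy for
        smooth data.
    n_accumulate : 0, 1 or 2 — also return the trapezoid-rule running time
        integral of the field (and of that integral) at the output steps.

    Returns
    -------
    out : (len(output_steps), n_nodes) array, plus up to two integral arrays
        of the same shape when ``n_accumulate`` > 0.
    """
    if diffusivity <= 0:
        raise ValueError("diffusivity must be positive")
    if n_nodes < 3:
        raise ValueError("grid must have at least 3 nodes")
    output_steps = np.asarray(output_steps, dtype=int)
    if np.any(output_steps < 0) or np.any(np.diff(output_steps) <= 0) and output_steps.size > 1:
        raise ValueError("output_steps must be non-negative and increasing")

    m = n_nodes - 2  # interior unknowns
    r = diffusivity * dt / dy**2
    cn_fac = _factor(r, m)
    # backward Euler on dt/2: (1 + 2*r_h) with r_h = D*(dt/2)/dy^2 = r/2
    be_fac = _factor(r, m)  # note: 1 + 2*(r/2) = 1 + r, same matrix

    u = np.zeros(n_nodes)
    n_steps = int(output_steps[-1]) if output_steps.size else 0

    out = np.empty((len(output_steps), n_nodes))
    cum1 = np.zeros(n_nodes)
    cum2 = np.zeros(n_nodes)
    out1 = np.empty_like(out) if n_accumulate >= 1 else None
    out2 = np.empty_like(out) if n_accumulate >= 2 else None

    def record(j):
        out[j] = u
        if out1 is not None:
            out1[j] = cum1
        if out2 is not None:
            out2[j] = cum2

    j = 0
    while j < len(output_steps) and output_steps[j] == 0:
        record(j)
        j += 1

    for step in range(n_steps):
        t0 = step * dt
        t1 = t0 + dt
        u_old = u.copy()
        if step == 0 and rannacher_substeps > 0:
            # implicit-Euler substeps across the first interval
            nsub = rannacher_substeps
            r_s = diffusivity * (dt / nsub) / dy**2
            fac = be_fac if nsub == 2 else _factor(2 * r_s, m)
            for k in range(nsub):
                b1 = float(lower(t0 + (k + 1) * dt / nsub))
                rhs = u[1:-1].copy()
                rhs[0] += r_s * b1
                u[1:-1] = cho_solve_banded(fac, rhs)
                u[0] = b1
                u[-1] = 0.0
        else:
            b0 = float(lower(t0))
            b1 = float(lower(t1))
            rhs = (1.0 - r) * u[1:-1]
            rhs[:-1] += (r / 2.0) * u[2:-1]
            rhs[1:] += (r / 2.0) * u[1:-2]
            rhs[0] += (r / 2.0) * (u[0] + b1)
            u[1:-1] = cho_solve_banded(cn_fac, rhs)
            u[0] = b1
            u[-1] = 0.0

        if n_accumulate:
            cum1_old = cum1.copy()
            cum1 = cum1 + dt * (u_old + u) / 2.0
            if n_accumulate >= 2:
                cum2 = cum2 + dt * (cum1_old + cum1) / 2.0

        while j < len(output_steps) and output_steps[j] == step + 1:
            record(j)
            j += 1

    results = [out]
    if out1 is not None:
        results.append(out1)
    if out2 is not None:
        results.append(out2)
    return results[0] if len(results) == 1 else tuple(results)
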