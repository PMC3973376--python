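"""Five-compartment linear ODE model of adult hippocampal neurogenesis.

The compartments are stem cells (c1), neural progenitors (c2),
neuroblasts (c3), mature neurons (c4) and astrocytes (c5).  With the
derived net rates lambda1, lambda2 and flux coefficients k12, k23, k15
(see :mod:`neurogen.params`) the dynamics are

    c1' = lambda1 * c1
    c2' = k12 * c1 + lambda2 * c2
    c3' = k23 * c2 - (p3 + d3) * c3
    c4' = p3 * c3 - d4 * c4
    c5' = k15 * c1 - d5 * c5

i.e. a lower-triangular constant-coefficient linear system.  The stem
and progenitor compartments admit simple closed forms used by the
fitting module and as solver cross-checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .params import CellState, Parameters, Trajectory, derived_rates

__all__ = [
    "SolverError",
    "SolverSettings",
    "system_matrix",
    "rhs",
    "closed_form_c1",
    "closed_form_c2",
    "solve_system",
    "check_stem_decline",
    "asymptotic_ratio",
    "check_assumption_3_2",
]


class SolverError(RuntimeError):
    """ODE integration failed; the message echoes the solver settings."""


@dataclass(frozen=True)
class SolverSettings:
    """Integrator configuration (adaptive, stiffness-switching)."""

    method: str = "LSODA"
    rtol: float = 1e-10
    atol: float = 1e-12

    def to_dict(self) -> dict:
        return {"method": self.method, "rtol": self.rtol, "atol": self.atol}


DEFAULT_SOLVER = SolverSettings()


def system_matrix(params: Parameters) -> np.ndarray:
    """Constant coefficient matrix A with c' = A c."""
    r = derived_rates(params)
    A = np.zeros((5, 5))
    A[0, 0] = r.lambda1
    A[1, 0] = r.k12
    A[1, 1] = r.lambda2
    A[2, 1] = r.k23
    A[2, 2] = -(params.p3 + params.d3)
    A[3, 2] = params.p3
    A[3, 3] = -params.d4
    A[4, 0] = r.k15
    A[4, 4] = -params.d5
    return A


def rhs(params: Parameters, state: CellState) -> np.ndarray:
    """Time-derivatives (c1'..c5') at the given state."""
    return system_matrix(params) @ state.to_array()


def closed_form_c1(params: Parameters, n1: float, t) -> np.ndarray | float:
    """Stem-cell count n1 * exp(lambda1 * t): a single exponential.

    The stem pool has no influx, so its count is exponentially declining
    whenever a1 * theta1 < 1/2 (net loss via astrocytic transformation).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    lam1 = derived_rates(params).lambda1
    out = n1 * np.exp(lam1 * t)
    return out if out.ndim else float(out)


def _expm1_over_x(x: np.ndarray) -> np.ndarray:
    """(exp(x) - 1)/x, stable at x -> 0 (limit 1)."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-150
    out[nz] = np.expm1(x[nz]) / x[nz]
    small = np.abs(x) < 1e-8
    # second-order series where cancellation would bite
    out[small] = 1.0 + x[small] / 2.0 + x[small] ** 2 / 6.0
    return out


def two_compartment_c2(lambda1: float, lambda2: float, k12: float,
                       n1: float, n2: float, t) -> np.ndarray | float:
    """Progenitor count of the stem->progenitor cascade in composite rates.

    c2(t) = n2 e^{lambda2 t} + k12 n1 (e^{lambda1 t} - e^{lambda2 t})/(lambda1 - lambda2),
    evaluated in a form that degrades gracefully to the confluent limit
    n2 e^{lambda t} + k12 n1 t e^{lambda t} as lambda1 -> lambda2.
    """
    t = np.asarray(t, dtype=float)
    x = (lambda1 - lambda2) * t
    # (e^{l1 t} - e^{l2 t})/(l1 - l2) = e^{l2 t} * t * expm1(x)/x
    conv = np.exp(lambda2 * t) * t * _expm1_over_x(x)
    out = n2 * np.exp(lambda2 * t) + k12 * n1 * conv
    return out if out.ndim else float(out)


def closed_form_c2(params: Parameters, n1: float, n2: float, t) -> np.ndarray | float:
    """Progenitor count fed by the declining stem pool (closed form)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    r = derived_rates(params)
    return two_compartment_c2(r.lambda1, r.lambda2, r.k12, n1, n2, t)


def solve_system(params: Parameters, init: CellState, grid,
                 settings: SolverSettings = DEFAULT_SOLVER) -> Trajectory:
    """Integrate the model on the supplied time grid (must start at 0).

    Returns a :class:`Trajectory` whose first row is exactly the initial
    state.  Tiny negative excursions from roundoff are clipped to zero.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or grid[0] != 0.0:
        raise ValueError("time grid must start at 0")
    A = system_matrix(params)
    y0 = init.to_array()
    sol = solve_ivp(
        lambda t, y: A @ y, (0.0, float(grid[-1])), y0,
        t_eval=grid, method=settings.method,
        rtol=settings.rtol, atol=settings.atol,
        jac=lambda t, y: A,
    )
    if not sol.success:
        raise SolverError(f"integration failed ({sol.message}); settings={settings.to_dict()}")
    states = sol.y.T.copy()
    states[0] = y0
    scale = max(1.0, float(np.max(np.abs(y0))))
    states[states > -1e-6 * scale] = np.maximum(states[states > -1e-6 * scale], 0.0)
    return Trajectory(grid, states, meta={"params": params.to_dict(), "solver": settings.to_dict()})


def check_stem_decline(params: Parameters) -> tuple[bool, float]:
    """Whether the stem pool is non-increasing, with its margin.

    The stem-cell count declines monotonically iff a1 * theta1 <= 1/2:
    symmetric divisions (gain) are then rarer than astrocytic
    transformations (loss).  The boundary a1 * theta1 = 1/2 gives a
    constant pool and is reported as declining with margin 0.
    Returns ``(declining, 1/2 - a1 * theta1)``.
    """
    margin = 0.5 - params.a1 * params.theta1
    return margin >= 0.0, margin


def asymptotic_ratio(params: Parameters) -> float:
    """Long-time limit of the stem/progenitor ratio c1(t)/c2(t).

    Is 0 when stem cells deplete faster (lambda1 < lambda2); equals
    (lambda1 - lambda2)/k12 when progenitors deplete faster, and then the
    positive limit is approached monotonically.  With no stem->progenitor
    flux (k12 = 0) and lambda1 > lambda2 the ratio diverges (inf).
    Raises on the structurally unstable lambda1 = lambda2 degeneracy.
    """
    r = derived_rates(params)
    if r.lambda1 < r.lambda2:
        return 0.0
    if r.lambda1 == r.lambda2:
        raise ValueError("lambda1 == lambda2: ratio limit degenerate (c1/c2 ~ 1/t -> 0 only if k12 > 0)")
    if r.k12 == 0.0:
        return math.inf
    return (r.lambda1 - r.lambda2) / r.k12


def check_assumption_3_2(params: Parameters) -> tuple[bool, bool]:
    """The parameter regime under which the sign results hold.

    Returns ``(a1 * theta1 < 1/2, lambda2 - lambda1 < 0)``: a declining
    stem pool and a net progenitor depletion rate strictly higher than
    the stem one.  Both flags must be true for the analytic sign
    sequences of the sensitivity module to be guaranteed.
    """
    r = derived_rates(params)
    return params.a1 * params.theta1 < 0.5, (r.lambda2 - r.lambda1) < 0.0
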