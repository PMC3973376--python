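"""Parameter sensitivities of cell counts and BrdU-labelled counts.

An inducible stem-cell knockout is modelled as an instantaneous change
of one stem-cell parameter (fraction of self-renewal a1, proliferation
rate p1 or division probability theta1).  Its effect on a quantity q is
summarized by the partial derivative dq/dp as a function of time since
the change, computed here by forward-sensitivity ODEs: for the linear
system c' = A c the sensitivity s = dc/dp solves

    s' = A s + (dA/dp) c,   s(0) = 0,

which is exact (no truncation beyond solver tolerance).  Labelled-cell
sensitivities chain the dependence through the pre-labelling
trajectory, the end-of-exposure label formula and the chase dynamics.

The qualitative summary of a sensitivity curve is its *sign sequence*:
the ordered distinct signs encountered as time runs from zero upward,
e.g. ``(0, -, 0, +)`` for a curve that starts at zero, dips negative
and recovers through a single crossing.  The number of maximal nonzero
phases of the sequence is the *phase count* (two-phase responses are
the model's signature of knockouts read out at different times).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from . import _symbolic
from .brdu import LabelingProtocol, initial_labels
from .model import DEFAULT_SOLVER, SolverError, SolverSettings, solve_system, system_matrix, check_assumption_3_2
from .params import COMPARTMENTS, CellState, ParameterError, Parameters

__all__ = [
    "SensitivityCurve",
    "SignSequence",
    "Table1Report",
    "forward_sensitivities",
    "brdu_incorporating_sensitivities",
    "label_sensitivities",
    "finite_difference_sensitivity",
    "ko_response",
    "sign_sequence",
    "phase_count",
    "table1_report",
    "TABLE1_PARAMETERS",
    "TABLE1_QUANTITIES",
]

TABLE1_PARAMETERS = ("a1", "p1", "theta1")
TABLE1_QUANTITIES = ("c1", "l1+", "c2", "l2+", "l5+")

INCORPORATING = ("l1+", "l2+", "l3+", "l4+", "l5+")
LABELLED = ("l1", "l2", "l3", "l4", "l5")


@dataclass(frozen=True)
class SensitivityCurve:
    """Derivative of one quantity with respect to one parameter on a grid."""

    parameter: str
    quantity: str
    time_grid: np.ndarray
    values: np.ndarray

    def max_abs(self) -> float:
        return float(np.max(np.abs(self.values))) if self.values.size else 0.0


@dataclass(frozen=True)
class SignSequence:
    """Distinct-sign summary of a curve.

    symbols : tuple of "+", "-", "0" with no two consecutive repeats;
        a "0" is recorded for the initial point when the curve starts at
        zero and for every zero crossing between opposite signs.
    crossing_times : refined times of the interior zero crossings
        (one per interior "0" lying between opposite signs, strictly
        increasing); leading/trailing zeros carry no crossing time.
    """

    symbols: tuple[str, ...]
    crossing_times: tuple[float, ...] = ()

    def __str__(self) -> str:
        return "(" + ", ".join(self.symbols) + ")"


def _augmented_solve(params: Parameters, param_name: str, y0: np.ndarray,
                     grid: np.ndarray, settings: SolverSettings) -> np.ndarray:
    """Integrate [state; sensitivity] under the block system; returns (n, 10)."""
    A = system_matrix(params)
    Ap = _symbolic.dA_dp(params, param_name)
    M = np.zeros((10, 10))
    M[:5, :5] = A
    M[5:, :5] = Ap
    M[5:, 5:] = A
    grid = np.asarray(grid, dtype=float)
    sol = solve_ivp(lambda t, y: M @ y, (float(grid[0]), float(grid[-1])), y0,
                    t_eval=grid, method=settings.method, rtol=settings.rtol,
                    atol=settings.atol, jac=lambda t, y: M)
    if not sol.success:
        raise SolverError(f"sensitivity integration failed ({sol.message}); settings={settings.to_dict()}")
    out = sol.y.T.copy()
    out[0] = y0
    return out


def forward_sensitivities(params: Parameters, init: CellState, param_name: str, grid,
                          settings: SolverSettings = DEFAULT_SOLVER) -> dict[str, SensitivityCurve]:
    """dc_i/dp on the grid for every compartment, via the augmented system.

    Initial data are parameter-independent, so every curve starts at
    exactly zero.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or grid[0] != 0.0:
        raise ValueError("time grid must start at 0")
    y0 = np.concatenate([init.to_array(), np.zeros(5)])
    ys = _augmented_solve(params, param_name, y0, grid, settings)
    return {
        name: SensitivityCurve(param_name, name, grid, ys[:, 5 + i])
        for i, name in enumerate(COMPARTMENTS)
    }


def brdu_incorporating_sensitivities(params: Parameters, init: CellState, param_name: str,
                                     t_grid, delta: float,
                                     settings: SolverSettings = DEFAULT_SOLVER) -> dict[str, SensitivityCurve]:
    """d l_i^+(t)/dp where l^+(t) = B(p) c(t; p) are end-of-exposure labels.

    Chain rule: dl^+/dp = (dB/dp) c + B (dc/dp).  Unlike the compartment
    counts, these are generally non-zero already at t = 0 — a parameter
    affecting division instantly changes what the mitotic marker reads
    out.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0 or t_grid[0] != 0.0:
        raise ValueError("time grid must start at 0")
    y0 = np.concatenate([init.to_array(), np.zeros(5)])
    ys = _augmented_solve(params, param_name, y0, t_grid, settings)
    B = _symbolic.b_matrix(params, delta)
    Bp = _symbolic.dB_dp(params, param_name, delta)
    vals = ys[:, :5] @ Bp.T + ys[:, 5:] @ B.T
    return {
        name: SensitivityCurve(param_name, name, t_grid, vals[:, i])
        for i, name in enumerate(INCORPORATING)
    }


def label_sensitivities(params: Parameters, init: CellState, param_name: str,
                        protocol: LabelingProtocol, tau_grid,
                        settings: SolverSettings = DEFAULT_SOLVER) -> dict[str, SensitivityCurve]:
    """d l_i(t_hat, tau)/dp as a function of the chase time tau.

    The administration time t_hat is fixed protocol input, not a
    differentiated variable.  The parameter dependence is chained
    through (i) the pre-labelling trajectory on [0, t_hat], (ii) the
    end-of-exposure label formula and (iii) the chase dynamics, each
    stage handled by the augmented linear system.
    """
    tau_grid = np.asarray(tau_grid, dtype=float)
    if tau_grid.size == 0 or tau_grid[0] != 0.0:
        raise ValueError("tau grid must start at 0")
    if protocol.t_hat > 0:
        pre = _augmented_solve(params, param_name,
                               np.concatenate([init.to_array(), np.zeros(5)]),
                               np.array([0.0, protocol.t_hat]), settings)
        c_hat, s_hat = pre[-1, :5], pre[-1, 5:]
    else:
        c_hat, s_hat = init.to_array(), np.zeros(5)
    B = _symbolic.b_matrix(params, protocol.delta)
    Bp = _symbolic.dB_dp(params, param_name, protocol.delta)
    l0 = B @ c_hat
    s0 = Bp @ c_hat + B @ s_hat
    ys = _augmented_solve(params, param_name, np.concatenate([l0, s0]), tau_grid, settings)
    return {
        name: SensitivityCurve(param_name, name, tau_grid, ys[:, 5 + i])
        for i, name in enumerate(LABELLED)
    }


def _quantity_values(params: Parameters, init: CellState, grid: np.ndarray,
                     kind: str, delta: float | None, protocol: LabelingProtocol | None,
                     settings: SolverSettings) -> np.ndarray:
    """(n, 5) values of the quantity family selected by ``kind``."""
    if kind == "counts":
        return solve_system(params, init, grid, settings).states
    if kind == "incorporating":
        from .brdu import brdu_incorporating_series

        return brdu_incorporating_series(params, init, grid, delta, settings)
    if kind == "label":
        if protocol.t_hat > 0:
            pre = solve_system(params, init, np.array([0.0, protocol.t_hat]), settings)
            c_hat = pre.at(-1)
        else:
            c_hat = init
        l0 = initial_labels(params, c_hat, protocol.delta)
        return solve_system(params, CellState.from_array(l0.to_array()), grid, settings).states
    raise ValueError(f"unknown kind {kind!r}")


_KIND_NAMES = {"counts": COMPARTMENTS, "incorporating": INCORPORATING, "label": LABELLED}


def finite_difference_sensitivity(params: Parameters, init: CellState, param_name: str,
                                  grid, h: float | None = None, kind: str = "counts",
                                  delta: float | None = None,
                                  protocol: LabelingProtocol | None = None,
                                  settings: SolverSettings = DEFAULT_SOLVER) -> dict[str, SensitivityCurve]:
    """Central-difference derivative estimate, the numerical oracle for
    the forward-sensitivity solutions (O(h^2) accurate).

    Raises :class:`ParameterError` if ``param +/- h`` leaves the valid
    domain.
    """
    grid = np.asarray(grid, dtype=float)
    p0 = getattr(params, param_name)
    if h is None:
        h = 1e-6 * max(1.0, abs(p0))
    hi = params.replace(**{param_name: p0 + h})
    lo = params.replace(**{param_name: p0 - h})
    vals = (_quantity_values(hi, init, grid, kind, delta, protocol, settings)
            - _quantity_values(lo, init, grid, kind, delta, protocol, settings)) / (2.0 * h)
    return {
        name: SensitivityCurve(param_name, name, grid, vals[:, i])
        for i, name in enumerate(_KIND_NAMES[kind])
    }


def ko_response(params: Parameters, init: CellState, param_name: str, delta_p: float,
                grid, delta: float | None = None,
                protocol: LabelingProtocol | None = None,
                settings: SolverSettings = DEFAULT_SOLVER) -> dict[str, np.ndarray]:
    """Finite-perturbation difference curves (KO minus wild type).

    Returns difference trajectories of the compartment counts and, when
    ``delta`` / ``protocol`` are supplied, of the BrdU-incorporating and
    labelled pools.  For small ``delta_p`` the differences divided by
    ``delta_p`` approach the corresponding sensitivity curves.
    """
    grid = np.asarray(grid, dtype=float)
    perturbed = params.replace(**{param_name: getattr(params, param_name) + delta_p})
    out: dict[str, np.ndarray] = {}
    kinds = ["counts"]
    if delta is not None:
        kinds.append("incorporating")
    if protocol is not None:
        kinds.append("label")
    for kind in kinds:
        base = _quantity_values(params, init, grid, kind, delta, protocol, settings)
        pert = _quantity_values(perturbed, init, grid, kind, delta, protocol, settings)
        for i, name in enumerate(_KIND_NAMES[kind]):
            out[name] = pert[:, i] - base[:, i]
    return out


# ---------------------------------------------------------------------------
# sign sequences


def sign_sequence(curve: SensitivityCurve | np.ndarray, time_grid=None,
                  tol: float = 1e-6) -> SignSequence:
    """Collapse a sampled curve to its sequence of distinct signs.

    Samples with |value| <= tol * max|curve| count as zero.  Runs of
    equal signs are collapsed; a zero crossing between opposite signs is
    always recorded as a "0" entry (whether or not a sample falls inside
    the zero band), and its time is refined with a cubic-spline
    bracketed root to ~1e-10.
    """
    if isinstance(curve, SensitivityCurve):
        values, times = np.asarray(curve.values, float), np.asarray(curve.time_grid, float)
    else:
        values = np.asarray(curve, dtype=float)
        times = np.arange(values.size, dtype=float) if time_grid is None else np.asarray(time_grid, float)
    m = float(np.max(np.abs(values))) if values.size else 0.0
    if m == 0.0:
        return SignSequence(("0",))
    thr = tol * m
    cls = np.zeros(values.size, dtype=int)
    cls[values > thr] = 1
    cls[values < -thr] = -1

    # collapse into runs of (class, first index, last index)
    runs: list[list[int]] = []
    for i, c in enumerate(cls):
        if runs and runs[-1][0] == c:
            runs[-1][2] = i
        else:
            runs.append([c, i, i])

    sym = {1: "+", -1: "-", 0: "0"}
    spline = CubicSpline(times, values) if times.size >= 4 else None

    def _refine(i_lo: int, i_hi: int) -> float:
        if spline is None:
            # linear interpolation fallback for very short grids
            t0, t1 = times[i_lo], times[i_hi]
            v0, v1 = values[i_lo], values[i_hi]
            return float(t0 - v0 * (t1 - t0) / (v1 - v0))
        return float(brentq(spline, times[i_lo], times[i_hi], xtol=1e-10))

    symbols: list[str] = []
    crossings: list[float] = []
    for j, (c, lo, hi) in enumerate(runs):
        if c != 0:
            if symbols and symbols[-1] != "0":
                # direct sign flip between adjacent samples: record the crossing
                symbols.append("0")
                crossings.append(_refine(runs[j - 1][2], lo))
            symbols.append(sym[c])
        else:
            symbols.append("0")
            prev_sign = runs[j - 1][0] if j > 0 else 0
            next_sign = runs[j + 1][0] if j + 1 < len(runs) else 0
            if prev_sign != 0 and next_sign != 0 and prev_sign != next_sign:
                crossings.append(_refine(runs[j - 1][2], runs[j + 1][1]))
    return SignSequence(tuple(symbols), tuple(crossings))


def phase_count(seq: SignSequence) -> int:
    """Number of maximal nonzero-sign phases (zeros excluded)."""
    return sum(1 for s in seq.symbols if s != "0")


# ---------------------------------------------------------------------------
# the sign-sequence table for stem-cell parameters


@dataclass
class Table1Report:
    """Sign sequences of {a1, p1, theta1} x {c1, l1+, c2, l2+, l5+}.

    ``assumption_ok`` records the two flags of the declining-regime
    assumption (stem decline; faster net progenitor depletion); the sign
    sequences are only guaranteed when both hold.
    """

    sequences: dict[tuple[str, str], SignSequence]
    assumption_ok: tuple[bool, bool]
    meta: dict = field(default_factory=dict)

    def as_strings(self) -> dict[str, dict[str, str]]:
        out: dict[str, dict[str, str]] = {}
        for (p, q), seq in self.sequences.items():
            out.setdefault(p, {})[q] = str(seq)
        return out


def table1_report(params: Parameters, init: CellState, grid=None, delta: float = 0.1,
                  tol: float = 1e-6,
                  settings: SolverSettings = DEFAULT_SOLVER) -> Table1Report:
    """Sign sequences of the five analysed quantities for the three
    stem-cell parameters.

    Quantities: stem count c1, progenitor count c2 and the
    BrdU-incorporating pools l1+, l2+, l5+ (stem, progenitor,
    astrocyte).  Default grid: 3001 points on [0, 30] model time units —
    beyond the slowest system timescale, so no phase is truncated.
    """
    if grid is None:
        grid = np.linspace(0.0, 30.0, 3001)
    grid = np.asarray(grid, dtype=float)
    flags = check_assumption_3_2(params)
    sequences: dict[tuple[str, str], SignSequence] = {}
    for p in TABLE1_PARAMETERS:
        counts = forward_sensitivities(params, init, p, grid, settings)
        labels = brdu_incorporating_sensitivities(params, init, p, grid, delta, settings)
        for q in TABLE1_QUANTITIES:
            curve = counts[q] if q in counts else labels[q]
            sequences[(p, q)] = sign_sequence(curve, tol=tol)
    return Table1Report(sequences=sequences, assumption_ok=flags,
                        meta={"delta": delta, "grid": [float(grid[0]), float(grid[-1]), int(grid.size)],
                              "tol": tol})
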