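"""Exact parameter-derivatives of the model's coefficient matrices.

The linear system matrix A(params) and the end-of-exposure labelling
matrix B(params, delta) (labels = B @ counts) are polynomial /
exponential in the kinetic parameters, so their partial derivatives are
obtained symbolically once per parameter and lambdified; results are
cached for the lifetime of the process.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import sympy as sp

from .params import PARAM_NAMES, Parameters

_SYMS = {name: sp.Symbol(name, real=True) for name in PARAM_NAMES}
_DELTA = sp.Symbol("delta", nonnegative=True)
_ARGS = tuple(_SYMS[n] for n in PARAM_NAMES) + (_DELTA,)


def _a_matrix_sym() -> sp.Matrix:
    s = _SYMS
    lam1 = (2 * s["a1"] * s["theta1"] - 1) * s["p1"]
    lam2 = (2 * s["a2"] * s["theta2"] - 1) * s["p2"] - s["d2"]
    k12 = 2 * (1 - s["a1"]) * s["theta1"] * s["kappa"] * s["p1"]
    k23 = (2 * (1 - s["a2"]) * s["theta2"] + (1 - s["theta2"])) * s["p2"]
    k15 = ((1 - s["theta1"]) + 2 * (1 - s["a1"]) * s["theta1"] * (1 - s["kappa"])) * s["p1"]
    A = sp.zeros(5, 5)
    A[0, 0] = lam1
    A[1, 0] = k12
    A[1, 1] = lam2
    A[2, 1] = k23
    A[2, 2] = -(s["p3"] + s["d3"])
    A[3, 2] = s["p3"]
    A[3, 3] = -s["d4"]
    A[4, 0] = k15
    A[4, 4] = -s["d5"]
    return A


def _b_matrix_sym() -> sp.Matrix:
    s = _SYMS
    F1 = 1 - sp.exp(-s["p1"] * _DELTA)
    F2 = 1 - sp.exp(-s["p2"] * _DELTA)
    B = sp.zeros(5, 5)
    B[0, 0] = F1 * s["theta1"] * 2 * s["a1"]
    B[1, 0] = F1 * s["theta1"] * 2 * (1 - s["a1"]) * s["kappa"]
    B[1, 1] = F2 * s["theta2"] * 2 * s["a2"]
    B[2, 1] = F2 * s["theta2"] * 2 * (1 - s["a2"])
    B[4, 0] = F1 * s["theta1"] * 2 * (1 - s["a1"]) * (1 - s["kappa"])
    return B


# Scalar building blocks of the closed-form solutions, used by the
# closed-form sensitivity coefficients.
def _scalar_exprs() -> dict[str, sp.Expr]:
    s = _SYMS
    F1 = 1 - sp.exp(-s["p1"] * _DELTA)
    F2 = 1 - sp.exp(-s["p2"] * _DELTA)
    return {
        "lambda1": (2 * s["a1"] * s["theta1"] - 1) * s["p1"],
        "lambda2": (2 * s["a2"] * s["theta2"] - 1) * s["p2"] - s["d2"],
        "k12": 2 * (1 - s["a1"]) * s["theta1"] * s["kappa"] * s["p1"],
        # multipliers of c1(t) / c2(t) in the BrdU-incorporating pools
        "K_l1": F1 * s["theta1"] * 2 * s["a1"],
        "K_l2_c1": F1 * s["theta1"] * 2 * (1 - s["a1"]) * s["kappa"],
        "K_l2_c2": F2 * s["theta2"] * 2 * s["a2"],
        "K_l5": F1 * s["theta1"] * 2 * (1 - s["a1"]) * (1 - s["kappa"]),
    }


def _args(params: Parameters, delta: float = 0.0) -> tuple[float, ...]:
    return tuple(getattr(params, n) for n in PARAM_NAMES) + (float(delta),)


@lru_cache(maxsize=None)
def _dA_fn(param_name: str):
    if param_name not in PARAM_NAMES:
        raise KeyError(f"unknown parameter {param_name!r}")
    dA = sp.diff(_a_matrix_sym(), _SYMS[param_name])
    return sp.lambdify(_ARGS, dA, "numpy")


@lru_cache(maxsize=None)
def _dB_fn(param_name: str):
    if param_name not in PARAM_NAMES:
        raise KeyError(f"unknown parameter {param_name!r}")
    dB = sp.diff(_b_matrix_sym(), _SYMS[param_name])
    return sp.lambdify(_ARGS, dB, "numpy")


@lru_cache(maxsize=None)
def _scalar_fn(expr_name: str, param_name: str | None):
    exprs = _scalar_exprs()
    if expr_name not in exprs:
        raise KeyError(f"unknown scalar expression {expr_name!r}")
    e = exprs[expr_name]
    if param_name is not None:
        e = sp.diff(e, _SYMS[param_name])
    return sp.lambdify(_ARGS, e, "numpy")


def dA_dp(params: Parameters, param_name: str) -> np.ndarray:
    """d(system matrix)/d(param), shape (5, 5)."""
    return np.asarray(_dA_fn(param_name)(*_args(params)), dtype=float)


def dB_dp(params: Parameters, param_name: str, delta: float) -> np.ndarray:
    """d(labelling matrix)/d(param) at exposure length delta."""
    return np.asarray(_dB_fn(param_name)(*_args(params, delta)), dtype=float)


def b_matrix(params: Parameters, delta: float) -> np.ndarray:
    """Labelling matrix B with initial labels = B @ counts."""
    F1 = -np.expm1(-params.p1 * delta)
    F2 = -np.expm1(-params.p2 * delta)
    B = np.zeros((5, 5))
    B[0, 0] = F1 * params.theta1 * 2.0 * params.a1
    B[1, 0] = F1 * params.theta1 * 2.0 * (1.0 - params.a1) * params.kappa
    B[1, 1] = F2 * params.theta2 * 2.0 * params.a2
    B[2, 1] = F2 * params.theta2 * 2.0 * (1.0 - params.a2)
    B[4, 0] = F1 * params.theta1 * 2.0 * (1.0 - params.a1) * (1.0 - params.kappa)
    return B


def scalar_value(params: Parameters, expr_name: str, delta: float = 0.0) -> float:
    """Evaluate one of the named scalar building blocks."""
    return float(_scalar_fn(expr_name, None)(*_args(params, delta)))


def scalar_partial(params: Parameters, expr_name: str, param_name: str, delta: float = 0.0) -> float:
    """Exact partial derivative of a named scalar w.r.t. a parameter."""
    return float(_scalar_fn(expr_name, param_name)(*_args(params, delta)))
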