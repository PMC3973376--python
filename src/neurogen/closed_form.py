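"""Closed-form sensitivity curves for the analytically tractable quantities.

The stem count, the progenitor count and the BrdU-incorporating stem,
progenitor and astrocyte pools are all linear combinations of the two
exponentials exp(lambda1 t) and exp(lambda2 t) (with an additional
t * exp(lambda1 t) term from differentiating lambda1).  Every parameter
derivative of these quantities therefore has the exact form

    D(t) = (A + B t) e^{lambda1 t} + C e^{lambda2 t},

and the coefficients A, B, C follow from the partial derivatives of the
composite rates, obtained symbolically.  This module derives those
coefficients from the model itself and evaluates the resulting curves;
it is an independent analytic route against which the ODE-based
forward sensitivities are cross-validated.

In the declining regime (lambda2 < lambda1 < 0) the curves with
C = -A can be written c1-prefactor times f(t) = B t + A (1 - e^{alpha t})
with alpha = lambda2 - lambda1 < 0, and classified by their sign
history: P1 (single positive phase), P2 (positive then negative,
one crossing), P3 (negative then positive, one crossing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _symbolic
from .params import CellState, Parameters, derived_rates
from .sensitivity import SensitivityCurve

__all__ = [
    "ClosedFormUnavailableError",
    "ClosedFormSensitivityCoefficients",
    "derive_sensitivity_coefficients",
    "closed_form_sensitivity",
    "CLOSED_FORM_QUANTITIES",
]

CLOSED_FORM_QUANTITIES = ("c1", "c2", "l1+", "l2+", "l5+")


class ClosedFormUnavailableError(NotImplementedError):
    """No closed-form coefficient set exists (or has been derived) for
    the requested (quantity, parameter) pair."""


@dataclass(frozen=True)
class ClosedFormSensitivityCoefficients:
    """Coefficients of D(t) = (A + B t) e^{lambda1 t} + C e^{lambda2 t}."""

    quantity: str
    parameter: str
    lambda1: float
    lambda2: float
    A: float
    B: float
    C: float

    @property
    def alpha(self) -> float:
        """Rate gap lambda2 - lambda1; negative in the declining regime."""
        return self.lambda2 - self.lambda1

    @property
    def beta(self) -> float:
        """Coefficient of the secular term t e^{lambda1 t}."""
        return self.B

    @property
    def gamma(self) -> float:
        """Coefficient of the bounded term (1 - e^{alpha t}) when C = -A."""
        return self.A

    def evaluate(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (self.A + self.B * t) * np.exp(self.lambda1 * t) + self.C * np.exp(self.lambda2 * t)

    @property
    def classification(self) -> str:
        """Sign-history class per the declining-regime trichotomy.

        P1: single positive phase for t > 0; P2: positive then negative
        with one crossing; P3: negative then positive with one crossing.
        Requires lambda2 < lambda1 < 0.
        """
        if not (self.lambda2 < self.lambda1 < 0):
            raise ValueError("classification defined only in the declining regime (lambda2 < lambda1 < 0)")
        v0 = self.A + self.C
        initial = v0 if abs(v0) > 1e-12 * (abs(self.A) + abs(self.C) + abs(self.B) + 1e-300) \
            else self.B + self.A * self.lambda1 + self.C * self.lambda2  # D'(0) when D(0) = 0
        terminal = self.B if self.B != 0.0 else self.A  # t e^{l1 t} dominates e^{l2 t}
        if initial > 0 and terminal > 0:
            return "P1"
        if initial > 0 and terminal < 0:
            return "P2"
        if initial < 0 and terminal > 0:
            return "P3"
        if initial < 0 and terminal < 0:
            return "N1"  # single negative phase (e.g. dc1/dp1)
        raise ValueError("degenerate coefficient set; no classification")


def derive_sensitivity_coefficients(params: Parameters, init: CellState, quantity: str,
                                    parameter: str, delta: float = 0.1) -> ClosedFormSensitivityCoefficients:
    """Derive (A, B, C) for d(quantity)/d(parameter) from the model.

    Exact for the five two-exponential quantities; the neuroblast,
    neuron and astrocyte counts involve further exponentials and are
    deliberately not covered (they are handled numerically).
    Requires lambda1 != lambda2 (the confluent case has a different
    functional basis).
    """
    if quantity not in CLOSED_FORM_QUANTITIES:
        raise ClosedFormUnavailableError(
            f"closed-form coefficients not derived for quantity {quantity!r}; "
            f"available: {CLOSED_FORM_QUANTITIES}")
    if parameter not in ("a1", "theta1", "p1", "kappa"):
        raise ClosedFormUnavailableError(
            f"closed-form coefficients not derived for parameter {parameter!r}; "
            "only stem-cell parameters are covered (progenitor-side parameters "
            "change lambda2 and the progenitor label multiplier, which this "
            "two-exponential bookkeeping does not track)")
    r = derived_rates(params)
    gap = r.lambda1 - r.lambda2
    if abs(gap) < 1e-12 * max(1.0, abs(r.lambda1)):
        raise ValueError("lambda1 == lambda2: two-exponential closed form degenerate")
    n1, n2 = init.c1, init.c2
    lam1_p = _symbolic.scalar_partial(params, "lambda1", parameter)
    k12 = r.k12
    k12_p = _symbolic.scalar_partial(params, "k12", parameter)

    def c2_coeffs() -> tuple[float, float, float]:
        # d c2/dp = n1 [k12_p g + k12 g_lambda1 lam1_p],
        # g = (e^{l1 t} - e^{l2 t})/(l1 - l2)
        A = n1 * (k12_p / gap - k12 * lam1_p / gap ** 2)
        B = n1 * k12 * lam1_p / gap
        return A, B, -A

    if quantity == "c1":
        return ClosedFormSensitivityCoefficients(quantity, parameter, r.lambda1, r.lambda2,
                                                 A=0.0, B=n1 * lam1_p, C=0.0)
    if quantity == "c2":
        A, B, C = c2_coeffs()
        return ClosedFormSensitivityCoefficients(quantity, parameter, r.lambda1, r.lambda2, A, B, C)
    if quantity in ("l1+", "l5+"):
        name = "K_l1" if quantity == "l1+" else "K_l5"
        K = _symbolic.scalar_value(params, name, delta)
        K_p = _symbolic.scalar_partial(params, name, parameter, delta)
        return ClosedFormSensitivityCoefficients(quantity, parameter, r.lambda1, r.lambda2,
                                                 A=K_p * n1, B=K * lam1_p * n1, C=0.0)
    # l2+ = K1 c1 + K2 c2
    K1 = _symbolic.scalar_value(params, "K_l2_c1", delta)
    K1_p = _symbolic.scalar_partial(params, "K_l2_c1", parameter, delta)
    K2 = _symbolic.scalar_value(params, "K_l2_c2", delta)
    K2_p = _symbolic.scalar_partial(params, "K_l2_c2", parameter, delta)
    A2, B2, C2 = c2_coeffs()
    c2_0 = n2  # c2 at t = 0
    # d(K2 c2)/dp = K2_p c2 + K2 dc2/dp; c2 itself = n2 e^{l2 t} + k12 n1 g(t)
    A = K1_p * n1 + K2 * A2 + K2_p * (k12 * n1 / gap)
    B = K1 * lam1_p * n1 + K2 * B2
    C = K2 * C2 + K2_p * (c2_0 - k12 * n1 / gap)
    return ClosedFormSensitivityCoefficients(quantity, parameter, r.lambda1, r.lambda2, A, B, C)


def closed_form_sensitivity(coeffs: ClosedFormSensitivityCoefficients, grid) -> SensitivityCurve:
    """Evaluate a closed-form sensitivity curve on a grid."""
    grid = np.asarray(grid, dtype=float)
    return SensitivityCurve(coeffs.parameter, coeffs.quantity, grid, coeffs.evaluate(grid))
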