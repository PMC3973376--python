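"""Parameterization and state containers for the neurogenesis lineage model.

The model tracks five cellular compartments of the adult dentate gyrus:
stem cells (c1), neural progenitors (c2), neuroblasts (c3), mature
neurons (c4) and astrocytes (c5).  Stem and progenitor kinetics are
governed by a proliferation rate ``p`` (per-cell rate of undergoing an
event), a division probability ``theta`` (division vs. direct
transformation) and a fraction of self-renewal ``a`` (probability that
a daughter cell keeps its mother's fate; ``2a - 1`` is the symmetric
division probability).  Time units are abstract "model time units"
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Mapping

import numpy as np

__all__ = [
    "ParameterError",
    "Parameters",
    "CellState",
    "DerivedRates",
    "Trajectory",
    "PARAM_NAMES",
    "COMPARTMENTS",
]

COMPARTMENTS = ("c1", "c2", "c3", "c4", "c5")

PARAM_NAMES = (
    "a1", "theta1", "p1", "kappa",
    "a2", "theta2", "p2", "d2",
    "p3", "d3", "d4", "d5",
)


class ParameterError(ValueError):
    """A kinetic parameter or cell count is outside its admissible range."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass(frozen=True)
class Parameters:
    """The 12 kinetic parameters of the five-compartment lineage model.

    Attributes
    ----------
    a1, a2 : float
        Fractions of self-renewal of stem cells / progenitors, in [1/2, 1].
    theta1, theta2 : float
        Division probabilities (division vs. transformation), in [0, 1].
    p1, p2 : float
        Proliferation rates (events per cell per model time unit), > 0.
    kappa : float
        Probability that the non-stem daughter of an asymmetric stem
        division is a progenitor (else an astrocyte), in [0, 1].
    d2, d3, d4, d5 : float
        Death (apoptosis) rates of progenitors, neuroblasts, neurons and
        astrocytes.  Stem cells have no independent death term: their
        pool declines only through astrocytic transformation.
    p3 : float
        Neuroblast maturation rate (neuroblast -> neuron), > 0.
    """

    a1: float
    theta1: float
    p1: float
    kappa: float
    a2: float
    theta2: float
    p2: float
    d2: float
    p3: float
    d3: float
    d4: float
    d5: float

    def __post_init__(self) -> None:
        for name in ("a1", "a2"):
            v = getattr(self, name)
            _check(0.5 <= v <= 1.0, f"{name}={v!r} must lie in [1/2, 1]")
        for name in ("theta1", "theta2", "kappa"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, f"{name}={v!r} must lie in [0, 1]")
        for name in ("p1", "p2", "p3"):
            v = getattr(self, name)
            _check(v > 0.0, f"{name}={v!r} must be > 0")
        for name in ("d2", "d3", "d4", "d5"):
            v = getattr(self, name)
            _check(v >= 0.0, f"{name}={v!r} must be >= 0")
        for name in PARAM_NAMES:
            _check(np.isfinite(getattr(self, name)), f"{name} must be finite")

    def replace(self, **changes: float) -> "Parameters":
        """Return a copy with the given fields replaced (re-validated)."""
        d = self.to_dict()
        d.update(changes)
        return Parameters(**d)

    def to_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in asdict(self).items()}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "Parameters":
        unknown = set(d) - set(PARAM_NAMES)
        if unknown:
            raise ParameterError(f"unknown parameter name(s): {sorted(unknown)}")
        missing = set(PARAM_NAMES) - set(d)
        if missing:
            raise ParameterError(f"missing parameter name(s): {sorted(missing)}")
        return cls(**{k: float(d[k]) for k in PARAM_NAMES})


@dataclass(frozen=True)
class CellState:
    """Cell counts per compartment (continuous, nonnegative, units: cells)."""

    c1: float
    c2: float
    c3: float
    c4: float
    c5: float

    def __post_init__(self) -> None:
        for name in COMPARTMENTS:
            v = getattr(self, name)
            _check(np.isfinite(v) and v >= 0.0, f"{name}={v!r} must be a nonnegative finite count")

    def to_array(self) -> np.ndarray:
        return np.array([self.c1, self.c2, self.c3, self.c4, self.c5], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "CellState":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (5,):
            raise ParameterError(f"expected 5 compartments, got shape {arr.shape}")
        return cls(*arr)

    def to_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in asdict(self).items()}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "CellState":
        unknown = set(d) - set(COMPARTMENTS)
        if unknown:
            raise ParameterError(f"unknown compartment(s): {sorted(unknown)}")
        return cls(**{k: float(d.get(k, 0.0)) for k in COMPARTMENTS})


@dataclass(frozen=True)
class DerivedRates:
    """Net rates and flux coefficients implied by a parameter set.

    lambda1 = (2 a1 theta1 - 1) p1          net stem-cell rate
    lambda2 = (2 a2 theta2 - 1) p2 - d2     net progenitor rate
    k12 = 2 (1 - a1) theta1 kappa p1        stem -> progenitor flux
    k23 = [2 (1 - a2) theta2 + (1 - theta2)] p2   progenitor -> neuroblast flux
    k15 = [(1 - theta1) + 2 (1 - a1) theta1 (1 - kappa)] p1  stem -> astrocyte flux
    net_event_change = 2 a1 theta1 - 1      expected stem-count change per stem event
    """

    lambda1: float
    lambda2: float
    k12: float
    k23: float
    k15: float
    net_event_change: float


def derived_rates(params: Parameters) -> DerivedRates:
    """Compute the net rates and inter-compartment flux coefficients."""
    a1, th1, p1, k = params.a1, params.theta1, params.p1, params.kappa
    a2, th2, p2, d2 = params.a2, params.theta2, params.p2, params.d2
    return DerivedRates(
        lambda1=(2.0 * a1 * th1 - 1.0) * p1,
        lambda2=(2.0 * a2 * th2 - 1.0) * p2 - d2,
        k12=2.0 * (1.0 - a1) * th1 * k * p1,
        k23=(2.0 * (1.0 - a2) * th2 + (1.0 - th2)) * p2,
        k15=((1.0 - th1) + 2.0 * (1.0 - a1) * th1 * (1.0 - k)) * p1,
        net_event_change=2.0 * a1 * th1 - 1.0,
    )


@dataclass
class Trajectory:
    """Compartment counts on a time grid.

    Attributes
    ----------
    time_grid : ndarray, shape (n,)
        Strictly increasing, nonnegative times.
    states : ndarray, shape (n, 5)
        Rows are (c1..c5) aligned with ``time_grid``.
    meta : dict
        Parameter set and solver settings used to produce the trajectory.
    """

    time_grid: np.ndarray
    states: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.time_grid.ndim != 1 or self.states.shape != (self.time_grid.size, 5):
            raise ValueError("states must be (len(time_grid), 5)")
        if self.time_grid.size and (np.any(np.diff(self.time_grid) <= 0) or self.time_grid[0] < 0):
            raise ValueError("time_grid must be strictly increasing and nonnegative")

    def compartment(self, name: str) -> np.ndarray:
        return self.states[:, COMPARTMENTS.index(name)]

    def at(self, index: int) -> CellState:
        return CellState.from_array(np.clip(self.states[index], 0.0, None))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.time_grid, **{c: self.states[:, i] for i, c in enumerate(COMPARTMENTS)}}
        )
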