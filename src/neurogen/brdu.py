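"""BrdU pulse-chase label kinetics for the neurogenesis lineage model.

BrdU (bromodeoxyuridine) is a thymidine analogue incorporated during
DNA synthesis: a cell is labelled iff it divides while the marker is
present.  In the exponential-lifetime picture underlying the ODE model,
the fraction of cells of a compartment undergoing an event during an
exposure window of length ``delta`` is ``1 - exp(-p * delta)``, a
fraction ``theta`` of those events are divisions, and each division
contributes on average its expected labelled offspring to the
respective daughter compartments.  Direct transformations involve no
DNA synthesis and never label.  After the window closes, labelled
pools obey the same linear dynamics as the full compartments (label
dilution is ignored; all progeny of labelled cells stay labelled).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .model import DEFAULT_SOLVER, SolverSettings, solve_system
from .params import CellState, ParameterError, Parameters, Trajectory

__all__ = [
    "LabelingProtocol",
    "LabeledState",
    "division_fraction",
    "initial_labels",
    "labeled_trajectory",
    "brdu_incorporating_series",
]


@dataclass(frozen=True)
class LabelingProtocol:
    """BrdU administration protocol.

    t_hat : time of BrdU administration after the parameter change (>= 0)
    delta : exposure duration, > 0 for any labelling to occur
    tau   : chase time after the labelling window ends (>= 0)
    """

    t_hat: float = 0.0
    delta: float = 0.1
    tau: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.t_hat) and self.t_hat >= 0):
            raise ParameterError(f"t_hat={self.t_hat!r} must be finite and >= 0")
        if not (np.isfinite(self.delta) and self.delta >= 0):
            raise ParameterError(f"delta={self.delta!r} must be finite and >= 0")
        if not (np.isfinite(self.tau) and self.tau >= 0):
            raise ParameterError(f"tau={self.tau!r} must be finite and >= 0")

    def to_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in asdict(self).items()}


@dataclass(frozen=True)
class LabeledState:
    """Labelled-cell counts per compartment at one (t_hat, tau).

    l4 = 0 whenever tau = 0: neurons arise from neuroblast
    transformation, not division, so none are labelled at the end of
    the exposure window.
    """

    l1: float
    l2: float
    l3: float
    l4: float
    l5: float

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not (np.isfinite(v) and v >= 0):
                raise ParameterError(f"{name}={v!r} must be a nonnegative finite count")

    def to_array(self) -> np.ndarray:
        return np.array([self.l1, self.l2, self.l3, self.l4, self.l5], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "LabeledState":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (5,):
            raise ParameterError(f"expected 5 labelled pools, got shape {arr.shape}")
        return cls(*arr)


def division_fraction(rate: float, delta: float) -> float:
    """Fraction 1 - exp(-rate * delta) of cells with an event in the window.

    This is the CDF of the exponential event-waiting time at the window
    length; it is 0 at delta = 0 and increases monotonically toward 1.
    """
    if rate < 0 or delta < 0:
        raise ValueError("rate and delta must be nonnegative")
    return float(-np.expm1(-rate * delta))


def initial_labels(params: Parameters, state_at_that: CellState, delta: float) -> LabeledState:
    """Labelled pools at the end of a BrdU exposure of length ``delta``.

    With F_i = 1 - exp(-p_i * delta) the fraction of compartment-i cells
    undergoing an event during exposure, the expected labelled counts are

        l1 = F1 * theta1 * 2 a1 * c1
        l2 = F1 * theta1 * 2 (1 - a1) kappa * c1 + F2 * theta2 * 2 a2 * c2
        l3 = F2 * theta2 * 2 (1 - a2) * c2
        l4 = 0
        l5 = F1 * theta1 * 2 (1 - a1) (1 - kappa) * c1

    i.e. each division labels both daughters and contributes its mean
    offspring per compartment; transformations never label.  Multiple
    divisions of one cell within the window are neglected (an O(delta^2)
    effect; the stochastic oracle quantifies it).
    """
    c = state_at_that
    F1 = division_fraction(params.p1, delta)
    F2 = division_fraction(params.p2, delta)
    a1, th1, kap = params.a1, params.theta1, params.kappa
    a2, th2 = params.a2, params.theta2
    return LabeledState(
        l1=F1 * th1 * 2.0 * a1 * c.c1,
        l2=F1 * th1 * 2.0 * (1.0 - a1) * kap * c.c1 + F2 * th2 * 2.0 * a2 * c.c2,
        l3=F2 * th2 * 2.0 * (1.0 - a2) * c.c2,
        l4=0.0,
        l5=F1 * th1 * 2.0 * (1.0 - a1) * (1.0 - kap) * c.c1,
    )


def labeled_trajectory(params: Parameters, labels0: LabeledState, tau_grid,
                       settings: SolverSettings = DEFAULT_SOLVER) -> Trajectory:
    """Evolve labelled pools over the chase period.

    Labelled cells follow exactly the dynamics of their compartments
    (labelled stem cells feed labelled progenitors and astrocytes, etc.),
    so this is the same linear system started from the labelled pools.
    """
    init = CellState.from_array(labels0.to_array())
    return labeled_trajectory_states(params, init, tau_grid, settings)


def labeled_trajectory_states(params: Parameters, init: CellState, tau_grid,
                              settings: SolverSettings = DEFAULT_SOLVER) -> Trajectory:
    return solve_system(params, init, tau_grid, settings)


def brdu_incorporating_series(params: Parameters, init: CellState, t_grid, delta: float,
                              settings: SolverSettings = DEFAULT_SOLVER) -> np.ndarray:
    """BrdU *incorporating* cells l_i^+(t) = l_i(t_hat=t, tau=0) on a grid.

    For each administration time t the unlabelled system is run to t and
    the end-of-exposure label formula applied; returns an array of shape
    (len(t_grid), 5).  Because every l_i^+ stemming from stem-cell
    divisions is proportional to c1(t), ratios such as l5^+/l1^+ are
    constant in t.
    """
    traj = solve_system(params, init, t_grid, settings)
    out = np.empty_like(traj.states)
    for i in range(traj.time_grid.size):
        out[i] = initial_labels(params, traj.at(i), delta).to_array()
    return out
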