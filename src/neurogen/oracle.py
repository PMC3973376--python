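"""Exact stochastic simulation of the cell-level lineage rules.

The ODE model is the mean-field of a multitype branching process in
which every cell carries an exponential event clock.  This module
simulates that process exactly (next-event sampling from the total
propensity over population-level channels) and serves as an independent
oracle: ensemble means must match the ODE solutions, and labelled
counts at small exposure lengths must match the end-of-exposure label
formula to first order.

Event catalogue (per label status, unlabelled/labelled):

* stem event, rate p1*N1: division w.p. theta1 — symmetric
  w.p. 2 a1 - 1 (two stem daughters) or asymmetric w.p. 2 (1 - a1)
  (stem + progenitor w.p. kappa, stem + astrocyte otherwise) — else
  astrocytic transformation;
* progenitor event, rate p2*N2: division w.p. theta2 — symmetric
  (two progenitors) or asymmetric (progenitor + neuroblast) — else
  transformation to a neuroblast; independent death clock d2*N2;
* neuroblast maturation p3*N3 and death d3*N3; neuron death d4*N4;
  astrocyte death d5*N5.

During a BrdU window both daughters of any division become labelled;
labels are heritable; transformations never create a label.  Rates are
linear, so population-level propensities are distributionally exact —
per-cell identity is never needed.

Streams use the counter-based Philox generator keyed by (seed,
replicate), so ensembles are reproducible across platforms and
replicate order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .brdu import LabelingProtocol
from .params import CellState, Parameters, Trajectory

__all__ = [
    "EventCapExceeded",
    "simulate_population",
    "simulate_ensemble",
    "simulate_brdu",
    "ensemble_summary",
]

EVENT_CAP = 10_000_000


class EventCapExceeded(RuntimeError):
    """The simulation exceeded the per-run event budget (explosion guard)."""


@njit(cache=True)
def _gillespie(rng, a1, th1, p1, kap, a2, th2, p2, d2, p3, d3, d4, d5,
               init_u, init_l, t_out, label_start, label_end, event_cap):
    """Core next-event loop.

    State: counts per (compartment, label status).  Returns
    (out, n_events) with out of shape (len(t_out), 10): columns 0-4 are
    unlabelled c1..c5, columns 5-9 labelled l1..l5 at the output times.
    n_events == -1 signals that the event cap was hit.
    """
    n = init_u.astype(np.float64).copy()      # unlabelled c1..c5
    m = init_l.astype(np.float64).copy()      # labelled   l1..l5
    out = np.zeros((t_out.size, 10))
    t = 0.0
    k_out = 0
    n_events = 0
    while k_out < t_out.size:
        # channel propensities: 0-6 unlabelled, 7-13 labelled
        # [stem event, prog event, prog death, nb maturation, nb death,
        #  neuron death, astro death]
        r = np.empty(14)
        r[0] = p1 * n[0]
        r[1] = p2 * n[1]
        r[2] = d2 * n[1]
        r[3] = p3 * n[2]
        r[4] = d3 * n[2]
        r[5] = d4 * n[3]
        r[6] = d5 * n[4]
        r[7] = p1 * m[0]
        r[8] = p2 * m[1]
        r[9] = d2 * m[1]
        r[10] = p3 * m[2]
        r[11] = d3 * m[2]
        r[12] = d4 * m[3]
        r[13] = d5 * m[4]
        total = r.sum()
        if total <= 0.0:
            while k_out < t_out.size:
                for j in range(5):
                    out[k_out, j] = n[j]
                    out[k_out, 5 + j] = m[j]
                k_out += 1
            break
        dt = -np.log(1.0 - rng.random()) / total
        t_new = t + dt
        while k_out < t_out.size and t_out[k_out] < t_new:
            for j in range(5):
                out[k_out, j] = n[j]
                out[k_out, 5 + j] = m[j]
            k_out += 1
        t = t_new
        if k_out >= t_out.size:
            break
        n_events += 1
        if n_events > event_cap:
            return out, -1
        u = rng.random() * total
        ch = 0
        acc = r[0]
        while acc < u and ch < 13:
            ch += 1
            acc += r[ch]
        labelled_cell = ch >= 7
        base = ch - 7 if labelled_cell else ch
        pop = m if labelled_cell else n
        window = (t >= label_start) and (t <= label_end)
        mark = labelled_cell or window   # daughters of this division are labelled?
        if base == 0:
            # stem event
            if rng.random() < th1:
                if rng.random() < 2.0 * a1 - 1.0:
                    # symmetric: two stem daughters
                    if mark:
                        pop[0] -= 1.0
                        m[0] += 2.0
                    else:
                        n[0] += 1.0
                else:
                    # asymmetric: stem + (progenitor | astrocyte)
                    other = 1 if rng.random() < kap else 4
                    if mark:
                        pop[0] -= 1.0
                        m[0] += 1.0
                        m[other] += 1.0
                    else:
                        n[other] += 1.0
            else:
                # astrocytic transformation, label status preserved
                pop[0] -= 1.0
                pop[4] += 1.0
        elif base == 1:
            # progenitor event
            if rng.random() < th2:
                if rng.random() < 2.0 * a2 - 1.0:
                    if mark:
                        pop[1] -= 1.0
                        m[1] += 2.0
                    else:
                        n[1] += 1.0
                else:
                    # asymmetric: progenitor + neuroblast
                    if mark:
                        pop[1] -= 1.0
                        m[1] += 1.0
                        m[2] += 1.0
                    else:
                        n[2] += 1.0
            else:
                pop[1] -= 1.0
                pop[2] += 1.0
        elif base == 2:
            pop[1] -= 1.0
        elif base == 3:
            pop[2] -= 1.0
            pop[3] += 1.0
        elif base == 4:
            pop[2] -= 1.0
        elif base == 5:
            pop[3] -= 1.0
        else:
            pop[4] -= 1.0
    return out, n_events


def _rng(seed: int, rep: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=[int(seed), int(rep)]))


def _run(params: Parameters, init_u: np.ndarray, init_l: np.ndarray, t_out: np.ndarray,
         label_start: float, label_end: float, seed: int, rep: int,
         event_cap: int) -> np.ndarray:
    out, n_events = _gillespie(
        _rng(seed, rep), params.a1, params.theta1, params.p1, params.kappa,
        params.a2, params.theta2, params.p2, params.d2, params.p3, params.d3,
        params.d4, params.d5, init_u, init_l, t_out, label_start, label_end,
        int(event_cap))
    if n_events < 0:
        raise EventCapExceeded(
            f"event cap {event_cap} exceeded (seed={seed}, replicate={rep}); "
            "population likely exploding")
    return out


def _int_init(init: CellState) -> np.ndarray:
    arr = init.to_array()
    rounded = np.rint(arr)
    if np.any(np.abs(arr - rounded) > 1e-9):
        raise ValueError("stochastic simulation requires integer initial counts")
    return rounded


def simulate_population(params: Parameters, init: CellState, horizon: float, seed: int,
                        t_out=None, event_cap: int = EVENT_CAP) -> Trajectory:
    """One exact stochastic realization of the compartment counts.

    Counts are recorded at the requested output times (default: 51
    evenly spaced points on [0, horizon]).
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    if t_out is None:
        t_out = np.linspace(0.0, float(horizon), 51)
    t_out = np.asarray(t_out, dtype=float)
    out = _run(params, _int_init(init), np.zeros(5), t_out, np.inf, np.inf,
               seed, 0, event_cap)
    return Trajectory(t_out, out[:, :5], meta={"seed": int(seed), "stochastic": True})


def simulate_ensemble(params: Parameters, init: CellState, t_out, n_rep: int, seed: int,
                      event_cap: int = EVENT_CAP) -> np.ndarray:
    """Replicate compartment counts, shape (n_rep, len(t_out), 5)."""
    t_out = np.asarray(t_out, dtype=float)
    iu = _int_init(init)
    out = np.empty((n_rep, t_out.size, 5))
    for rep in range(n_rep):
        out[rep] = _run(params, iu, np.zeros(5), t_out, np.inf, np.inf,
                        seed, rep, event_cap)[:, :5]
    return out


def simulate_brdu(params: Parameters, init: CellState, protocol: LabelingProtocol,
                  seed: int, n_rep: int, tau_out=None,
                  event_cap: int = EVENT_CAP) -> dict[str, np.ndarray]:
    """Replicate labelled (and total) counts after a BrdU pulse-chase.

    The window [t_hat, t_hat + delta] marks both daughters of every
    division; counts are read out at chase times ``tau_out`` (default:
    the protocol's single tau) after the window closes.  Returns arrays
    ``labeled`` and ``total`` of shape (n_rep, len(tau_out), 5) plus the
    chase-time grid.
    """
    tau_out = np.asarray([protocol.tau] if tau_out is None else tau_out, dtype=float)
    t_abs = protocol.t_hat + protocol.delta + tau_out
    iu = _int_init(init)
    labeled = np.empty((n_rep, tau_out.size, 5))
    total = np.empty_like(labeled)
    for rep in range(n_rep):
        out = _run(params, iu, np.zeros(5), t_abs,
                   protocol.t_hat, protocol.t_hat + protocol.delta, seed, rep, event_cap)
        labeled[rep] = out[:, 5:]
        total[rep] = out[:, :5] + out[:, 5:]
    return {"tau": tau_out, "labeled": labeled, "total": total}


def ensemble_summary(samples: np.ndarray) -> dict[str, np.ndarray]:
    """Mean and Monte-Carlo standard error over the replicate axis."""
    n = samples.shape[0]
    mean = samples.mean(axis=0)
    se = samples.std(axis=0, ddof=1) / np.sqrt(n)
    return {"mean": mean, "se": se, "n_rep": n}
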