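"""Synthetic data generation for the fitting and KO pipelines.

Stereological cell counts of the kind the model is fitted to (per-age
mean and s.e.m. of stem and progenitor counts) are not redistributable,
so every fixture is generated here: noisy replicate counts around the
model's closed-form age curves, summarized as mean +/- s.e.m., plus an
optional saturation distortion (a floor on late-age stem counts) that
reproduces the qualitative failure mode of fitting a pure exponential
to data whose stem pool levels off.

Default noise: multiplicative lognormal with a 5% coefficient of
variation and 4 replicates per age — a plausible scale for
stereological counting — on a 10-point age grid spanning [0, 24] model
time units (evoking months of adult age).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .brdu import LabelingProtocol, initial_labels
from .model import closed_form_c1, closed_form_c2, solve_system
from .params import CellState, Parameters
from .fitting import AgeSeries

__all__ = ["AgeSeriesDesign", "generate_age_series", "generate_ko_dataset"]


def _default_ages() -> np.ndarray:
    return np.linspace(0.0, 24.0, 10)


@dataclass
class AgeSeriesDesign:
    """Design of a synthetic age-decline series.

    noise: 'lognormal' (mean-preserving multiplicative) or 'truncnorm'
    (normal with sd = cv * true value, clipped at 0).  With cv = 0 the
    reported means equal the closed-form curves and the s.e.m. is the
    configured ``sem_floor``.  ``saturation_floor``, when set, clamps
    the true stem curve from below — the misfit fixture.
    """

    params: Parameters
    init: CellState
    ages: np.ndarray = field(default_factory=_default_ages)
    cv: float = 0.05
    replicates: int = 4
    noise: str = "lognormal"
    sem_floor: float = 1.0
    saturation_floor: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.cv > 0 and self.replicates < 2:
            raise ValueError("need >= 2 replicates to form an s.e.m. from noisy draws")
        if self.noise not in ("lognormal", "truncnorm"):
            raise ValueError("noise must be 'lognormal' or 'truncnorm'")
        if self.sem_floor <= 0:
            raise ValueError("sem_floor must be > 0")


def _noisy(rng: np.random.Generator, true: float, cv: float, kind: str, n: int) -> np.ndarray:
    if kind == "lognormal":
        sigma = np.sqrt(np.log1p(cv ** 2))
        return true * rng.lognormal(-sigma ** 2 / 2.0, sigma, size=n)
    return np.clip(rng.normal(true, cv * true, size=n), 0.0, None)


def generate_age_series(design: AgeSeriesDesign) -> AgeSeries:
    """Noisy replicate means and s.e.m. around the closed-form curves.

    Deterministic for a given design (seeded).  Observed mean is the
    replicate average, s.e.m. the replicate SD / sqrt(replicates)
    (floored at ``sem_floor`` so downstream inverse-variance weights
    stay finite).
    """
    rng = np.random.default_rng(design.seed)
    p, n1, n2 = design.params, design.init.c1, design.init.c2
    stem_true = np.asarray(closed_form_c1(p, n1, design.ages))
    if design.saturation_floor is not None:
        stem_true = np.maximum(stem_true, design.saturation_floor)
    prog_true = np.asarray(closed_form_c2(p, n1, n2, design.ages))
    rows = []
    for comp, true_curve in (("stem", stem_true), ("progenitor", prog_true)):
        for age, true in zip(design.ages, true_curve):
            if design.cv == 0:
                mean, sem = float(true), design.sem_floor
            else:
                draws = _noisy(rng, float(true), design.cv, design.noise, design.replicates)
                mean = float(draws.mean())
                sem = max(float(draws.std(ddof=1) / np.sqrt(design.replicates)), design.sem_floor)
            rows.append({"age": float(age), "compartment": comp, "mean": mean, "sem": sem})
    return AgeSeries(pd.DataFrame(rows))


def generate_ko_dataset(params: Parameters, init: CellState, param_name: str,
                        delta_p: float, obs_times, protocol: LabelingProtocol,
                        cv: float = 0.05, replicates: int = 4, seed: int = 0,
                        noise: str = "lognormal") -> pd.DataFrame:
    """Paired wild-type/KO observations of cell counts and labelled counts.

    The KO is an instantaneous change of one stem-cell parameter by
    ``delta_p`` at time 0.  For each observation time t the dataset
    holds noisy replicate summaries of the compartment counts c_i(t)
    and of the labelled pools l_i(t_hat, tau = t) under the given BrdU
    protocol, for both parameter sets.  Columns: group, time, quantity,
    mean, sem.
    """
    rng = np.random.default_rng(seed)
    obs_times = np.asarray(obs_times, dtype=float)
    grid = np.unique(np.concatenate([[0.0], obs_times]))
    idx = np.searchsorted(grid, obs_times)
    rows = []
    for group, p in (("wt", params),
                     ("ko", params.replace(**{param_name: getattr(params, param_name) + delta_p}))):
        counts = solve_system(p, init, grid).states[idx]
        if protocol.t_hat > 0:
            c_hat = solve_system(p, init, np.array([0.0, protocol.t_hat])).at(-1)
        else:
            c_hat = init
        l0 = initial_labels(p, c_hat, protocol.delta)
        labels = solve_system(p, CellState.from_array(l0.to_array()), grid).states[idx]
        for block, names in ((counts, ("c1", "c2", "c3", "c4", "c5")),
                             (labels, ("l1", "l2", "l3", "l4", "l5"))):
            for j, t in enumerate(obs_times):
                for i, name in enumerate(names):
                    true = float(block[j, i])
                    if cv == 0 or true == 0.0:
                        mean, sem = true, 1.0
                    else:
                        draws = _noisy(rng, true, cv, noise, replicates)
                        mean = float(draws.mean())
                        sem = max(float(draws.std(ddof=1) / np.sqrt(replicates)), 1e-12)
                    rows.append({"group": group, "time": float(t), "quantity": name,
                                 "mean": mean, "sem": sem})
    return pd.DataFrame(rows)
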