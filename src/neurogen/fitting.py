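"""Weighted least-squares fitting of the age-decline curves.

Stem-cell and progenitor counts decline with adult age; the model
predicts c1(t) = n1 e^{lambda1 t} and a two-exponential progenitor
curve.  Observed age series (mean count and s.e.m. per age) are fitted
by minimizing the sum of squared residuals weighted by the inverse
square of each observation's standard error of the mean, in either of
two modes: fitting the stem count together with the stem/progenitor
ratio, or together with the progenitor count directly.

Only the rate/size composites

    lambda1, lambda2, n1, n2, K = k12 * n1

are identifiable from (c1, c2) data — any kinetic parameter vector
mapping to the same composites yields identical curves — so the
optimizer works on the composites (rates free, sizes in log space) and
individual parameters are recovered downstream only under additional
constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import two_compartment_c2

__all__ = [
    "AgeSeries",
    "FitConfig",
    "FitResult",
    "MODES",
    "weighted_ssr",
    "fit",
    "predict",
]

MODES = ("c1_and_ratio", "c1_and_c2")
COMPOSITE_NAMES = ("lambda1", "lambda2", "n1", "n2", "K")


class FitError(RuntimeError):
    """No optimizer start converged."""


@dataclass
class AgeSeries:
    """Age series of compartment counts with standard errors.

    ``data`` columns: age, compartment ('stem' | 'progenitor' | 'ratio'),
    mean, sem.  Every used observation must have sem > 0; a 'ratio' row,
    when absent, is derived from matching stem/progenitor rows with a
    first-order error propagation.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"age", "compartment", "mean", "sem"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"age series needs columns {sorted(required)}")
        if (self.data["sem"] <= 0).any():
            raise ValueError("every observation needs sem > 0")
        if (self.data["age"] < 0).any():
            raise ValueError("ages must be nonnegative")
        bad = set(self.data["compartment"]) - {"stem", "progenitor", "ratio"}
        if bad:
            raise ValueError(f"unknown compartment label(s): {sorted(bad)}")

    def observations(self, compartment: str) -> pd.DataFrame:
        sub = self.data[self.data["compartment"] == compartment]
        if compartment == "ratio" and sub.empty:
            sub = self._derived_ratio()
        return sub.sort_values("age").reset_index(drop=True)

    def _derived_ratio(self) -> pd.DataFrame:
        stem = self.observations("stem").set_index("age")
        prog = self.observations("progenitor").set_index("age")
        ages = stem.index.intersection(prog.index)
        r = stem.loc[ages, "mean"] / prog.loc[ages, "mean"]
        sem = np.abs(r) * np.sqrt((stem.loc[ages, "sem"] / stem.loc[ages, "mean"]) ** 2
                                  + (prog.loc[ages, "sem"] / prog.loc[ages, "mean"]) ** 2)
        return pd.DataFrame({"age": ages, "compartment": "ratio",
                             "mean": r.values, "sem": sem.values})

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "AgeSeries":
        return cls(pd.read_csv(path))


def predict(composites: dict[str, float], ages, compartment: str) -> np.ndarray:
    """Model curve for one compartment label given the composites."""
    t = np.asarray(ages, dtype=float)
    lam1, lam2 = composites["lambda1"], composites["lambda2"]
    n1, n2, K = composites["n1"], composites["n2"], composites["K"]
    stem = n1 * np.exp(lam1 * t)
    if compartment == "stem":
        return stem
    prog = two_compartment_c2(lam1, lam2, K, 1.0, n2, t)
    if compartment == "progenitor":
        return np.asarray(prog)
    if compartment == "ratio":
        return stem / np.asarray(prog)
    raise ValueError(f"unknown compartment {compartment!r}")


def _mode_compartments(mode: str) -> tuple[str, str]:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    return ("stem", "ratio") if mode == "c1_and_ratio" else ("stem", "progenitor")


def _residuals(composites: dict[str, float], data: AgeSeries, mode: str) -> np.ndarray:
    res = []
    # wild multi-start points can overflow the exponentials; the resulting
    # inf residuals are simply rejected by the optimizer
    with np.errstate(over="ignore", invalid="ignore"):
        for comp in _mode_compartments(mode):
            obs = data.observations(comp)
            model = predict(composites, obs["age"].values, comp)
            res.append((model - obs["mean"].values) / obs["sem"].values)
    return np.nan_to_num(np.concatenate(res), nan=1e50, posinf=1e50, neginf=-1e50)


def weighted_ssr(composites: dict[str, float], data: AgeSeries, mode: str) -> float:
    """Sum over observations of ((model - observed)/sem)^2."""
    r = _residuals(composites, data, mode)
    return float(r @ r)


@dataclass
class FitConfig:
    """Multi-start settings: random starts in log-size space around a
    log-linear initial guess, each polished by trust-region least
    squares."""

    n_starts: int = 100
    max_nfev: int = 2000
    rate_low: float = -2.0
    rate_high: float = 0.2


@dataclass
class FitResult:
    composites: dict[str, float]
    ssr: float
    r_squared: float
    mode: str
    n_obs: int
    seed: int
    trace: dict = field(default_factory=dict)

    def predict(self, ages, compartment: str) -> np.ndarray:
        return predict(self.composites, ages, compartment)


def _pack(c: dict[str, float]) -> np.ndarray:
    return np.array([c["lambda1"], c["lambda2"], np.log(c["n1"]), np.log(c["n2"]),
                     np.log(max(c["K"], 1e-12))])


def _unpack(x: np.ndarray) -> dict[str, float]:
    return {"lambda1": float(x[0]), "lambda2": float(x[1]),
            "n1": float(np.exp(x[2])), "n2": float(np.exp(x[3])), "K": float(np.exp(x[4]))}


def _initial_guess(data: AgeSeries, mode: str) -> dict[str, float]:
    stem = data.observations("stem")
    t, y, s = stem["age"].values, stem["mean"].values, stem["sem"].values
    pos = y > 0
    w = (y[pos] / s[pos]) ** 2  # delta-method weights for log counts
    coef = np.polyfit(t[pos], np.log(y[pos]), 1, w=np.sqrt(w))
    lam1, n1 = float(coef[0]), float(np.exp(coef[1]))
    prog = data.observations("progenitor")
    if prog.empty:  # ratio-only file: back out progenitor scale from the ratio
        ratio = data.observations("ratio")
        n2 = n1 / float(ratio["mean"].iloc[0])
    else:
        n2 = float(prog["mean"].iloc[0])
    return {"lambda1": lam1, "lambda2": lam1 - 0.1, "n1": n1, "n2": n2, "K": 0.1 * n1}


def fit(data: AgeSeries, mode: str, config: FitConfig | None = None, seed: int = 0) -> FitResult:
    """Best-of-multi-start weighted least squares on the composites.

    Deterministic for a given (data, mode, config, seed).  The weighted
    R^2 is computed on the same inverse-variance-weighted residuals as
    the objective, against the weighted mean of the stacked
    observations (the choice of R^2 variant is a package convention).
    """
    config = config or FitConfig()
    for comp in _mode_compartments(mode):
        if len(data.observations(comp)) < 4:
            raise ValueError(f"need >= 4 observations of {comp!r} for an identifiable fit")
    rng = np.random.default_rng(seed)
    guess = _initial_guess(data, mode)
    x_guess = _pack(guess)

    starts = [x_guess]
    for _ in range(max(0, config.n_starts - 1)):
        x = x_guess.copy()
        x[0] = rng.uniform(config.rate_low, config.rate_high)
        x[1] = rng.uniform(config.rate_low, config.rate_high)
        x[2:] = x_guess[2:] + rng.normal(0.0, 1.0, size=3)
        starts.append(x)

    best = None
    n_fail = 0
    for x0 in starts:
        try:
            sol = least_squares(lambda x: _residuals(_unpack(x), data, mode), x0,
                                method="trf", max_nfev=config.max_nfev)
        except Exception:
            n_fail += 1
            continue
        ssr = float(sol.fun @ sol.fun)
        if np.isfinite(ssr) and (best is None or ssr < best[0]):
            best = (ssr, sol)
    if best is None:
        raise FitError(f"all {len(starts)} starts failed (last guess {guess})")
    ssr, sol = best

    obs_stack, w_stack = [], []
    for comp in _mode_compartments(mode):
        obs = data.observations(comp)
        obs_stack.append(obs["mean"].values)
        w_stack.append(1.0 / obs["sem"].values ** 2)
    obs_stack, w_stack = np.concatenate(obs_stack), np.concatenate(w_stack)
    wmean = float(np.sum(w_stack * obs_stack) / np.sum(w_stack))
    sst = float(np.sum(w_stack * (obs_stack - wmean) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else float("nan")

    return FitResult(
        composites=_unpack(sol.x), ssr=ssr, r_squared=r2, mode=mode,
        n_obs=obs_stack.size, seed=seed,
        trace={"n_starts": len(starts), "n_failed": n_fail, "nfev": int(sol.nfev),
               "initial_guess": guess},
    )
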