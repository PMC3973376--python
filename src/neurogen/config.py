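"""Scenario configuration and reproducible run orchestration.

A scenario config (YAML or JSON) pins everything needed to regenerate a
run byte-for-byte: parameter set, initial counts, scenario kind, BrdU
protocol, grids, seed and solver overrides.  Unknown keys are rejected
and validation errors name the offending field.  All CSV output uses
comma separators, a header row and 17 significant digits, so
write-read round trips are lossless well past 15 digits.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from . import __version__
from .brdu import LabelingProtocol, initial_labels, labeled_trajectory
from .fitting import AgeSeries, FitConfig, fit
from .model import SolverSettings, solve_system
from .oracle import ensemble_summary, simulate_ensemble
from .params import COMPARTMENTS, CellState, Parameters
from .sensitivity import (brdu_incorporating_sensitivities, forward_sensitivities,
                          sign_sequence, table1_report)
from .synth import AgeSeriesDesign, generate_age_series

__all__ = ["ScenarioConfig", "load_config", "run_scenario", "paper_s52_config"]

FLOAT_FMT = "%.17g"


class GridSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    start: float = 0.0
    stop: float = 30.0
    num: int = Field(default=3001, ge=2)

    def to_array(self) -> np.ndarray:
        return np.linspace(self.start, self.stop, self.num)


class SolverOverrides(BaseModel):
    model_config = ConfigDict(extra="forbid")
    method: str = "LSODA"
    rtol: float = Field(default=1e-10, gt=0, le=1e-3)
    atol: float = Field(default=1e-12, ge=0)

    def to_settings(self) -> SolverSettings:
        return SolverSettings(method=self.method, rtol=self.rtol, atol=self.atol)


class ScenarioConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["counts", "brdu", "sensitivity", "table1", "fit", "oracle", "synth"]
    params: dict[str, float]
    init: dict[str, float]
    seed: int = 0
    grid: GridSpec = GridSpec()
    t_hat: float = Field(default=0.0, ge=0)
    delta: float = Field(default=0.1, ge=0)
    tau_grid: Optional[GridSpec] = None
    parameter: Optional[str] = None          # sensitivity kind
    fit_mode: Literal["c1_and_ratio", "c1_and_c2"] = "c1_and_ratio"
    data_path: Optional[str] = None          # fit kind
    n_starts: int = Field(default=100, ge=1)
    n_rep: int = Field(default=200, ge=1)    # oracle kind
    horizon: float = Field(default=5.0, gt=0)
    cv: float = Field(default=0.05, ge=0)    # synth kind
    replicates: int = Field(default=4, ge=1)
    sem_floor: float = Field(default=1.0, gt=0)
    saturation_floor: Optional[float] = None
    ages: Optional[list[float]] = None
    solver: SolverOverrides = SolverOverrides()

    @field_validator("params")
    @classmethod
    def _valid_params(cls, v: dict[str, float]) -> dict[str, float]:
        Parameters.from_dict(v)  # raises with the offending name
        return v

    @field_validator("init")
    @classmethod
    def _valid_init(cls, v: dict[str, float]) -> dict[str, float]:
        CellState.from_dict(v)
        return v

    @model_validator(mode="after")
    def _per_kind(self) -> "ScenarioConfig":
        if self.kind == "sensitivity" and self.parameter is None:
            raise ValueError("kind 'sensitivity' requires 'parameter'")
        if self.kind == "fit":
            if self.data_path is None:
                raise ValueError("kind 'fit' requires 'data_path'")
            if not Path(self.data_path).exists():
                raise ValueError(f"data_path {self.data_path!r} does not exist")
        return self

    def parameters(self) -> Parameters:
        return Parameters.from_dict(self.params)

    def cell_state(self) -> CellState:
        return CellState.from_dict(self.init)

    def protocol(self, tau: float = 0.0) -> LabelingProtocol:
        return LabelingProtocol(t_hat=self.t_hat, delta=self.delta, tau=tau)


def load_config(path) -> ScenarioConfig:
    """Load and fully validate a YAML/JSON scenario config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path!r} must be a mapping")
    return ScenarioConfig.model_validate(raw)


def paper_s52_config() -> ScenarioConfig:
    """The packaged canonical simulation config (declining-regime
    parameter set with the standard initial counts)."""
    path = Path(__file__).parent / "data" / "paper_s52.yaml"
    return load_config(path)


def _write_csv(df, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_scenario(config: ScenarioConfig, out_dir) -> dict:
    """Execute a scenario and write its artifacts under ``out_dir``.

    Returns a manifest of written paths; also writes ``run_log.json``
    recording package version, seed and solver settings so any run is
    reproducible from its log alone.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params, init = config.parameters(), config.cell_state()
    settings = config.solver.to_settings()
    grid = config.grid.to_array()
    artifacts: dict[str, str] = {}

    if config.kind == "counts":
        traj = solve_system(params, init, grid, settings)
        _write_csv(traj.to_frame(), out / "trajectory.csv")
        artifacts["trajectory"] = str(out / "trajectory.csv")
    elif config.kind == "brdu":
        tau_grid = (config.tau_grid or config.grid).to_array()
        if config.t_hat > 0:
            c_hat = solve_system(params, init, np.array([0.0, config.t_hat]), settings).at(-1)
        else:
            c_hat = init
        l0 = initial_labels(params, c_hat, config.delta)
        traj = labeled_trajectory(params, l0, tau_grid, settings)
        df = traj.to_frame().rename(columns={"time": "tau",
                                             **{c: f"l{i+1}" for i, c in enumerate(COMPARTMENTS)}})
        _write_csv(df, out / "brdu.csv")
        artifacts["brdu"] = str(out / "brdu.csv")
    elif config.kind == "sensitivity":
        counts = forward_sensitivities(params, init, config.parameter, grid, settings)
        labels = brdu_incorporating_sensitivities(params, init, config.parameter, grid,
                                                  config.delta, settings)
        import pandas as pd

        df = pd.DataFrame({"time": grid,
                           **{f"d{q}": c.values for q, c in counts.items()},
                           **{f"d{q}": c.values for q, c in labels.items()}})
        _write_csv(df, out / f"sens_{config.parameter}.csv")
        summary = {q: str(sign_sequence(c)) for q, c in {**counts, **labels}.items()}
        _write_json(summary, out / f"sens_{config.parameter}_signs.json")
        artifacts["sensitivity"] = str(out / f"sens_{config.parameter}.csv")
        artifacts["signs"] = str(out / f"sens_{config.parameter}_signs.json")
    elif config.kind == "table1":
        report = table1_report(params, init, grid, config.delta, settings=settings)
        _write_json({"table": report.as_strings(),
                     "assumption_ok": list(report.assumption_ok),
                     "meta": report.meta}, out / "table1.json")
        artifacts["table1"] = str(out / "table1.json")
    elif config.kind == "fit":
        data = AgeSeries.from_csv(config.data_path)
        result = fit(data, config.fit_mode, FitConfig(n_starts=config.n_starts),
                     seed=config.seed)
        _write_json({"composites": result.composites, "ssr": result.ssr,
                     "r_squared": result.r_squared, "mode": result.mode,
                     "n_obs": result.n_obs, "trace": result.trace},
                    out / "fit.json")
        import pandas as pd

        dense = np.linspace(grid[0], grid[-1], 301)
        _write_csv(pd.DataFrame({"age": dense,
                                 "stem": result.predict(dense, "stem"),
                                 "progenitor": result.predict(dense, "progenitor"),
                                 "ratio": result.predict(dense, "ratio")}),
                   out / "fitted_curves.csv")
        artifacts["fit"] = str(out / "fit.json")
        artifacts["curves"] = str(out / "fitted_curves.csv")
    elif config.kind == "oracle":
        t_out = np.linspace(0.0, config.horizon, 11)
        ens = simulate_ensemble(params, init, t_out, config.n_rep, config.seed)
        summ = ensemble_summary(ens)
        _write_json({"t": t_out.tolist(),
                     "mean": summ["mean"].tolist(), "se": summ["se"].tolist(),
                     "n_rep": summ["n_rep"]}, out / "oracle_summary.json")
        artifacts["oracle"] = str(out / "oracle_summary.json")
    elif config.kind == "synth":
        design = AgeSeriesDesign(params=params, init=init,
                                 ages=np.asarray(config.ages) if config.ages else _default_ages(),
                                 cv=config.cv, replicates=config.replicates,
                                 sem_floor=config.sem_floor,
                                 saturation_floor=config.saturation_floor,
                                 seed=config.seed)
        series = generate_age_series(design)
        series.to_csv(out / "age_series.csv")
        _write_json({"design": {"ages": design.ages.tolist(), "cv": design.cv,
                                "replicates": design.replicates, "noise": design.noise,
                                "sem_floor": design.sem_floor,
                                "saturation_floor": design.saturation_floor,
                                "seed": design.seed}},
                    out / "age_series_provenance.json")
        artifacts["age_series"] = str(out / "age_series.csv")

    log = {"package_version": __version__, "kind": config.kind, "seed": config.seed,
           "solver": config.solver.model_dump(), "artifacts": artifacts}
    _write_json(log, out / "run_log.json")
    artifacts["log"] = str(out / "run_log.json")
    return artifacts


def _default_ages() -> np.ndarray:
    return np.linspace(0.0, 24.0, 10)
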