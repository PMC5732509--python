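"""Robustness analyses around the calibrated base run.

* one-parameter sweeps of a transition hazard over a grid (used for
  the two hazards that calibrated to zero in females, swept up to the
  next age band's value);
* a sweep of the diabetes prevalence assumed among 20-year-old
  entrants (0%–0.4% around the 0.2% default);
* an extended projection horizon (2055 instead of 2035);
* exponential secular drift of the two rate families, with an optional
  mode that recalibrates the drift coefficients jointly with the rates.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationOptions,
    CalibrationResult,
    DIALYSIS_RATE_BOUND,
    DM_RATE_BOUND,
    N_RATES,
    _model_observables,
    _unpack,
)
from .constants import BANDS, DEFAULT_DT, DIALYSIS_BANDS, N_STOCKS
from .dataset import ObservedDataset
from .model import (
    ExogenousInputs,
    LinearPropagator,
    ModelParameters,
    Trajectory,
    simulate,
)
from .scenarios import SCENARIO_NAMES, run_scenarios

MAX_DRIFT = 0.05

#: grid endpoints used for the two female hazards that calibrated to
#: zero: swept from 0 up to the published next-age-band value
PUBLISHED_SWEEP_ENDPOINTS = {
    "DM3039ir": 0.00138225,
    "DMDi4049ir": 0.00136167,
}


@dataclass(frozen=True)
class SimulationContext:
    """Everything needed to rerun the base projection."""

    params: ModelParameters
    exog: ExogenousInputs
    t0: float = 2000.0
    t1: float = 2035.0
    dt: float = DEFAULT_DT


@dataclass
class SweepResult:
    param_name: str
    grid: np.ndarray
    trajectories: list[Trajectory]
    report: pd.DataFrame  # aggregates at report years per grid value


def parameter_hash(params: ModelParameters) -> str:
    h = hashlib.sha256()
    h.update(params.dm_incidence.tobytes())
    h.update(params.dialysis_incidence.tobytes())
    h.update(params.initial_state.tobytes())
    return h.hexdigest()


def _set_rate(params: ModelParameters, name: str, value: float
              ) -> ModelParameters:
    for i, band in enumerate(BANDS):
        if name == f"DM{band}ir":
            dm = params.dm_incidence.copy()
            dm[i] = value
            return params.with_rates(dm_incidence=dm)
    for k, band in enumerate(DIALYSIS_BANDS):
        if name == f"DMDi{band}ir":
            di = params.dialysis_incidence.copy()
            di[k] = value
            return params.with_rates(dialysis_incidence=di)
    raise ValueError(f"unknown rate parameter {name!r}")


def _check_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must not be empty")
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    return grid


def _report(trajs: list[Trajectory], grid: np.ndarray, label: str,
            report_years: tuple[int, ...]) -> pd.DataFrame:
    rows = []
    for value, traj in zip(grid, trajs):
        agg = traj.aggregates()
        for year in report_years:
            for var in ("TotalDM", "DMDiover40", "dm_prevalence_pct"):
                rows.append((label, value, year, var,
                             float(agg.loc[year, var])))
    return pd.DataFrame(rows, columns=["parameter", "grid_value", "year",
                                       "variable", "value"])


def sweep_rate(param_name: str, grid, context: SimulationContext,
               report_years: tuple[int, ...] = (2035,)) -> SweepResult:
    """Re-simulate the base run for each grid value of one hazard,
    everything else held fixed."""
    grid = _check_grid(grid)
    is_dm = param_name.startswith("DM") and not param_name.startswith("DMDi")
    bound = DM_RATE_BOUND if is_dm else DIALYSIS_RATE_BOUND
    if np.any(grid < 0) or np.any(grid > bound):
        raise ValueError(f"grid outside [0, {bound}] for {param_name}")
    trajs = []
    for value in grid:
        p = _set_rate(context.params, param_name, float(value))
        trajs.append(simulate(p, context.exog, t0=context.t0, t1=context.t1,
                              dt=context.dt))
    return SweepResult(param_name, grid, trajs,
                       _report(trajs, grid, param_name, report_years))


def sweep_entry_prevalence(grid, context: SimulationContext,
                           report_years: tuple[int, ...] = (2035,)
                           ) -> SweepResult:
    """Base run per assumed diabetes prevalence at age 20."""
    grid = _check_grid(grid)
    if np.any(grid < 0) or np.any(grid > 1):
        raise ValueError("entry prevalence must lie in [0, 1]")
    trajs = []
    for value in grid:
        exog = replace(context.exog, entry_dm_prevalence=float(value))
        trajs.append(simulate(context.params, exog, t0=context.t0,
                              t1=context.t1, dt=context.dt))
    return SweepResult("entry_dm_prevalence", grid, trajs,
                       _report(trajs, grid, "entry_dm_prevalence",
                               report_years))


@dataclass(frozen=True)
class DriftParams:
    """Exponential secular drift of the rate families.

    Effective rate(t) = calibrated rate × exp(g · (t − reference_year)),
    one coefficient per family.  Never scales the exogenous dialysis
    entry (that series is data, not a hazard).
    """

    g_dm: float = 0.0
    g_dialysis: float = 0.0
    reference_year: float = 2000.0
    scales_dialysis_entry: bool = False

    def __post_init__(self) -> None:
        if abs(self.g_dm) > MAX_DRIFT or abs(self.g_dialysis) > MAX_DRIFT:
            raise ValueError(f"|drift| must not exceed {MAX_DRIFT}/yr")

    def dm_multiplier(self, t: float) -> float:
        return math.exp(self.g_dm * (t - self.reference_year))

    def dialysis_multiplier(self, t: float) -> float:
        return math.exp(self.g_dialysis * (t - self.reference_year))


def run_with_drift(drift: DriftParams, context: SimulationContext,
                   scenario=None) -> Trajectory:
    """Base (or scenario) run with exponentially drifting rates."""
    return simulate(context.params, context.exog, scenario=scenario,
                    t0=context.t0, t1=context.t1, dt=context.dt, drift=drift)


def calibrate_with_drift(data: ObservedDataset,
                         options: CalibrationOptions | None = None
                         ) -> tuple[CalibrationResult, DriftParams]:
    """Joint recalibration of rates, initial stocks and the two drift
    coefficients (bounded at ±0.05/yr)."""
    from scipy.optimize import minimize

    from .calibration import compute_weights

    opts = options or CalibrationOptions()
    weights = compute_weights(data)
    start_year = int(data.years[0])
    prop = LinearPropagator(data.exog, start_year, int(data.years[-1]),
                            dt=opts.dt)
    data_stocks = data.initial_stocks()
    obs = data.observation_matrix()
    names = data.observation_names()
    w_vec = np.array([weights.weight.get(n, 0.0) for n in names])
    n_base = N_RATES + (N_STOCKS if opts.fit_initial_stocks else 0)
    n_dim = n_base + 2
    n_evals = 0

    def unpack_drift(x) -> tuple[ModelParameters, DriftParams]:
        params = _unpack(x[:n_base], data_stocks, opts, data.sex, start_year)
        drift = DriftParams(
            g_dm=(2.0 * x[n_base] - 1.0) * MAX_DRIFT,
            g_dialysis=(2.0 * x[n_base + 1] - 1.0) * MAX_DRIFT,
            reference_year=float(start_year),
        )
        return params, drift

    def objective(x) -> float:
        nonlocal n_evals
        n_evals += 1
        params, drift = unpack_drift(x)
        states = prop.annual_states(params, drift=drift)
        r = w_vec * (_model_observables(states) - obs)
        return float((r * r).sum())

    rng = np.random.default_rng(opts.seed)
    starts = [np.full(n_dim, 0.5)]
    starts[0][:N_RATES] = 0.1
    for _ in range(max(opts.n_starts - 1, 0)):
        starts.append(rng.uniform(0.05, 0.95, size=n_dim))
    best = None
    payoffs = []
    for x0 in starts:
        res = minimize(objective, x0, method="Powell",
                       bounds=[(0.0, 1.0)] * n_dim,
                       options={"maxfev": opts.maxfev, "xtol": opts.xtol,
                                "ftol": opts.ftol})
        payoffs.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    params, drift = unpack_drift(best.x)
    states = prop.annual_states(params, drift=drift)
    resid = _model_observables(states) - obs
    summary = pd.DataFrame({
        "variable": names,
        "weight": w_vec,
        "rms_weighted_residual": np.sqrt(np.mean((w_vec * resid) ** 2,
                                                 axis=0)),
        "mean_observed": obs.mean(axis=0),
    })
    result = CalibrationResult(
        params=params, payoff_value=float(best.fun), n_evaluations=n_evals,
        converged=bool(best.success), residual_summary=summary,
        start_payoffs=payoffs)
    return result, drift


def extend_horizon(context: SimulationContext, end_year: int = 2055,
                   drift=None) -> dict[str, Trajectory]:
    """All four scenarios re-run to a later horizon with held exogenous
    values."""
    if end_year < 2035:
        raise ValueError("end_year must be at least 2035")
    return run_scenarios(context.params, context.exog, SCENARIO_NAMES,
                         t0=context.t0, t1=float(end_year), dt=context.dt,
                         drift=drift)
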