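"""Weighted least-squares calibration of the constant transition rates.

For each sex the unknowns are six diabetes-incidence hazards, four
dialysis-initiation hazards (ages 40+) and the sixteen initial stocks.
The payoff is the sum over fitted stock variables and calibration
years of the squared weighted residual between simulated and observed
values, with each variable's weight equal to the inverse of its
2000–2015 observed mean so that residuals are scale-free.  The payoff
is minimized by a bounded derivative-free optimizer (Powell) restarted
from several deterministic seeds; the best payoff wins.

Initial stocks are bounded within ±20% of the values implied by the
first-year observations, which keeps the 26-parameter problem
identified while still letting the optimizer absorb measurement error
in the starting year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .constants import DEFAULT_DT, N_STOCKS
from .dataset import ObservedDataset
from .model import LinearPropagator, ModelParameters, Trajectory

logger = logging.getLogger(__name__)

#: rate bounds (1/year) within which the optimizer searches
DM_RATE_BOUND = 0.05
DIALYSIS_RATE_BOUND = 0.02
N_RATES = 10


@dataclass(frozen=True)
class CalibrationWeights:
    """Inverse-mean weight per fitted variable (1/persons).

    Variables whose observed mean is zero are excluded (their weight
    would be infinite and would destabilize the fit).
    """

    weight: dict[str, float]

    def __post_init__(self) -> None:
        for name, w in self.weight.items():
            if not w > 0:
                raise ValueError(f"non-positive weight for {name}")

    def scaled(self, factor: float) -> "CalibrationWeights":
        return CalibrationWeights(
            {k: v * factor for k, v in self.weight.items()})


@dataclass
class CalibrationOptions:
    n_starts: int = 8
    seed: int = 0
    maxfev: int = 30_000
    dt: float = DEFAULT_DT
    stock_bound_frac: float = 0.20
    fit_initial_stocks: bool = True
    xtol: float = 1e-6
    ftol: float = 1e-10


@dataclass
class CalibrationResult:
    params: ModelParameters
    payoff_value: float
    n_evaluations: int
    converged: bool
    residual_summary: pd.DataFrame
    start_payoffs: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """(sex, parameter, value, lower_bound, upper_bound) table."""
        rows = []
        rates = self.params.rate_dict()
        for i, (name, value) in enumerate(rates.items()):
            bound = DM_RATE_BOUND if i < 6 else DIALYSIS_RATE_BOUND
            rows.append((self.params.sex, name, value, 0.0, bound))
        from .constants import STOCKS, stock_name
        for j, sb in enumerate(STOCKS):
            rows.append((self.params.sex, f"init_{stock_name(*sb)}",
                         self.params.initial_state[j], np.nan, np.nan))
        return pd.DataFrame(rows, columns=["sex", "parameter", "value",
                                           "lower_bound", "upper_bound"])


def compute_weights(data: ObservedDataset) -> CalibrationWeights:
    """Inverse of each fitted variable's mean over the calibration years."""
    names = data.observation_names()
    obs = data.observation_matrix()
    weights: dict[str, float] = {}
    for j, name in enumerate(names):
        mean = float(obs[:, j].mean())
        if mean <= 0:
            logger.warning("excluding variable %s from payoff (zero mean)",
                           name)
            continue
        weights[name] = 1.0 / mean
    return CalibrationWeights(weights)


def _model_observables(states: np.ndarray) -> np.ndarray:
    """Map annual state vectors to the 16 fitted variables
    (pop per band, DM per band, DMDi per band)."""
    pop = states[:, 0:6] + states[:, 6:12]
    pop = pop.copy()
    pop[:, 2:] += states[:, 12:16]
    return np.hstack([pop, states[:, 6:12], states[:, 12:16]])


def payoff(traj: Trajectory | np.ndarray, data: ObservedDataset,
           weights: CalibrationWeights) -> float:
    """Σ over variables and years of (weight · residual)²."""
    if isinstance(traj, Trajectory):
        idx = [int(np.where(traj.years == y)[0][0]) for y in data.years]
        states = traj.states[idx]
    else:
        states = np.asarray(traj, dtype=float)
    model = _model_observables(states)
    obs = data.observation_matrix()
    names = data.observation_names()
    total = 0.0
    for j, name in enumerate(names):
        if name not in weights.weight:
            continue
        w = weights.weight[name]
        r = w * (model[:, j] - obs[:, j])
        total += float(np.dot(r, r))
    return total


# --------------------------------------------------------------------------
# the optimizer
# --------------------------------------------------------------------------


def _unpack(x: np.ndarray, data_stocks: np.ndarray,
            opts: CalibrationOptions, sex: str, start_year: int
            ) -> ModelParameters:
    """Map the unit-cube optimizer vector to model parameters."""
    dm = x[:6] * DM_RATE_BOUND
    di = x[6:10] * DIALYSIS_RATE_BOUND
    if opts.fit_initial_stocks:
        f = opts.stock_bound_frac
        stocks = data_stocks * (1.0 - f + 2.0 * f * x[10:])
    else:
        stocks = data_stocks
    return ModelParameters(sex=sex, dm_incidence=dm, dialysis_incidence=di,
                           initial_state=stocks, start_year=start_year)


def calibrate(data: ObservedDataset,
              options: CalibrationOptions | None = None) -> CalibrationResult:
    """Fit the ten rates (and initial stocks) for one sex.

    Multi-start bounded Powell minimization of the weighted payoff;
    starts are drawn deterministically from ``options.seed``; the
    best-payoff start wins, ties broken by first found.
    """
    opts = options or CalibrationOptions()
    weights = compute_weights(data)
    start_year = int(data.years[0])
    end_year = int(data.years[-1])
    prop = LinearPropagator(data.exog, start_year, end_year, dt=opts.dt)
    data_stocks = data.initial_stocks()
    obs = data.observation_matrix()
    names = data.observation_names()
    w_vec = np.array([weights.weight.get(n, 0.0) for n in names])

    n_evals = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        params = _unpack(x, data_stocks, opts, data.sex, start_year)
        states = prop.annual_states(params)
        model = _model_observables(states)
        r = w_vec * (model - obs)
        return float((r * r).sum())

    n_dim = N_RATES + (N_STOCKS if opts.fit_initial_stocks else 0)
    rng = np.random.default_rng(opts.seed)
    starts = [np.full(n_dim, 0.5)]
    starts[0][:N_RATES] = 0.1  # rates start low: hazards are ≪ their bounds
    for _ in range(max(opts.n_starts - 1, 0)):
        starts.append(rng.uniform(0.05, 0.95, size=n_dim))

    best = None
    start_payoffs: list[float] = []
    failures: list[str] = []
    for s_i, x0 in enumerate(starts):
        try:
            res = minimize(
                objective, x0, method="Powell",
                bounds=[(0.0, 1.0)] * n_dim,
                options={"maxfev": opts.maxfev, "xtol": opts.xtol,
                         "ftol": opts.ftol},
            )
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(f"start {s_i}: {exc}")
            continue
        start_payoffs.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("optimizer failed on every start:\n"
                           + "\n".join(failures))

    params = _unpack(best.x, data_stocks, opts, data.sex, start_year)
    states = prop.annual_states(params)
    model = _model_observables(states)
    resid = model - obs
    summary = pd.DataFrame({
        "variable": names,
        "weight": w_vec,
        "rms_weighted_residual": np.sqrt(
            np.mean((w_vec * resid) ** 2, axis=0)),
        "mean_observed": obs.mean(axis=0),
    })
    logger.info("calibration (%s): payoff %.4g after %d evaluations",
                data.sex, float(best.fun), n_evals)
    return CalibrationResult(
        params=params,
        payoff_value=float(best.fun),
        n_evaluations=n_evals,
        converged=bool(best.success),
        residual_summary=summary,
        start_payoffs=start_payoffs,
    )


def params_from_frame(frame: pd.DataFrame, sex: str) -> ModelParameters:
    """Rebuild :class:`ModelParameters` from a serialized result table
    (the inverse of :meth:`CalibrationResult.to_frame`)."""
    from .constants import BANDS, DIALYSIS_BANDS, STOCKS, stock_name

    sub = frame[frame["sex"] == sex].set_index("parameter")["value"]
    return ModelParameters(
        sex=sex,
        dm_incidence=np.array([sub[f"DM{b}ir"] for b in BANDS]),
        dialysis_incidence=np.array([sub[f"DMDi{b}ir"]
                                     for b in DIALYSIS_BANDS]),
        initial_state=np.array([sub[f"init_{stock_name(*sb)}"]
                                for sb in STOCKS]),
    )


def calibrate_both_sexes(datasets: dict[str, ObservedDataset],
                         options: CalibrationOptions | None = None
                         ) -> dict[str, CalibrationResult]:
    """Independent per-sex calibrations (the model couples sexes nowhere)."""
    return {sex: calibrate(ds, options) for sex, ds in sorted(datasets.items())}
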