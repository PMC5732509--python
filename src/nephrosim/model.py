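"""Stock-and-flow core of the aging-chain diabetes/dialysis model.

The model tracks, separately per sex, sixteen population stocks: six
age bands for people without diabetes (NDM), six for people with
diabetes not on dialysis (DM), and four (age 40+) for people on
dialysis due to diabetic nephropathy (DMDi).  People enter the system
at age 20, age through the bands with a first-order outflow of
``stock / 10`` per year for each closed ten-year band, acquire
diabetes at band-specific incidence rates, initiate dialysis at
band-specific rates from age 40, and die at state/band/year-specific
mortality rates.  Dialysis initiations before age 40 are outside the
model; survivors of that group enter the DMDi4049 stock through an
exogenous inflow at age 40.

The state vector is flat (length 16) in the order given by
:data:`nephrosim.constants.STOCKS`; this realizes the compartment
state at one instant.  Integration is explicit Euler with a fixed
sub-annual step (default 1/16 year) and annual output sampling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Protocol, runtime_checkable

import numpy as np
import pandas as pd

from .constants import (
    BAND_WIDTH,
    BANDS,
    DEFAULT_DT,
    DEFAULT_ENTRY_DM_PREVALENCE,
    DIALYSIS_BANDS,
    DM_SLICE,
    DMDI_SLICE,
    N_BANDS,
    N_DIALYSIS_BANDS,
    N_STOCKS,
    NDM_SLICE,
    SEXES,
    STOCK_INDEX,
    STOCKS,
    stock_name,
)

logger = logging.getLogger(__name__)

AGGREGATE_COLUMNS = (
    "NDMover20",
    "DMover20",
    "DMDiover40",
    "TotalDM",
    "popover20",
    "dm_prevalence_pct",
)


# --------------------------------------------------------------------------
# exogenous series
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StepSeries:
    """Annual step function: constant within each calendar year.

    Values beyond the last tabulated year hold the final value (the
    post-2015 hold rule for exogenous inputs); times before the first
    year are a domain error.
    """

    start_year: int
    values: np.ndarray  # shape (n_years,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("StepSeries requires a non-empty 1-d value array")
        if np.any(self.values < 0):
            raise ValueError("StepSeries values must be non-negative")

    @property
    def end_year(self) -> int:
        return self.start_year + self.values.size - 1

    def value_at(self, t: float) -> float:
        idx = self._index(t)
        return float(self.values[idx])

    def values_at(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.minimum(np.floor(t + 1e-9).astype(int) - self.start_year,
                         self.values.size - 1)
        if np.any(idx < 0):
            raise ValueError(
                f"time before series start year {self.start_year}"
            )
        return self.values[idx]

    def _index(self, t: float) -> int:
        idx = int(math.floor(t + 1e-9)) - self.start_year
        if idx < 0:
            raise ValueError(
                f"time {t} precedes series start year {self.start_year}"
            )
        return min(idx, self.values.size - 1)

    def held_until(self, horizon: int) -> "StepSeries":
        """Materialize the hold-forward rule through ``horizon``."""
        if horizon <= self.end_year:
            return self
        extra = np.full(horizon - self.end_year, self.values[-1])
        return StepSeries(self.start_year, np.concatenate([self.values, extra]))


@dataclass(frozen=True)
class MortalityTable:
    """Per-stock annual mortality rates (1/year), step-constant in time.

    ``rates`` has shape (n_years, 16) aligned with the flat stock order.
    """

    start_year: int
    rates: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rates", np.asarray(self.rates, dtype=float))
        if self.rates.ndim != 2 or self.rates.shape[1] != N_STOCKS:
            raise ValueError(f"rates must have shape (n_years, {N_STOCKS})")
        if np.any(self.rates < 0):
            raise ValueError("mortality rates must be non-negative")

    @property
    def end_year(self) -> int:
        return self.start_year + self.rates.shape[0] - 1

    def value_at(self, t: float) -> np.ndarray:
        idx = int(math.floor(t + 1e-9)) - self.start_year
        if idx < 0:
            raise ValueError(
                f"time {t} precedes mortality table start year {self.start_year}"
            )
        return self.rates[min(idx, self.rates.shape[0] - 1)]

    def rows_for_years(self, years: np.ndarray) -> np.ndarray:
        idx = np.minimum(np.asarray(years, dtype=int) - self.start_year,
                         self.rates.shape[0] - 1)
        if np.any(idx < 0):
            raise ValueError("year precedes mortality table start")
        return self.rates[idx]


@dataclass(frozen=True)
class ExogenousInputs:
    """Externally supplied drivers of one sex's model.

    entry_at_20
        persons/year entering the 20–29 bands (Allto20-style series;
        supplied through the horizon for the entry cohort).
    dialysis_entry_at_40
        persons/year entering DMDi4049 at age 40 (survivors of under-40
        dialysis initiation, which is otherwise outside the model).
    mortality
        per-stock mortality rates.
    entry_dm_prevalence
        fraction of 20-year-old entrants who already have diabetes
        (default 0.2%).
    """

    sex: str
    entry_at_20: StepSeries
    dialysis_entry_at_40: StepSeries
    mortality: MortalityTable
    entry_dm_prevalence: float = DEFAULT_ENTRY_DM_PREVALENCE

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not 0.0 <= self.entry_dm_prevalence <= 1.0:
            raise ValueError("entry_dm_prevalence must lie in [0, 1]")


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelParameters:
    """Sex-specific constant transition rates plus the initial stocks.

    ``dm_incidence`` holds six NDM→DM hazards (per band, 1/year);
    ``dialysis_incidence`` holds four DM→DMDi hazards for bands 40+.
    ``initial_state`` is the flat 16-stock vector at ``start_year``.
    """

    sex: str
    dm_incidence: np.ndarray
    dialysis_incidence: np.ndarray
    initial_state: np.ndarray
    start_year: int = 2000

    def __post_init__(self) -> None:
        object.__setattr__(self, "dm_incidence",
                           np.asarray(self.dm_incidence, dtype=float))
        object.__setattr__(self, "dialysis_incidence",
                           np.asarray(self.dialysis_incidence, dtype=float))
        object.__setattr__(self, "initial_state",
                           np.asarray(self.initial_state, dtype=float))
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.dm_incidence.shape != (N_BANDS,):
            raise ValueError("dm_incidence must hold 6 band rates")
        if self.dialysis_incidence.shape != (N_DIALYSIS_BANDS,):
            raise ValueError("dialysis_incidence must hold 4 band rates")
        if self.initial_state.shape != (N_STOCKS,):
            raise ValueError(f"initial_state must hold {N_STOCKS} stocks")
        if np.any(self.dm_incidence < 0) or np.any(self.dialysis_incidence < 0):
            raise ValueError("incidence rates must be non-negative")
        if np.any(self.initial_state < 0):
            raise ValueError("initial stocks must be non-negative")

    def with_rates(self, dm_incidence=None, dialysis_incidence=None
                   ) -> "ModelParameters":
        return replace(
            self,
            dm_incidence=self.dm_incidence if dm_incidence is None
            else np.asarray(dm_incidence, dtype=float),
            dialysis_incidence=self.dialysis_incidence
            if dialysis_incidence is None
            else np.asarray(dialysis_incidence, dtype=float),
        )

    def rate_dict(self) -> dict[str, float]:
        """Rates keyed by the conventional symbols (DM2029ir, DMDi4049ir, …)."""
        out = {f"DM{b}ir": float(r) for b, r in zip(BANDS, self.dm_incidence)}
        out.update({f"DMDi{b}ir": float(r)
                    for b, r in zip(DIALYSIS_BANDS, self.dialysis_incidence)})
        return out


# --------------------------------------------------------------------------
# rate modifiers (intervention scenarios, exponential drift)
# --------------------------------------------------------------------------


@runtime_checkable
class RateModifier(Protocol):
    """Time-varying multipliers applied to the two rate families.

    ``scales_dialysis_entry`` says whether the dialysis multiplier also
    scales the exogenous age-40 dialysis entry (true for intervention
    scenarios, false for secular drift in initiation rates).
    """

    scales_dialysis_entry: bool

    def dm_multiplier(self, t: float) -> float: ...

    def dialysis_multiplier(self, t: float) -> float: ...


def _modifier_factors(modifier, t: float) -> tuple[float, float, float]:
    """(dm factor, dialysis-rate factor, dialysis-entry factor) at time t."""
    if modifier is None:
        return 1.0, 1.0, 1.0
    fd = float(modifier.dm_multiplier(t))
    fq = float(modifier.dialysis_multiplier(t))
    fe = fq if getattr(modifier, "scales_dialysis_entry", False) else 1.0
    return fd, fq, fe


def _combined_factors(scenario, drift, t: float) -> tuple[float, float, float]:
    sd, sq, se = _modifier_factors(scenario, t)
    dd, dq, de = _modifier_factors(drift, t)
    return sd * dd, sq * dq, se * de


# --------------------------------------------------------------------------
# flows
# --------------------------------------------------------------------------


@dataclass
class FlowVector:
    """All instantaneous flows (persons/year) at one time point."""

    entry_ndm: float           # NDMto20
    entry_dm: float            # DMto20
    dialysis_entry_40: float   # DMDito40 inflow into DMDi4049
    aging_out: np.ndarray      # (16,) flow leaving each stock to the next band
    incidence: np.ndarray      # (6,) NDM→DM per band
    initiation: np.ndarray     # (4,) DM→DMDi per band 40+
    deaths: np.ndarray         # (16,) per stock

    def net(self) -> np.ndarray:
        """Net change of each stock (inflows − outflows), persons/year.

        Recomputed from the individual flow components so it can serve
        as an independent balance check on the integrator.
        """
        d = np.zeros(N_STOCKS)
        d[STOCK_INDEX[("NDM", "2029")]] += self.entry_ndm
        d[STOCK_INDEX[("DM", "2029")]] += self.entry_dm
        d[STOCK_INDEX[("DMDi", "4049")]] += self.dialysis_entry_40
        for i, (state, band) in enumerate(STOCKS):
            out = self.aging_out[i]
            if out:
                d[i] -= out
                d[STOCK_INDEX[(state, _next_band(band))]] += out
        for b, band in enumerate(BANDS):
            f = self.incidence[b]
            d[STOCK_INDEX[("NDM", band)]] -= f
            d[STOCK_INDEX[("DM", band)]] += f
        for k, band in enumerate(DIALYSIS_BANDS):
            f = self.initiation[k]
            d[STOCK_INDEX[("DM", band)]] -= f
            d[STOCK_INDEX[("DMDi", band)]] += f
        d -= self.deaths
        return d

    def total_entries(self) -> float:
        return self.entry_ndm + self.entry_dm + self.dialysis_entry_40

    def total_deaths(self) -> float:
        return float(self.deaths.sum())


def _next_band(band: str) -> str:
    return BANDS[BANDS.index(band) + 1]


def derivatives(state: np.ndarray, t: float, params: ModelParameters,
                exog: ExogenousInputs, scenario=None, drift=None) -> FlowVector:
    """Evaluate every instantaneous flow of the system at time ``t``.

    ``scenario`` and ``drift`` are optional :class:`RateModifier`
    objects; their multipliers combine multiplicatively on the two rate
    families.  Raises if ``t`` precedes the exogenous domain or if any
    stock is negative.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (N_STOCKS,):
        raise ValueError(f"state must hold {N_STOCKS} stocks")
    if np.any(state < 0):
        bad = STOCKS[int(np.argmin(state))]
        raise ValueError(f"negative stock {stock_name(*bad)} in input state")

    f_dm, f_di, f_entry = _combined_factors(scenario, drift, t)

    entry = exog.entry_at_20.value_at(t)
    p0 = exog.entry_dm_prevalence
    entry_dm = entry * p0
    entry_ndm = entry * (1.0 - p0)
    entry40 = exog.dialysis_entry_at_40.value_at(t) * f_entry

    aging_out = np.zeros(N_STOCKS)
    for i, (_, band) in enumerate(STOCKS):
        if band != "over70":
            aging_out[i] = state[i] / BAND_WIDTH

    ndm = state[NDM_SLICE]
    dm = state[DM_SLICE]
    incidence = params.dm_incidence * f_dm * ndm
    initiation = params.dialysis_incidence * f_di * dm[2:]

    deaths = exog.mortality.value_at(t) * state

    return FlowVector(
        entry_ndm=float(entry_ndm),
        entry_dm=float(entry_dm),
        dialysis_entry_40=float(entry40),
        aging_out=aging_out,
        incidence=incidence,
        initiation=initiation,
        deaths=deaths,
    )


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Annual snapshots of the 16 stocks plus derived aggregates."""

    sex: str
    years: np.ndarray           # integer calendar years
    states: np.ndarray          # (n_years, 16)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.years.size, N_STOCKS):
            raise ValueError("states must have shape (n_years, 16)")

    def stock(self, state: str, band: str) -> np.ndarray:
        return self.states[:, STOCK_INDEX[(state, band)]]

    def band_population(self) -> np.ndarray:
        """Total population per band, shape (n_years, 6)."""
        pop = self.states[:, NDM_SLICE] + self.states[:, DM_SLICE]
        pop = pop.copy()
        pop[:, 2:] += self.states[:, DMDI_SLICE]
        return pop

    def aggregates(self) -> pd.DataFrame:
        return aggregate(self)

    def value_at(self, variable: str, year: int) -> float:
        """Aggregate or stock value at an integer year."""
        mask = self.years == int(year)
        if not mask.any():
            raise ValueError(f"year {year} not covered by trajectory")
        i = int(np.argmax(mask))
        if variable in AGGREGATE_COLUMNS:
            return float(self.aggregates().loc[int(year), variable])
        for (state, band), j in STOCK_INDEX.items():
            if stock_name(state, band) == variable:
                return float(self.states[i, j])
        raise KeyError(f"unknown variable {variable!r}")

    def to_frame(self) -> pd.DataFrame:
        """Tidy (year, sex, variable, value) table of stocks + aggregates."""
        rows = []
        agg = self.aggregates()
        for i, year in enumerate(self.years):
            for (state, band), j in STOCK_INDEX.items():
                rows.append((int(year), self.sex, stock_name(state, band),
                             self.states[i, j]))
            for col in AGGREGATE_COLUMNS:
                rows.append((int(year), self.sex, col, agg.loc[int(year), col]))
        return pd.DataFrame(rows, columns=["year", "sex", "variable", "value"])


def aggregate(traj: Trajectory) -> pd.DataFrame:
    """Annual aggregate series: NDMover20, DMover20, DMDiover40, TotalDM,
    popover20 and the adult diabetes prevalence in percent."""
    if traj.years.size == 0:
        return pd.DataFrame(columns=list(AGGREGATE_COLUMNS),
                            index=pd.Index([], name="year", dtype=int))
    ndm = traj.states[:, NDM_SLICE].sum(axis=1)
    dm = traj.states[:, DM_SLICE].sum(axis=1)
    dmdi = traj.states[:, DMDI_SLICE].sum(axis=1)
    total_dm = dm + dmdi
    pop = ndm + total_dm
    with np.errstate(divide="ignore", invalid="ignore"):
        prev = np.where(pop > 0, total_dm / pop * 100.0, 0.0)
    return pd.DataFrame(
        {
            "NDMover20": ndm,
            "DMover20": dm,
            "DMDiover40": dmdi,
            "TotalDM": total_dm,
            "popover20": pop,
            "dm_prevalence_pct": prev,
        },
        index=pd.Index(traj.years, name="year"),
    )


# --------------------------------------------------------------------------
# integration
# --------------------------------------------------------------------------


@dataclass
class SimulationAudit:
    """Cumulative balance bookkeeping re-summed from the flow vectors."""

    cumulative_entries: float = 0.0
    cumulative_deaths: float = 0.0
    clipped_steps: int = 0


def _check_dt(dt: float) -> int:
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > 1.0:
        raise ValueError("dt larger than 1 year is rejected")
    k = round(1.0 / dt)
    if abs(k * dt - 1.0) > 1e-9:
        raise ValueError("1/dt must be an integer so output falls on years")
    return k


def simulate(params: ModelParameters, exog: ExogenousInputs, scenario=None,
             t0: float = 2000.0, t1: float = 2035.0, dt: float = DEFAULT_DT,
             drift=None, audit: SimulationAudit | None = None) -> Trajectory:
    """Integrate the stock-and-flow system with explicit Euler steps.

    Output is sampled at integer calendar years in [t0, t1].  Stocks
    that undershoot zero are clipped to zero with a logged warning.
    Passing a :class:`SimulationAudit` accumulates total entries and
    deaths re-summed from each step's :class:`FlowVector`.
    """
    if params.sex != exog.sex:
        raise ValueError("params and exog must describe the same sex")
    if not t0 < t1:
        raise ValueError("t0 must precede t1")
    if float(t0) != int(t0) or float(t1) != int(t1):
        raise ValueError("t0 and t1 must be integer calendar years")
    k = _check_dt(dt)

    n_years = int(t1) - int(t0)
    x = params.initial_state.astype(float).copy()
    out_years = np.arange(int(t0), int(t1) + 1)
    out = np.empty((n_years + 1, N_STOCKS))
    out[0] = x

    for y in range(n_years):
        year = t0 + y
        for j in range(k):
            t = year + j * dt
            flows = derivatives(x, t, params, exog, scenario, drift)
            dx = flows.net()
            if not np.all(np.isfinite(dx)):
                bad = STOCKS[int(np.argmax(~np.isfinite(dx)))]
                raise RuntimeError(
                    f"non-finite flow for stock {stock_name(*bad)} at t={t}"
                )
            if audit is not None:
                audit.cumulative_entries += dt * flows.total_entries()
                audit.cumulative_deaths += dt * flows.total_deaths()
            x = x + dt * dx
            neg = x < 0
            if neg.any():
                worst = STOCKS[int(np.argmin(x))]
                logger.warning(
                    "clipping negative stock %s (%.3g) at t=%.4f",
                    stock_name(*worst), float(x.min()), t + dt,
                )
                x = np.where(neg, 0.0, x)
                if audit is not None:
                    audit.clipped_steps += 1
        out[y + 1] = x

    return Trajectory(sex=params.sex, years=out_years, states=out)


# --------------------------------------------------------------------------
# fast linear propagation (used by calibration)
# --------------------------------------------------------------------------

_AGING_PAIRS = [
    (STOCK_INDEX[(s, _next_band(b))], STOCK_INDEX[(s, b)])
    for (s, b) in STOCKS if b != "over70"
]
_INCIDENCE_PAIRS = [
    (STOCK_INDEX[("NDM", b)], STOCK_INDEX[("DM", b)]) for b in BANDS
]
_INITIATION_PAIRS = [
    (STOCK_INDEX[("DM", b)], STOCK_INDEX[("DMDi", b)]) for b in DIALYSIS_BANDS
]


def _base_system(exog: ExogenousInputs, years: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Rate-independent part of (A, b) per simulated year.

    A holds aging and mortality; b holds the exogenous entry inflows.
    Shapes (Y, 16, 16) and (Y, 16) for Y = len(years) simulated years.
    """
    years = np.asarray(years, dtype=int)
    Y = years.size
    A = np.zeros((Y, N_STOCKS, N_STOCKS))
    mort = exog.mortality.rows_for_years(years)
    diag = np.arange(N_STOCKS)
    A[:, diag, diag] -= mort
    for to_i, from_i in _AGING_PAIRS:
        A[:, from_i, from_i] -= 1.0 / BAND_WIDTH
        A[:, to_i, from_i] += 1.0 / BAND_WIDTH
    b = np.zeros((Y, N_STOCKS))
    entry = exog.entry_at_20.values_at(years.astype(float))
    p0 = exog.entry_dm_prevalence
    b[:, STOCK_INDEX[("NDM", "2029")]] = entry * (1.0 - p0)
    b[:, STOCK_INDEX[("DM", "2029")]] = entry * p0
    b[:, STOCK_INDEX[("DMDi", "4049")]] = \
        exog.dialysis_entry_at_40.values_at(years.astype(float))
    return A, b


def _add_rates(A: np.ndarray, params: ModelParameters,
               dm_factor, di_factor) -> None:
    """Scatter the (possibly scaled) transition rates into A in place.

    ``dm_factor``/``di_factor`` broadcast against the year axis.
    """
    for b_i, (ndm_i, dm_i) in enumerate(_INCIDENCE_PAIRS):
        r = params.dm_incidence[b_i] * dm_factor
        A[:, ndm_i, ndm_i] -= r
        A[:, dm_i, ndm_i] += r
    for k_i, (dm_i, dmdi_i) in enumerate(_INITIATION_PAIRS):
        q = params.dialysis_incidence[k_i] * di_factor
        A[:, dm_i, dm_i] -= q
        A[:, dmdi_i, dm_i] += q


class LinearPropagator:
    """Pre-assembled Euler propagation for rate-constant-within-year runs.

    Caches the rate-independent system matrices for a fixed exogenous
    context so repeated calibration payoff evaluations only scatter the
    candidate rates and chain small matrix products.  The result is
    algebraically identical to :func:`simulate` (same Euler scheme)
    as long as no stock goes negative — guaranteed for bounded rates.
    """

    def __init__(self, exog: ExogenousInputs, start_year: int, end_year: int,
                 dt: float = DEFAULT_DT):
        self.k = _check_dt(dt)
        self.dt = dt
        self.years = np.arange(start_year, end_year)  # simulated years
        self.out_years = np.arange(start_year, end_year + 1)
        self.exog = exog
        self._A_base, self._b = _base_system(exog, self.years)
        self._eye = np.eye(N_STOCKS)

    def annual_states(self, params: ModelParameters, scenario=None,
                      drift=None) -> np.ndarray:
        """States at each integer year, shape (n_years+1, 16)."""
        if scenario is None and drift is None:
            P, Q = self._constant_year_operators(params)
            c = self.dt * self._b[:, :, None]
            q = (Q @ c)[:, :, 0]
        else:
            P, q = self._substep_year_operators(params, scenario, drift)
        x = params.initial_state.astype(float)
        out = np.empty((self.years.size + 1, N_STOCKS))
        out[0] = x
        for y in range(self.years.size):
            x = P[y] @ x + q[y]
            out[y + 1] = x
        return out

    def _constant_year_operators(self, params):
        A = self._A_base.copy()
        _add_rates(A, params, 1.0, 1.0)
        P1 = self._eye + self.dt * A
        # square-and-multiply: P = P1^k, Q = sum_{j<k} P1^j
        P = None
        Q = None
        base_P = P1
        base_Q = np.broadcast_to(self._eye, P1.shape).copy()
        k = self.k
        while k:
            if k & 1:
                if P is None:
                    P, Q = base_P, base_Q
                else:
                    # append base-exponent steps after the accumulated ones:
                    # Q_{a+b} = P^b Q_a + Q_b, P_{a+b} = P^b P^a
                    Q = np.matmul(base_P, Q) + base_Q
                    P = np.matmul(base_P, P)
            k >>= 1
            if k:
                base_Q = base_Q + np.matmul(base_P, base_Q)
                base_P = np.matmul(base_P, base_P)
        return P, Q

    def _substep_year_operators(self, params, scenario, drift):
        """Per-substep products for time-varying rate multipliers."""
        Y = self.years.size
        P = np.broadcast_to(self._eye, (Y, N_STOCKS, N_STOCKS)).copy()
        q = np.zeros((Y, N_STOCKS))
        year_f = self.years.astype(float)
        for j in range(self.k):
            t = year_f + j * self.dt
            fd = np.array([_combined_factors(scenario, drift, ti)[0]
                           for ti in t])
            fq = np.array([_combined_factors(scenario, drift, ti)[1]
                           for ti in t])
            fe = np.array([_combined_factors(scenario, drift, ti)[2]
                           for ti in t])
            A = self._A_base.copy()
            _add_rates(A, params, fd, fq)
            P1 = self._eye + self.dt * A
            b = self._b.copy()
            b[:, STOCK_INDEX[("DMDi", "4049")]] = \
                self._b[:, STOCK_INDEX[("DMDi", "4049")]] * fe
            # exogenous entry at 20 is never scaled by modifiers
            P = np.matmul(P1, P)
            q = np.matmul(P1, q[:, :, None])[:, :, 0] + self.dt * b
        return P, q
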