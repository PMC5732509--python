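"""Synthetic observation cross-tables for testing and desk-scale runs.

Two generators are provided:

* :func:`generate_synthetic_country` forward-simulates a known ground
  truth (rates, initial stocks, exogenous series) over the calibration
  window and emits the resulting cross-table, optionally perturbed by
  independent multiplicative log-normal observation noise.  Because
  the truth is known by construction, calibration can be tested for
  parameter recovery.

* :func:`build_japan_like_fixture` builds a deterministic dataset
  whose sex-specific diabetes and dialysis totals hit the published
  2000/2015 endpoint values exactly, with smooth monotone interpolation
  in between, fixed documented age-allocation shares, and mortality
  schedules derived through the standard decomposition (DM:non-DM
  hazard ratio 2, dialysis mortality removed from the diabetic rate).
  The true sex/age composition of the underlying national tables is
  unpublished, so the band allocation is a plausible construct:
  projections from this fixture approximate, rather than reproduce,
  absolute published projections, while ratio-type results are driven
  by model structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (
    BANDS,
    CALIBRATION_END,
    CALIBRATION_START,
    DEFAULT_ENTRY_DM_PREVALENCE,
    DEFAULT_HORIZON,
    DIALYSIS_BANDS,
    N_STOCKS,
    SEXES,
    STOCK_INDEX,
)
from .data_prep import decompose_mortality, nondialysis_dm_mortality
from .dataset import ObservedDataset
from .model import (
    ExogenousInputs,
    ModelParameters,
    MortalityTable,
    StepSeries,
    Trajectory,
    simulate,
)

# --------------------------------------------------------------------------
# published endpoint anchors (persons)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureAnchors:
    """Published 2000/2015 endpoint totals the fixture reproduces exactly."""

    total_dm_2000: dict[str, float]
    total_dm_2015: dict[str, float]
    dialysis_2000: dict[str, float]
    dialysis_2015: dict[str, float]          # ages 40+, inside the model
    dialysis_under40_2015: dict[str, float]  # outside the model
    dialysis_all_ages_2015: dict[str, float]


JAPAN_ANCHORS = FixtureAnchors(
    total_dm_2000={"male": 4.19e6, "female": 2.90e6},      # sums to 7.09e6
    total_dm_2015={"male": 5.32e6, "female": 3.39e6},      # sums to 8.71e6
    dialysis_2000={"male": 34_672.0, "female": 17_219.0},  # sums to 51,891
    dialysis_2015={"male": 83_858.0, "female": 35_048.0},  # sums to 118,906
    dialysis_under40_2015={"male": 947.0, "female": 421.0},
    dialysis_all_ages_2015={"male": 84_806.0, "female": 35_470.0},
)

# --------------------------------------------------------------------------
# Japan-like allocation constants (documented constructs, not published data)
# --------------------------------------------------------------------------

#: adult population by band (persons), chosen to resemble the Japanese
#: age pyramid: a shrinking young-adult base and strong growth at 70+.
_POP_2000 = {
    "male": np.array([9.0e6, 8.5e6, 8.0e6, 9.5e6, 7.5e6, 5.5e6]),
    "female": np.array([8.6e6, 8.3e6, 8.0e6, 9.8e6, 8.0e6, 8.0e6]),
}
_POP_2015 = {
    "male": np.array([6.5e6, 8.0e6, 9.3e6, 7.8e6, 8.9e6, 8.5e6]),
    "female": np.array([6.2e6, 7.7e6, 9.1e6, 7.9e6, 9.3e6, 12.0e6]),
}

#: share of each sex's total diabetic population (incl. dialysis) per band
_DM_SHARES = {
    "male": np.array([0.02, 0.05, 0.12, 0.22, 0.30, 0.29]),
    "female": np.array([0.01, 0.03, 0.08, 0.17, 0.30, 0.41]),
}

#: share of each sex's 40+ dialysis population per band (older-skewed)
_DIALYSIS_SHARES = {
    "male": np.array([0.08, 0.22, 0.37, 0.33]),
    "female": np.array([0.06, 0.18, 0.36, 0.40]),
}

#: all-cause mortality per band (1/yr), endpoints of a linear trend
_MORT_ALL_2000 = {
    "male": np.array([0.0008, 0.0011, 0.0025, 0.006, 0.015, 0.065]),
    "female": np.array([0.0004, 0.0006, 0.0013, 0.003, 0.007, 0.050]),
}
_MORT_ALL_2015 = {
    "male": np.array([0.0006, 0.0009, 0.0021, 0.005, 0.012, 0.055]),
    "female": np.array([0.0003, 0.0005, 0.0011, 0.0025, 0.0055, 0.045]),
}

#: dialysis-patient mortality per 40+ band (1/yr), far above DM mortality
_MORT_DIALYSIS_2000 = {
    "male": np.array([0.045, 0.060, 0.095, 0.160]),
    "female": np.array([0.040, 0.055, 0.085, 0.150]),
}
_MORT_DIALYSIS_2015 = {
    "male": np.array([0.035, 0.050, 0.080, 0.140]),
    "female": np.array([0.030, 0.045, 0.075, 0.130]),
}

#: entry cohort at age 20 (persons/yr) in 2000, declining 0.8%/yr
_ENTRY20_2000 = {"male": 640_000.0, "female": 610_000.0}
_ENTRY20_DECLINE = 0.008

#: dialysis entry at age 40 (persons/yr), 2000 → 2015 endpoints
_ENTRY40 = {"male": (70.0, 165.0), "female": (30.0, 70.0)}


def _taper_interp(v0: float | np.ndarray, v1: float | np.ndarray,
                  years: np.ndarray, y0: int = CALIBRATION_START,
                  y1: int = CALIBRATION_END) -> np.ndarray:
    """Monotone cubic Hermite between two endpoint values.

    End slopes are 1.5× and 0.5× the mean slope, so growth decelerates
    toward the second anchor (the published series flatten late).
    Both slope factors lie inside the monotonicity region [0, 3].
    """
    v0 = np.asarray(v0, dtype=float)
    v1 = np.asarray(v1, dtype=float)
    h = float(y1 - y0)
    s = (np.asarray(years, dtype=float) - y0) / h
    if v0.ndim > 0:
        s = s[:, None]
    m0 = 1.5 * (v1 - v0) / h
    m1 = 0.5 * (v1 - v0) / h
    h00 = 2 * s**3 - 3 * s**2 + 1
    h10 = s**3 - 2 * s**2 + s
    h01 = -2 * s**3 + 3 * s**2
    h11 = s**3 - s**2
    return h00 * v0 + h10 * h * m0 + h01 * v1 + h11 * h * m1


def _fixture_mortality_table(sex: str, years: np.ndarray, pop: np.ndarray,
                             dm_total: np.ndarray, dmdi: np.ndarray,
                             horizon: int) -> MortalityTable:
    """State-specific mortality built by the standard decomposition,
    held at the 2015 values through ``horizon``."""
    n = years.size
    frac = (years - years[0]) / (years[-1] - years[0])
    m_all = ((1 - frac)[:, None] * _MORT_ALL_2000[sex]
             + frac[:, None] * _MORT_ALL_2015[sex])
    m_di = ((1 - frac)[:, None] * _MORT_DIALYSIS_2000[sex]
            + frac[:, None] * _MORT_DIALYSIS_2015[sex])
    rates = np.zeros((n, N_STOCKS))
    for i in range(n):
        prev = dm_total[i] / pop[i]
        for b, band in enumerate(BANDS):
            m_ndm, m_dm = decompose_mortality(m_all[i, b], prev[b])
            if band in DIALYSIS_BANDS:
                k = DIALYSIS_BANDS.index(band)
                m_dm = nondialysis_dm_mortality(
                    m_dm, dm_total[i, b], m_di[i, k], dmdi[i, k])
                rates[i, STOCK_INDEX[("DMDi", band)]] = m_di[i, k]
            rates[i, STOCK_INDEX[("NDM", band)]] = m_ndm
            rates[i, STOCK_INDEX[("DM", band)]] = m_dm
    table = MortalityTable(int(years[0]), rates)
    if horizon > table.end_year:
        extra = np.repeat(rates[-1:], horizon - table.end_year, axis=0)
        table = MortalityTable(int(years[0]),
                               np.vstack([rates, extra]))
    return table


def _fixture_exog(sex: str, years: np.ndarray, pop: np.ndarray,
                  dm_total: np.ndarray, dmdi: np.ndarray,
                  horizon: int) -> ExogenousInputs:
    entry_years = np.arange(CALIBRATION_START, horizon + 1)
    entry = _ENTRY20_2000[sex] * np.exp(
        -_ENTRY20_DECLINE * (entry_years - CALIBRATION_START))
    e40_0, e40_1 = _ENTRY40[sex]
    e40 = _taper_interp(e40_0, e40_1, years)
    return ExogenousInputs(
        sex=sex,
        entry_at_20=StepSeries(CALIBRATION_START, entry),
        dialysis_entry_at_40=StepSeries(int(years[0]), e40),
        mortality=_fixture_mortality_table(sex, years, pop, dm_total, dmdi,
                                           horizon),
        entry_dm_prevalence=DEFAULT_ENTRY_DM_PREVALENCE,
    )


def build_japan_like_fixture(horizon: int = DEFAULT_HORIZON
                             ) -> dict[str, ObservedDataset]:
    """Deterministic two-sex cross-table anchored to published endpoints.

    The 2000 and 2015 sex totals for diabetes (including dialysis) and
    for 40+ dialysis equal the published values exactly; intermediate
    years follow a decelerating monotone cubic; band allocation uses
    the documented fixed shares.
    """
    years = np.arange(CALIBRATION_START, CALIBRATION_END + 1)
    out: dict[str, ObservedDataset] = {}
    for sex in SEXES:
        pop = _taper_interp(_POP_2000[sex], _POP_2015[sex], years)
        dm_total_sex = _taper_interp(JAPAN_ANCHORS.total_dm_2000[sex],
                                     JAPAN_ANCHORS.total_dm_2015[sex], years)
        dmdi_total_sex = _taper_interp(JAPAN_ANCHORS.dialysis_2000[sex],
                                       JAPAN_ANCHORS.dialysis_2015[sex],
                                       years)
        dm_total = dm_total_sex[:, None] * _DM_SHARES[sex]
        dmdi = dmdi_total_sex[:, None] * _DIALYSIS_SHARES[sex]
        dm = dm_total.copy()
        dm[:, 2:] -= dmdi  # observed dm excludes dialysis patients
        exog = _fixture_exog(sex, years, pop, dm_total, dmdi, horizon)
        out[sex] = ObservedDataset(sex=sex, years=years, pop=pop, dm=dm,
                                   dmdi=dmdi, exog=exog).validate()
    return out


# --------------------------------------------------------------------------
# ground-truth generator
# --------------------------------------------------------------------------

#: default true rates, age-increasing with Japan-like magnitudes; the
#: female 30–39 diabetes and 40–49 dialysis-initiation hazards are zero,
#: matching the published calibration, and the published female 40–49
#: diabetes and 50–59 dialysis-initiation values are used verbatim.
_TRUE_DM_INCIDENCE = {
    "male": np.array([0.0005, 0.0012, 0.004, 0.008, 0.012, 0.010]),
    "female": np.array([0.0004, 0.0, 0.00138225, 0.004, 0.007, 0.006]),
}
_TRUE_DIALYSIS_INCIDENCE = {
    "male": np.array([0.0012, 0.0020, 0.0028, 0.0022]),
    "female": np.array([0.0, 0.00136167, 0.0020, 0.0016]),
}


@dataclass(frozen=True)
class TruthParams:
    """Ground truth for one sex's synthetic country.

    ``cv`` is the coefficient of variation of independent multiplicative
    log-normal observation noise (0 ⇒ observations equal model output).
    """

    params: ModelParameters
    exog: ExogenousInputs
    cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if self.params.sex != self.exog.sex:
            raise ValueError("params and exog must describe the same sex")


def default_truth(sex: str, cv: float = 0.0, seed: int = 0,
                  dm_incidence: np.ndarray | None = None,
                  dialysis_incidence: np.ndarray | None = None
                  ) -> TruthParams:
    """Japan-like ground truth: fixture demography and mortality with
    known constant transition rates."""
    fixture = build_japan_like_fixture()[sex]
    params = ModelParameters(
        sex=sex,
        dm_incidence=(_TRUE_DM_INCIDENCE[sex] if dm_incidence is None
                      else dm_incidence),
        dialysis_incidence=(_TRUE_DIALYSIS_INCIDENCE[sex]
                            if dialysis_incidence is None
                            else dialysis_incidence),
        initial_state=fixture.initial_stocks(),
        start_year=CALIBRATION_START,
    )
    return TruthParams(params=params, exog=fixture.exog, cv=cv, seed=seed)


def generate_synthetic_country(truth: TruthParams) -> ObservedDataset:
    """Forward-simulate the truth over the calibration window and emit
    the (optionally noisy) observation cross-table."""
    from .calibration import DM_RATE_BOUND, DIALYSIS_RATE_BOUND

    if np.any(truth.params.dm_incidence > DM_RATE_BOUND) or np.any(
            truth.params.dialysis_incidence > DIALYSIS_RATE_BOUND):
        raise ValueError("truth rates violate the calibration rate bounds")
    traj = simulate(truth.params, truth.exog, scenario=None,
                    t0=CALIBRATION_START, t1=CALIBRATION_END)
    pop = traj.band_population()
    dm = traj.states[:, 6:12]
    dmdi = traj.states[:, 12:16]
    if truth.cv > 0:
        rng = np.random.default_rng(truth.seed)
        sigma = np.sqrt(np.log1p(truth.cv**2))
        def noisy(a: np.ndarray) -> np.ndarray:
            z = rng.standard_normal(a.shape)
            return a * np.exp(sigma * z - 0.5 * sigma**2)
        pop, dm, dmdi = noisy(pop), noisy(dm), noisy(dmdi)
        # keep the structural inequality dm + dialysis <= pop intact
        pop = np.maximum(pop, np.concatenate(
            [dm[:, :2], dm[:, 2:] + dmdi], axis=1))
    return ObservedDataset(sex=truth.params.sex, years=traj.years,
                           pop=pop, dm=dm, dmdi=dmdi,
                           exog=truth.exog).validate()
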