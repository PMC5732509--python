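"""Derivation rules that turn raw national statistics into model inputs.

These are the processing steps applied to the published sources
(population estimates, vital statistics, the dialysis registry and a
prevalence meta-regression) before calibration:

* diabetes prevalence anchors at 2000/2005/2010 are interpolated and
  extrapolated linearly across the calibration window and converted to
  counts;
* sex/age-specific dialysis counts before 2011 are back-cast from
  all-cause dialysis counts, the mean 2011–15 diabetic-nephropathy
  share, and the known yearly total;
* all-cause mortality is split into non-diabetic and diabetic rates
  assuming a 1:2 hazard ratio, and the diabetic rate is further
  corrected to exclude patients on dialysis;
* the age-40 dialysis inflow is the mean of the 35–39 and 40–44 counts
  divided by the five-year band width;
* dialysis mortality observed 2012–15 is extrapolated backward on an
  ordinary least-squares line;
* every exogenous series is held at its last observed value beyond the
  observation window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import StepSeries

logger = logging.getLogger(__name__)

ANCHOR_YEARS = (2000, 2005, 2010)


@dataclass(frozen=True)
class PrevalenceAnchors:
    """Diabetes prevalence (%) at the three anchor years for one sex/band."""

    sex: str
    band: str
    pct_at: dict[int, float]

    def __post_init__(self) -> None:
        missing = [y for y in ANCHOR_YEARS if y not in self.pct_at]
        if missing:
            raise ValueError(
                f"missing prevalence anchor(s) {missing} for "
                f"{self.sex}/{self.band}"
            )
        for y, p in self.pct_at.items():
            if not 0.0 <= p <= 100.0:
                raise ValueError(
                    f"prevalence {p}% outside [0, 100] at {y} for "
                    f"{self.sex}/{self.band}"
                )


def interpolate_prevalence(anchors: PrevalenceAnchors,
                           years: np.ndarray | range) -> np.ndarray:
    """Prevalence (%) per year: linear between anchors, extrapolated
    beyond 2010 on the 2005–2010 slope, clipped to [0, 100]."""
    years = np.asarray(list(years), dtype=float)
    y0, y1, y2 = (anchors.pct_at[y] for y in ANCHOR_YEARS)
    out = np.empty_like(years)
    early = years <= 2005
    mid = (years > 2005) & (years <= 2010)
    late = years > 2010
    out[early] = y0 + (y1 - y0) / 5.0 * (years[early] - 2000)
    out[mid] = y1 + (y2 - y1) / 5.0 * (years[mid] - 2005)
    out[late] = y2 + (y2 - y1) / 5.0 * (years[late] - 2010)
    clipped = np.clip(out, 0.0, 100.0)
    if np.any(clipped != out):
        logger.warning("prevalence extrapolation clipped to [0, 100] for %s/%s",
                       anchors.sex, anchors.band)
    return clipped


def counts_from_prevalence(pct: np.ndarray, population: np.ndarray
                           ) -> np.ndarray:
    """Counts = prevalence (%) / 100 × population, with aligned years."""
    pct = np.asarray(pct, dtype=float)
    population = np.asarray(population, dtype=float)
    if pct.shape != population.shape:
        raise ValueError("prevalence and population series must align")
    return pct / 100.0 * population


def backcast_dialysis_counts(allcause: np.ndarray, mean_dn_share: np.ndarray,
                             total_dn: float) -> np.ndarray:
    """Back-cast band-specific diabetic-nephropathy dialysis counts.

    ``raw = allcause × share`` is rescaled so the bands sum exactly to
    the known yearly total ``total_dn``.
    """
    allcause = np.asarray(allcause, dtype=float)
    share = np.asarray(mean_dn_share, dtype=float)
    if np.any(share < 0) or np.any(share > 1):
        raise ValueError("shares must lie in [0, 1]")
    if total_dn < 0:
        raise ValueError("total_dn must be non-negative")
    raw = allcause * share
    s = raw.sum()
    if total_dn == 0:
        return np.zeros_like(raw)
    if s == 0:
        raise ValueError("all raw counts are zero but total_dn > 0")
    return raw * (total_dn / s)


def decompose_mortality(m_all: float, dm_prev: float,
                        hazard_ratio: float = 2.0) -> tuple[float, float]:
    """Split all-cause mortality into (non-DM, DM) rates.

    Solves ``m_ndm (1 − p) + hr · m_ndm · p = m_all`` so the mixture
    reproduces the observed rate exactly; ``m_dm = hr · m_ndm``.
    """
    if m_all < 0:
        raise ValueError("mortality rate must be non-negative")
    if not 0.0 <= dm_prev < 1.0:
        raise ValueError("dm_prev must lie in [0, 1)")
    if hazard_ratio < 1.0:
        raise ValueError("hazard_ratio must be at least 1")
    m_ndm = m_all / (1.0 + (hazard_ratio - 1.0) * dm_prev)
    return m_ndm, hazard_ratio * m_ndm


def nondialysis_dm_mortality(m_dm: float, n_dm_total: float, m_di: float,
                             n_di: float) -> float:
    """Mortality among diabetics not on dialysis, by death bookkeeping.

    Removes the dialysis group's deaths from the all-diabetes death
    count; a negative remainder is floored at 0 with a warning.
    """
    if n_dm_total <= n_di:
        raise ValueError("n_dm_total must exceed n_di")
    if n_di < 0:
        raise ValueError("n_di must be non-negative")
    value = (m_dm * n_dm_total - m_di * n_di) / (n_dm_total - n_di)
    if value < 0:
        logger.warning(
            "non-dialysis DM mortality %.4g floored at 0 "
            "(dialysis deaths exceed all-DM deaths)", value)
        return 0.0
    return value


def inflow_at_40(n_35_39: float, n_40_44: float) -> float:
    """Annual age-40 dialysis entry: mean of the two five-year bands
    straddling 40, divided by the five-year width."""
    if n_35_39 < 0 or n_40_44 < 0:
        raise ValueError("counts must be non-negative")
    return (n_35_39 + n_40_44) / 2.0 / 5.0


def extrapolate_dialysis_mortality(rates: np.ndarray,
                                   observed_years=(2012, 2013, 2014, 2015),
                                   target_years=range(2000, 2012)
                                   ) -> np.ndarray:
    """Back-cast dialysis mortality on an OLS line through the observed
    points, clipped to [0, 1]."""
    rates = np.asarray(rates, dtype=float)
    obs_years = np.asarray(list(observed_years), dtype=float)
    if rates.shape != obs_years.shape:
        raise ValueError("one rate per observed year is required")
    if not np.all(np.isfinite(rates)):
        raise ValueError("non-finite observed rates")
    slope, intercept = np.polyfit(obs_years, rates, 1)
    targets = np.asarray(list(target_years), dtype=float)
    line = intercept + slope * targets
    clipped = np.clip(line, 0.0, 1.0)
    if np.any(clipped != line):
        logger.warning("back-cast dialysis mortality clipped to [0, 1]")
    return clipped


def extend_exogenous(series: StepSeries, horizon: int) -> StepSeries:
    """Hold a series at its final value through ``horizon`` (the
    post-2015 rule for exogenous inputs)."""
    return series.held_until(horizon)
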