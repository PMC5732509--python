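"""Observation cross-table container and its tidy-CSV dialect.

An :class:`ObservedDataset` holds, for one sex, the annual calibration
targets (band-specific population, diabetes-not-on-dialysis counts and
diabetic-nephropathy dialysis counts) together with the exogenous
series that drive the simulation.

The on-disk dialect is a single tidy CSV with columns
``year, sex, age_band, variable, value``.  Variables:

==================  ==========================================  =========
variable            meaning                                     age_band
==================  ==========================================  =========
pop                 population, persons                         all bands
dm                  diabetes not on dialysis, persons           all bands
dialysis_dn         dialysis due to diabetic nephropathy        40+ bands
mort_ndm            mortality without diabetes, 1/yr            all bands
mort_dm             mortality with diabetes (no dialysis)       all bands
mort_dmdi           mortality on dialysis, 1/yr                 40+ bands
entry20             entry cohort at age 20, persons/yr          (blank)
dialysis_entry40    dialysis entry at age 40, persons/yr        (blank)
==================  ==========================================  =========
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import (
    BANDS,
    DIALYSIS_BANDS,
    N_BANDS,
    N_DIALYSIS_BANDS,
    N_STOCKS,
    SEXES,
    STOCK_INDEX,
)
from .model import ExogenousInputs, MortalityTable, StepSeries

logger = logging.getLogger(__name__)

BAND_VARIABLES = ("pop", "dm", "dialysis_dn", "mort_ndm", "mort_dm",
                  "mort_dmdi")
SERIES_VARIABLES = ("entry20", "dialysis_entry40")
_DIALYSIS_ONLY = {"dialysis_dn", "mort_dmdi"}


class ValidationError(ValueError):
    """Raised with the full list of dataset violations."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__(
            "dataset validation failed:\n  " + "\n  ".join(violations))


@dataclass
class ObservedDataset:
    """One sex's observation cross-table plus exogenous inputs."""

    sex: str
    years: np.ndarray                  # calibration years, ascending
    pop: np.ndarray                    # (n_years, 6)
    dm: np.ndarray                     # (n_years, 6)  not on dialysis
    dmdi: np.ndarray                   # (n_years, 4)  bands 40+
    exog: ExogenousInputs

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.pop = np.asarray(self.pop, dtype=float)
        self.dm = np.asarray(self.dm, dtype=float)
        self.dmdi = np.asarray(self.dmdi, dtype=float)

    # -- validation --------------------------------------------------------

    def violations(self) -> list[str]:
        v: list[str] = []
        n = self.years.size
        if self.sex not in SEXES:
            v.append(f"unknown sex {self.sex!r}")
        if np.any(np.diff(self.years) != 1):
            v.append("years must be consecutive")
        for name, arr, width in (("pop", self.pop, N_BANDS),
                                 ("dm", self.dm, N_BANDS),
                                 ("dmdi", self.dmdi, N_DIALYSIS_BANDS)):
            if arr.shape != (n, width):
                v.append(f"{name} must have shape ({n}, {width}), "
                         f"got {arr.shape}")
                return v
            bad = np.argwhere(arr < 0)
            for i, j in bad:
                v.append(f"negative {name} count in {self.years[i]}"
                         f" band index {j}")
        dm_plus = self.dm.copy()
        dm_plus[:, 2:] += self.dmdi
        over = np.argwhere(dm_plus > self.pop)
        for i, j in over:
            v.append(f"dm + dialysis exceeds pop in {self.years[i]} "
                     f"band {BANDS[j]}")
        return v

    def validate(self) -> "ObservedDataset":
        v = self.violations()
        if v:
            raise ValidationError(v)
        return self

    # -- derived quantities ------------------------------------------------

    def year_row(self, year: int) -> int:
        idx = np.where(self.years == year)[0]
        if idx.size == 0:
            raise ValueError(f"year {year} not in dataset")
        return int(idx[0])

    def initial_stocks(self, year: int | None = None) -> np.ndarray:
        """Flat 16-stock vector implied by the observations at ``year``
        (default: first year): NDM = pop − dm − dmdi."""
        i = self.year_row(int(year) if year is not None else self.years[0])
        ndm = self.pop[i] - self.dm[i]
        ndm[2:] -= self.dmdi[i]
        x = np.empty(N_STOCKS)
        for b, band in enumerate(BANDS):
            x[STOCK_INDEX[("NDM", band)]] = ndm[b]
            x[STOCK_INDEX[("DM", band)]] = self.dm[i, b]
        for k, band in enumerate(DIALYSIS_BANDS):
            x[STOCK_INDEX[("DMDi", band)]] = self.dmdi[i, k]
        return x

    def observation_matrix(self) -> np.ndarray:
        """(n_years, 16) matrix of fitted variables: pop×6, dm×6, dmdi×4."""
        return np.hstack([self.pop, self.dm, self.dmdi])

    @staticmethod
    def observation_names() -> list[str]:
        return ([f"pop{b}" for b in BANDS]
                + [f"DM{b}" for b in BANDS]
                + [f"DMDi{b}" for b in DIALYSIS_BANDS])

    # -- CSV round trip ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, year in enumerate(self.years):
            for b, band in enumerate(BANDS):
                rows.append((int(year), self.sex, band, "pop", self.pop[i, b]))
                rows.append((int(year), self.sex, band, "dm", self.dm[i, b]))
            for k, band in enumerate(DIALYSIS_BANDS):
                rows.append((int(year), self.sex, band, "dialysis_dn",
                             self.dmdi[i, k]))
        mort = self.exog.mortality
        for y in range(mort.start_year, mort.end_year + 1):
            row = mort.rates[y - mort.start_year]
            for b, band in enumerate(BANDS):
                rows.append((y, self.sex, band, "mort_ndm",
                             row[STOCK_INDEX[("NDM", band)]]))
                rows.append((y, self.sex, band, "mort_dm",
                             row[STOCK_INDEX[("DM", band)]]))
            for band in DIALYSIS_BANDS:
                rows.append((y, self.sex, band, "mort_dmdi",
                             row[STOCK_INDEX[("DMDi", band)]]))
        e20 = self.exog.entry_at_20
        for y in range(e20.start_year, e20.end_year + 1):
            rows.append((y, self.sex, "", "entry20",
                         e20.values[y - e20.start_year]))
        e40 = self.exog.dialysis_entry_at_40
        for y in range(e40.start_year, e40.end_year + 1):
            rows.append((y, self.sex, "", "dialysis_entry40",
                         e40.values[y - e40.start_year]))
        return pd.DataFrame(rows, columns=["year", "sex", "age_band",
                                           "variable", "value"])


def write_datasets(datasets: dict[str, ObservedDataset],
                   path: str | Path) -> None:
    frames = [datasets[sex].to_frame() for sex in sorted(datasets)]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.10g")


def _pivot_band_variable(df: pd.DataFrame, variable: str, years: np.ndarray,
                         bands: tuple[str, ...],
                         violations: list[str]) -> np.ndarray:
    sub = df[df["variable"] == variable]
    out = np.full((years.size, len(bands)), np.nan)
    lookup = {(int(r.year), str(r.age_band)): float(r.value)
              for r in sub.itertuples()}
    for i, year in enumerate(years):
        for j, band in enumerate(bands):
            key = (int(year), band)
            if key not in lookup:
                violations.append(
                    f"missing {variable} for year {year} band {band}")
            else:
                out[i, j] = lookup[key]
    return out


def _series_from_rows(df: pd.DataFrame, variable: str,
                      violations: list[str]) -> StepSeries | None:
    sub = df[df["variable"] == variable].sort_values("year")
    if sub.empty:
        violations.append(f"missing series {variable}")
        return None
    years = sub["year"].to_numpy(dtype=int)
    if np.any(np.diff(years) != 1):
        violations.append(f"series {variable} has gaps in years")
        return None
    return StepSeries(int(years[0]), sub["value"].to_numpy(dtype=float))


def read_datasets(path: str | Path, entry_dm_prevalence: float = 0.002
                  ) -> dict[str, ObservedDataset]:
    """Parse the tidy CSV dialect, collecting every violation at once."""
    df = pd.read_csv(path, dtype={"age_band": str}, keep_default_na=False)
    required = {"year", "sex", "age_band", "variable", "value"}
    if not required.issubset(df.columns):
        raise ValidationError(
            [f"missing columns {sorted(required - set(df.columns))}"])
    violations: list[str] = []
    unknown = set(df["variable"]) - set(BAND_VARIABLES) - set(SERIES_VARIABLES)
    for var in sorted(unknown):
        violations.append(f"unknown variable {var!r}")
    bad_band = df[df["variable"].isin(_DIALYSIS_ONLY)
                  & ~df["age_band"].isin(DIALYSIS_BANDS)]
    for r in bad_band.itertuples():
        violations.append(
            f"{r.variable} not allowed for band {r.age_band!r} "
            f"(row year {r.year}, sex {r.sex})")
    datasets: dict[str, ObservedDataset] = {}
    for sex in sorted(set(df["sex"])):
        sub = df[df["sex"] == sex]
        obs_years = np.unique(sub.loc[sub["variable"] == "pop", "year"]
                              .to_numpy(dtype=int))
        if obs_years.size == 0:
            violations.append(f"no pop observations for sex {sex!r}")
            continue
        pop = _pivot_band_variable(sub, "pop", obs_years, BANDS, violations)
        dm = _pivot_band_variable(sub, "dm", obs_years, BANDS, violations)
        dmdi = _pivot_band_variable(sub, "dialysis_dn", obs_years,
                                    DIALYSIS_BANDS, violations)
        mort_years = np.unique(sub.loc[sub["variable"] == "mort_ndm", "year"]
                               .to_numpy(dtype=int))
        if mort_years.size == 0:
            violations.append(f"no mortality rows for sex {sex!r}")
            continue
        m_ndm = _pivot_band_variable(sub, "mort_ndm", mort_years, BANDS,
                                     violations)
        m_dm = _pivot_band_variable(sub, "mort_dm", mort_years, BANDS,
                                    violations)
        m_di = _pivot_band_variable(sub, "mort_dmdi", mort_years,
                                    DIALYSIS_BANDS, violations)
        e20 = _series_from_rows(sub, "entry20", violations)
        e40 = _series_from_rows(sub, "dialysis_entry40", violations)
        if violations:
            continue
        rates = np.zeros((mort_years.size, N_STOCKS))
        for b, band in enumerate(BANDS):
            rates[:, STOCK_INDEX[("NDM", band)]] = m_ndm[:, b]
            rates[:, STOCK_INDEX[("DM", band)]] = m_dm[:, b]
        for k, band in enumerate(DIALYSIS_BANDS):
            rates[:, STOCK_INDEX[("DMDi", band)]] = m_di[:, k]
        exog = ExogenousInputs(
            sex=sex,
            entry_at_20=e20,
            dialysis_entry_at_40=e40,
            mortality=MortalityTable(int(mort_years[0]), rates),
            entry_dm_prevalence=entry_dm_prevalence,
        )
        ds = ObservedDataset(sex=sex, years=obs_years, pop=pop, dm=dm,
                             dmdi=dmdi, exog=exog)
        violations.extend(ds.violations())
        datasets[sex] = ds
    if violations:
        raise ValidationError(violations)
    return datasets
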