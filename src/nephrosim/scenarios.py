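"""Intervention scenarios: incidence-halving ramps and run comparison.

Two hypothetical interventions are modelled as multipliers on the
calibrated rate families.  DMP (diabetes prevention) halves every
diabetes-incidence hazard linearly between 2015 and 2025 and holds the
halved level afterwards; ESRDP (end-stage renal disease prevention)
does the same to every dialysis-initiation hazard and, consistently,
to the exogenous age-40 dialysis entry; DMP+ESRDP applies both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ExogenousInputs, ModelParameters, Trajectory, simulate

SCENARIO_NAMES = ("base", "DMP", "ESRDP", "DMP+ESRDP")


@dataclass(frozen=True)
class ScenarioSpec:
    """Time-varying multipliers on the two rate families."""

    name: str
    ramps_dm: bool
    ramps_dialysis: bool
    ramp_start: float = 2015.0
    ramp_end: float = 2025.0
    final_level: float = 0.5
    scales_dialysis_entry: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.final_level <= 1.0:
            raise ValueError("final_level must lie in (0, 1]")
        if not self.ramp_start < self.ramp_end:
            raise ValueError("ramp_start must precede ramp_end")

    def _ramp(self, t: float) -> float:
        return ramp_multiplier(t, self)

    def dm_multiplier(self, t: float) -> float:
        return self._ramp(t) if self.ramps_dm else 1.0

    def dialysis_multiplier(self, t: float) -> float:
        return self._ramp(t) if self.ramps_dialysis else 1.0


def ramp_multiplier(t: float, spec: ScenarioSpec) -> float:
    """1 before the ramp, linear down to ``final_level`` at ``ramp_end``,
    constant afterwards."""
    if t <= spec.ramp_start:
        return 1.0
    if t >= spec.ramp_end:
        return spec.final_level
    frac = (t - spec.ramp_start) / (spec.ramp_end - spec.ramp_start)
    return 1.0 + frac * (spec.final_level - 1.0)


def make_scenario(name: str) -> ScenarioSpec:
    if name not in SCENARIO_NAMES:
        raise ValueError(
            f"unknown scenario {name!r}; valid names are {SCENARIO_NAMES}")
    return ScenarioSpec(
        name=name,
        ramps_dm=name in ("DMP", "DMP+ESRDP"),
        ramps_dialysis=name in ("ESRDP", "DMP+ESRDP"),
    )


def run_scenarios(params: ModelParameters, exog: ExogenousInputs,
                  names=SCENARIO_NAMES, t0: float = 2000.0,
                  t1: float = 2035.0, dt: float = 1.0 / 16.0,
                  drift=None) -> dict[str, Trajectory]:
    """Simulate the named scenarios with shared parameters and inputs."""
    out = {}
    for name in names:
        spec = make_scenario(name)
        scenario = None if name == "base" else spec
        out[name] = simulate(params, exog, scenario=scenario, t0=t0, t1=t1,
                             dt=dt, drift=drift)
    return out


@dataclass
class RunComparison:
    """Scenario-vs-base levels and relative reductions at a report year."""

    sex: str
    scenario: str
    report_year: int
    base_level: dict[str, float]
    scenario_level: dict[str, float]
    pct_reduction: dict[str, float]
    base_peak: tuple[int, float]       # (year, value) of TotalDM, earliest tie
    scenario_peak: tuple[int, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for var in self.base_level:
            rows.append((self.sex, "base", var, self.report_year,
                         self.base_level[var], 0.0))
            rows.append((self.sex, self.scenario, var, self.report_year,
                         self.scenario_level[var], self.pct_reduction[var]))
        return pd.DataFrame(rows, columns=["sex", "run", "variable", "year",
                                           "level", "pct_reduction_vs_base"])


def _peak(traj: Trajectory, variable: str = "TotalDM") -> tuple[int, float]:
    series = traj.aggregates()[variable]
    i = int(np.argmax(series.to_numpy()))  # argmax returns the earliest tie
    return int(series.index[i]), float(series.iloc[i])


def compare_runs(base: Trajectory, scenario: Trajectory,
                 report_year: int = 2035,
                 scenario_name: str = "scenario") -> RunComparison:
    """Levels and percent reductions of TotalDM and DMDiover40 at the
    report year, plus each run's TotalDM peak."""
    if base.sex != scenario.sex:
        raise ValueError("runs must describe the same sex")
    variables = ("TotalDM", "DMDiover40")
    base_level = {}
    scen_level = {}
    reduction = {}
    for var in variables:
        b = base.value_at(var, report_year)   # raises if year not covered
        s = scenario.value_at(var, report_year)
        base_level[var] = b
        scen_level[var] = s
        reduction[var] = (b - s) / b * 100.0 if b else 0.0
    return RunComparison(
        sex=base.sex,
        scenario=scenario_name,
        report_year=int(report_year),
        base_level=base_level,
        scenario_level=scen_level,
        pct_reduction=reduction,
        base_peak=_peak(base),
        scenario_peak=_peak(scenario),
    )
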