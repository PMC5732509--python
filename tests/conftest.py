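import numpy as np
import pytest
from hypothesis import settings

import nephrosim as ns

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def japan_fixture():
    return ns.build_japan_like_fixture()


@pytest.fixture(scope="session")
def fixture_calibration(japan_fixture):
    """Default-settings calibration of both sexes on the Japan-like fixture."""
    return ns.calibrate_both_sexes(japan_fixture)


@pytest.fixture(scope="session")
def scenario_runs(japan_fixture, fixture_calibration):
    """Base + all intervention runs to 2035 per sex."""
    return {
        sex: ns.run_scenarios(res.params, japan_fixture[sex].exog)
        for sex, res in fixture_calibration.items()
    }


@pytest.fixture(scope="session")
def male_truth():
    return ns.default_truth("male")


@pytest.fixture(scope="session")
def male_synth(male_truth):
    return ns.generate_synthetic_country(male_truth)


@pytest.fixture()
def quick_options():
    """Reduced-restart optimizer settings for unit-level calibrations."""
    return ns.CalibrationOptions(n_starts=2, seed=0, maxfev=20_000)


def single_stock_inputs(sex="male", mortality_rate=0.0, entry=0.0,
                        entry40=0.0, start_year=2000, n_years=40,
                        mort_stock=None):
    """Exogenous inputs with flat series, optionally one nonzero mortality."""
    rates = np.zeros((n_years, 16))
    if mort_stock is not None:
        rates[:, mort_stock] = mortality_rate
    return ns.ExogenousInputs(
        sex=sex,
        entry_at_20=ns.StepSeries(start_year, np.full(n_years, entry)),
        dialysis_entry_at_40=ns.StepSeries(start_year,
                                           np.full(n_years, entry40)),
        mortality=ns.MortalityTable(start_year, rates),
        entry_dm_prevalence=0.002,
    )
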