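"""Core stock-and-flow integrator: flows, balance, convergence."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import nephrosim as ns
from nephrosim.constants import N_STOCKS, STOCK_INDEX
from nephrosim.model import LinearPropagator

from conftest import single_stock_inputs


from functools import lru_cache


@lru_cache(maxsize=1)
def _truth_and_base():
    """Shared Japan-like truth and its base run for the property tests."""
    truth = ns.default_truth("male")
    base = ns.simulate(truth.params, truth.exog, t0=2000, t1=2025)
    return truth, base


def _params(sex="male", dm=None, di=None, init=None):
    return ns.ModelParameters(
        sex=sex,
        dm_incidence=np.zeros(6) if dm is None else np.asarray(dm, float),
        dialysis_incidence=np.zeros(4) if di is None else np.asarray(di, float),
        initial_state=np.zeros(16) if init is None else np.asarray(init, float),
    )


class TestDerivatives:
    def test_incidence_flow_is_rate_times_stock(self):
        init = np.zeros(16)
        init[STOCK_INDEX[("NDM", "4049")]] = 1000.0
        dm = np.zeros(6)
        dm[2] = 0.01
        flows = ns.derivatives(init, 2000.0, _params(dm=dm, init=init),
                               single_stock_inputs())
        assert flows.incidence[2] == pytest.approx(10.0)

    def test_null_system_has_zero_flows(self):
        flows = ns.derivatives(np.zeros(16), 2005.0, _params(),
                               single_stock_inputs())
        assert flows.net() == pytest.approx(np.zeros(16))
        assert flows.total_entries() == 0.0

    def test_entry_split_by_entry_prevalence(self):
        exog = single_stock_inputs(entry=1_000_000.0)
        flows = ns.derivatives(np.zeros(16), 2000.0, _params(), exog)
        assert flows.entry_dm == pytest.approx(2_000.0)
        assert flows.entry_ndm == pytest.approx(998_000.0)

    def test_time_before_exogenous_domain_rejected(self):
        with pytest.raises(ValueError, match="precedes"):
            ns.derivatives(np.zeros(16), 1990.0, _params(),
                           single_stock_inputs())

    def test_negative_stock_rejected_by_name(self):
        bad = np.zeros(16)
        bad[STOCK_INDEX[("DM", "5059")]] = -1.0
        with pytest.raises(ValueError, match="DM5059"):
            ns.derivatives(bad, 2000.0, _params(), single_stock_inputs())


class TestSimulate:
    def test_single_compartment_decay_matches_closed_form(self):
        """An isolated terminal stock with a pure death rate must follow
        exp(-r t) within 0.5% at dt = 1/16."""
        i = STOCK_INDEX[("NDM", "over70")]  # over70: no aging outflow
        init = np.zeros(16)
        init[i] = 1000.0
        exog = single_stock_inputs(mortality_rate=0.1, mort_stock=i)
        traj = ns.simulate(_params(init=init), exog, t0=2000, t1=2010,
                           dt=1 / 16)
        final = traj.states[-1, i]
        assert final == pytest.approx(1000.0 * np.exp(-1.0), rel=0.005)

    def test_identity_scenario_equals_no_scenario(self, male_truth):
        identity = ns.ScenarioSpec(name="identity", ramps_dm=False,
                                   ramps_dialysis=False)
        a = ns.simulate(male_truth.params, male_truth.exog, scenario=None,
                        t0=2000, t1=2015)
        b = ns.simulate(male_truth.params, male_truth.exog, scenario=identity,
                        t0=2000, t1=2015)
        np.testing.assert_array_equal(a.states, b.states)

    def test_population_conservation_via_flow_resummation(self, male_truth):
        """Cumulative Δpopulation equals cumulative (entries − deaths)
        re-summed independently from the flow vectors."""
        audit = ns.SimulationAudit()
        traj = ns.simulate(male_truth.params, male_truth.exog, t0=2000,
                           t1=2035, audit=audit)
        assert audit.clipped_steps == 0
        delta = traj.states[-1].sum() - traj.states[0].sum()
        balance = audit.cumulative_entries - audit.cumulative_deaths
        assert delta == pytest.approx(balance, rel=1e-9)

    def test_stepwise_flow_balance(self, male_truth):
        """Each Euler increment equals (inflows − outflows)·dt recomputed
        from the FlowVector."""
        dt = 1 / 4
        x = male_truth.params.initial_state.copy()
        traj = ns.simulate(male_truth.params, male_truth.exog, t0=2000,
                           t1=2002, dt=dt)
        for step in range(int(2 / dt)):
            t = 2000 + step * dt
            flows = ns.derivatives(x, t, male_truth.params, male_truth.exog)
            x = x + dt * flows.net()
        np.testing.assert_allclose(x, traj.states[2], rtol=1e-12)

    def test_convergence_halving_dt(self, male_truth):
        a = ns.simulate(male_truth.params, male_truth.exog, t0=2000, t1=2035,
                        dt=1 / 16).aggregates().loc[2035]
        b = ns.simulate(male_truth.params, male_truth.exog, t0=2000, t1=2035,
                        dt=1 / 32).aggregates().loc[2035]
        for col in ("TotalDM", "DMDiover40", "popover20"):
            assert abs(a[col] - b[col]) / b[col] < 1e-3

    @pytest.mark.parametrize("dt", [2.0, 0.3, -0.1])
    def test_invalid_dt_rejected(self, male_truth, dt):
        with pytest.raises(ValueError):
            ns.simulate(male_truth.params, male_truth.exog, t0=2000, t1=2005,
                        dt=dt)

    def test_negative_undershoot_clipped_with_warning(self, caplog):
        i = STOCK_INDEX[("NDM", "over70")]
        init = np.zeros(16)
        init[i] = 1000.0
        exog = single_stock_inputs(mortality_rate=20.0, mort_stock=i)
        with caplog.at_level("WARNING"):
            traj = ns.simulate(_params(init=init), exog, t0=2000, t1=2001,
                               dt=1 / 16)
        assert np.all(traj.states >= 0)
        assert any("clipping" in r.message for r in caplog.records)

    @given(m=st.floats(min_value=0.0, max_value=1.0))
    def test_dm_incidence_scaling_never_raises_totaldm(self, m):
        """Scaling all diabetes-incidence rates by m ∈ [0, 1] must not
        increase TotalDM at any year."""
        truth, base = _truth_and_base()
        scaled = truth.params.with_rates(
            dm_incidence=truth.params.dm_incidence * m)
        traj = ns.simulate(scaled, truth.exog, t0=2000, t1=2025)
        assert np.all(traj.aggregates()["TotalDM"].to_numpy()
                      <= base.aggregates()["TotalDM"].to_numpy() + 1e-6)

    @given(m=st.floats(min_value=0.0, max_value=1.0))
    def test_dialysis_scaling_never_raises_dmdi(self, m):
        """Scaling the dialysis-initiation rates (and the age-40 dialysis
        entry) by m ∈ [0, 1] must not increase DMDiover40 at any year."""
        truth, base = _truth_and_base()
        scaled = truth.params.with_rates(
            dialysis_incidence=truth.params.dialysis_incidence * m)
        import dataclasses
        exog = dataclasses.replace(
            truth.exog,
            dialysis_entry_at_40=ns.StepSeries(
                truth.exog.dialysis_entry_at_40.start_year,
                truth.exog.dialysis_entry_at_40.values * m))
        traj = ns.simulate(scaled, exog, t0=2000, t1=2025)
        assert np.all(traj.aggregates()["DMDiover40"].to_numpy()
                      <= base.aggregates()["DMDiover40"].to_numpy() + 1e-6)

    @given(seed=st.integers(min_value=0, max_value=50))
    def test_nonnegativity_with_bounded_rates(self, seed):
        """With hazards far below 1/dt all stocks stay non-negative."""
        rng = np.random.default_rng(seed)
        init = rng.uniform(0, 1e6, size=16)
        params = _params(dm=rng.uniform(0, 0.05, 6),
                         di=rng.uniform(0, 0.02, 4), init=init)
        exog = single_stock_inputs(entry=rng.uniform(0, 1e5))
        rates = rng.uniform(0, 0.5, size=(40, 16))
        exog = ns.ExogenousInputs(
            sex="male", entry_at_20=exog.entry_at_20,
            dialysis_entry_at_40=exog.dialysis_entry_at_40,
            mortality=ns.MortalityTable(2000, rates))
        traj = ns.simulate(params, exog, t0=2000, t1=2020)
        assert np.all(traj.states >= 0)


class TestFastPath:
    def test_linear_propagator_matches_reference(self, male_truth):
        prop = LinearPropagator(male_truth.exog, 2000, 2015)
        ref = ns.simulate(male_truth.params, male_truth.exog, t0=2000,
                          t1=2015)
        fast = prop.annual_states(male_truth.params)
        np.testing.assert_allclose(fast, ref.states, rtol=1e-9)

    def test_linear_propagator_matches_reference_with_modifiers(
            self, male_truth):
        scen = ns.make_scenario("DMP+ESRDP")
        drift = ns.DriftParams(g_dm=-0.01, g_dialysis=0.02)
        prop = LinearPropagator(male_truth.exog, 2000, 2015)
        ref = ns.simulate(male_truth.params, male_truth.exog, scenario=scen,
                          drift=drift, t0=2000, t1=2015)
        fast = prop.annual_states(male_truth.params, scenario=scen,
                                  drift=drift)
        np.testing.assert_allclose(fast, ref.states, rtol=1e-9)


class TestAggregate:
    def test_totaldm_is_dm_plus_dialysis(self, male_truth):
        traj = ns.simulate(male_truth.params, male_truth.exog, t0=2000,
                           t1=2010)
        agg = traj.aggregates()
        np.testing.assert_allclose(
            agg["TotalDM"], agg["DMover20"] + agg["DMDiover40"])
        np.testing.assert_allclose(
            agg["popover20"], agg["NDMover20"] + agg["TotalDM"])

    def test_prevalence_is_percent_ratio(self):
        states = np.zeros((1, 16))
        states[0, 6] = 8.00e6   # DM2029
        states[0, 12] = 0.16e6  # DMDi4049
        states[0, 0] = 100e6 - 8.16e6
        traj = ns.Trajectory(sex="male", years=[2035], states=states)
        agg = traj.aggregates()
        assert agg.loc[2035, "TotalDM"] == pytest.approx(8.16e6)
        assert agg.loc[2035, "dm_prevalence_pct"] == pytest.approx(8.16)

    def test_empty_trajectory_aggregates_empty(self):
        traj = ns.Trajectory(sex="male", years=np.array([], dtype=int),
                             states=np.zeros((0, 16)))
        assert ns.aggregate(traj).empty
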