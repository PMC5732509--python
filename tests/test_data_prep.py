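"""Derivation rules for prevalence, dialysis back-casting and mortality."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nephrosim import data_prep as dp
from nephrosim.model import StepSeries


@pytest.fixture
def anchors():
    return dp.PrevalenceAnchors(sex="male", band="5059",
                                pct_at={2000: 5.0, 2005: 6.0, 2010: 6.6})


class TestPrevalenceInterpolation:
    @pytest.mark.parametrize("year, expected", [
        (2000, 5.0), (2003, 5.6), (2005, 6.0), (2010, 6.6),
        (2013, 6.96), (2015, 7.2),  # extrapolated at the 2005-2010 slope
    ])
    def test_linear_interpolation_and_extrapolation(self, anchors, year,
                                                    expected):
        out = dp.interpolate_prevalence(anchors, [year])
        assert out[0] == pytest.approx(expected)

    def test_constant_anchors_give_constant_series(self):
        a = dp.PrevalenceAnchors("female", "2029",
                                 {2000: 7.0, 2005: 7.0, 2010: 7.0})
        out = dp.interpolate_prevalence(a, range(2000, 2016))
        np.testing.assert_allclose(out, 7.0)

    def test_missing_anchor_names_band_and_sex(self):
        with pytest.raises(ValueError, match="female/6069"):
            dp.PrevalenceAnchors("female", "6069", {2000: 5.0, 2005: 6.0})

    def test_extrapolation_clipped_to_valid_percent(self):
        a = dp.PrevalenceAnchors("male", "2029",
                                 {2000: 3.0, 2005: 2.0, 2010: 1.0})
        out = dp.interpolate_prevalence(a, range(2000, 2016))
        assert np.all(out >= 0)

    @given(p0=st.floats(0, 50), p1=st.floats(0, 50), p2=st.floats(0, 50))
    def test_anchor_years_reproduced_exactly(self, p0, p1, p2):
        a = dp.PrevalenceAnchors("male", "4049",
                                 {2000: p0, 2005: p1, 2010: p2})
        out = dp.interpolate_prevalence(a, [2000, 2005, 2010])
        np.testing.assert_allclose(out, [p0, p1, p2], atol=1e-12)


class TestCountsFromPrevalence:
    @pytest.mark.parametrize("pct, pop, expected", [
        (6.0, 10_000_000, 600_000), (0.0, 5e6, 0.0), (100.0, 1234.0, 1234.0),
    ])
    def test_count_is_fraction_of_population(self, pct, pop, expected):
        out = dp.counts_from_prevalence(np.array([pct]), np.array([pop]))
        assert out[0] == pytest.approx(expected)

    def test_mismatched_years_rejected(self):
        with pytest.raises(ValueError, match="align"):
            dp.counts_from_prevalence(np.ones(3), np.ones(4))


class TestBackcastDialysis:
    def test_rescaled_to_known_total(self):
        out = dp.backcast_dialysis_counts(np.array([100.0, 300.0]),
                                          np.array([0.3, 0.4]), 100.0)
        np.testing.assert_allclose(out, [20.0, 80.0])

    def test_zero_total_gives_zeros(self):
        out = dp.backcast_dialysis_counts(np.array([100.0, 300.0]),
                                          np.array([0.3, 0.4]), 0.0)
        np.testing.assert_allclose(out, 0.0)

    def test_equal_shares_preserve_allcause_proportions(self):
        allcause = np.array([10.0, 30.0, 60.0])
        out = dp.backcast_dialysis_counts(allcause, np.full(3, 0.25), 50.0)
        np.testing.assert_allclose(out / out.sum(),
                                   allcause / allcause.sum())

    def test_zero_raw_with_positive_total_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            dp.backcast_dialysis_counts(np.zeros(2), np.array([0.5, 0.5]),
                                        10.0)

    @given(total=st.floats(0, 1e6),
           shares=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6))
    def test_output_sums_exactly_to_total(self, total, shares):
        shares = np.asarray(shares)
        allcause = np.linspace(100, 500, shares.size)
        out = dp.backcast_dialysis_counts(allcause, shares, total)
        assert out.sum() == pytest.approx(total, abs=1e-6)


class TestMortalityDecomposition:
    @pytest.mark.parametrize("m_all, p, hr, exp_ndm, exp_dm", [
        (0.011, 0.1, 2.0, 0.010, 0.020),
        (0.02, 0.0, 2.0, 0.02, 0.04),     # degenerate prevalence
        (0.03, 0.25, 1.0, 0.03, 0.03),    # identity hazard ratio
    ])
    def test_known_decompositions(self, m_all, p, hr, exp_ndm, exp_dm):
        m_ndm, m_dm = dp.decompose_mortality(m_all, p, hr)
        assert m_ndm == pytest.approx(exp_ndm)
        assert m_dm == pytest.approx(exp_dm)

    @given(m_all=st.floats(0, 0.5), p=st.floats(0, 0.9),
           hr=st.floats(1, 5))
    def test_mixture_reproduces_observed_rate_exactly(self, m_all, p, hr):
        m_ndm, m_dm = dp.decompose_mortality(m_all, p, hr)
        assert m_ndm * (1 - p) + m_dm * p == pytest.approx(m_all, abs=1e-14)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            dp.decompose_mortality(-0.01, 0.1)


class TestNondialysisMortality:
    def test_death_count_bookkeeping(self):
        out = dp.nondialysis_dm_mortality(0.02, 1_000_000, 0.08, 50_000)
        assert out == pytest.approx(16_000 / 950_000)

    def test_no_dialysis_patients_is_identity(self):
        assert dp.nondialysis_dm_mortality(0.02, 1e6, 0.08, 0.0) == \
            pytest.approx(0.02)

    def test_floored_at_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = dp.nondialysis_dm_mortality(0.001, 100_000, 0.5, 90_000)
        assert out == 0.0
        assert any("floored" in r.message for r in caplog.records)

    def test_dialysis_exceeding_dm_total_rejected(self):
        with pytest.raises(ValueError):
            dp.nondialysis_dm_mortality(0.02, 100.0, 0.08, 100.0)


class TestInflowAt40:
    @pytest.mark.parametrize("n35, n40, expected", [
        (600.0, 400.0, 100.0), (0.0, 0.0, 0.0), (947.0, 947.0, 189.4),
    ])
    def test_mean_of_straddling_bands_over_width(self, n35, n40, expected):
        assert dp.inflow_at_40(n35, n40) == pytest.approx(expected)


class TestDialysisMortalityBackcast:
    def test_exact_line_extrapolated_backward(self):
        out = dp.extrapolate_dialysis_mortality(
            np.array([0.080, 0.082, 0.084, 0.086]))
        assert out[-1] == pytest.approx(0.078)   # 2011
        assert out[0] == pytest.approx(0.056)    # 2000
        np.testing.assert_allclose(np.diff(out), 0.002)

    def test_constant_observations_stay_constant(self):
        out = dp.extrapolate_dialysis_mortality(np.full(4, 0.05))
        np.testing.assert_allclose(out, 0.05)

    def test_trend_crossing_zero_clipped(self, caplog):
        with caplog.at_level("WARNING"):
            out = dp.extrapolate_dialysis_mortality(
                np.array([0.01, 0.06, 0.11, 0.16]))
        assert np.all(out >= 0.0)
        assert any("clipped" in r.message for r in caplog.records)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            dp.extrapolate_dialysis_mortality(
                np.array([0.05, np.nan, 0.05, 0.05]))


class TestExtendExogenous:
    def test_hold_at_final_value(self):
        s = StepSeries(2000, np.linspace(4.0, 5.0, 16))
        out = dp.extend_exogenous(s, 2035)
        assert out.end_year == 2035
        assert out.value_at(2016) == pytest.approx(5.0)
        assert out.value_at(2035) == pytest.approx(5.0)

    @pytest.mark.parametrize("horizon", [2015, 2055])
    def test_horizon_variants(self, horizon):
        s = StepSeries(2000, np.linspace(4.0, 5.0, 16))
        out = dp.extend_exogenous(s, horizon)
        assert out.value_at(float(horizon)) == pytest.approx(5.0)
        assert out.value_at(2010) == s.value_at(2010)

    def test_derived_rates_in_unit_interval(self, japan_fixture):
        for ds in japan_fixture.values():
            assert np.all(ds.exog.mortality.rates >= 0)
            assert np.all(ds.exog.mortality.rates <= 1)
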