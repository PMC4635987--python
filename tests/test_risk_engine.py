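"""Risk-equation evaluation, probability conversions and life-table lookups."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from t2dm_cesim import (
    ConfigurationError,
    DriftSpec,
    LifeTable,
    RiskEquationSpec,
    RiskFactorVector,
    annual_event_probability,
    annual_to_cycle,
    background_mortality,
    linear_predictor,
    progress_risk_factor,
)


def rf(**overrides) -> RiskFactorVector:
    base = dict(
        age=57.51, female=False, duration=6.01, hba1c=8.05, sbp=133.3,
        tc_hdl_ratio=4.53, bmi=30.76, smoker=False, afro_caribbean=False,
    )
    base.update(overrides)
    return RiskFactorVector(**base)


class TestLinearPredictor:
    def test_zero_spec_gives_zero(self):
        spec = RiskEquationSpec("mi", "constant_hazard", intercept=0.0)
        assert linear_predictor(spec, rf()) == 0.0

    def test_single_coefficient_arithmetic(self):
        spec = RiskEquationSpec(
            "mi", "constant_hazard", intercept=-1.0, coefficients={"hba1c": 2.0}
        )
        assert linear_predictor(spec, rf(hba1c=8.05)) == pytest.approx(15.1, abs=1e-12)

    def test_matches_independent_hand_sum(self):
        # brute-force oracle: explicit sum over three centred covariates
        spec = RiskEquationSpec(
            "stroke",
            "weibull_cumhaz",
            intercept=-4.2,
            shape=1.4,
            coefficients={"hba1c": 0.13, "sbp": 0.008, "female": -0.5},
            centering={"hba1c": 6.72, "sbp": 135.7},
            history_terms={"mi": 0.6},
        )
        state = rf(hba1c=9.1, sbp=151.0, female=True)
        expected = -4.2 + 0.13 * (9.1 - 6.72) + 0.008 * (151.0 - 135.7) - 0.5 * 1.0 + 0.6 * 1.0
        got = linear_predictor(spec, state, history={"mi": True})
        assert got == pytest.approx(expected, abs=1e-12)

    def test_missing_covariate_is_named_error(self):
        spec = RiskEquationSpec(
            "mi", "constant_hazard", intercept=0.0, coefficients={"egfr": 1.0}
        )
        with pytest.raises(ConfigurationError, match="egfr"):
            linear_predictor(spec, rf())

    def test_missing_history_flag_is_named_error(self):
        spec = RiskEquationSpec(
            "cv_death", "constant_hazard", intercept=0.0, history_terms={"mi": 1.0}
        )
        with pytest.raises(ConfigurationError, match="mi"):
            linear_predictor(spec, rf(), history={})


class TestAnnualEventProbability:
    def test_zero_hazard(self):
        spec = RiskEquationSpec("mi", "constant_hazard", intercept=-np.inf)
        assert annual_event_probability(spec, rf()) == 0.0

    def test_constant_hazard_closed_form(self):
        # hazard ln 2 -> annual probability 1 - e^(-ln 2) = 0.5
        spec = RiskEquationSpec("mi", "constant_hazard", intercept=math.log(math.log(2)))
        assert annual_event_probability(spec, rf()) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("duration", [0.0, 1.0, 6.01, 25.0])
    def test_weibull_shape_one_equals_constant_hazard(self, duration):
        lp = -3.1
        weib = RiskEquationSpec("chf", "weibull_cumhaz", intercept=lp, shape=1.0)
        const = RiskEquationSpec("chf", "constant_hazard", intercept=lp)
        state = rf(duration=duration)
        assert annual_event_probability(weib, state) == pytest.approx(
            annual_event_probability(const, state), abs=1e-14
        )

    def test_weibull_shape_gt_one_is_nondecreasing_in_duration(self):
        spec = RiskEquationSpec("amputation", "weibull_cumhaz", intercept=-6.0, shape=2.067)
        durations = np.linspace(0, 39, 200)
        probs = [annual_event_probability(spec, rf(duration=d)) for d in durations]
        assert np.all(np.diff(probs) >= 0)

    @given(
        intercept=st.floats(-30, 3),
        shape=st.floats(0.1, 4.0),
        hba1c=st.floats(3.1, 19.9),
        beta=st.floats(-1, 1),
        duration=st.floats(0, 60),
        form=st.sampled_from(["weibull_cumhaz", "constant_hazard", "logistic_annual"]),
    )
    def test_probability_always_in_unit_interval(self, intercept, shape, hba1c, beta, duration, form):
        spec = RiskEquationSpec(
            "mi", form, intercept=intercept, shape=shape, coefficients={"hba1c": beta}
        )
        p = annual_event_probability(spec, rf(hba1c=hba1c, duration=duration))
        assert 0.0 <= p <= 1.0


class TestAnnualToCycle:
    @pytest.mark.parametrize(
        "p_annual,cycle,expected",
        [
            (0.0, 0.5, 0.0),
            (0.19, 0.5, 0.1),  # 1 - 0.81**0.5
            (0.3, 1.0, 0.3),
            (0.97, 1.0, 0.97),
        ],
    )
    def test_closed_forms(self, p_annual, cycle, expected):
        assert annual_to_cycle(p_annual, cycle) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(0, 0.999999))
    def test_two_half_cycles_recover_annual(self, p):
        half = annual_to_cycle(p, 0.5)
        recovered = 1 - (1 - half) ** 2
        assert recovered == pytest.approx(p, abs=1e-12)

    def test_certain_event_returns_one_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert annual_to_cycle(1.0, 0.5) == 1.0
        assert any("rate" in r.message for r in caplog.records)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            annual_to_cycle(0.5, 0.0)
        with pytest.raises(ConfigurationError):
            annual_to_cycle(1.2, 0.5)


def two_band_table():
    rows = []
    for sex, q1, q2 in (("male", 0.01, 0.10), ("female", 0.004, 0.07)):
        rows.append({"age_lo": 18, "age_hi": 65, "sex": sex, "q_annual": q1})
        rows.append({"age_lo": 65, "age_hi": 110, "sex": sex, "q_annual": q2})
    return LifeTable(pd.DataFrame(rows))


class TestLifeTable:
    def test_flat_table_closed_form(self):
        rows = [
            {"age_lo": 18, "age_hi": 110, "sex": s, "q_annual": 0.02} for s in ("male", "female")
        ]
        lt = LifeTable(pd.DataFrame(rows))
        assert background_mortality(50.0, False, lt, 0.5) == pytest.approx(
            1 - 0.98**0.5, abs=1e-12
        )

    def test_band_boundary_resolves_to_upper_band(self):
        lt = two_band_table()
        # half-open [lo, hi): age 65 belongs to the 65-110 band
        assert lt.annual_probability(65.0, False)[0] == 0.10
        assert lt.annual_probability(64.999, False)[0] == 0.01

    def test_sexes_independently_retrievable(self):
        lt = two_band_table()
        age = np.array([30.0, 30.0])
        female = np.array([False, True])
        assert list(lt.annual_probability(age, female)) == [0.01, 0.004]

    def test_age_above_coverage_uses_terminal_band(self, caplog):
        lt = two_band_table()
        with caplog.at_level("WARNING"):
            assert lt.annual_probability(112.0, True)[0] == 0.07

    def test_noncontiguous_bands_rejected(self):
        rows = [
            {"age_lo": 18, "age_hi": 60, "sex": s, "q_annual": 0.01} for s in ("male", "female")
        ] + [{"age_lo": 70, "age_hi": 110, "sex": s, "q_annual": 0.1} for s in ("male", "female")]
        with pytest.raises(ConfigurationError, match="contiguous"):
            LifeTable(pd.DataFrame(rows))


class TestDrift:
    def test_zero_slope_is_identity(self):
        d = DriftSpec("hba1c", 0.0)
        assert progress_risk_factor(d, 7.4, 3.0, 0.5) == 7.4

    def test_linear_half_cycle(self):
        d = DriftSpec("hba1c", 0.15)
        assert progress_risk_factor(d, 7.4, 3.0, 0.5) == pytest.approx(7.475, abs=1e-12)

    def test_twenty_cycles_telescope_to_closed_form(self):
        # stepping 20 half-year cycles equals the closed-form 10-year drift
        d = DriftSpec("sbp", 0.8)
        value = 133.3
        for _ in range(20):
            value = progress_risk_factor(d, value, 0.0, 0.5)
        assert value == pytest.approx(133.3 + 0.8 * 10.0, abs=1e-9)


class TestEventFreeTimeMatchesAnalytic:
    def test_constant_hazard_mean_event_free_time(self, rng):
        # 50,000 geometric draws on the cycle grid vs the discrete closed form
        rate, cy, horizon = 0.08, 0.5, 40.0
        spec = RiskEquationSpec("mi", "constant_hazard", intercept=math.log(rate))
        p_cycle = annual_to_cycle(annual_event_probability(spec, rf()), cy)
        n, n_cycles = 50_000, int(horizon / cy)
        draws = rng.random((n, n_cycles)) < p_cycle
        first = np.where(draws.any(axis=1), draws.argmax(axis=1), n_cycles)
        event_free = first * cy  # complete cycles survived before the event
        s = 1 - p_cycle
        # E[min(first, N)] * cy with first ~ geometric(p): cy * sum_{k=1..N} s^k... via survival
        expected = cy * sum(s**k for k in range(1, n_cycles + 1))
        se = event_free.std() / math.sqrt(n)
        assert abs(event_free.mean() - expected) < 3 * se
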