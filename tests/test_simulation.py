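"""Engine-level tests against closed-form toy-model oracles."""

import math

import numpy as np
import pytest

from t2dm_cesim import (
    DriftSpec,
    RiskEquationSpec,
    RiskFactorVector,
    TherapyProfile,
    annual_event_probability,
    annual_to_cycle,
    fixtures,
    run_comparison,
    simulate_cohort,
    simulate_patient,
)
from t2dm_cesim.simulate import _CompiledEquation, compute_icer


class TestSurvivalOracles:
    def test_zero_hazards_survive_full_horizon(self):
        toy = fixtures.make_toy_risk_model({})
        res = simulate_cohort(100, fixtures.make_toy_model_inputs(toy), seed=1)
        assert res.alive.all()
        assert np.all(res.ly == 40.0)
        assert np.all(res.qaly == 40.0)  # utility 1, undiscounted

    def test_constant_hazard_mean_life_years_matches_closed_form(self):
        h = 0.05
        toy = fixtures.make_toy_risk_model({"cv_death": h})
        res = simulate_cohort(50_000, fixtures.make_toy_model_inputs(toy), seed=2)
        se = res.ly.std() / math.sqrt(len(res.ly))
        continuous = toy.expected_life_years_continuous()  # (1 - e^(-40h)) / h
        discrete = toy.expected_life_years()
        assert abs(res.ly.mean() - continuous) < 3 * se
        assert abs(res.ly.mean() - discrete) < 3 * se
        # the two oracles agree to O(cycle^2) under the mid-interval convention
        assert abs(discrete - continuous) < 0.01

    def test_background_mortality_equivalent_to_death_equation(self):
        # flat life table at q = 1 - e^(-h) is the same process as a
        # constant-hazard death equation with rate h
        h = 0.04
        toy_eq = fixtures.make_toy_risk_model({"cv_death": h})
        toy_bg = fixtures.make_toy_risk_model({}, background_annual_q=1 - math.exp(-h))
        r_eq = simulate_cohort(30_000, fixtures.make_toy_model_inputs(toy_eq), seed=3)
        r_bg = simulate_cohort(30_000, fixtures.make_toy_model_inputs(toy_bg), seed=4)
        se = math.hypot(r_eq.ly.std(), r_bg.ly.std()) / math.sqrt(30_000)
        assert abs(r_eq.ly.mean() - r_bg.ly.mean()) < 3 * se
        assert toy_eq.death_rate == pytest.approx(toy_bg.death_rate)

    def test_competing_event_counts_proportional_to_rates(self):
        rates = {"mi": 0.03, "stroke": 0.06, "cv_death": 0.02}
        toy = fixtures.make_toy_risk_model(rates)
        n = 20_000
        res = simulate_cohort(n, fixtures.make_toy_model_inputs(toy), seed=5)
        for ev in ("mi", "stroke"):
            p_expected = toy.expected_event_count(ev)
            p_hat = res.summary.event_counts[ev] / n
            se = math.sqrt(p_expected * (1 - p_expected) / n)
            assert abs(p_hat - p_expected) < 3 * se

    def test_no_accrual_after_death_and_bounds(self):
        toy = fixtures.make_toy_risk_model({"cv_death": 0.3})
        inputs = fixtures.make_toy_model_inputs(toy, baseline_utility=0.9, discount_rate=0.035)
        res = simulate_cohort(5_000, inputs, seed=6)
        assert np.all(res.ly <= 40.0)
        assert np.all(res.qaly <= res.ly_disc + 1e-12)  # utility < 1 everywhere
        # dead patients stopped accruing: with rate 0.3 mean LY far below horizon
        assert res.ly[~res.alive].max() < 40.0


class TestDeterministicAccrual:
    def test_qaly_equals_discounted_cycle_year_sum(self):
        toy = fixtures.make_toy_risk_model({})
        inputs = fixtures.make_toy_model_inputs(toy, baseline_utility=0.8, discount_rate=0.035)
        res = simulate_cohort(3, inputs, seed=7)
        expected = 0.8 * 0.5 * sum(1.035 ** (-0.5 * k) for k in range(80))
        assert res.qaly == pytest.approx(expected, abs=1e-9)
        assert np.all(res.ly == 40.0)

    def test_pure_drug_cost_stream_recovered(self):
        toy = fixtures.make_toy_risk_model({})
        priced = TherapyProfile(name="priced", delta_hba1c=0.0, delta_weight=0.0, annual_drug_cost=50.0)
        inputs_a = fixtures.make_toy_model_inputs(toy, discount_rate=0.035)
        inputs_b = fixtures.make_toy_model_inputs(toy, discount_rate=0.035, therapy=priced)
        res = run_comparison(inputs_a, inputs_b, n_cohorts=2, n_patients=10, seed=8)
        expected_stream = 25.0 * sum(1.035 ** (-0.5 * k) for k in range(80))
        assert res.delta_cost == pytest.approx(expected_stream, abs=1e-9)
        assert res.delta_qaly == 0.0
        assert "undefined" in res.icer_label


class TestReproducibility:
    def test_same_seed_identical_summaries(self, base_cfg):
        from t2dm_cesim import build_model_inputs

        inputs = build_model_inputs(base_cfg, "b")
        r1 = simulate_cohort(2_000, inputs, seed=11)
        r2 = simulate_cohort(2_000, inputs, seed=11)
        assert r1.summary == r2.summary
        assert np.array_equal(r1.cost, r2.cost)

    def test_single_patient_equals_n1_cohort(self, base_cfg):
        from t2dm_cesim import build_model_inputs

        inputs = build_model_inputs(base_cfg, "a")
        p = simulate_patient(inputs, seed=13)
        res = simulate_cohort(1, inputs, seed=13)
        assert p.cost == res.summary.mean_cost
        assert p.qaly == res.summary.mean_qaly
        assert p.ly == res.summary.mean_ly_undisc

    def test_identical_arms_with_common_random_numbers_cancel_exactly(self, base_cfg):
        from t2dm_cesim import build_model_inputs

        inputs = build_model_inputs(base_cfg, "a")
        res = run_comparison(
            inputs, inputs, n_cohorts=2, n_patients=1_000, seed=17, common_random_numbers=True
        )
        assert res.delta_cost == 0.0
        assert res.delta_qaly == 0.0

    def test_disjoint_seeds_agree_within_monte_carlo_error(self):
        toy = fixtures.make_toy_risk_model({"cv_death": 0.05})
        inputs = fixtures.make_toy_model_inputs(toy)
        n = 30_000
        r1 = simulate_cohort(n, inputs, seed=19)
        r2 = simulate_cohort(n, inputs, seed=23)
        assert r1.summary != r2.summary
        se = math.hypot(r1.ly.std(), r2.ly.std()) / math.sqrt(n)
        assert abs(r1.ly.mean() - r2.ly.mean()) < 3 * se


class TestSamplingError:
    def test_doubling_patients_shrinks_cohort_sd_by_root_two(self):
        toy = fixtures.make_toy_risk_model({"cv_death": 0.06})
        inputs = fixtures.make_toy_model_inputs(toy)
        rngs = np.random.SeedSequence(29).spawn(120)
        small = [simulate_cohort(250, inputs, np.random.default_rng(s)).ly.mean() for s in rngs[:60]]
        large = [simulate_cohort(500, inputs, np.random.default_rng(s)).ly.mean() for s in rngs[60:]]
        ratio = np.std(small) / np.std(large)
        assert math.sqrt(2) * 0.8 < ratio < math.sqrt(2) * 1.2


class TestCompiledEquationsMatchReference:
    def test_fast_path_probability_equals_public_api(self):
        spec = RiskEquationSpec(
            "chf",
            "weibull_cumhaz",
            intercept=-5.0,
            shape=1.7,
            coefficients={"hba1c": 0.15, "bmi": 0.07, "female": -0.4, "sbp": 0.01},
            centering={"hba1c": 8.05, "bmi": 30.76, "sbp": 133.3},
            history_terms={"mi": 0.8},
        )
        rng = np.random.default_rng(0)
        n = 500
        rf = RiskFactorVector(
            age=np.full(n, 60.0),
            female=rng.random(n) < 0.5,
            duration=np.full(n, 9.0),
            hba1c=rng.uniform(5, 12, n),
            sbp=np.full(n, 140.0),
            tc_hdl_ratio=np.full(n, 4.5),
            bmi=rng.uniform(22, 40, n),
            smoker=np.zeros(n, dtype=bool),
            afro_caribbean=np.zeros(n, dtype=bool),
        )
        history = {"mi": rng.random(n) < 0.3}
        compiled = _CompiledEquation(spec, rf)
        fast = compiled.cycle_probability(rf.hba1c, rf.bmi, 9.0, history, 0.5)
        reference = annual_to_cycle(annual_event_probability(spec, rf, history), 0.5)
        np.testing.assert_allclose(fast, reference, rtol=1e-12, atol=1e-15)


class TestIcerLabels:
    @pytest.mark.parametrize(
        "dc,de,expected_icer,expected_label",
        [
            (100.0, 1.0, 100.0, "100"),
            (-50.0, 0.5, float("nan"), "dominant"),
            (50.0, -0.5, float("nan"), "dominated"),
            (50.0, 0.0, float("nan"), "undefined (zero QALY difference)"),
            (-100.0, -0.05, 2000.0, "2000"),
        ],
    )
    def test_dominance_quadrants(self, dc, de, expected_icer, expected_label):
        icer, label = compute_icer(dc, de)
        if math.isnan(expected_icer):
            assert math.isnan(icer)
        else:
            assert icer == pytest.approx(expected_icer)
        assert label == expected_label
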