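"""Tornado, PSA draws, CEAC and scenario machinery (small simulation sizes)."""

import math

import numpy as np
import pandas as pd
import pytest

from t2dm_cesim import (
    ParameterRangeSpec,
    PsaResult,
    build_model_inputs,
    ceac,
    draw_psa_config,
    fixtures,
    run_psa,
    scenario_run,
    simulate_cohort,
    tornado,
)
from t2dm_cesim.analysis import SCENARIOS, _sample_one
from t2dm_cesim.errors import ConfigurationError


def psa_from(pairs) -> PsaResult:
    frame = pd.DataFrame(
        [{"draw": i, "delta_qaly": e, "delta_cost": c} for i, (e, c) in enumerate(pairs)]
    )
    return PsaResult(draws=frame, seed=0, n_patients=0)


class TestCeac:
    def test_three_point_hand_enumeration(self):
        # NMB at lambda 20,000: (0.1, 1000) -> +1000; (0.1, 3000) -> -1000;
        # (-0.1, -500) -> -1500: exactly one of three draws is cost-effective
        psa = psa_from([(0.1, 1000.0), (0.1, 3000.0), (-0.1, -500.0)])
        curve = ceac(psa, [20_000.0])
        assert curve["probability_cost_effective"].iloc[0] == pytest.approx(1 / 3)

    def test_dominant_draws_give_probability_one_everywhere(self):
        psa = psa_from([(0.2, -100.0), (0.01, -5.0)])
        curve = ceac(psa, [0.0, 10_000.0, 50_000.0])
        assert (curve["probability_cost_effective"] == 1.0).all()

    def test_lambda_zero_counts_cost_saving_draws(self):
        psa = psa_from([(0.1, -10.0), (0.1, 10.0), (-0.3, 0.0)])
        curve = ceac(psa, [0.0])
        assert curve["probability_cost_effective"].iloc[0] == pytest.approx(2 / 3)

    def test_monotone_in_lambda_when_all_gains_positive(self, rng):
        pairs = list(zip(rng.uniform(0.0, 0.2, 200), rng.normal(200, 400, 200)))
        curve = ceac(psa_from(pairs), np.arange(0, 50_001, 1000))
        probs = curve["probability_cost_effective"].to_numpy()
        assert np.all(np.diff(probs) >= 0)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_negative_threshold_rejected(self):
        with pytest.raises(ConfigurationError):
            ceac(psa_from([(0.1, 0.0)]), [-5.0])


class TestPsaSampling:
    def test_degenerate_distributions_return_base_config(self, base_cfg, rng):
        specs = [
            ParameterRangeSpec(path=p.path, distribution=p.distribution, mean=p.mean, se=0.0)
            for p in base_cfg.psa
        ]
        drawn = draw_psa_config(base_cfg, specs, rng)
        assert drawn.config_hash() == base_cfg.config_hash()

    def test_beta_draws_respect_unit_interval(self, rng):
        spec = ParameterRangeSpec(
            path="therapies.dapa_met.p_discontinue", distribution="beta", mean=0.081, se=0.02
        )
        draws = [_sample_one(spec, rng) for _ in range(2_000)]
        assert all(0.0 <= d <= 1.0 for d in draws)

    def test_normal_treatment_effect_mean_recovered(self, rng):
        spec = ParameterRangeSpec(
            path="therapies.dapa_met.delta_weight", distribution="normal", mean=-3.36, se=0.278
        )
        n = 10_000
        draws = np.array([_sample_one(spec, rng) for _ in range(n)])
        assert abs(draws.mean() - (-3.36)) < 3 * 0.278 / math.sqrt(n)

    def test_gamma_matches_mean_and_se(self, rng):
        spec = ParameterRangeSpec(path="costs.nondrug_multiplier", distribution="gamma", mean=1.0, se=0.1276)
        draws = np.array([_sample_one(spec, rng) for _ in range(10_000)])
        assert draws.min() > 0
        assert abs(draws.mean() - 1.0) < 3 * 0.1276 / math.sqrt(10_000)

    def test_domain_resampling_gives_up_after_100_attempts(self, base_cfg, rng):
        spec = ParameterRangeSpec(
            path="costs.nondrug_multiplier", distribution="normal", mean=1.0, se=0.01,
            domain=(5.0, 6.0),
        )
        with pytest.raises(ConfigurationError, match="persistently outside"):
            draw_psa_config(base_cfg, [spec], rng)


class TestRunPsa:
    def test_same_master_seed_reproduces_scatter(self, base_cfg):
        r1 = run_psa(base_cfg, n_draws=3, n_patients=300, seed=41)
        r2 = run_psa(base_cfg, n_draws=3, n_patients=300, seed=41)
        pd.testing.assert_frame_equal(r1.draws, r2.draws)

    def test_scaled_runs_agree_within_sampling_error(self, base_cfg):
        # fewer, larger cohorts vs more, smaller cohorts: same expectation
        r_large = run_psa(base_cfg, n_draws=6, n_patients=2_000, seed=43)
        r_small = run_psa(base_cfg, n_draws=12, n_patients=1_000, seed=47)
        se = math.hypot(
            r_large.draws["delta_qaly"].std() / math.sqrt(6),
            r_small.draws["delta_qaly"].std() / math.sqrt(12),
        )
        diff = r_large.draws["delta_qaly"].mean() - r_small.draws["delta_qaly"].mean()
        assert abs(diff) < 4 * se


class TestTornado:
    def test_degenerate_range_has_zero_width(self, base_cfg):
        base_val = base_cfg.therapies["dapa_met"].delta_weight
        spec = ParameterRangeSpec(
            path="therapies.dapa_met.delta_weight", low=base_val, high=base_val
        )
        table = tornado(base_cfg, [spec], n_cohorts=1, n_patients=300, seed=51)
        assert table.loc[0, "cost_range"] == 0.0
        assert table.loc[0, "qaly_range"] == 0.0

    def test_cost_parameter_cannot_move_health_outcomes(self, base_cfg):
        # identical seed + fixed draw consumption: a pure price change leaves
        # every health trajectory bitwise unchanged
        spec = ParameterRangeSpec(path="costs.nondrug_multiplier", low=0.75, high=1.25)
        table = tornado(base_cfg, [spec], n_cohorts=1, n_patients=500, seed=53)
        assert table.loc[0, "qaly_range"] == 0.0
        assert table.loc[0, "cost_range"] > 0.0

    def test_comparator_weight_effect_dominates_qaly_uncertainty(self, base_cfg):
        specs = [
            ParameterRangeSpec(path="therapies.dpp4i_met.delta_weight", low=-1.155, high=-0.065),
            ParameterRangeSpec(path="costs.nondrug_multiplier", low=0.75, high=1.25),
        ]
        table = tornado(base_cfg, specs, n_cohorts=1, n_patients=2_000, seed=57)
        table = table.set_index("parameter")
        assert (
            table.loc["therapies.dpp4i_met.delta_weight", "qaly_range"]
            > table.loc["costs.nondrug_multiplier", "qaly_range"]
        )
        # sorted output puts the weight effect first
        assert tornado(base_cfg, specs, n_cohorts=1, n_patients=500, seed=57).loc[0, "parameter"] \
            == "therapies.dpp4i_met.delta_weight"


class TestScenarios:
    def test_empty_overrides_reproduce_base_case(self, base_cfg):
        kwargs = dict(n_cohorts=1, n_patients=400, seed=61)
        base = scenario_run(base_cfg, {}, **kwargs)
        again = scenario_run(base_cfg, {}, **kwargs)
        assert base.delta_cost == again.delta_cost
        assert base.delta_qaly == again.delta_qaly

    def test_higher_threshold_extends_time_on_first_line(self, base_cfg):
        from t2dm_cesim.config import set_by_path

        raised = set_by_path(base_cfg, "sequence.switch_threshold_hba1c", 8.5)
        t_base = simulate_cohort(800, build_model_inputs(base_cfg, "b"), seed=63)
        t_raised = simulate_cohort(800, build_model_inputs(raised, "b"), seed=63)
        assert t_raised.years_on_first_line.mean() > t_base.years_on_first_line.mean()

    def test_stronger_dapagliflozin_effect_raises_incremental_cost(self, base_cfg):
        kwargs = dict(n_cohorts=1, n_patients=3_000, seed=67)
        larger = scenario_run(base_cfg, SCENARIOS["dapa_hba1c_effect_ci_lower"], **kwargs)
        smaller = scenario_run(base_cfg, SCENARIOS["dapa_hba1c_effect_ci_upper"], **kwargs)
        assert larger.delta_cost > smaller.delta_cost

    def test_unset_scenario_value_is_an_error(self, base_cfg):
        with pytest.raises(ConfigurationError, match="needs a value"):
            scenario_run(base_cfg, SCENARIOS["alt_bmi_utilities"], n_cohorts=1, n_patients=10, seed=1)

    def test_unknown_override_path_is_config_error(self, base_cfg):
        with pytest.raises(ConfigurationError, match="unknown config path"):
            scenario_run(base_cfg, {"sequence.nonexistent": 1.0}, n_cohorts=1, n_patients=10, seed=1)
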