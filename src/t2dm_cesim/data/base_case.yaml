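# Base-case model inputs: baseline cohort, 1-year treatment effects,
# per-cycle event probabilities, unit costs (GBP, 2011 prices) and utility
# decrements. This file is the single versioned transcription of the study
# inputs; every value not sourced from the study is tagged under
# `assumptions` at the bottom.

meta:
  name: base_case
  version: "1.0"
  price_year: 2011
  currency: GBP

run:
  horizon_years: 40.0
  cycle_years: 0.5
  n_cohorts: 100
  n_patients: 30000
  seed: 12345
  common_random_numbers: false
  effect_mode: ramp

cohort:
  age: 57.51
  prop_female: 0.47
  duration: 6.01
  height_m: 1.69
  prop_afro_caribbean: 0.062
  prop_smoker: 0.369
  hba1c: 8.05
  weight_kg: 87.84
  sbp: 133.30
  tc_mgdl: 199.57
  hdl_mgdl: 44.09

therapies:
  dapa_met:
    delta_hba1c: -0.69
    delta_weight: -3.36
    p_discontinue: 0.081
    p_hypo_symptomatic: 0.031
    p_hypo_severe: 0.0004
    p_hypo_nocturnal: 0.0
    p_uti: 0.074
    p_genital_infection: 0.123
    annual_drug_cost: 476.92      # dapagliflozin 10 mg od
    includes_metformin: true
    requires_renal_monitoring: true
  dpp4i_met:
    delta_hba1c: -0.61
    delta_weight: -0.61
    p_discontinue: 0.043
    p_hypo_symptomatic: 0.046
    p_hypo_severe: 0.001
    p_hypo_nocturnal: 0.0
    p_uti: 0.054
    p_genital_infection: 0.0
    annual_drug_cost: 433.57      # sitagliptin 100 mg od
    includes_metformin: true
  insulin_met:
    delta_hba1c: -1.10
    delta_weight: 1.08
    p_discontinue: 0.0
    p_hypo_symptomatic: 0.011
    p_hypo_severe: 0.037
    p_hypo_nocturnal: 0.0
    p_uti: 0.0
    p_genital_infection: 0.0
    daily_cost_per_kg: 0.0053     # basal insulin, weight-based dosing
    includes_metformin: true
  intensified_insulin:
    delta_hba1c: -1.11
    delta_weight: 1.90
    p_discontinue: 0.0
    p_hypo_symptomatic: 0.616
    p_hypo_severe: 0.022
    p_hypo_nocturnal: 0.0
    p_uti: 0.0
    p_genital_infection: 0.0
    daily_cost_per_kg: 0.008      # basal dose increased by 50%
    includes_metformin: false

sequence:
  arm_a: [dpp4i_met, insulin_met, intensified_insulin]
  arm_b: [dapa_met, insulin_met, intensified_insulin]
  switch_threshold_hba1c: 8.05    # mean baseline HbA1c

weight_trajectory:
  effect_year: 1.0
  plateau_through: 2.0
  regain_complete_at: 5.0

drift:
  hba1c_slope_per_year: 0.15
  sbp_slope_per_year: 0.0
  tc_hdl_slope_per_year: 0.0

costs:
  metformin_annual: 23.46
  severe_hypo: 390.0
  uti: 36.0
  genital_infection: 36.0
  discontinuation: 36.0
  renal_monitoring_annual: 38.67
  nondrug_multiplier: 1.0
  complications:
    ihd:        {fatal: null,    nonfatal: 3479.0,  maintenance: 1149.0}
    mi:         {fatal: 2244.0,  nonfatal: 6709.0,  maintenance: 1105.0}
    chf:        {fatal: 3880.0,  nonfatal: 3880.0,  maintenance: 1360.0}
    stroke:     {fatal: 5658.0,  nonfatal: 4103.0,  maintenance: 776.0}
    amputation: {fatal: 13359.0, nonfatal: 13359.0, maintenance: 771.0}
    blindness:  {fatal: null,    nonfatal: 1752.0,  maintenance: 742.0}
    esrd:       {fatal: null,    nonfatal: 34806.0, maintenance: 34806.0}

utilities:
  baseline_utility: 0.785
  complication_multiplier: 1.0
  complications:
    ihd: 0.090
    mi: 0.550
    chf: 0.108
    stroke: 0.164
    amputation: 0.280
    blindness: 0.074
    esrd: 0.263
  hypo_symptomatic: 0.042
  hypo_nocturnal: 0.008
  hypo_severe: 0.047
  uti: 0.00283
  genital_infection: 0.00283
  bmi_per_unit_increase: 0.0472
  bmi_per_unit_decrease: 0.0171

discount:
  rate: 0.035

risk_equations_file: risk_equations_synthetic_ukpds68.yaml
life_table_file: life_table_synthetic_uk.csv

# one-way sensitivity ranges: treatment effects at their 95% interval limits
# (SE from the indirect-comparison interval widths: HbA1c 0.089, weight 0.278);
# disutilities +/-10%, total non-drug costs +/-25%
tornado:
  - {path: therapies.dpp4i_met.delta_weight,   low: -1.155,  high: -0.065}
  - {path: therapies.dapa_met.delta_weight,    low: -3.905,  high: -2.815}
  - {path: therapies.dapa_met.delta_hba1c,     low: -0.865,  high: -0.515}
  - {path: therapies.dpp4i_met.delta_hba1c,    low: -0.785,  high: -0.435}
  - {path: utilities.bmi_per_unit_increase,    low: 0.04248, high: 0.05192}
  - {path: utilities.bmi_per_unit_decrease,    low: 0.01539, high: 0.01881}
  - {path: utilities.complication_multiplier,  low: 0.90,    high: 1.10}
  - {path: costs.nondrug_multiplier,           low: 0.75,    high: 1.25}

# PSA distributions: beta for probabilities/utility anchors, gamma for costs
# and decrement magnitudes, normal for treatment effects; SE = interval
# width / 3.92 where an interval exists, otherwise the univariate-rule
# percentage of the mean
psa:
  - {path: therapies.dapa_met.delta_hba1c,     distribution: normal, mean: -0.69,  se: 0.089}
  - {path: therapies.dpp4i_met.delta_hba1c,    distribution: normal, mean: -0.61,  se: 0.089}
  - {path: therapies.dapa_met.delta_weight,    distribution: normal, mean: -3.36,  se: 0.278}
  - {path: therapies.dpp4i_met.delta_weight,   distribution: normal, mean: -0.61,  se: 0.278}
  - {path: therapies.dapa_met.p_discontinue,   distribution: beta,   mean: 0.081,  se: 0.0081}
  - {path: therapies.dpp4i_met.p_discontinue,  distribution: beta,   mean: 0.043,  se: 0.0043}
  - {path: therapies.dapa_met.p_uti,           distribution: beta,   mean: 0.074,  se: 0.0074}
  - {path: therapies.dpp4i_met.p_uti,          distribution: beta,   mean: 0.054,  se: 0.0054}
  - {path: therapies.dapa_met.p_genital_infection, distribution: beta, mean: 0.123, se: 0.0123}
  - {path: therapies.dapa_met.p_hypo_symptomatic,  distribution: beta, mean: 0.031, se: 0.0031}
  - {path: therapies.dpp4i_met.p_hypo_symptomatic, distribution: beta, mean: 0.046, se: 0.0046}
  - {path: utilities.bmi_per_unit_increase,    distribution: gamma,  mean: 0.0472, se: 0.00241}
  - {path: utilities.bmi_per_unit_decrease,    distribution: gamma,  mean: 0.0171, se: 0.00087}
  - {path: utilities.complication_multiplier,  distribution: normal, mean: 1.0,    se: 0.051}
  - {path: utilities.baseline_utility,         distribution: beta,   mean: 0.785,  se: 0.04}
  - {path: costs.nondrug_multiplier,           distribution: gamma,  mean: 1.0,    se: 0.1276}

assumptions:
  baseline_utility: >-
    assumption: event-free utility anchor not stated by the study inputs;
    0.785 adopted and varied in sensitivity analysis.
  weight_regain: >-
    assumption: weight regain end-point unstated beyond 'linear'; complete at
    5 years from line start, varied in sensitivity analysis.
  hba1c_drift: >-
    assumption: post-year-1 HbA1c progression slope 0.15 %-points/year
    (UKPDS-derived magnitude); SBP/lipid drift 0, matching their zero
    treatment effects.
  nocturnal_hypo: >-
    assumption: nocturnal hypoglycaemia has a printed disutility but no
    printed probability; default probability 0 with this config slot.
  metformin_on_insulin: >-
    assumption: metformin co-prescription continues on the insulin+MET line
    and stops on intensified insulin.
  renal_monitoring: >-
    assumption: renal-monitoring cost applied annually while on the SGLT2
    inhibitor only.
  risk_equations: >-
    synthetic: the referenced risk-equation file is a synthetic stand-in of
    UKPDS-68 character, not a verified transcription; the life table is a
    synthetic Gompertz fit of UK magnitude.
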