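# SYNTHETIC stand-in risk-equation set (see meta.note). Generated by
# t2dm_cesim.fixtures.synthetic_equations_document(); edit there, not here.
meta:
  name: risk_equations_synthetic_ukpds68
  synthetic: true
  note: 'Synthetic stand-in for the UKPDS-68 outcomes-model coefficient set: UKPDS-style
    Weibull proportional-hazards equations with intercepts calibrated to UKPDS-magnitude
    annual incidences at the base-case risk profile. Not a transcription of the published
    coefficients; replace this file with a verified transcription for production use.'
equations:
  ihd:
    form: weibull_cumhaz
    shape: 1.15
    intercept: -4.994897643438127
    coefficients:
      age_at_diagnosis: 0.031
      female: -0.532
      hba1c: 0.125
      sbp: 0.0058
      tc_hdl_ratio: 0.166
    centering:
      age_at_diagnosis: 51.5
      hba1c: 8.05
      sbp: 133.3
      tc_hdl_ratio: 4.526423225221138
    history_terms: {}
  mi:
    form: weibull_cumhaz
    shape: 1.257
    intercept: -4.560255926821315
    coefficients:
      age_at_diagnosis: 0.055
      female: -0.826
      afro_caribbean: -1.312
      smoker: 0.346
      hba1c: 0.118
      sbp: 0.0101
      tc_hdl_ratio: 0.139
    centering:
      age_at_diagnosis: 51.5
      hba1c: 8.05
      sbp: 133.3
      tc_hdl_ratio: 4.526423225221138
    history_terms:
      ihd: 0.41
  chf:
    form: weibull_cumhaz
    shape: 1.711
    intercept: -7.164632274281345
    coefficients:
      age_at_diagnosis: 0.093
      hba1c: 0.157
      sbp: 0.0114
      bmi: 0.072
    centering:
      age_at_diagnosis: 51.5
      hba1c: 8.05
      sbp: 133.3
      bmi: 30.755225657364942
    history_terms: {}
  stroke:
    form: weibull_cumhaz
    shape: 1.497
    intercept: -6.181076607471386
    coefficients:
      age_at_diagnosis: 0.085
      female: -0.516
      smoker: 0.355
      hba1c: 0.128
      sbp: 0.017
      tc_hdl_ratio: 0.127
    centering:
      age_at_diagnosis: 51.5
      hba1c: 8.05
      sbp: 133.3
      tc_hdl_ratio: 4.526423225221138
    history_terms:
      mi: 0.55
  amputation:
    form: weibull_cumhaz
    shape: 2.067
    intercept: -9.211136502707129
    coefficients:
      age_at_diagnosis: 0.023
      female: -0.445
      smoker: 0.525
      hba1c: 0.435
      sbp: 0.0228
    centering:
      age_at_diagnosis: 51.5
      hba1c: 8.05
      sbp: 133.3
    history_terms: {}
  blindness:
    form: weibull_cumhaz
    shape: 1.154
    intercept: -5.951057722833615
    coefficients:
      age_at_diagnosis: 0.069
      hba1c: 0.221
      sbp: 0.0101
    centering:
      age_at_diagnosis: 51.5
      hba1c: 8.05
      sbp: 133.3
    history_terms: {}
  esrd:
    form: weibull_cumhaz
    shape: 1.865
    intercept: -9.150839855251261
    coefficients:
      hba1c: 0.156
      sbp: 0.0404
    centering:
      hba1c: 8.05
      sbp: 133.3
    history_terms: {}
  cv_death:
    form: weibull_cumhaz
    shape: 1.6
    intercept: -6.493255959449769
    coefficients:
      age_at_diagnosis: 0.098
      female: -0.4
      smoker: 0.35
      hba1c: 0.15
      sbp: 0.012
      tc_hdl_ratio: 0.14
    centering:
      age_at_diagnosis: 51.5
      hba1c: 8.05
      sbp: 133.3
      tc_hdl_ratio: 4.526423225221138
    history_terms:
      mi: 1.13
      stroke: 0.71
      chf: 0.78
      amputation: 0.59
      esrd: 1.55
      ihd: 0.3
  diabetes_death:
    form: weibull_cumhaz
    shape: 1.2
    intercept: -7.464086965171758
    coefficients:
      hba1c: 0.2
    centering:
      hba1c: 8.05
    history_terms:
      esrd: 2.0
      amputation: 1.0
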