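# Methods

## Model overview

`t2dm_cesim` is a patient-level (first-order Monte Carlo) cost-effectiveness
model of second-line therapy in type 2 diabetes: dapagliflozin added to
metformin (DAPA+MET) against a DPP-4 inhibitor added to metformin
(DPP-4i+MET), from a UK health-service perspective. Patients are simulated
individually through 6-month cycles over a 40-year horizon. The cohort is
homogeneous at baseline (mean risk-factor values; sex, smoking and ethnicity
drawn at the cohort prevalences), which reflects the mean-value cohort design
of the analysis the model implements; per-patient baseline dispersion is
available as an optional extension (`fixtures.make_heterogeneous_cohort`) for
testing heterogeneity, not used in the base case.

Within each cycle, in a fixed, documented order:

1. risk factors (HbA1c, weight → BMI) are evaluated from the current
   treatment line's trajectories;
2. seven complications (IHD, MI, congestive heart failure, stroke,
   amputation, blindness, end-stage renal disease) are drawn from parametric
   risk equations, first occurrence only — a complication enters the
   patient's history once and stays there;
3. death is drawn from three competing sources with fixed precedence:
   cardiovascular death, other diabetes-related death (both risk equations),
   then background all-cause mortality from a sex-specific life table applied
   only to patients not already dead of a diabetes-related cause;
4. adverse events (symptomatic/severe/nocturnal hypoglycaemia, urinary tract
   infection, genital infection) are drawn as independent per-cycle
   Bernoulli events; treatment discontinuation is drawn in the first cycle
   only;
5. costs and utility are accrued (discounting below);
6. history, age and diabetes duration advance by half a year;
7. the switching rule is applied to the end-of-cycle HbA1c.

A fixed number of uniform variates (16 channels) is consumed per cycle
regardless of parameter values. Two runs from the same seed therefore differ
only through parameters that actually changed — the contract the tornado
analysis and several tests rely on.

## Risk equations

Equations follow the UKPDS outcomes-model convention: proportional hazards on
centred covariates with, for most events, a Weibull cumulative hazard on the
diabetes-duration timescale, H(t) = exp(lp)·t^s. The annual probability in
duration year (d, d+1] is 1 − exp(H(d) − H(d+1)); annual probabilities are
converted to cycle length c through the rate scale, p_c = 1 − (1 − p)^c.
Constant-hazard and annual-logistic forms are also supported (the constant
form is the backbone of the closed-form test fixtures). Prior events shift
the linear predictors of the death equations (and MI/stroke equations)
additively. Centring constants live in the coefficient file, not in code.

**The shipped coefficient set is a synthetic stand-in.** The published
UKPDS-68 coefficients are external to this repository; the packaged
`risk_equations_synthetic_ukpds68.yaml` (generated by
`fixtures.build_synthetic_ukpds_equations`, and clearly labelled synthetic)
uses UKPDS-style functional forms, UKPDS-magnitude slope coefficients, and
intercepts calibrated in closed form so that the annual event probabilities
at the base-case risk profile equal target incidences of UKPDS-cohort
magnitude (MI 1.5%/yr, IHD 0.8%, stroke 0.7%, CHF 0.5%, blindness 0.4%,
amputation 0.15%, ESRD 0.1%, CV death 0.7%, other diabetes death 0.1%, all
at duration year 6–7). The calibration identity is unit-tested. A verified
transcription can be dropped in by replacing the file; the engine reads any
coefficient set matching the schema. The same applies to background
mortality: `life_table_synthetic_uk.csv` is a Gompertz table
(μ(x) = A·e^(0.09x), female hazard 60% of male) matched to UK
interim-life-table magnitudes, not a transcription.

Consequences: *incremental* results, which difference out most of the
absolute event burden, are the quantities this model is built to estimate;
absolute per-arm totals (costs, LYs, QALYs) depend directly on the stand-in
calibration and should be read as order-of-magnitude only.

## Treatment pathway

Three lines per arm: DAPA+MET or DPP-4i+MET, then basal insulin + MET, then
intensified insulin (dose +50%, absorbing). Each line applies its one-year
HbA1c and weight effects as a linear ramp over the first year on the line
(a step-at-entry mode is available via `run.effect_mode`). After the effect
year, HbA1c rises by a disease-progression drift, default
**+0.15 %-points/year** — a commonly used UKPDS-derived progression
magnitude; the exact regression path is not public, so the slope is a
config assumption, flagged and varied in sensitivity analysis. SBP and the
cholesterol ratio carry zero treatment effects and zero drift by default.

Switching: a patient moves to the next line at the end of the first cycle in
which HbA1c has climbed back to the threshold (≥, default 8.05% = mean
baseline HbA1c). Discontinuation (first cycle only; 8.1% DAPA, 4.3% DPP-4i)
moves the patient to the insulin line from the second cycle and incurs a £36
cost. The new line re-anchors its effects to the *current* simulated HbA1c
and weight.

Weight on a line: linear change to entry weight + Δ over year 1, flat
through year 2, then linear regain to the entry weight, complete at year 5
from line start. The regain end-point is not stated by the source inputs;
5 years is the package's default, exposed in config. Because lines re-anchor
to the weight at entry, a patient who leaves a line mid-trajectory (e.g. an
early discontinuer) keeps that line's partial weight change as the new
anchor — an intentional, documented consequence of the re-anchoring design.

## Economics

Discounting is 3.5%/year for costs and effects, applied at cycle start; no
half-cycle discounting correction is made (with 6-month cycles the error is
second-order). Patients dying within a cycle accrue *continuous* quantities
— life-years, QALYs, drug and maintenance costs — for half the cycle (the
mid-interval death convention) and one-off event costs in full; patients
dead at cycle start accrue nothing. The mid-interval convention makes
expected life-years under a constant hazard equal the continuous closed form
(1 − e^(−40h))/h to second order in the cycle length, which the test suite
exploits as an oracle.

Costs (GBP, 2011 price year): fixed annual acquisition costs for the oral
lines (+£23.46/yr metformin where co-prescribed; metformin continues on the
insulin+MET line and stops on intensified insulin); weight-based insulin
dosing (£0.0053/kg/day basal, £0.008/kg/day intensified — £170.24 and
£256.96 per year at 88 kg); complication costs as one-off fatal/non-fatal
amounts plus annual maintenance while in history, with the fatal amount
replacing the non-fatal one when the patient dies in the event cycle;
£390 per severe hypoglycaemic event; £36 per UTI/genital infection and per
discontinuation; £38.67/yr renal monitoring while on the SGLT2 inhibitor
only (config-switchable).

Utility: an event-free anchor (default **0.785** — not stated by the source
inputs; flagged as an assumption and varied in SA) minus persistent
decrements for complications in history (MI 0.550, stroke 0.164, ESRD 0.263,
amputation 0.280, CHF 0.108, IHD 0.090, blindness 0.074), minus transient
decrements in the event cycle for hypoglycaemia (0.042/0.047/0.008) and
infections (0.00283), plus an asymmetric BMI term relative to baseline BMI:
+0.0171 per unit below, −0.0472 per unit above. Utility is not clamped at
zero (clamping would silently bias; a warning is logged once).

## Comparison, uncertainty, scenarios

The base case runs replicate cohorts per arm with independent RNG streams
per (cohort, arm) spawned from one master seed (a common-random-numbers mode
exists but is off by default; the replicate spread of the incremental
results is wide, consistent with independently simulated arms). ΔC, ΔE and
the ICER come from the grand means; 95% intervals are 2.5/97.5 percentiles
of per-cohort increments. Dominance is labelled rather than divided through.

Tornado: each parameter in turn at its low/high bound (treatment effects at
95% limits, with SEs from the indirect-comparison interval widths — HbA1c
0.089 %-points, weight 0.278 kg; disutilities ±10%; total non-drug costs
±25% via a single multiplier), full comparison at each bound from the same
master seed; sorted by ΔQALY range.

PSA: all declared parameters drawn jointly and independently — normal for
treatment effects, beta for probabilities and the utility anchor, gamma for
positive magnitudes (cost multiplier, BMI utility slopes) — one cohort per
arm per draw; CEAC = fraction of draws with λ·ΔE − ΔC ≥ 0 (ties count as
cost-effective; the tie event has probability zero).

Scenarios shipped: switching threshold 8.5%; dapagliflozin HbA1c effect at
its 95% limits; alternative BMI utilities (values caller-supplied). Scenario
contrasts should be run paired (same master seed as the base run): the fixed
per-cycle draw consumption then cancels replicate noise, leaving the
structural effect. One structural behaviour worth knowing: because the weight
regain clock starts at line entry and completes at year 5, raising the
switching threshold extends the expensive first line without extending the
BMI-utility benefit, so both ΔC and ΔE rise modestly and the ICER drifts
slightly *up*. A model in which weight regain is triggered by treatment
discontinuation instead would tie the benefit to treatment duration and push
the scenario ICER the other way; that variant is not implemented here.

## Problem sizes and numerical choices

The engine advances the whole cohort as numpy arrays (~1 s per 30,000-patient
arm over 80 cycles), so the study-scale cohort size is kept everywhere.
Replicate counts are scaled down as the package's default analysis sizes:
base case 20 cohorts × 30,000 (study: 100), scenario runs 10 × 30,000, PSA
200 draws × 30,000 per arm (study: 1,000 draws). Patients-per-draw is
deliberately *not* reduced in the PSA: the CEAC mixes parameter uncertainty
with sampling noise, and shrinking the per-draw cohort would inflate the
noise component and mechanically pull the curve toward 50%. All sizes are
flags on the drivers and first-class config fields.

Tie-breaks and edge rules: life-table age bands are half-open [lo, hi), ages
beyond coverage use the terminal band (logged once); switching uses ≥ at the
threshold; an annual probability of exactly 1 converts to cycle probability
1 with a warning (the rate is undefined); probabilities are clipped to
[0, 1] after the exponential maps; non-finite accumulators or probabilities
raise named errors.

## What the synthetic fixtures do and do not show

The toy constant-hazard models (`fixtures.make_toy_risk_model`) exist so
every engine mechanism is testable against closed forms: truncated-
exponential life expectancy, first-occurrence event counts under competing
risks, discounted accrual streams. They emulate the *mechanics* of the
pipeline, not clinical reality. Passing those tests shows the simulation
arithmetic is right; it does not validate the synthetic UKPDS-style
calibration against real epidemiology. Similarly, headline incremental
results produced with the synthetic stand-ins reproduce the *structure* of
the published comparison (signs, ICER region, drivers of sensitivity), and
their agreement in magnitude is a tolerance-band statement, not a
replication of the published point estimates.

## Known limitations

* UKPDS-68 coefficients and the UK life table are synthetic stand-ins (see
  above); absolute totals are calibration-dependent.
* Less severe health states (microalbuminuria, foot ulcer) are out of scope,
  as are repeat events of the same complication.
* The HbA1c progression is a linear drift, not the full UKPDS
  autoregressive risk-factor path; SBP/lipids are flat.
* CV death is an independent equation rather than a case-fatality model tied
  to incident events; fatal-event costing uses same-cycle coincidence of an
  incident event and a diabetes-related death.
* The event-free utility anchor and the weight-regain end-point are
  assumptions (flagged in config, varied in SA).
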