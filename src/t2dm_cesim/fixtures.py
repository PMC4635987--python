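"""Synthetic inputs: base-case config, risk-equation stand-ins, toy models.

Everything the pipeline needs ships with the package or is generated here:

* ``make_base_case_config`` — the versioned base-case transcription of the
  study inputs (the single place those numbers live), referencing the packaged
  risk-equation and life-table files.
* ``build_synthetic_ukpds_equations`` — the synthetic stand-in for the UKPDS-68
  coefficient set: Weibull proportional-hazards equations on the
  diabetes-duration timescale whose intercepts are calibrated in closed form so
  the annual event probabilities at the base-case risk profile equal stated
  target incidences of UKPDS-cohort magnitude. The packaged
  ``risk_equations_synthetic_ukpds68.yaml`` is generated by this function.
* ``make_gompertz_life_table`` — a synthetic sex-specific life table with
  Gompertz hazard, parameterised to UK-interim-life-table magnitudes; also a
  flat variant for closed-form tests.
* ``make_toy_risk_model`` — constant-hazard equation sets whose survival and
  event-count expectations have closed forms (embedded in the returned
  ToyModelSpec so tests never duplicate them).
* ``make_heterogeneous_cohort`` — optional per-patient baseline dispersion
  around the cohort means (zero dispersion reproduces the mean-value cohort).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import RunConfig, load_and_validate
from .errors import ConfigurationError
from .risk_engine import COMPLICATIONS, LifeTable, RiskEquationSpec
from .simulate import CohortBaseline

_DATA = Path(__file__).parent / "data"

BASE_CASE_FILE = _DATA / "base_case.yaml"


def make_base_case_config() -> RunConfig:
    """Load and validate the packaged base-case configuration."""
    return load_and_validate(BASE_CASE_FILE)


# --- synthetic UKPDS-68-style equation set -------------------------------
#
# Slope coefficients are of the magnitude reported for the UKPDS risk-equation
# set (log-hazard per unit of each centred risk factor); they are NOT a
# verified transcription of the published coefficients, which is why the set
# is labelled synthetic. Intercepts are calibrated so that, at the base-case
# risk profile (the centring point, with sex/smoking/ethnicity at cohort
# prevalences), the annual probability of each event in duration year
# (6.01, 7.01] equals the target incidence below.

_BASELINE = CohortBaseline()

#: centring constants = the base-case risk profile
_SYNTH_CENTRES = {
    "age_at_diagnosis": _BASELINE.age - _BASELINE.duration,
    "hba1c": _BASELINE.hba1c,
    "sbp": _BASELINE.sbp,
    "tc_hdl_ratio": _BASELINE.tc_hdl_ratio,
    "bmi": _BASELINE.bmi,
}

_SYNTH_PREVALENCE = {"female": 0.47, "smoker": 0.369, "afro_caribbean": 0.062}

#: event -> (shape, target annual probability at baseline, coefficient map)
_SYNTH_EQUATIONS: dict[str, tuple[float, float, dict[str, float]]] = {
    "ihd": (1.150, 0.008, {
        "age_at_diagnosis": 0.031, "female": -0.532, "hba1c": 0.125,
        "sbp": 0.0058, "tc_hdl_ratio": 0.166,
    }),
    "mi": (1.257, 0.015, {
        "age_at_diagnosis": 0.055, "female": -0.826, "afro_caribbean": -1.312,
        "smoker": 0.346, "hba1c": 0.118, "sbp": 0.0101, "tc_hdl_ratio": 0.139,
    }),
    "chf": (1.711, 0.005, {
        "age_at_diagnosis": 0.093, "hba1c": 0.157, "sbp": 0.0114, "bmi": 0.072,
    }),
    "stroke": (1.497, 0.007, {
        "age_at_diagnosis": 0.085, "female": -0.516, "smoker": 0.355,
        "hba1c": 0.128, "sbp": 0.0170, "tc_hdl_ratio": 0.127,
    }),
    "amputation": (2.067, 0.0015, {
        "age_at_diagnosis": 0.023, "female": -0.445, "smoker": 0.525,
        "hba1c": 0.435, "sbp": 0.0228,
    }),
    "blindness": (1.154, 0.004, {
        "age_at_diagnosis": 0.069, "hba1c": 0.221, "sbp": 0.0101,
    }),
    "esrd": (1.865, 0.001, {
        "hba1c": 0.156, "sbp": 0.0404,
    }),
    "cv_death": (1.600, 0.007, {
        "age_at_diagnosis": 0.098, "female": -0.400, "smoker": 0.350,
        "hba1c": 0.150, "sbp": 0.0120, "tc_hdl_ratio": 0.140,
    }),
    "diabetes_death": (1.200, 0.001, {
        "hba1c": 0.200,
    }),
}

#: prior-event shifts on the death-equation linear predictors
_SYNTH_HISTORY_TERMS = {
    "cv_death": {"mi": 1.13, "stroke": 0.71, "chf": 0.78, "amputation": 0.59,
                 "esrd": 1.55, "ihd": 0.30},
    "diabetes_death": {"esrd": 2.00, "amputation": 1.00},
    "mi": {"ihd": 0.41},
    "stroke": {"mi": 0.55},
}

_SYNTH_BASELINE_DURATION = 6.01


def build_synthetic_ukpds_equations() -> dict[str, RiskEquationSpec]:
    """Construct the synthetic stand-in equation set (see module docstring).

    Calibration: with covariates at their centres the linear predictor for the
    mean cohort member is intercept + sum(prevalence * boolean slope), and the
    annual probability in (d0, d0+1] is 1 - exp(-exp(lp) * ((d0+1)^s - d0^s)).
    Solving for the intercept at the target probability:
    intercept = ln(-ln(1-p)) - ln((d0+1)^s - d0^s) - sum(prevalence * slope).
    """
    d0 = _SYNTH_BASELINE_DURATION
    out = {}
    for event_id, (shape, target_p, coeffs) in _SYNTH_EQUATIONS.items():
        time_term = (d0 + 1.0) ** shape - d0**shape
        boolean_offset = sum(
            _SYNTH_PREVALENCE[name] * beta
            for name, beta in coeffs.items()
            if name in _SYNTH_PREVALENCE
        )
        intercept = math.log(-math.log1p(-target_p)) - math.log(time_term) - boolean_offset
        centering = {n: _SYNTH_CENTRES[n] for n in coeffs if n in _SYNTH_CENTRES}
        out[event_id] = RiskEquationSpec(
            event_id=event_id,
            form="weibull_cumhaz",
            shape=shape,
            intercept=intercept,
            coefficients=dict(coeffs),
            centering=centering,
            history_terms=dict(_SYNTH_HISTORY_TERMS.get(event_id, {})),
        )
    return out


def synthetic_equations_document() -> dict:
    """The YAML-serialisable document for the packaged synthetic equation file."""
    eqs = build_synthetic_ukpds_equations()
    return {
        "meta": {
            "name": "risk_equations_synthetic_ukpds68",
            "synthetic": True,
            "note": (
                "Synthetic stand-in for the UKPDS-68 outcomes-model coefficient set: "
                "UKPDS-style Weibull proportional-hazards equations with intercepts "
                "calibrated to UKPDS-magnitude annual incidences at the base-case "
                "risk profile. Not a transcription of the published coefficients; "
                "replace this file with a verified transcription for production use."
            ),
        },
        "equations": {
            ev: {
                "form": s.form,
                "shape": s.shape,
                "intercept": s.intercept,
                "coefficients": s.coefficients,
                "centering": s.centering,
                "history_terms": s.history_terms,
            }
            for ev, s in eqs.items()
        },
    }


# --- life tables ----------------------------------------------------------

def make_gompertz_life_table(
    a_male: float = 4.1e-5,
    b: float = 0.09,
    female_factor: float = 0.60,
    age_lo: int = 18,
    age_hi: int = 110,
) -> pd.DataFrame:
    """Synthetic sex-specific life table with Gompertz hazard mu(x) = A e^(Bx).

    Defaults give annual mortality of UK-interim-life-table magnitude
    (male q(60) ~ 0.009, q(80) ~ 0.055); female hazard is a constant fraction
    of male. One-year bands [x, x+1) from ``age_lo`` to ``age_hi``.
    """
    rows = []
    for sex, scale in (("male", a_male), ("female", a_male * female_factor)):
        for x in range(age_lo, age_hi):
            cum = scale / b * (math.exp(b * (x + 1)) - math.exp(b * x))
            rows.append({"age_lo": x, "age_hi": x + 1, "sex": sex, "q_annual": 1 - math.exp(-cum)})
    return pd.DataFrame(rows)


def make_flat_life_table(q_annual: float = 0.0, age_lo: int = 0, age_hi: int = 130) -> LifeTable:
    """Single-band life table with a constant annual mortality probability."""
    rows = [
        {"age_lo": age_lo, "age_hi": age_hi, "sex": sex, "q_annual": q_annual}
        for sex in ("male", "female")
    ]
    return LifeTable(pd.DataFrame(rows))


# --- toy constant-hazard models ------------------------------------------

@dataclass
class ToyModelSpec:
    """A constant-hazard model with its closed-form expectations embedded."""

    rates: dict[str, float]
    background_annual_q: float
    horizon_years: float
    cycle_years: float
    equations: dict[str, RiskEquationSpec] = field(default_factory=dict)
    life_table: LifeTable | None = None

    @property
    def death_rate(self) -> float:
        r = sum(v for k, v in self.rates.items() if k in ("cv_death", "diabetes_death"))
        if self.background_annual_q > 0:
            r += -math.log1p(-self.background_annual_q)
        return r

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon_years / self.cycle_years))

    def expected_life_years(self) -> float:
        """Exact expectation under the engine's cycle/death conventions.

        Death is drawn per cycle with probability q = 1 - exp(-R*cycle); a
        patient surviving a cycle accrues the full cycle, one dying accrues
        half (mid-interval convention).
        """
        R = self.death_rate
        cy = self.cycle_years
        if R == 0:
            return self.horizon_years
        q = 1 - math.exp(-R * cy)
        s = 1 - q
        per_cycle = s * cy + q * cy / 2.0
        # sum_{k=0}^{N-1} s^k * per_cycle
        return per_cycle * (1 - s**self.n_cycles) / (1 - s)

    def expected_life_years_continuous(self) -> float:
        """Continuous-time truncated-exponential expectation (1-e^(-RT))/R."""
        R = self.death_rate
        if R == 0:
            return self.horizon_years
        return (1 - math.exp(-R * self.horizon_years)) / R

    def expected_event_count(self, event: str) -> float:
        """P(first occurrence of a complication within the horizon), exact.

        The event is drawn each cycle with probability q_e while the patient
        is alive and event-free; death (rate R) competes within each cycle.
        """
        r = self.rates[event]
        cy = self.cycle_years
        q_e = 1 - math.exp(-r * cy)
        s_d = math.exp(-self.death_rate * cy)
        # occurs in cycle k: survived death draws 0..k-1 and no prior event;
        # both event and death can fire in the same cycle (event drawn first),
        # so the event draw in cycle k only needs survival through k-1 cycles.
        ratio = s_d * (1 - q_e)
        n = self.n_cycles
        if ratio == 1.0:
            return q_e * n
        return q_e * (1 - ratio**n) / (1 - ratio)


def make_toy_risk_model(
    rates: Mapping[str, float],
    background_annual_q: float = 0.0,
    horizon_years: float = 40.0,
    cycle_years: float = 0.5,
) -> ToyModelSpec:
    """Constant-hazard equation set + flat life table with closed-form oracle.

    ``rates`` maps event ids (complications and/or ``cv_death`` /
    ``diabetes_death``) to constant annual hazards; zero-rate events are
    omitted from the equation set.
    """
    known = set(COMPLICATIONS) | {"cv_death", "diabetes_death"}
    unknown = set(rates) - known
    if unknown:
        raise ConfigurationError(f"unknown event ids in toy model: {sorted(unknown)}")
    if any(r < 0 for r in rates.values()):
        raise ConfigurationError("toy-model rates must be >= 0")
    equations = {
        ev: RiskEquationSpec(event_id=ev, form="constant_hazard", intercept=math.log(r))
        for ev, r in rates.items()
        if r > 0
    }
    return ToyModelSpec(
        rates=dict(rates),
        background_annual_q=background_annual_q,
        horizon_years=horizon_years,
        cycle_years=cycle_years,
        equations=equations,
        life_table=make_flat_life_table(background_annual_q),
    )


def make_toy_model_inputs(
    toy: ToyModelSpec,
    baseline_utility: float = 1.0,
    discount_rate: float = 0.0,
    therapy: "TherapyProfile | None" = None,
    switch_threshold: float = 19.0,
    **overrides,
) -> "ModelInputs":
    """ModelInputs wired to a toy constant-hazard model.

    Defaults isolate the survival process: a single zero-effect, zero-cost
    therapy line, switching threshold out of reach, utility 1, no discounting
    and zero unit costs, so life-years/QALYs follow the toy model's closed
    forms exactly. Any ModelInputs field can be overridden.
    """
    from .economics import ComplicationCost, CostInputs, DiscountSettings, UtilityInputs
    from .risk_engine import DriftSpec
    from .simulate import ModelInputs
    from .treatment import TherapyProfile, TreatmentSequence, WeightTrajectorySpec

    if therapy is None:
        therapy = TherapyProfile(name="null", delta_hba1c=0.0, delta_weight=0.0, annual_drug_cost=0.0)
    fields = dict(
        baseline=CohortBaseline(),
        sequence=TreatmentSequence(lines=[therapy], switch_threshold_hba1c=switch_threshold),
        weight_spec=WeightTrajectorySpec(),
        hba1c_drift=DriftSpec("hba1c", 0.0),
        equations=toy.equations,
        life_table=toy.life_table,
        costs=CostInputs(
            metformin_annual=0.0,
            complications={ev: ComplicationCost(fatal=None, nonfatal=0.0, maintenance=0.0) for ev in COMPLICATIONS},
            severe_hypo=0.0, uti=0.0, genital_infection=0.0,
            discontinuation=0.0, renal_monitoring_annual=0.0,
        ),
        utilities=UtilityInputs(
            baseline_utility=baseline_utility,
            complications={},
            hypo_symptomatic=0.0, hypo_nocturnal=0.0, hypo_severe=0.0,
            uti=0.0, genital_infection=0.0,
            bmi_per_unit_increase=0.0, bmi_per_unit_decrease=0.0,
        ),
        discount=DiscountSettings(rate=discount_rate),
        horizon_years=toy.horizon_years,
        cycle_years=toy.cycle_years,
    )
    fields.update(overrides)
    return ModelInputs(**fields)


# --- heterogeneous baseline cohorts --------------------------------------

_HET_GUARDS = {
    "age": (18.0, 120.0),
    "duration": (0.0, 80.0),
    "hba1c": (3.5, 19.5),
    "weight_kg": (30.0, 250.0),
    "sbp": (60.0, 260.0),
    "tc_hdl_ratio": (0.5, 20.0),
}


def make_heterogeneous_cohort(
    n: int,
    dispersions: Mapping[str, float],
    rng: np.random.Generator,
    means: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-patient baselines drawn normally around the cohort means.

    ``dispersions`` maps baseline columns (age, duration, hba1c, weight_kg,
    sbp, tc_hdl_ratio) to standard deviations; zero (or omitted) dispersion
    reproduces the mean-value cohort exactly. Out-of-guard draws (e.g. weight
    below 30 kg) are resampled.
    """
    b = CohortBaseline()
    defaults = {
        "age": b.age,
        "duration": b.duration,
        "hba1c": b.hba1c,
        "weight_kg": b.weight_kg,
        "sbp": b.sbp,
        "tc_hdl_ratio": b.tc_hdl_ratio,
    }
    if means:
        defaults.update(means)
    unknown = set(dispersions) - set(defaults)
    if unknown:
        raise ConfigurationError(f"unknown baseline columns: {sorted(unknown)}")
    if any(sd < 0 for sd in dispersions.values()):
        raise ConfigurationError("dispersions must be >= 0")
    cols = {}
    for name, mean in defaults.items():
        sd = dispersions.get(name, 0.0)
        if sd == 0:
            cols[name] = np.full(n, mean)
            continue
        lo, hi = _HET_GUARDS[name]
        vals = rng.normal(mean, sd, size=n)
        for _ in range(1000):
            bad = (vals < lo) | (vals > hi)
            if not bad.any():
                break
            vals[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        else:
            raise ConfigurationError(f"could not keep {name} within guards {lo}..{hi}")
        cols[name] = vals
    return pd.DataFrame(cols)
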