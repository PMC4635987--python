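"""Per-cycle complication and mortality risks from parametric risk equations.

The engine follows the UKPDS outcomes-model convention: each complication or
death cause has a proportional-hazards equation whose linear predictor is built
from centred risk factors (HbA1c, SBP, total:HDL cholesterol ratio, BMI,
demographics) plus additive terms for prior-event history. Three functional
forms are supported:

``weibull_cumhaz``
    Cumulative hazard H(t) = exp(lp) * t**shape on the diabetes-duration
    timescale; the annual event probability in year (d, d+1] is
    1 - exp(H(d) - H(d+1)).
``constant_hazard``
    Exponential special case, annual probability 1 - exp(-exp(lp)).
``logistic_annual``
    The linear predictor is a log-odds for the annual probability.

Annual probabilities are converted to the 6-month cycle by passing through the
rate scale: p_cycle = 1 - (1 - p_annual)**cycle_years. Background (non-diabetes)
mortality comes from a sex-specific life table with half-open [lo, hi) age
bands.

All functions broadcast over numpy arrays so a whole cohort is evaluated at
once; scalars work identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, NumericsError

logger = logging.getLogger(__name__)

#: Complication identifiers in fixed evaluation order.
COMPLICATIONS = ("ihd", "mi", "chf", "stroke", "amputation", "blindness", "esrd")
#: Death-cause identifiers evaluated after complications.
DEATH_CAUSES = ("cv_death", "diabetes_death")

VALID_FORMS = ("weibull_cumhaz", "logistic_annual", "constant_hazard")


@dataclass
class RiskFactorVector:
    """Modifiable and fixed risk factors for one patient or a cohort (arrays).

    ``tc_hdl_ratio`` is total cholesterol over HDL cholesterol (both mg/dL);
    ``bmi`` is weight/height^2 in kg/m^2. ``duration`` is years since diabetes
    diagnosis and is also the Weibull timescale.
    """

    age: np.ndarray | float
    female: np.ndarray | bool
    duration: np.ndarray | float
    hba1c: np.ndarray | float
    sbp: np.ndarray | float
    tc_hdl_ratio: np.ndarray | float
    bmi: np.ndarray | float
    smoker: np.ndarray | bool
    afro_caribbean: np.ndarray | bool

    def covariates(self) -> dict[str, np.ndarray | float]:
        """Named covariate map used to resolve equation coefficients.

        ``age_at_diagnosis`` is derived (age - duration); boolean factors are
        exposed as 0/1.
        """
        return {
            "age": self.age,
            "age_at_diagnosis": np.asarray(self.age) - np.asarray(self.duration),
            "duration": self.duration,
            "female": np.asarray(self.female, dtype=float),
            "hba1c": self.hba1c,
            "sbp": self.sbp,
            "tc_hdl_ratio": self.tc_hdl_ratio,
            "bmi": self.bmi,
            "smoker": np.asarray(self.smoker, dtype=float),
            "afro_caribbean": np.asarray(self.afro_caribbean, dtype=float),
        }

    def validate(self) -> None:
        """Range checks on scalar/summary level; raises ConfigurationError."""
        checks = [
            (np.all((np.asarray(self.hba1c) > 3) & (np.asarray(self.hba1c) < 20)), "hba1c must lie in (3, 20)"),
            (np.all(np.asarray(self.bmi) > 10), "bmi must exceed 10 kg/m^2"),
            (np.all((np.asarray(self.age) >= 18) & (np.asarray(self.age) <= 120)), "age must lie in [18, 120]"),
            (np.all(np.asarray(self.tc_hdl_ratio) > 0), "tc_hdl_ratio must be positive"),
            (np.all(np.asarray(self.duration) >= 0), "duration must be non-negative"),
        ]
        bad = [msg for ok, msg in checks if not ok]
        if bad:
            raise ConfigurationError("; ".join(bad))


@dataclass
class RiskEquationSpec:
    """One complication or death-cause equation.

    ``coefficients`` maps covariate names (see RiskFactorVector.covariates) to
    log-hazard (or log-odds) slopes; ``centering`` holds the constants
    subtracted from each covariate before the slope applies, so equation
    fidelity lives entirely in the coefficient file. ``history_terms`` are
    additive linear-predictor shifts for prior events.
    """

    event_id: str
    form: str
    intercept: float
    shape: float = 1.0
    coefficients: dict[str, float] = field(default_factory=dict)
    centering: dict[str, float] = field(default_factory=dict)
    history_terms: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.form not in VALID_FORMS:
            raise ConfigurationError(
                f"equation {self.event_id!r}: unknown form {self.form!r} (expected one of {VALID_FORMS})"
            )
        if not self.shape > 0:
            raise ConfigurationError(f"equation {self.event_id!r}: shape must be > 0, got {self.shape}")


@dataclass
class DriftSpec:
    """Post-treatment-effect disease-progression path for one risk factor.

    Only the linear form is used in the base case: the factor rises by
    ``slope_per_year`` for every year beyond the 1-year treatment-effect
    window. Slope 0 freezes the factor.
    """

    factor: str
    slope_per_year: float = 0.0


class LifeTable:
    """Sex-specific annual mortality probabilities over contiguous age bands.

    Bands are half-open [age_lo, age_hi). Ages at or beyond the last band's
    upper edge resolve to the terminal band (logged once).
    """

    REQUIRED_COLUMNS = ("age_lo", "age_hi", "sex", "q_annual")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED_COLUMNS if c not in table.columns]
        if missing:
            raise ConfigurationError(f"life table missing columns: {missing}")
        self._warned_above_coverage = False
        self._edges = {}
        self._q = {}
        for sex in ("male", "female"):
            rows = table[table["sex"] == sex].sort_values("age_lo")
            if rows.empty:
                raise ConfigurationError(f"life table has no rows for sex={sex!r}")
            lo = rows["age_lo"].to_numpy(dtype=float)
            hi = rows["age_hi"].to_numpy(dtype=float)
            q = rows["q_annual"].to_numpy(dtype=float)
            if np.any((q < 0) | (q > 1)):
                raise ConfigurationError(f"life table {sex} probabilities outside [0, 1]")
            if not np.allclose(lo[1:], hi[:-1]):
                raise ConfigurationError(f"life table {sex} age bands not contiguous")
            self._edges[sex] = (lo, hi)
            self._q[sex] = q
        self.table = table.reset_index(drop=True)

    @property
    def coverage(self) -> tuple[float, float]:
        lo, hi = self._edges["male"]
        return float(lo[0]), float(hi[-1])

    def annual_probability(self, age, female) -> np.ndarray:
        """Annual all-cause mortality probability for given ages and sexes."""
        age = np.atleast_1d(np.asarray(age, dtype=float))
        female = np.atleast_1d(np.asarray(female, dtype=bool))
        age, female = np.broadcast_arrays(age, female)
        out = np.empty(age.shape, dtype=float)
        for sex, is_f in (("male", False), ("female", True)):
            mask = female == is_f
            if not mask.any():
                continue
            lo, hi = self._edges[sex]
            if np.any(age[mask] < lo[0]):
                raise ConfigurationError(
                    f"age below life-table coverage [{lo[0]}, {hi[-1]}) for sex={sex}"
                )
            if np.any(age[mask] >= hi[-1]) and not self._warned_above_coverage:
                logger.warning(
                    "ages beyond life-table coverage (>= %s); using terminal band", hi[-1]
                )
                self._warned_above_coverage = True
            idx = np.clip(np.searchsorted(lo, age[mask], side="right") - 1, 0, len(lo) - 1)
            out[mask] = self._q[sex][idx]
        return out


def linear_predictor(
    spec: RiskEquationSpec,
    rf: RiskFactorVector,
    history: Mapping[str, np.ndarray | bool] | None = None,
) -> np.ndarray | float:
    """intercept + sum(coeff * (covariate - centre)) + sum(history terms).

    Raises ConfigurationError naming any covariate or history flag the state
    does not provide.
    """
    cov = rf.covariates()
    lp = np.asarray(spec.intercept, dtype=float)
    for name, beta in spec.coefficients.items():
        if name not in cov:
            raise ConfigurationError(
                f"equation {spec.event_id!r}: covariate {name!r} not in risk-factor vector"
            )
        centre = spec.centering.get(name, 0.0)
        lp = lp + beta * (np.asarray(cov[name], dtype=float) - centre)
    history = history or {}
    for name, beta in spec.history_terms.items():
        if name not in history:
            raise ConfigurationError(
                f"equation {spec.event_id!r}: history flag {name!r} not provided"
            )
        lp = lp + beta * np.asarray(history[name], dtype=float)
    return lp


def annual_event_probability(
    spec: RiskEquationSpec,
    rf: RiskFactorVector,
    history: Mapping[str, np.ndarray | bool] | None = None,
) -> np.ndarray | float:
    """Probability of the event in the coming year given current state.

    For ``weibull_cumhaz`` the year is (d, d+1] on the diabetes-duration
    timescale d = rf.duration.
    """
    lp = linear_predictor(spec, rf, history)
    if spec.form == "constant_hazard":
        p = -np.expm1(-np.exp(lp))
    elif spec.form == "weibull_cumhaz":
        d = np.asarray(rf.duration, dtype=float)
        if np.any(d < 0):
            raise ConfigurationError(f"equation {spec.event_id!r}: negative duration")
        # H(d+1) - H(d) with H(t) = exp(lp) * t**shape
        p = -np.expm1(-np.exp(lp) * ((d + 1.0) ** spec.shape - d**spec.shape))
    else:  # logistic_annual
        p = 1.0 / (1.0 + np.exp(-lp))
    if not np.all(np.isfinite(p)):
        raise NumericsError(f"non-finite probability from equation {spec.event_id!r}")
    return np.clip(p, 0.0, 1.0)


def annual_to_cycle(p_annual, cycle_years: float):
    """Convert an annual probability to a per-cycle one via the rate scale.

    1 - exp(ln(1 - p) * cycle_years) == 1 - (1 - p)**cycle_years. A probability
    of exactly 1 is returned as 1 with a warning (the rate is undefined).
    """
    if cycle_years <= 0:
        raise ConfigurationError(f"cycle_years must be positive, got {cycle_years}")
    p = np.asarray(p_annual, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ConfigurationError("annual probability outside [0, 1]")
    if np.any(p == 1.0):
        logger.warning("annual probability of 1 has no finite rate; cycle probability set to 1")
    with np.errstate(divide="ignore"):
        out = -np.expm1(np.log1p(-p) * cycle_years)
    out = np.where(p == 1.0, 1.0, out)
    return float(out) if np.isscalar(p_annual) else out


def background_mortality(age, female, lt: LifeTable, cycle_years: float):
    """Per-cycle all-cause background mortality from the life table."""
    q = lt.annual_probability(age, female)
    out = annual_to_cycle(q, cycle_years)
    if np.isscalar(age) or (np.asarray(age).ndim == 0):
        return float(np.asarray(out).reshape(-1)[0])
    return out


def progress_risk_factor(d: DriftSpec, current, duration_on_drift: float, cycle_years: float):
    """Advance a risk factor one cycle along its progression path.

    ``duration_on_drift`` is unused by the linear form (kept in the signature
    so non-linear paths can be added without touching callers).
    """
    return np.asarray(current, dtype=float) + d.slope_per_year * cycle_years


def drift_total(d: DriftSpec, years_on_drift: float) -> float:
    """Closed-form cumulative drift after ``years_on_drift`` years (linear form)."""
    return d.slope_per_year * max(years_on_drift, 0.0)
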