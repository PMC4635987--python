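"""Therapy lines, 1-year treatment effects, switching rule and weight trajectory.

Each therapy line carries a one-year HbA1c and weight effect (applied as a
linear ramp over the first year on the line by default, or as a step at line
start), per-cycle adverse-event probabilities, a first-cycle discontinuation
probability and its drug-cost parameters. Patients stay on a line until their
HbA1c climbs back to the switching threshold (default: the cohort's mean
baseline HbA1c, 8.05%), then move down the fixed sequence
first-line -> insulin+metformin -> intensified insulin (absorbing).

The weight path on a line: linear change to entry_weight + delta over year 1,
plateau through year 2, then linear return to the entry weight, complete by
``regain_complete_at`` years (default 5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigurationError
from .risk_engine import DriftSpec, drift_total

#: Adverse-event channels drawn every cycle, in fixed order.
ADVERSE_EVENTS = ("hypo_symptomatic", "hypo_severe", "hypo_nocturnal", "uti", "genital_infection")


@dataclass
class TherapyProfile:
    """One treatment line's effects, event probabilities and cost parameters.

    Exactly one of ``annual_drug_cost`` (fixed annual acquisition cost, GBP) or
    ``daily_cost_per_kg`` (weight-based dosing, GBP/kg/day) must be set.
    ``requires_renal_monitoring`` marks SGLT2-inhibitor lines that carry the
    annual renal-monitoring cost.
    """

    name: str
    delta_hba1c: float
    delta_weight: float
    p_discontinue: float = 0.0
    p_hypo_symptomatic: float = 0.0
    p_hypo_severe: float = 0.0
    p_hypo_nocturnal: float = 0.0
    p_uti: float = 0.0
    p_genital_infection: float = 0.0
    delta_sbp: float = 0.0
    delta_tc: float = 0.0
    delta_hdl: float = 0.0
    annual_drug_cost: Optional[float] = None
    daily_cost_per_kg: Optional[float] = None
    includes_metformin: bool = False
    requires_renal_monitoring: bool = False

    def __post_init__(self):
        for attr in ("p_discontinue", *(f"p_{e}" for e in ADVERSE_EVENTS)):
            p = getattr(self, attr)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"therapy {self.name!r}: {attr}={p} outside [0, 1]")
        if (self.annual_drug_cost is None) == (self.daily_cost_per_kg is None):
            raise ConfigurationError(
                f"therapy {self.name!r}: exactly one of annual_drug_cost / daily_cost_per_kg required"
            )

    def adverse_event_probabilities(self) -> dict[str, float]:
        return {e: getattr(self, f"p_{e}") for e in ADVERSE_EVENTS}


@dataclass
class TreatmentSequence:
    """Ordered therapy lines; the last line is absorbing."""

    lines: list[TherapyProfile]
    switch_threshold_hba1c: float = 8.05

    def __post_init__(self):
        if not self.lines:
            raise ConfigurationError("treatment sequence needs at least one line")
        if self.switch_threshold_hba1c < 6.5:
            raise ConfigurationError(
                f"switch threshold {self.switch_threshold_hba1c} below plausible floor 6.5%"
            )


@dataclass
class WeightTrajectorySpec:
    """Timing of the on-line weight path (years from line start)."""

    effect_year: float = 1.0
    plateau_through: float = 2.0
    regain_complete_at: float = 5.0

    def __post_init__(self):
        if not self.effect_year <= self.plateau_through <= self.regain_complete_at:
            raise ConfigurationError(
                "weight trajectory requires effect_year <= plateau_through <= regain_complete_at"
            )


def hba1c_path(
    entry_hba1c,
    therapy: TherapyProfile,
    t_on_line,
    drift: DriftSpec,
    effect_mode: str = "ramp",
):
    """HbA1c (%) at ``t_on_line`` years on a line starting from ``entry_hba1c``.

    The one-year effect is attained linearly over [0, 1) years (``ramp``) or
    immediately (``step``); beyond year 1 the disease-progression drift applies.
    """
    t = np.asarray(t_on_line, dtype=float)
    if np.any(t < 0):
        raise ConfigurationError("t_on_line must be non-negative")
    if effect_mode == "ramp":
        attained = np.minimum(t, 1.0)
    elif effect_mode == "step":
        attained = 1.0
    else:
        raise ConfigurationError(f"unknown effect_mode {effect_mode!r}")
    value = (
        np.asarray(entry_hba1c, dtype=float)
        + therapy.delta_hba1c * attained
        + drift.slope_per_year * np.maximum(t - 1.0, 0.0)
    )
    return value


def should_switch(current_hba1c, seq: TreatmentSequence):
    """True where HbA1c has climbed back to the switching threshold (>=)."""
    return np.asarray(current_hba1c, dtype=float) >= seq.switch_threshold_hba1c


def weight_shape(t_on_line, spec: WeightTrajectorySpec):
    """Fraction of the line's weight delta present at ``t_on_line`` years.

    Rises 0 -> 1 over the effect year, holds through the plateau, then falls
    linearly back to 0 by ``regain_complete_at``; continuous everywhere.
    """
    t = np.asarray(t_on_line, dtype=float)
    ramp = np.minimum(t / spec.effect_year, 1.0) if spec.effect_year > 0 else 1.0
    regain_span = spec.regain_complete_at - spec.plateau_through
    if regain_span > 0:
        fall = np.clip((spec.regain_complete_at - t) / regain_span, 0.0, 1.0)
    else:
        fall = np.where(t < spec.regain_complete_at, 1.0, 0.0)
    return np.minimum(ramp, fall)


def weight_at(t_on_line, entry_weight_kg, therapy: TherapyProfile, spec: WeightTrajectorySpec):
    """Weight (kg) on a line, anchored to the weight at line entry."""
    t = np.asarray(t_on_line, dtype=float)
    if np.any(t < 0):
        raise ConfigurationError("t_on_line must be non-negative")
    return np.asarray(entry_weight_kg, dtype=float) + therapy.delta_weight * weight_shape(t, spec)


def time_to_threshold(
    entry_hba1c: float,
    therapy: TherapyProfile,
    seq: TreatmentSequence,
    drift: DriftSpec,
    cycle_years: float,
    max_years: float = 200.0,
) -> float:
    """Deterministic years until the end-of-cycle HbA1c triggers a switch.

    Closed-form companion to the engine's switching rule (used by tests and
    the tornado narrative): returns the first multiple of ``cycle_years`` at
    which hba1c_path >= threshold, or inf if never reached within max_years.
    """
    n = int(round(max_years / cycle_years))
    for k in range(1, n + 1):
        t = k * cycle_years
        if hba1c_path(entry_hba1c, therapy, t, drift) >= seq.switch_threshold_hba1c:
            return t
    return float("inf")


def advance_line(state, seq: TreatmentSequence, mask=None):
    """Move (masked) patients to the next line; absorbing at the last line.

    ``state`` is any object with array attributes ``line_index``, ``t_on_line``,
    ``entry_hba1c``, ``entry_weight``, ``hba1c``, ``weight`` (the engine's
    cohort state or a single-patient record). Line entry re-anchors the HbA1c
    and weight paths to their current simulated values and resets the clock.
    """
    last = len(seq.lines) - 1
    movable = state.line_index < last
    if mask is not None:
        movable = movable & np.asarray(mask, dtype=bool)
    state.line_index = np.where(movable, state.line_index + 1, state.line_index)
    state.t_on_line = np.where(movable, 0.0, state.t_on_line)
    state.entry_hba1c = np.where(movable, state.hba1c, state.entry_hba1c)
    state.entry_weight = np.where(movable, state.weight, state.entry_weight)
    return state


def sample_first_cycle_discontinuation(rng, therapy: TherapyProfile, cycle_index: int = 0, size=None):
    """Bernoulli(p_discontinue) draw; only valid in the first model cycle."""
    if cycle_index != 0:
        raise ConfigurationError(
            "first-cycle discontinuation sampled outside cycle 0 (contract violation)"
        )
    draw = rng.random(size) < therapy.p_discontinue
    return draw if size is not None else bool(draw)


def sample_adverse_events(rng, therapy: TherapyProfile, size=None) -> dict[str, np.ndarray]:
    """Independent per-cycle Bernoulli draws for each adverse-event channel."""
    probs = therapy.adverse_event_probabilities()
    return {e: rng.random(size) < p for e, p in probs.items()}


def hba1c_after(entry_hba1c: float, therapy: TherapyProfile, years: float, drift: DriftSpec) -> float:
    """Scalar convenience: HbA1c after ``years`` on a line (ramp mode)."""
    return float(
        entry_hba1c + therapy.delta_hba1c * min(years, 1.0) + drift_total(drift, years - 1.0)
    )
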