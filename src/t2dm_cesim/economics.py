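"""Cost and utility accrual with 3.5%/year discounting.

Costs (GBP, 2011 price year) split into:

* drug acquisition — fixed annual cost, or weight-based daily dosing for the
  insulin lines (GBP/kg/day x current weight x 365);
* complication costs — a one-off fatal or non-fatal cost in the event cycle,
  then an annual maintenance cost while the complication is in history;
* adverse-event, discontinuation and renal-monitoring costs.

Utility is an annual rate: an event-free anchor minus persistent decrements
for complications in history, minus transient decrements for the cycle's
hypoglycaemic/adverse events, plus an asymmetric BMI term relative to the
cohort's baseline BMI (+0.0171 per unit below, -0.0472 per unit above).
Discounting applies at cycle start for both costs and effects; there is no
half-cycle discounting correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConfigurationError
from .risk_engine import COMPLICATIONS
from .treatment import TherapyProfile

logger = logging.getLogger(__name__)


@dataclass
class ComplicationCost:
    """Fatal / non-fatal one-off costs and annual maintenance cost (GBP)."""

    fatal: float | None
    nonfatal: float
    maintenance: float


@dataclass
class CostInputs:
    metformin_annual: float
    complications: dict[str, ComplicationCost]
    severe_hypo: float = 390.0
    uti: float = 36.0
    genital_infection: float = 36.0
    discontinuation: float = 36.0
    renal_monitoring_annual: float = 38.67

    def __post_init__(self):
        unknown = set(self.complications) - set(COMPLICATIONS)
        if unknown:
            raise ConfigurationError(f"unknown complication ids in cost inputs: {sorted(unknown)}")


@dataclass
class UtilityInputs:
    """Annual utility anchor and decrements (all decrements as magnitudes)."""

    baseline_utility: float = 0.785
    complications: dict[str, float] = field(default_factory=dict)
    hypo_symptomatic: float = 0.042
    hypo_nocturnal: float = 0.008
    hypo_severe: float = 0.047
    uti: float = 0.00283
    genital_infection: float = 0.00283
    bmi_per_unit_increase: float = 0.0472
    bmi_per_unit_decrease: float = 0.0171

    def __post_init__(self):
        unknown = set(self.complications) - set(COMPLICATIONS)
        if unknown:
            raise ConfigurationError(f"unknown complication ids in utilities: {sorted(unknown)}")


@dataclass
class DiscountSettings:
    rate: float = 0.035

    def __post_init__(self):
        if self.rate < 0:
            raise ConfigurationError("discount rate must be >= 0")


def discount_factor(t, s: DiscountSettings):
    """(1 + rate)^(-t), evaluated at the cycle-start time t (years)."""
    return (1.0 + s.rate) ** (-np.asarray(t, dtype=float))


def cycle_drug_cost(therapy: TherapyProfile, weight_kg, cycle_years: float, ci: CostInputs):
    """Acquisition cost for one cycle, including metformin where co-prescribed."""
    if therapy.annual_drug_cost is not None:
        base = np.full_like(np.asarray(weight_kg, dtype=float), therapy.annual_drug_cost)
    else:
        base = therapy.daily_cost_per_kg * np.asarray(weight_kg, dtype=float) * 365.0
    if therapy.includes_metformin:
        base = base + ci.metformin_annual
    return base * cycle_years


def event_and_maintenance_costs(
    events: Mapping[str, np.ndarray | bool],
    history: Mapping[str, np.ndarray | bool],
    ci: CostInputs,
    cycle_years: float,
    *,
    fatal: np.ndarray | bool = False,
    ae_events: Mapping[str, np.ndarray | bool] | None = None,
    discontinued: np.ndarray | bool = False,
    maintenance_exposure_years: np.ndarray | float | None = None,
) -> np.ndarray | float:
    """Total complication + adverse-event costs for one cycle.

    ``events`` are this cycle's incident complications; where ``fatal`` is set
    (death in the same cycle) the fatal cost replaces the non-fatal one for
    complications that have a fatal price. ``history`` flags (state at cycle
    start) accrue maintenance at their annual rate over
    ``maintenance_exposure_years`` (defaults to ``cycle_years``; the engine
    passes half a cycle for patients dying within the cycle).
    """
    unknown = set(events) - set(COMPLICATIONS)
    if unknown:
        raise ConfigurationError(f"unknown event ids: {sorted(unknown)}")
    fatal = np.asarray(fatal, dtype=bool)
    exposure = cycle_years if maintenance_exposure_years is None else maintenance_exposure_years
    total = np.asarray(0.0)
    for ev, occurred in events.items():
        cc = ci.complications.get(ev)
        if cc is None:
            raise ConfigurationError(f"no cost entry for complication {ev!r}")
        occ = np.asarray(occurred, dtype=float)
        if cc.fatal is None:
            total = total + occ * cc.nonfatal
        else:
            total = total + occ * np.where(fatal, cc.fatal, cc.nonfatal)
    for ev, flag in history.items():
        cc = ci.complications.get(ev)
        if cc is None:
            raise ConfigurationError(f"no cost entry for complication {ev!r}")
        total = total + np.asarray(flag, dtype=float) * cc.maintenance * exposure
    if ae_events:
        ae_prices = {
            "hypo_severe": ci.severe_hypo,
            "uti": ci.uti,
            "genital_infection": ci.genital_infection,
            "hypo_symptomatic": 0.0,
            "hypo_nocturnal": 0.0,
        }
        for ev, occurred in ae_events.items():
            total = total + np.asarray(occurred, dtype=float) * ae_prices[ev]
    total = total + np.asarray(discontinued, dtype=float) * ci.discontinuation
    return total


_warned_negative_utility = False


def cycle_utility(
    history: Mapping[str, np.ndarray | bool],
    ae_events: Mapping[str, np.ndarray | bool],
    ui: UtilityInputs,
    bmi,
    baseline_bmi: float,
) -> np.ndarray | float:
    """Annual utility rate for the cycle.

    ``history`` should already include this cycle's incident complications
    (decrements persist from the event cycle onward); adverse-event and
    hypoglycaemia decrements apply in their event cycle only. The BMI term is
    asymmetric around the cohort baseline and the result is deliberately not
    clamped at 0 (a warning is logged once if it goes negative).
    """
    u = np.asarray(ui.baseline_utility, dtype=float)
    for ev, flag in history.items():
        u = u - ui.complications.get(ev, 0.0) * np.asarray(flag, dtype=float)
    ae_decrements = {
        "hypo_symptomatic": ui.hypo_symptomatic,
        "hypo_severe": ui.hypo_severe,
        "hypo_nocturnal": ui.hypo_nocturnal,
        "uti": ui.uti,
        "genital_infection": ui.genital_infection,
    }
    for ev, occurred in (ae_events or {}).items():
        u = u - ae_decrements[ev] * np.asarray(occurred, dtype=float)
    diff = np.asarray(bmi, dtype=float) - baseline_bmi
    bmi_term = np.where(diff >= 0, -ui.bmi_per_unit_increase * diff, ui.bmi_per_unit_decrease * (-diff))
    u = u + bmi_term
    global _warned_negative_utility
    if np.any(u < 0) and not _warned_negative_utility:
        logger.warning("cycle utility below 0 encountered; values are not clamped")
        _warned_negative_utility = True
    return u


@dataclass
class OutcomeAccumulator:
    """Per-patient running totals (arrays for a cohort)."""

    cost: np.ndarray | float = 0.0
    qaly: np.ndarray | float = 0.0
    ly: np.ndarray | float = 0.0
    ly_disc: np.ndarray | float = 0.0
    cost_undisc: np.ndarray | float = 0.0
    qaly_undisc: np.ndarray | float = 0.0


def accrue(
    acc: OutcomeAccumulator,
    cost,
    utility_rate,
    t: float,
    exposure_years,
    s: DiscountSettings,
) -> OutcomeAccumulator:
    """Add one cycle's discounted cost and QALYs to the accumulator.

    ``cost`` is the cycle's total monetary outlay; ``utility_rate`` the annual
    utility accrued over ``exposure_years`` of the cycle actually lived
    (0 for patients dead at cycle start). The discount factor is evaluated at
    the cycle-start time ``t``.
    """
    df = discount_factor(t, s)
    acc.cost = acc.cost + df * np.asarray(cost, dtype=float)
    acc.qaly = acc.qaly + df * np.asarray(utility_rate, dtype=float) * np.asarray(exposure_years, dtype=float)
    acc.ly = acc.ly + np.asarray(exposure_years, dtype=float)
    acc.ly_disc = acc.ly_disc + df * np.asarray(exposure_years, dtype=float)
    acc.cost_undisc = acc.cost_undisc + np.asarray(cost, dtype=float)
    acc.qaly_undisc = acc.qaly_undisc + np.asarray(utility_rate, dtype=float) * np.asarray(exposure_years, dtype=float)
    return acc
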