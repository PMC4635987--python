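"""Run configuration schema, validation, loading and result writers.

A run config is a single YAML document carrying the cohort baseline, the
therapy profiles and sequence for both arms, economic inputs, drift and
weight-trajectory assumptions, simulation settings, and the tornado/PSA
parameter lists. Risk-equation coefficients and the life table live in
separate files referenced by path (resolved relative to the config file, or to
the packaged data directory).

Validation is aggregated: ``load_and_validate`` reports every violation, not
just the first, and unknown keys are errors (no silent ignore).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, PrivateAttr, ValidationError

from .economics import ComplicationCost, CostInputs, DiscountSettings, UtilityInputs
from .errors import ConfigurationError, ConfigValidationError
from .risk_engine import COMPLICATIONS, DriftSpec, LifeTable, RiskEquationSpec
from .simulate import CohortBaseline, IncrementalResult, ModelInputs
from .treatment import TherapyProfile, TreatmentSequence, WeightTrajectorySpec

_PACKAGE_DATA = Path(__file__).parent / "data"

Probability = Field(ge=0.0, le=1.0)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MetaConfig(_Strict):
    name: str = "unnamed"
    version: str = "1"
    price_year: int = 2011
    currency: str = "GBP"


class RunSettings(_Strict):
    horizon_years: float = 40.0
    cycle_years: float = Field(default=0.5, gt=0)
    n_cohorts: int = Field(default=100, ge=1)
    n_patients: int = Field(default=30000, ge=1)
    seed: int = 12345
    common_random_numbers: bool = False
    effect_mode: Literal["ramp", "step"] = "ramp"


class CohortConfig(_Strict):
    age: float = Field(ge=18, le=120)
    prop_female: float = Probability
    duration: float = Field(ge=0)
    height_m: float = Field(gt=0.5, lt=2.5)
    prop_afro_caribbean: float = Probability
    prop_smoker: float = Probability
    hba1c: float = Field(gt=3, lt=20)
    weight_kg: float = Field(gt=30)
    sbp: float = Field(gt=0)
    tc_mgdl: float = Field(gt=0)
    hdl_mgdl: float = Field(gt=0)


class TherapyConfig(_Strict):
    delta_hba1c: float
    delta_weight: float
    p_discontinue: float = Probability
    p_hypo_symptomatic: float = Probability
    p_hypo_severe: float = Probability
    p_hypo_nocturnal: float = Probability
    p_uti: float = Probability
    p_genital_infection: float = Probability
    delta_sbp: float = 0.0
    delta_tc: float = 0.0
    delta_hdl: float = 0.0
    annual_drug_cost: Optional[float] = Field(default=None, ge=0)
    daily_cost_per_kg: Optional[float] = Field(default=None, ge=0)
    includes_metformin: bool = False
    requires_renal_monitoring: bool = False


class SequenceConfig(_Strict):
    arm_a: list[str]
    arm_b: list[str]
    switch_threshold_hba1c: float = Field(default=8.05, ge=6.5)


class WeightTrajectoryConfig(_Strict):
    effect_year: float = Field(default=1.0, ge=0)
    plateau_through: float = 2.0
    regain_complete_at: float = 5.0


class DriftConfig(_Strict):
    hba1c_slope_per_year: float = 0.15
    sbp_slope_per_year: float = 0.0
    tc_hdl_slope_per_year: float = 0.0


class ComplicationCostConfig(_Strict):
    fatal: Optional[float] = Field(default=None, ge=0)
    nonfatal: float = Field(ge=0)
    maintenance: float = Field(ge=0)


class CostConfig(_Strict):
    metformin_annual: float = Field(ge=0)
    severe_hypo: float = Field(default=390.0, ge=0)
    uti: float = Field(default=36.0, ge=0)
    genital_infection: float = Field(default=36.0, ge=0)
    discontinuation: float = Field(default=36.0, ge=0)
    renal_monitoring_annual: float = Field(default=38.67, ge=0)
    complications: dict[str, ComplicationCostConfig]
    nondrug_multiplier: float = Field(default=1.0, ge=0)


class UtilityConfig(_Strict):
    baseline_utility: float = Field(default=0.785, ge=0, le=1)
    complications: dict[str, float]
    hypo_symptomatic: float = Field(default=0.042, ge=0)
    hypo_nocturnal: float = Field(default=0.008, ge=0)
    hypo_severe: float = Field(default=0.047, ge=0)
    uti: float = Field(default=0.00283, ge=0)
    genital_infection: float = Field(default=0.00283, ge=0)
    bmi_per_unit_increase: float = Field(default=0.0472, ge=0)
    bmi_per_unit_decrease: float = Field(default=0.0171, ge=0)
    complication_multiplier: float = Field(default=1.0, ge=0)


class DiscountConfig(_Strict):
    rate: float = Field(default=0.035, ge=0)


class TornadoParam(_Strict):
    path: str
    low: float
    high: float


class PsaParam(_Strict):
    path: str
    distribution: Literal["normal", "beta", "gamma", "lognormal"]
    mean: float
    se: float = Field(ge=0)


class RunConfig(_Strict):
    meta: MetaConfig = MetaConfig()
    run: RunSettings = RunSettings()
    cohort: CohortConfig
    therapies: dict[str, TherapyConfig]
    sequence: SequenceConfig
    weight_trajectory: WeightTrajectoryConfig = WeightTrajectoryConfig()
    drift: DriftConfig = DriftConfig()
    costs: CostConfig
    utilities: UtilityConfig
    discount: DiscountConfig = DiscountConfig()
    risk_equations_file: str
    life_table_file: str
    tornado: list[TornadoParam] = []
    psa: list[PsaParam] = []
    assumptions: dict[str, str] = {}

    _base_dir: Optional[Path] = PrivateAttr(default=None)

    def resolve(self, name: str) -> Path:
        """Resolve a referenced file against the config dir, then package data."""
        p = Path(name)
        if p.is_absolute() and p.exists():
            return p
        for root in filter(None, [self._base_dir, _PACKAGE_DATA]):
            cand = Path(root) / name
            if cand.exists():
                return cand
        raise ConfigurationError(f"referenced file not found: {name!r}")

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def _semantic_violations(cfg: RunConfig) -> list[str]:
    """Cross-field checks pydantic cannot express field-locally."""
    out = []
    n = cfg.run.horizon_years / cfg.run.cycle_years
    if abs(n - round(n)) > 1e-9:
        out.append(
            f"non-integral cycle count: horizon {cfg.run.horizon_years} / cycle {cfg.run.cycle_years}"
        )
    for arm in ("arm_a", "arm_b"):
        for name in getattr(cfg.sequence, arm):
            if name not in cfg.therapies:
                out.append(f"sequence.{arm} references unknown therapy {name!r}")
    for name, t in cfg.therapies.items():
        if (t.annual_drug_cost is None) == (t.daily_cost_per_kg is None):
            out.append(
                f"therapies.{name}: exactly one of annual_drug_cost / daily_cost_per_kg required"
            )
    w = cfg.weight_trajectory
    if not w.effect_year <= w.plateau_through <= w.regain_complete_at:
        out.append("weight_trajectory: require effect_year <= plateau_through <= regain_complete_at")
    for coll, label in ((cfg.costs.complications, "costs"), (cfg.utilities.complications, "utilities")):
        unknown = set(coll) - set(COMPLICATIONS)
        if unknown:
            out.append(f"{label}.complications has unknown event ids: {sorted(unknown)}")
    for f in (cfg.risk_equations_file, cfg.life_table_file):
        try:
            cfg.resolve(f)
        except ConfigurationError as e:
            out.append(str(e))
    return out


def validate_config(cfg: RunConfig) -> None:
    violations = _semantic_violations(cfg)
    if violations:
        raise ConfigValidationError(violations)


def config_from_dict(payload: dict, base_dir: Path | None = None) -> RunConfig:
    violations: list[str] = []
    try:
        cfg = RunConfig.model_validate(payload)
    except ValidationError as err:
        for e in err.errors():
            loc = ".".join(str(p) for p in e["loc"])
            violations.append(f"{loc}: {e['msg']}")
        raise ConfigValidationError(violations) from err
    cfg._base_dir = base_dir
    violations = _semantic_violations(cfg)
    if violations:
        raise ConfigValidationError(violations)
    return cfg


def load_and_validate(path: str | Path) -> RunConfig:
    """Load a YAML run config; raise ConfigValidationError listing all violations."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict):
        raise ConfigValidationError(["config document is not a mapping"])
    return config_from_dict(payload, base_dir=path.parent)


def load_risk_equations(path: str | Path) -> dict[str, RiskEquationSpec]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    eqs = {}
    for event_id, spec in doc["equations"].items():
        eqs[event_id] = RiskEquationSpec(
            event_id=event_id,
            form=spec["form"],
            intercept=float(spec["intercept"]),
            shape=float(spec.get("shape", 1.0)),
            coefficients={k: float(v) for k, v in (spec.get("coefficients") or {}).items()},
            centering={k: float(v) for k, v in (spec.get("centering") or {}).items()},
            history_terms={k: float(v) for k, v in (spec.get("history_terms") or {}).items()},
        )
    return eqs


def load_life_table(path: str | Path) -> LifeTable:
    return LifeTable(pd.read_csv(path))


def _therapy_profile(name: str, tc: TherapyConfig) -> TherapyProfile:
    return TherapyProfile(
        name=name,
        delta_hba1c=tc.delta_hba1c,
        delta_weight=tc.delta_weight,
        p_discontinue=tc.p_discontinue,
        p_hypo_symptomatic=tc.p_hypo_symptomatic,
        p_hypo_severe=tc.p_hypo_severe,
        p_hypo_nocturnal=tc.p_hypo_nocturnal,
        p_uti=tc.p_uti,
        p_genital_infection=tc.p_genital_infection,
        delta_sbp=tc.delta_sbp,
        delta_tc=tc.delta_tc,
        delta_hdl=tc.delta_hdl,
        annual_drug_cost=tc.annual_drug_cost,
        daily_cost_per_kg=tc.daily_cost_per_kg,
        includes_metformin=tc.includes_metformin,
        requires_renal_monitoring=tc.requires_renal_monitoring,
    )


def build_model_inputs(
    cfg: RunConfig, arm: str, cohort_frame: pd.DataFrame | None = None
) -> ModelInputs:
    """Assemble one arm's ModelInputs from a validated config.

    ``arm`` is "a" (comparator) or "b" (intervention). The non-drug cost
    multiplier and complication-disutility multiplier are applied here, so
    sensitivity analyses can perturb them as single parameters.
    """
    if arm not in ("a", "b"):
        raise ConfigurationError(f"arm must be 'a' or 'b', got {arm!r}")
    line_names = cfg.sequence.arm_a if arm == "a" else cfg.sequence.arm_b
    lines = [_therapy_profile(n, cfg.therapies[n]) for n in line_names]
    m = cfg.costs.nondrug_multiplier
    costs = CostInputs(
        metformin_annual=cfg.costs.metformin_annual,
        complications={
            ev: ComplicationCost(
                fatal=None if cc.fatal is None else cc.fatal * m,
                nonfatal=cc.nonfatal * m,
                maintenance=cc.maintenance * m,
            )
            for ev, cc in cfg.costs.complications.items()
        },
        severe_hypo=cfg.costs.severe_hypo * m,
        uti=cfg.costs.uti * m,
        genital_infection=cfg.costs.genital_infection * m,
        discontinuation=cfg.costs.discontinuation * m,
        renal_monitoring_annual=cfg.costs.renal_monitoring_annual * m,
    )
    um = cfg.utilities.complication_multiplier
    utilities = UtilityInputs(
        baseline_utility=cfg.utilities.baseline_utility,
        complications={ev: d * um for ev, d in cfg.utilities.complications.items()},
        hypo_symptomatic=cfg.utilities.hypo_symptomatic,
        hypo_nocturnal=cfg.utilities.hypo_nocturnal,
        hypo_severe=cfg.utilities.hypo_severe,
        uti=cfg.utilities.uti,
        genital_infection=cfg.utilities.genital_infection,
        bmi_per_unit_increase=cfg.utilities.bmi_per_unit_increase,
        bmi_per_unit_decrease=cfg.utilities.bmi_per_unit_decrease,
    )
    return ModelInputs(
        baseline=CohortBaseline(**cfg.cohort.model_dump()),
        sequence=TreatmentSequence(
            lines=lines, switch_threshold_hba1c=cfg.sequence.switch_threshold_hba1c
        ),
        weight_spec=WeightTrajectorySpec(**cfg.weight_trajectory.model_dump()),
        hba1c_drift=DriftSpec("hba1c", cfg.drift.hba1c_slope_per_year),
        equations=load_risk_equations(cfg.resolve(cfg.risk_equations_file)),
        life_table=load_life_table(cfg.resolve(cfg.life_table_file)),
        costs=costs,
        utilities=utilities,
        discount=DiscountSettings(rate=cfg.discount.rate),
        horizon_years=cfg.run.horizon_years,
        cycle_years=cfg.run.cycle_years,
        effect_mode=cfg.run.effect_mode,
        cohort_frame=cohort_frame,
    )


def get_by_path(cfg: RunConfig, path: str):
    """Read a dotted parameter path, e.g. ``therapies.dapa_met.delta_weight``."""
    obj = cfg
    for part in path.split("."):
        if isinstance(obj, dict):
            if part not in obj:
                raise ConfigurationError(f"unknown config path {path!r} (at {part!r})")
            obj = obj[part]
        else:
            if not hasattr(obj, part):
                raise ConfigurationError(f"unknown config path {path!r} (at {part!r})")
            obj = getattr(obj, part)
    return obj


def set_by_path(cfg: RunConfig, path: str, value) -> RunConfig:
    """Return a deep copy of the config with one dotted path replaced."""
    new = cfg.model_copy(deep=True)
    new._base_dir = cfg._base_dir
    parts = path.split(".")
    obj = new
    for part in parts[:-1]:
        if isinstance(obj, dict):
            if part not in obj:
                raise ConfigurationError(f"unknown config path {path!r} (at {part!r})")
            obj = obj[part]
        else:
            if not hasattr(obj, part):
                raise ConfigurationError(f"unknown config path {path!r} (at {part!r})")
            obj = getattr(obj, part)
    last = parts[-1]
    if isinstance(obj, dict):
        if last not in obj:
            raise ConfigurationError(f"unknown config path {path!r} (at {last!r})")
        obj[last] = value
    else:
        if not hasattr(obj, last):
            raise ConfigurationError(f"unknown config path {path!r} (at {last!r})")
        setattr(obj, last, value)
    return new


ARM_SUMMARY_COLUMNS = [
    "arm",
    "total_cost",
    "total_ly",
    "total_qaly",
    "incremental_cost",
    "incremental_ly",
    "incremental_qaly",
    "icer",
]


def write_results(
    result: IncrementalResult,
    out_dir: str | Path,
    cfg: RunConfig | None = None,
    arm_names: tuple[str, str] = ("DPP-4i + MET", "DAPA + MET"),
) -> dict[str, Path]:
    """Write the per-arm summary, incremental table, replicates and manifest.

    Returns a name -> path map of everything written. The per-arm summary
    mirrors the discounted base-case results table (totals per arm, increments
    on the intervention row, ICER printed to the pound).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    a, b = result.arm_a, result.arm_b
    summary = pd.DataFrame(
        [
            {
                "arm": arm_names[0],
                "total_cost": a.mean_cost,
                "total_ly": a.mean_ly,
                "total_qaly": a.mean_qaly,
                "incremental_cost": np.nan,
                "incremental_ly": np.nan,
                "incremental_qaly": np.nan,
                "icer": "",
            },
            {
                "arm": arm_names[1],
                "total_cost": b.mean_cost,
                "total_ly": b.mean_ly,
                "total_qaly": b.mean_qaly,
                "incremental_cost": result.delta_cost,
                "incremental_ly": result.delta_ly,
                "incremental_qaly": result.delta_qaly,
                "icer": result.icer_label,
            },
        ],
        columns=ARM_SUMMARY_COLUMNS,
    )
    incremental = pd.DataFrame(
        [
            {
                "delta_cost": result.delta_cost,
                "delta_ly": result.delta_ly,
                "delta_qaly": result.delta_qaly,
                "icer": result.icer,
                "icer_label": result.icer_label,
                "ci_cost_lo": result.ci_cost[0],
                "ci_cost_hi": result.ci_cost[1],
                "ci_qaly_lo": result.ci_qaly[0],
                "ci_qaly_hi": result.ci_qaly[1],
            }
        ]
    )
    events = pd.DataFrame(
        {
            "event": list(a.event_counts),
            arm_names[0]: list(a.event_counts.values()),
            arm_names[1]: [b.event_counts.get(ev, 0) for ev in a.event_counts],
        }
    )
    paths = {
        "arm_summary": out_dir / "arm_summary.csv",
        "incremental": out_dir / "incremental.csv",
        "replicates": out_dir / "replicates.csv",
        "events": out_dir / "events.csv",
        "manifest": out_dir / "manifest.json",
    }
    summary.to_csv(paths["arm_summary"], index=False)
    incremental.to_csv(paths["incremental"], index=False, float_format="%.17g")
    result.replicates.to_csv(paths["replicates"], index=False)
    events.to_csv(paths["events"], index=False)
    from . import __version__

    manifest = {
        "package_version": __version__,
        "seed": result.seed,
        "n_cohorts": result.n_cohorts,
        "n_patients": result.n_patients,
        "config_hash": cfg.config_hash() if cfg is not None else None,
        "config_name": cfg.meta.name if cfg is not None else None,
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2)
    return paths
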