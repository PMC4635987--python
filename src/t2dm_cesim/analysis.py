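"""Sensitivity analyses over the simulation engine.

* ``tornado`` — one-at-a-time perturbation of parameters to their low/high
  bounds, a full two-arm comparison at each bound from the same master seed
  (so runs differ only through the perturbed parameter).
* ``run_psa`` / ``draw_psa_config`` — probabilistic sensitivity analysis:
  each draw samples all declared parameters independently from their
  distributions (beta for probabilities/utilities, gamma for costs, normal
  for treatment effects), runs one cohort per arm and records (ΔQALY, ΔCost).
* ``ceac`` — cost-effectiveness acceptability: the fraction of PSA draws with
  non-negative net monetary benefit λ·ΔE − ΔC at each willingness-to-pay λ.
* ``scenario_run`` — named structural scenarios as config overrides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig, build_model_inputs, get_by_path, set_by_path
from .errors import ConfigurationError
from .simulate import IncrementalResult, run_comparison, simulate_cohort

__all__ = [
    "ParameterRangeSpec",
    "PsaResult",
    "SCENARIOS",
    "ceac",
    "draw_psa_config",
    "run_psa",
    "scenario_run",
    "tornado",
]


@dataclass
class ParameterRangeSpec:
    """One parameter's sensitivity-analysis range and PSA distribution.

    ``low``/``high`` are the univariate bounds (95% interval limits where the
    evidence provides them, otherwise the conventional ±10% on complication
    disutilities and ±25% on total non-drug costs). For PSA, ``distribution``
    with (mean, se) hyperparameters; ``domain`` optionally restricts support
    (out-of-domain draws are resampled).
    """

    path: str
    low: float | None = None
    high: float | None = None
    distribution: str | None = None
    mean: float | None = None
    se: float | None = None
    domain: tuple[float, float] | None = None

    @classmethod
    def from_tornado_config(cls, p) -> "ParameterRangeSpec":
        return cls(path=p.path, low=p.low, high=p.high)

    @classmethod
    def from_psa_config(cls, p) -> "ParameterRangeSpec":
        return cls(path=p.path, distribution=p.distribution, mean=p.mean, se=p.se)


@dataclass
class PsaResult:
    """Scatter of per-draw incremental outcomes (intervention minus comparator)."""

    draws: pd.DataFrame  # columns: draw, delta_qaly, delta_cost
    seed: int
    n_patients: int


def tornado(
    base_config: RunConfig,
    specs: Sequence[ParameterRangeSpec] | None = None,
    n_cohorts: int = 1,
    n_patients: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """One-way sensitivity table: two full comparisons per parameter.

    Every run reuses the same master seed, so with the engine's fixed
    per-cycle draw consumption, the low and high runs differ only through the
    perturbed parameter. Rows are sorted by the width of the ΔQALY range
    (descending), with the ΔCost range reported alongside.
    """
    if specs is None:
        specs = [ParameterRangeSpec.from_tornado_config(p) for p in base_config.tornado]
    rows = []
    for spec in specs:
        base_value = get_by_path(base_config, spec.path)
        out = {}
        for bound, value in (("low", spec.low), ("high", spec.high)):
            cfg = set_by_path(base_config, spec.path, value)
            res = run_comparison(
                build_model_inputs(cfg, "a"),
                build_model_inputs(cfg, "b"),
                n_cohorts=n_cohorts,
                n_patients=n_patients,
                seed=seed,
                common_random_numbers=base_config.run.common_random_numbers,
            )
            out[bound] = res
        rows.append(
            {
                "parameter": spec.path,
                "base_value": base_value,
                "low": spec.low,
                "high": spec.high,
                "delta_cost_low": out["low"].delta_cost,
                "delta_cost_high": out["high"].delta_cost,
                "delta_qaly_low": out["low"].delta_qaly,
                "delta_qaly_high": out["high"].delta_qaly,
            }
        )
    table = pd.DataFrame(rows)
    table["cost_range"] = (table["delta_cost_high"] - table["delta_cost_low"]).abs()
    table["qaly_range"] = (table["delta_qaly_high"] - table["delta_qaly_low"]).abs()
    return table.sort_values("qaly_range", ascending=False, ignore_index=True)


def _sample_one(spec: ParameterRangeSpec, rng: np.random.Generator) -> float:
    mean, se = spec.mean, spec.se
    if se == 0:
        return mean
    if spec.distribution == "normal":
        return float(rng.normal(mean, se))
    if spec.distribution == "beta":
        if not 0 < mean < 1:
            raise ConfigurationError(f"beta mean for {spec.path} must lie in (0,1), got {mean}")
        v = se**2
        nu = mean * (1 - mean) / v - 1.0
        if nu <= 0:
            raise ConfigurationError(f"beta variance too large for {spec.path}")
        return float(rng.beta(mean * nu, (1 - mean) * nu))
    if spec.distribution == "gamma":
        shape = (mean / se) ** 2
        scale = se**2 / mean
        return float(rng.gamma(shape, scale))
    if spec.distribution == "lognormal":
        sigma2 = np.log1p(se**2 / mean**2)
        mu = np.log(mean) - sigma2 / 2.0
        return float(rng.lognormal(mu, np.sqrt(sigma2)))
    raise ConfigurationError(f"unknown PSA distribution {spec.distribution!r} for {spec.path}")


def draw_psa_config(
    base_config: RunConfig,
    specs: Sequence[ParameterRangeSpec] | None = None,
    rng: np.random.Generator | None = None,
) -> RunConfig:
    """One joint independent draw of all PSA parameters.

    Draws outside a spec's declared domain are resampled; a parameter still
    out of domain after 100 attempts raises a configuration error.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if specs is None:
        specs = [ParameterRangeSpec.from_psa_config(p) for p in base_config.psa]
    cfg = base_config
    for spec in specs:
        for _ in range(100):
            value = _sample_one(spec, rng)
            if spec.domain is None or spec.domain[0] <= value <= spec.domain[1]:
                break
        else:
            raise ConfigurationError(
                f"PSA draw for {spec.path} persistently outside domain {spec.domain}"
            )
        cfg = set_by_path(cfg, spec.path, value)
    return cfg


def run_psa(
    base_config: RunConfig,
    n_draws: int,
    n_patients: int,
    seed: int,
    specs: Sequence[ParameterRangeSpec] | None = None,
) -> PsaResult:
    """PSA: per draw, sample a config and run one cohort per arm.

    Arms use independent RNG streams (as in the base case); parameter draws
    use their own stream, all spawned from the master seed.
    """
    if specs is None:
        specs = [ParameterRangeSpec.from_psa_config(p) for p in base_config.psa]
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_draws)
    rows = []
    for i, child in enumerate(children):
        s_param, s_a, s_b = child.spawn(3)
        cfg = draw_psa_config(base_config, specs, np.random.default_rng(s_param))
        res_a = simulate_cohort(n_patients, build_model_inputs(cfg, "a"), np.random.default_rng(s_a))
        res_b = simulate_cohort(n_patients, build_model_inputs(cfg, "b"), np.random.default_rng(s_b))
        rows.append(
            {
                "draw": i,
                "delta_qaly": res_b.summary.mean_qaly - res_a.summary.mean_qaly,
                "delta_cost": res_b.summary.mean_cost - res_a.summary.mean_cost,
            }
        )
    return PsaResult(draws=pd.DataFrame(rows), seed=seed, n_patients=n_patients)


def ceac(psa: PsaResult, thresholds) -> pd.DataFrame:
    """Probability cost-effective vs willingness-to-pay λ (NMB ≥ 0 rule)."""
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds < 0):
        raise ConfigurationError("willingness-to-pay thresholds must be >= 0")
    de = psa.draws["delta_qaly"].to_numpy()
    dc = psa.draws["delta_cost"].to_numpy()
    probs = [(lam * de - dc >= 0).mean() for lam in thresholds]
    return pd.DataFrame({"threshold": thresholds, "probability_cost_effective": probs})


#: Named structural scenarios shipped with the base case. Values of None mark
#: scenarios whose replacement values the caller must supply.
SCENARIOS: dict[str, dict[str, float | None]] = {
    "switch_threshold_8_5": {"sequence.switch_threshold_hba1c": 8.5},
    "alt_bmi_utilities": {
        "utilities.bmi_per_unit_increase": None,
        "utilities.bmi_per_unit_decrease": None,
    },
    "dapa_hba1c_effect_ci_lower": {"therapies.dapa_met.delta_hba1c": -0.865},
    "dapa_hba1c_effect_ci_upper": {"therapies.dapa_met.delta_hba1c": -0.515},
}


def scenario_run(
    base_config: RunConfig,
    overrides: Mapping[str, float],
    n_cohorts: Optional[int] = None,
    n_patients: Optional[int] = None,
    seed: Optional[int] = None,
) -> IncrementalResult:
    """Run a comparison with config overrides (empty overrides = base case)."""
    cfg = base_config
    for path, value in overrides.items():
        if value is None:
            raise ConfigurationError(f"scenario override {path!r} needs a value")
        cfg = set_by_path(cfg, path, value)
    return run_comparison(
        build_model_inputs(cfg, "a"),
        build_model_inputs(cfg, "b"),
        n_cohorts=n_cohorts if n_cohorts is not None else cfg.run.n_cohorts,
        n_patients=n_patients if n_patients is not None else cfg.run.n_patients,
        seed=seed if seed is not None else cfg.run.seed,
        common_random_numbers=cfg.run.common_random_numbers,
    )
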