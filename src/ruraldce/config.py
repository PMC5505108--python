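"""Configuration, packaged fixtures and scenario handling.

The packaged fixtures encode the printed study inputs (attribute space,
coefficient table, packages, cost rules, workforce baseline, economic and
health parameters, threshold).  ``load_config`` assembles them into one
pipeline configuration, deep-merging any user overrides, and validates the
result, reporting every failing field at once.
"""

from __future__ import annotations

import copy
from importlib import resources

import numpy as np
import yaml

from .costing import CostComponent, EconomicParams
from .design import AttributeSpace, DgpParams, build_attribute_space
from .health import HealthEffectParams, OutcomeParams
from .mixedlogit import EstimationResult
from .preference import IncentivePackage
from .workforce import Demography, WorkforceParams, initialize_state

__all__ = [
    "load_fixture",
    "load_config",
    "validate_config",
    "apply_scenario",
    "parameter_table",
    "attribute_space",
    "packages_from_config",
    "cost_rules_from_config",
    "economic_params",
    "health_params",
    "workforce_params",
    "demography",
    "dgp_from_parameters",
]

_FIXTURES = (
    "attributes", "parameters", "packages", "costs", "workforce",
    "health", "economics", "cea", "published_cea",
)


def load_fixture(name: str) -> dict:
    """Load one packaged YAML fixture by stem name."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {_FIXTURES}")
    ref = resources.files("ruraldce.data").joinpath(f"{name}.yaml")
    with ref.open() as fh:
        return yaml.safe_load(fh)


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def default_config() -> dict:
    """Pipeline configuration assembled from the packaged fixtures."""
    return {
        "attribute_space": load_fixture("attributes"),
        "parameters": load_fixture("parameters"),
        "packages": load_fixture("packages"),
        "costs": load_fixture("costs"),
        "workforce": load_fixture("workforce"),
        "health": load_fixture("health"),
        "economics": load_fixture("economics"),
        "cea": load_fixture("cea"),
        "simulation": {
            "n_respondents": 329,
            "n_tasks": 12,
            "n_alternatives": 2,
            "design_candidates": 200,
        },
        "estimation": {
            "n_draws": 500,
            "draw_scheme": "halton",
            "fixed_coefficients": ["salary"],
            "maxiter": 500,
        },
        "ppi": {"method": "simulated", "n_draws": 100000},
        "horizons": [5, 30],
        "salary_scale": 1.0,
        "utility_shifts": {},
    }


def load_config(path=None) -> dict:
    """Load, merge with packaged defaults, and validate a pipeline config."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_merge(cfg, user)
    validate_config(cfg)
    return cfg


_REQUIRED = [
    ("attribute_space", "attributes"),
    ("parameters", "coefficients"),
    ("parameters", "salary_annual_usd"),
    ("packages", "packages"),
    ("costs", "components"),
    ("workforce", "public_mds"),
    ("workforce", "attrition"),
    ("workforce", "graduates_per_year"),
    ("workforce", "demography"),
    ("health", "outcomes"),
    ("economics", "discount_rate"),
    ("cea", "threshold_usd_per_qaly"),
]


def validate_config(cfg: dict) -> None:
    """Schema validation; raises one error listing every failing field."""
    errors = []
    for path in _REQUIRED:
        node = cfg
        for key in path:
            if not isinstance(node, dict) or key not in node:
                errors.append(".".join(path))
                node = None
                break
            node = node[key]
    outcomes = (cfg.get("health") or {}).get("outcomes") or []
    for o in outcomes:
        if "elasticity" not in o:
            errors.append(f"health.outcomes[{o.get('name', '?')}].elasticity")
    if errors:
        raise ValueError("invalid configuration; missing fields: "
                         + ", ".join(sorted(set(errors))))


# ---------------------------------------------------------------------------
# Constructors from config blocks


def attribute_space(cfg: dict) -> AttributeSpace:
    return build_attribute_space(cfg["attribute_space"])


def parameter_table(cfg: dict) -> EstimationResult:
    """Printed coefficient table as an estimation-result object."""
    coefs = cfg["parameters"]["coefficients"]
    shifts = cfg.get("utility_shifts", {})
    table = {}
    se = {}
    for name, entry in coefs.items():
        mean = entry["mean"] + shifts.get(name, 0.0) * entry.get("sd", 0.0)
        table[name] = (mean, entry.get("sd", 0.0))
        se[name] = entry.get("se", np.nan)
    return EstimationResult.from_parameter_table(table, n_respondents=329, se=se)


def dgp_from_parameters(cfg: dict, space: AttributeSpace) -> DgpParams:
    coefs = cfg["parameters"]["coefficients"]
    missing = [c for c in space.column_names if c not in coefs]
    if missing:
        raise ValueError(f"parameter table lacks coefficients for: {missing}")
    return DgpParams(
        means=tuple(coefs[c]["mean"] for c in space.column_names),
        sds=tuple(coefs[c].get("sd", 0.0) for c in space.column_names),
    )


def packages_from_config(cfg: dict) -> list[IncentivePackage]:
    return [
        IncentivePackage(id=int(pid), components=tuple(comps))
        for pid, comps in cfg["packages"]["packages"].items()
    ]


def cost_rules_from_config(cfg: dict) -> dict[str, CostComponent]:
    rules = {}
    for name, entry in cfg["costs"]["components"].items():
        rules[name] = CostComponent(
            id=name,
            unit_cost=entry["unit_cost"],
            uptake=entry.get("uptake", 1.0),
            recurrence=entry.get("recurrence", "annual"),
            lag_years=entry.get("lag_years", 0),
            depreciation_years=entry.get("depreciation_years"),
            kind=entry.get("kind", "variable"),
        )
    return rules


def economic_params(cfg: dict) -> EconomicParams:
    e = cfg["economics"]
    return EconomicParams(
        discount_rate=e["discount_rate"],
        inflation_path=tuple(e.get("inflation_path", ())),
        method=e.get("method", "cash"),
    )


def health_params(cfg: dict) -> HealthEffectParams:
    h = cfg["health"]
    outcomes = tuple(
        OutcomeParams(
            name=o["name"],
            elasticity=o["elasticity"],
            annual_incidence=o["annual_incidence"],
            event_age=o["event_age"],
            life_expectancy_at_event=o["life_expectancy_at_event"],
        )
        for o in h["outcomes"]
    )
    return HealthEffectParams(
        outcomes=outcomes,
        qaly_discount=h.get("qaly_discount", 0.03),
        qaly_weights=h.get("qaly_weights", {}) or {},
        default_weight=h.get("default_qaly_weight", 1.0),
        rural_incidence_share=h.get("rural_incidence_share"),
    )


def workforce_params(cfg: dict) -> WorkforceParams:
    w = cfg["workforce"]
    shares = w.get("sector_shares")
    if shares is not None:
        total = sum(shares.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"sector shares must sum to 1, got {total}")
    return initialize_state(
        public_count=w["public_mds"],
        rural_public_count=w["rural_public_mds"],
        public_share=w["public_share"],
        graduates_per_year=w["graduates_per_year"],
        attrition=w["attrition"],
        start_year=w.get("start_year", 2011),
    )


def demography(cfg: dict) -> Demography:
    d = cfg["workforce"]["demography"]
    return Demography(
        base_year=d["base_year"],
        total=d["total_population"],
        rural_share=d["rural_population"] / d["total_population"],
        growth_rate=d.get("growth_rate", 0.014),
        urbanization_rate=d.get("urbanization_rate", 0.005),
    )


# ---------------------------------------------------------------------------
# Sensitivity scenarios


def apply_scenario(cfg: dict, scenario: dict) -> dict:
    """Return a config with one named parameter perturbed.

    Supported params: accounting_method, horizon, discount_rate,
    qaly_discount, attrition, public_share, rural_share_scale, salary_scale,
    utility_shift (component +/- n SDs).
    """
    out = copy.deepcopy(cfg)
    param = scenario.get("param")
    if param is None:  # base case
        return out
    value = scenario.get("value")
    if param == "accounting_method":
        out["economics"]["method"] = value
    elif param == "horizon":
        out["horizons"] = [int(value)]
    elif param == "discount_rate":
        out["economics"]["discount_rate"] = float(value)
        out["health"]["qaly_discount"] = float(value)
    elif param == "qaly_discount":
        out["health"]["qaly_discount"] = float(value)
    elif param == "attrition":
        out["workforce"]["attrition"] = float(value)
    elif param == "public_share":
        out["workforce"]["public_share"] = float(value)
    elif param == "rural_share_scale":
        w = out["workforce"]
        w["rural_public_mds"] = min(
            w["rural_public_mds"] * float(value), w["public_mds"]
        )
    elif param == "salary_scale":
        out["salary_scale"] = float(value)
    elif param == "utility_shift":
        comp = scenario["component"]
        if comp not in out["parameters"]["coefficients"]:
            raise KeyError(f"unknown component {comp!r} in utility_shift")
        out.setdefault("utility_shifts", {})[comp] = float(value)
    else:
        raise KeyError(f"unknown sensitivity parameter {param!r}")
    return out
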