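"""Health effects of physician redistribution: cases averted and QALYs.

The chain per year, location (rural/urban) and outcome (infant mortality,
under-5 mortality excluding infants, maternal mortality):

1. percent change in physician density between the with- and without-program
   trajectories;
2. percent change in the outcome = density elasticity x percent density
   change (elasticities are expected negative: more physicians, fewer
   deaths);
3. cases averted = -(percent outcome change) x baseline annual incidence in
   that location; the national net sums rural gains and urban losses;
4. each net case averted contributes the outcome's discounted QALYs per
   case, built from remaining life expectancy at the event age and
   age-specific QALY/life-year weights.

Yearly QALY totals are additionally discounted back to program start at the
health discount rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OutcomeParams",
    "HealthEffectParams",
    "HealthResult",
    "pct_density_change",
    "outcome_change",
    "cases_averted",
    "discounted_qalys_per_case",
    "package_health_effect",
]


@dataclass(frozen=True)
class OutcomeParams:
    """One mortality outcome: elasticity, incidence and QALY inputs."""

    name: str
    elasticity: float  # d log(outcome) / d log(density); expected < 0
    annual_incidence: float  # national deaths per year at baseline
    event_age: float  # age at death (0 infants, 2.5 under-5, 25 maternal)
    life_expectancy_at_event: float  # remaining years had the death been averted

    def __post_init__(self):
        if self.annual_incidence < 0:
            raise ValueError(f"{self.name}: incidence must be >= 0")
        if self.life_expectancy_at_event <= 0:
            raise ValueError(f"{self.name}: life expectancy must be positive")


@dataclass(frozen=True)
class HealthEffectParams:
    outcomes: tuple[OutcomeParams, ...]
    qaly_discount: float = 0.03
    # age -> QALY/life-year weight; ages not listed fall back to `default_weight`
    qaly_weights: dict = field(default_factory=dict)
    default_weight: float = 1.0
    rural_incidence_share: float | None = None  # None: split by population

    def __post_init__(self):
        if self.qaly_discount < 0:
            raise ValueError("QALY discount rate must be >= 0")
        if not self.outcomes:
            raise ValueError("at least one outcome required")

    def weight(self, age: float) -> float:
        w = self.qaly_weights.get(int(age), self.default_weight)
        if not 0 < w <= 1:
            raise ValueError(f"QALY weight at age {age} must be in (0, 1]")
        return w


def pct_density_change(with_traj, without_traj, location: str,
                       year: int) -> float:
    """(density_with - density_without) / density_without for one year."""
    col = f"{location}_density"
    for t in (with_traj, without_traj):
        if col not in t.df.columns:
            raise KeyError(f"trajectory lacks {col!r}; attach densities first")
    w = with_traj.df.set_index("year")[col]
    wo = without_traj.df.set_index("year")[col]
    if year not in w.index or year not in wo.index:
        raise KeyError(f"year {year} not covered by both trajectories")
    base = float(wo.loc[year])
    if base == 0:
        raise ZeroDivisionError("baseline density is zero; percent change undefined")
    return (float(w.loc[year]) - base) / base


def outcome_change(elasticity: float, density_change: float) -> float:
    """Percent outcome change implied by a percent density change."""
    return elasticity * density_change


def cases_averted(outcome: OutcomeParams,
                  changes_by_location: dict[str, float],
                  incidence_by_location: dict[str, float]) -> float:
    """Net national cases averted (negative = net cases gained)."""
    net = 0.0
    for loc, change in changes_by_location.items():
        if loc not in incidence_by_location:
            raise KeyError(f"no baseline incidence for location {loc!r}")
        net += -change * incidence_by_location[loc]
    return net


def discounted_qalys_per_case(outcome: OutcomeParams,
                              params: HealthEffectParams) -> float:
    """Discounted quality-weighted life years gained by averting one death.

    Sums over the remaining life years ``y`` the age-specific weight at
    ``event_age + y`` discounted at the QALY rate; the first year is
    undiscounted.
    """
    n_years = int(round(outcome.life_expectancy_at_event))
    if n_years < 1:
        raise ValueError("life expectancy must round to at least one year")
    r = params.qaly_discount
    return float(
        sum(
            params.weight(outcome.event_age + y) / (1 + r) ** y
            for y in range(n_years)
        )
    )


@dataclass
class HealthResult:
    package_id: int | str
    df: pd.DataFrame  # per year: density changes, cases averted, QALYs
    total_discounted_qalys: float


def _incidence_split(outcome: OutcomeParams, params: HealthEffectParams,
                     rural_pop: float, urban_pop: float) -> dict[str, float]:
    share = params.rural_incidence_share
    if share is None:
        share = rural_pop / (rural_pop + urban_pop)
    return {
        "rural": outcome.annual_incidence * share,
        "urban": outcome.annual_incidence * (1 - share),
    }


def package_health_effect(with_traj, without_traj,
                          params: HealthEffectParams, horizon: int,
                          package_id: int | str = "package",
                          ) -> HealthResult:
    """Chain density changes through to total discounted QALYs gained."""
    qalys_per_case = {
        o.name: discounted_qalys_per_case(o, params) for o in params.outcomes
    }
    start_year = int(without_traj.df["year"].iloc[0])
    rows = []
    total = 0.0
    for k in range(1, horizon + 1):
        year = start_year + k
        changes = {
            loc: pct_density_change(with_traj, without_traj, loc, year)
            for loc in ("rural", "urban")
        }
        wo = without_traj.df.set_index("year")
        rural_pop = float(wo.loc[year, "rural_population"])
        urban_pop = float(wo.loc[year, "urban_population"])
        row = {"year": year, "rural_density_change": changes["rural"],
               "urban_density_change": changes["urban"]}
        year_qalys = 0.0
        for o in params.outcomes:
            oc = {loc: outcome_change(o.elasticity, changes[loc])
                  for loc in changes}
            inc = _incidence_split(o, params, rural_pop, urban_pop)
            averted = cases_averted(o, oc, inc)
            row[f"cases_averted_{o.name}"] = averted
            year_qalys += averted * qalys_per_case[o.name]
        disc = (1 + params.qaly_discount) ** (k - 1)
        row["qalys"] = year_qalys
        row["discounted_qalys"] = year_qalys / disc
        total += year_qalys / disc
        rows.append(row)
    return HealthResult(
        package_id=package_id,
        df=pd.DataFrame(rows),
        total_discounted_qalys=float(total),
    )
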