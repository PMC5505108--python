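"""Direct program costs of incentive packages.

Cost rules follow the published costing survey: variable components accrue
per rural recruit (with component-specific uptake fractions and deferral
lags), capital items can be accounted for on a cash basis (full cost in the
purchase year) or by straight-line depreciation (30-year schedule for
buildings, 7-year for equipment), and facility-improvement programs follow a
fixed upgrade schedule independent of uptake.

Deferred nominal-fixed benefits are deflated by the inflation path: a fee of
$1500 paid one year out with 6.7% first-year inflation has a present real
cost of 1500/1.067 ≈ $1406.  The inflation path covers the first five years;
beyond it the financial discount rate is used as the inflation rate, so
deferral and discounting cancel there by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CostComponent",
    "EconomicParams",
    "CostResult",
    "annualize_capital",
    "real_discounted_cost",
    "expected_component_cost",
    "fixed_cost_schedule",
    "component_annualized_costs",
    "package_direct_cost",
]


@dataclass(frozen=True)
class EconomicParams:
    """Discounting and inflation conventions.

    ``inflation_path`` lists annual inflation rates for the first years of
    the program (year 1 first); beyond the path the financial discount rate
    is used as the inflation rate.
    """

    discount_rate: float = 0.03
    inflation_path: tuple[float, ...] = (0.067, 0.053, 0.047, 0.042, 0.038)
    method: str = "cash"  # 'cash' | 'depreciation'

    def __post_init__(self):
        if self.discount_rate <= -1:
            raise ValueError("discount rate must exceed -1")
        if any(i <= -1 for i in self.inflation_path):
            raise ValueError("inflation rates must exceed -1")
        if self.method not in ("cash", "depreciation"):
            raise ValueError(f"unknown accounting method {self.method!r}")

    def inflation(self, year_offset: int) -> float:
        """Inflation rate applying over year ``year_offset`` (1-based)."""
        if year_offset < 1:
            raise ValueError("year offset must be >= 1")
        if year_offset <= len(self.inflation_path):
            return self.inflation_path[year_offset - 1]
        return self.discount_rate

    def cumulative_inflation(self, year_offset: int) -> float:
        return float(
            np.prod([1 + self.inflation(y) for y in range(1, year_offset + 1)])
        )


@dataclass(frozen=True)
class CostComponent:
    """Cost rule for one incentive component.

    ``recurrence`` 'annual' bills every retained recruit-year once the
    ``lag_years`` qualification period has passed; 'one_time' bills each
    recruit once, at entry plus ``lag_years``.  ``depreciation_years`` marks
    capital items eligible for straight-line treatment.
    """

    id: str
    unit_cost: float
    uptake: float = 1.0
    recurrence: str = "annual"
    lag_years: int = 0
    depreciation_years: int | None = None
    kind: str = "variable"  # 'variable' | 'facility'

    def __post_init__(self):
        if self.unit_cost < 0:
            raise ValueError(f"{self.id}: unit cost must be >= 0")
        if not 0 <= self.uptake <= 1:
            raise ValueError(f"{self.id}: uptake must be in [0, 1]")
        if self.recurrence not in ("annual", "one_time"):
            raise ValueError(f"{self.id}: unknown recurrence {self.recurrence!r}")


@dataclass
class CostResult:
    package_id: int | str
    df: pd.DataFrame  # year_offset, nominal, real, discounted
    warnings: list[str] = field(default_factory=list)

    @property
    def total_nominal(self) -> float:
        return float(self.df["nominal"].sum())

    @property
    def total_discounted(self) -> float:
        return float(self.df["discounted"].sum())


def annualize_capital(unit_cost: float, schedule_years: int) -> float:
    """Straight-line annual charge of a capital cost."""
    if schedule_years < 1:
        raise ValueError("depreciation schedule must be >= 1 year")
    return unit_cost / schedule_years


def real_discounted_cost(nominal: float, year_offset: int,
                         econ: EconomicParams) -> float:
    """Year-0 real cost of a nominal-fixed amount deferred ``year_offset`` years.

    The deferral deflator is the cumulative excess of inflation over the
    financial discount rate: ``nominal * prod((1+d)/(1+i_y))``.  When the
    inflation rate equals the discount rate every year the cost is unchanged.
    """
    if year_offset < 0:
        raise ValueError("year offset must be >= 0")
    factor = 1.0
    for y in range(1, year_offset + 1):
        factor *= (1 + econ.discount_rate) / (1 + econ.inflation(y))
    return nominal * factor


def expected_component_cost(component: CostComponent,
                            eligible_count: float) -> float:
    """Expected annual (or per-event) cost across the eligible pool."""
    if eligible_count < 0:
        raise ValueError("eligible count must be >= 0")
    return component.unit_cost * component.uptake * eligible_count


def fixed_cost_schedule(facility_plan: dict, econ: EconomicParams,
                        horizon: int) -> tuple[np.ndarray, list[str]]:
    """Per-year nominal cost of the facility upgrade program.

    ``facility_plan`` lists, per tier, the building and equipment unit costs,
    upgrades per year and the total facility count; upgrades stop when the
    totals are exhausted (clipped with a logged warning).  Cash accounting
    bills the full cost in the upgrade year; depreciation spreads buildings
    over 30 years and equipment over 7 from the upgrade year.
    """
    notes: list[str] = []
    cost = np.zeros(horizon + 1)  # index = year offset, 0 unused
    for tier in facility_plan["tiers"]:
        per_year = tier["upgrades_per_year"]
        remaining = tier["total_facilities"]
        b_cost, e_cost = tier["building_cost"], tier["equipment_cost"]
        for y in range(1, horizon + 1):
            n = min(per_year, remaining)
            if n < per_year and remaining > 0:
                msg = (f"{tier['id']}: upgrades clipped to {n} in year {y} "
                       f"(facility total exhausted)")
                warnings.warn(msg)
                notes.append(msg)
            remaining -= n
            if n <= 0:
                continue
            if econ.method == "cash":
                cost[y] += n * (b_cost + e_cost)
            else:
                b_annual = annualize_capital(b_cost, 30)
                e_annual = annualize_capital(e_cost, 7)
                for dt in range(30):
                    if y + dt <= horizon:
                        cost[y + dt] += n * b_annual
                for dt in range(7):
                    if y + dt <= horizon:
                        cost[y + dt] += n * e_annual
    return cost[1:], notes


def component_annualized_costs(cost_rules: dict[str, "CostComponent"],
                               econ: EconomicParams,
                               facility_plan: dict | None = None,
                               facility_attribution: float = 0.1,
                               facility_reference_physicians: float = 21,
                               deferral_discount: float = 0.0,
                               ) -> dict[str, float]:
    """Annualized per-recruit cost of each component, for valuation ratios.

    Annual components cost ``unit * uptake`` per year; one-time capital items
    are spread by straight-line depreciation; deferred items are deflated by
    the inflation path over the qualification lag (inflation only by default,
    matching the published cost column).  Facility programs are costed as the
    year-1 depreciated schedule total, attributed to the program and divided
    across the reference eligible-physician pool.
    """
    defer_econ = EconomicParams(
        discount_rate=deferral_discount,
        inflation_path=econ.inflation_path,
        method=econ.method,
    )
    out: dict[str, float] = {}
    for name, comp in cost_rules.items():
        if comp.kind == "facility":
            if facility_plan is None:
                continue
            depr = EconomicParams(
                discount_rate=econ.discount_rate,
                inflation_path=econ.inflation_path,
                method="depreciation",
            )
            sched, _ = fixed_cost_schedule(facility_plan, depr, horizon=1)
            out[name] = (
                sched[0] * facility_attribution / facility_reference_physicians
            )
            continue
        if comp.recurrence == "annual":
            base = comp.unit_cost * comp.uptake
        elif comp.depreciation_years:
            base = annualize_capital(comp.unit_cost, comp.depreciation_years)
        else:
            base = comp.unit_cost
        out[name] = real_discounted_cost(base, comp.lag_years, defer_econ)
    return out


def _retained(recruits: np.ndarray, attrition: float, lag: int) -> np.ndarray:
    """Retained qualifying recruit-years: cohort e counts from year e + lag."""
    T = recruits.size
    out = np.zeros(T)
    keep = 1 - attrition
    for e in range(T):
        for t in range(e + lag, T):
            out[t] += recruits[e] * keep ** (t - e)
    return out


def package_direct_cost(package, trajectory, cost_rules: dict[str, CostComponent],
                        econ: EconomicParams, horizon: int,
                        facility_plan: dict | None = None,
                        attrition: float = 0.025,
                        facility_attribution: float = 0.1,
                        ) -> CostResult:
    """Nominal, real and discounted yearly cost of one package.

    Variable components are driven by the trajectory's new rural recruits per
    year; facility components follow the fixed upgrade schedule, attributed
    to the package at ``facility_attribution`` (the share of facility costs
    chargeable to the rural incentive program).
    """
    df = trajectory.df
    recruits = df["new_public_rural"].to_numpy()[1:horizon + 1]
    if recruits.size < horizon:
        raise ValueError("trajectory does not cover the requested horizon")
    nominal = np.zeros(horizon)
    notes: list[str] = []
    for name in package.components:
        if name not in cost_rules:
            raise KeyError(f"component {name!r} has no cost rule")
        comp = cost_rules[name]
        if comp.kind == "facility":
            if facility_plan is None:
                raise ValueError("facility component present but no facility plan")
            sched, n = fixed_cost_schedule(facility_plan, econ, horizon)
            nominal += facility_attribution * sched
            notes.extend(n)
            continue
        if comp.recurrence == "annual":
            pool = _retained(recruits, attrition, comp.lag_years)
            nominal += comp.unit_cost * comp.uptake * pool
        else:  # one_time
            keep = (1 - attrition) ** comp.lag_years
            if comp.depreciation_years and econ.method == "depreciation":
                annual = annualize_capital(comp.unit_cost, comp.depreciation_years)
                for e in range(horizon):
                    t_bill = e + comp.lag_years
                    for dt in range(comp.depreciation_years):
                        if t_bill + dt < horizon:
                            nominal[t_bill + dt] += (
                                annual * comp.uptake * recruits[e] * keep
                            )
            else:
                for e in range(horizon):
                    t_bill = e + comp.lag_years
                    if t_bill < horizon:
                        nominal[t_bill] += (
                            comp.unit_cost * comp.uptake * recruits[e] * keep
                        )
    offsets = np.arange(1, horizon + 1)
    cum_infl = np.array([econ.cumulative_inflation(t) for t in offsets])
    real = nominal * (1 + econ.discount_rate) ** offsets / cum_infl
    discounted = nominal / cum_infl
    out = pd.DataFrame(
        {"year_offset": offsets, "nominal": nominal, "real": real,
         "discounted": discounted}
    )
    return CostResult(package_id=package.id, df=out, warnings=notes)
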