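"""Monetary valuation of incentive components from choice-model coefficients.

The valuation of component ``c`` is the coefficient ratio scaled by annual
salary:

    valuation_c = (b_c / b_S) * annual_salary

where ``b_S`` is the salary coefficient expressed per 100% of annual salary.
Uncertainty comes from the first-order delta method on ``(b_c, b_S)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixedlogit import EstimationResult

__all__ = [
    "SalaryBasis",
    "ValuationRecord",
    "component_valuation",
    "valuation_se_delta",
    "valuation_cost_ratio",
]

Z95 = 1.959963984540054


@dataclass(frozen=True)
class SalaryBasis:
    """Annual salary anchoring the valuation scale."""

    annual_salary: float
    currency: str = "USD"
    note: str = ""

    def __post_init__(self):
        if self.annual_salary <= 0:
            raise ValueError("annual salary must be positive")


@dataclass
class ValuationRecord:
    component: str
    valuation: float
    se: float
    ci_low: float
    ci_high: float
    annualized_cost: float | None = None
    ratio: float | None = None
    ratio_ci_low: float | None = None
    ratio_ci_high: float | None = None

    def with_cost(self, annualized_cost: float) -> "ValuationRecord":
        r = valuation_cost_ratio(self, annualized_cost)
        return r


def valuation_se_delta(result: EstimationResult, component: str,
                       salary_basis: SalaryBasis,
                       salary_column: str = "salary") -> tuple[float, float, float]:
    """Delta-method SE and 95% CI of a component valuation.

    With ``v = A * b_c / b_S`` the gradient is ``(A/b_S, -A*b_c/b_S**2)`` and
    ``Var(v) = g' Sigma g`` using the estimated covariance of (b_c, b_S).
    """
    bc, _ = result.coef(component)
    bs, _ = result.coef(salary_column)
    A = salary_basis.annual_salary
    var_c = result.vcov(component, component)
    var_s = result.vcov(salary_column, salary_column)
    cov_cs = result.vcov(component, salary_column)
    if not np.all(np.isfinite([var_c, var_s, cov_cs])):
        raise ValueError(
            f"covariance entries for ({component!r}, {salary_column!r}) unavailable"
        )
    g = np.array([A / bs, -A * bc / bs**2])
    var = g @ np.array([[var_c, cov_cs], [cov_cs, var_s]]) @ g
    se = float(np.sqrt(max(var, 0.0)))
    v = A * bc / bs
    return se, v - Z95 * se, v + Z95 * se


def component_valuation(result: EstimationResult, salary_basis: SalaryBasis,
                        components: list[str] | None = None,
                        salary_column: str = "salary") -> list[ValuationRecord]:
    """One valuation record per non-salary component.

    No rounding is applied; present rounded values only at reporting time.
    """
    bs, _ = result.coef(salary_column)
    if bs <= 0:
        raise ValueError("salary coefficient must be positive; valuation undefined")
    if components is None:
        components = [c for c in result.columns if c != salary_column]
    out = []
    for c in components:
        bc, _ = result.coef(c)
        v = salary_basis.annual_salary * bc / bs
        try:
            se, lo, hi = valuation_se_delta(result, c, salary_basis, salary_column)
        except ValueError:
            se, lo, hi = np.nan, np.nan, np.nan
        out.append(ValuationRecord(component=c, valuation=float(v), se=se,
                                   ci_low=lo, ci_high=hi))
    return out


def valuation_cost_ratio(record: ValuationRecord,
                         annualized_cost: float) -> ValuationRecord:
    """Valuation/cost ratio with CI from dividing the valuation CI bounds."""
    if annualized_cost <= 0:
        raise ValueError("annualized cost must be positive")
    record.annualized_cost = annualized_cost
    record.ratio = record.valuation / annualized_cost
    record.ratio_ci_low = record.ci_low / annualized_cost
    record.ratio_ci_high = record.ci_high / annualized_cost
    return record


def valuation_table(records: list[ValuationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "component": [r.component for r in records],
            "valuation": [r.valuation for r in records],
            "se": [r.se for r in records],
            "ci_low": [r.ci_low for r in records],
            "ci_high": [r.ci_high for r in records],
            "annualized_cost": [r.annualized_cost for r in records],
            "ratio": [r.ratio for r in records],
            "ratio_ci_low": [r.ratio_ci_low for r in records],
            "ratio_ci_high": [r.ratio_ci_high for r in records],
        }
    )
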