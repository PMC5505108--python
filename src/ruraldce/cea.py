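"""Cost-effectiveness ranking: ACERs, dominance frontier, ICERs, thresholds.

The comparator is "no program" at zero cost and zero QALYs.  Strongly
dominated options (at least as costly and no more effective than another,
with one strict inequality) are removed first; extended (weak) dominance then
removes options iteratively until the ICER sequence along the frontier is
strictly increasing.  The decision rule keeps the highest-QALY frontier
package whose ICER is at or below the willingness-to-pay threshold
(3 x GDP per capita by convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CEAPoint",
    "average_cer",
    "dominance_frontier",
    "threshold_decision",
    "ThresholdDecision",
    "run_sensitivity",
]


@dataclass(frozen=True)
class CEAPoint:
    package_id: int | str
    cost: float
    qalys: float


def average_cer(cost: float, qalys: float) -> float:
    """Average cost-effectiveness ratio versus no program."""
    if qalys <= 0:
        raise ValueError("ACER undefined for non-positive QALYs")
    return cost / qalys


def dominance_frontier(points: list[CEAPoint]) -> pd.DataFrame:
    """Classify packages as frontier / strongly / extendedly dominated.

    Returns a DataFrame with ACERs, dominance status, and the ICER of each
    frontier point versus the previous frontier point (the origin for the
    cheapest).  Duplicate (cost, QALY) points tie-break deterministically:
    the lower package id keeps the frontier slot.
    """
    if not points:
        raise ValueError("at least one package required")
    df = pd.DataFrame(
        {
            "package_id": [p.package_id for p in points],
            "cost": [p.cost for p in points],
            "qalys": [p.qalys for p in points],
        }
    )
    df["acer"] = [
        average_cer(c, q) if q > 0 else np.inf
        for c, q in zip(df["cost"], df["qalys"])
    ]
    status = ["frontier"] * len(df)

    # strong dominance (origin dominates anything with cost>0, qalys<=0)
    for i in range(len(df)):
        ci, qi = df.loc[i, "cost"], df.loc[i, "qalys"]
        if ci >= 0 and qi <= 0 and (ci > 0 or qi < 0):
            status[i] = "strongly dominated"
            continue
        for j in range(len(df)):
            if i == j:
                continue
            cj, qj = df.loc[j, "cost"], df.loc[j, "qalys"]
            strict = (cj < ci) or (qj > qi)
            if cj <= ci and qj >= qi and strict:
                status[i] = "strongly dominated"
                break
            if cj == ci and qj == qi and df.loc[j, "package_id"] < df.loc[i, "package_id"]:
                status[i] = "strongly dominated"  # duplicate point tie-break
                break

    def _icers(idx: list[int]) -> list[float]:
        out = []
        pc, pq = 0.0, 0.0
        for i in idx:
            out.append((df.loc[i, "cost"] - pc) / (df.loc[i, "qalys"] - pq))
            pc, pq = df.loc[i, "cost"], df.loc[i, "qalys"]
        return out

    # extended dominance: prune until ICERs strictly increase
    alive = [i for i in range(len(df)) if status[i] == "frontier"]
    alive.sort(key=lambda i: (df.loc[i, "qalys"], df.loc[i, "cost"],
                              df.loc[i, "package_id"]))
    changed = True
    while changed and len(alive) > 1:
        changed = False
        icers = _icers(alive)
        for k in range(len(alive) - 1):
            if icers[k] >= icers[k + 1]:
                status[alive[k]] = "extendedly dominated"
                alive.pop(k)
                changed = True
                break

    df["status"] = status
    df["icer"] = np.nan
    for i, icer in zip(alive, _icers(alive)):
        df.loc[i, "icer"] = icer
    return df


@dataclass
class ThresholdDecision:
    threshold: float
    n_under_threshold: int
    under_threshold_ids: list
    optimal_package: int | str | None
    optimal_icer: float | None


def threshold_decision(cea_table: pd.DataFrame, threshold: float,
                       ) -> ThresholdDecision:
    """Apply the willingness-to-pay threshold to a CEA table.

    Counts packages with ACER strictly below the threshold; the optimal
    package is the highest-QALY frontier point whose ICER is <= threshold
    (none when every frontier ICER exceeds it).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    under = cea_table[cea_table["acer"] < threshold]
    frontier = cea_table[cea_table["status"] == "frontier"]
    if frontier.empty:
        raise ValueError("empty frontier")
    eligible = frontier[frontier["icer"] <= threshold]
    if eligible.empty:
        opt_id, opt_icer = None, None
    else:
        best = eligible.loc[eligible["qalys"].idxmax()]
        opt_id, opt_icer = best["package_id"], float(best["icer"])
    return ThresholdDecision(
        threshold=threshold,
        n_under_threshold=int(len(under)),
        under_threshold_ids=list(under["package_id"]),
        optimal_package=opt_id,
        optimal_icer=opt_icer,
    )


def run_sensitivity(base_config: dict, scenarios: list[dict],
                    pipeline_fn) -> pd.DataFrame:
    """Re-run the full pipeline under single-parameter perturbations.

    ``scenarios`` is a list of ``{"name": ..., "param": ..., "value": ...}``
    entries; ``pipeline_fn(config)`` must return a (cea_table, threshold)
    pair.  The base case is always the first row.
    """
    from .config import apply_scenario  # local import to avoid cycle

    rows = []
    for scen in [{"name": "base case"}] + list(scenarios):
        cfg = apply_scenario(base_config, scen)
        table, threshold = pipeline_fn(cfg)
        decision = threshold_decision(table, threshold)
        opt = decision.optimal_package
        acer = icer = np.nan
        if opt is not None:
            row = table[table["package_id"] == opt].iloc[0]
            acer, icer = float(row["acer"]), float(row["icer"])
        rows.append(
            {"scenario": scen["name"], "optimal_package": opt,
             "acer": acer, "icer": icer,
             "n_under_threshold": decision.n_under_threshold}
        )
    return pd.DataFrame(rows)
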