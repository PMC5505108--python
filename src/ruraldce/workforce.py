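"""Physician workforce projection under rural incentive packages.

Three strata are tracked: private (urban), public urban, public rural.  Each
year existing stock shrinks by the attrition rate; new graduates then enter.
Without an incentive program entrants split across strata at the baseline
shares.  With a program, the private share is unchanged and the rural share
of public entrants is multiplied by the package's relative risk (2*PPI),
capped so rural entrants never exceed total public entrants:

    new_rural_t = graduates_t * share_public * share_rural_given_public * rr

Densities are physicians per 10,000 population by location, with rural/urban
populations from a parameterized demographic trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WorkforceParams",
    "Demography",
    "WorkforceTrajectory",
    "initialize_state",
    "project",
    "density",
]

STRATA = ("private", "public_urban", "public_rural")


@dataclass(frozen=True)
class WorkforceParams:
    """Baseline stocks and flow parameters for the projection."""

    stocks: dict  # stratum -> count at start year
    graduates_per_year: float
    attrition: float
    public_share: float  # share of entrants entering public service
    rural_given_public: float  # baseline rural share of public entrants
    start_year: int = 2011

    def __post_init__(self):
        missing = [s for s in STRATA if s not in self.stocks]
        if missing:
            raise ValueError(f"missing strata in stocks: {missing}")
        if not 0 <= self.attrition < 1:
            raise ValueError("attrition must be in [0, 1)")
        if self.graduates_per_year < 0:
            raise ValueError("graduates_per_year must be >= 0")
        for nm, v in (("public_share", self.public_share),
                      ("rural_given_public", self.rural_given_public)):
            if not 0 <= v <= 1:
                raise ValueError(f"{nm} must be in [0, 1]")


def initialize_state(public_count: float, rural_public_count: float,
                     public_share: float, graduates_per_year: float = 180.0,
                     attrition: float = 0.025, start_year: int = 2011,
                     ) -> WorkforceParams:
    """Seed the strata from public-system counts and the public sector share.

    Total stock = public stock / public share; the private stratum holds the
    remainder and the public stock splits urban/rural by the observed counts.
    """
    if not 0 < public_share <= 1:
        raise ValueError("public share must be in (0, 1]")
    if rural_public_count > public_count:
        raise ValueError("rural public count exceeds public count")
    total = public_count / public_share
    stocks = {
        "private": total - public_count,
        "public_urban": public_count - rural_public_count,
        "public_rural": rural_public_count,
    }
    return WorkforceParams(
        stocks=stocks,
        graduates_per_year=graduates_per_year,
        attrition=attrition,
        public_share=public_share,
        rural_given_public=rural_public_count / public_count,
        start_year=start_year,
    )


@dataclass(frozen=True)
class Demography:
    """Geometric population trajectory with a declining rural share.

    ``total`` grows at ``growth_rate`` per year from the base year; the rural
    share shrinks by the ``urbanization_rate`` (relative decline per year),
    emulating published urbanization projections without external tables.
    """

    base_year: int
    total: float
    rural_share: float
    growth_rate: float = 0.014
    urbanization_rate: float = 0.005

    def __post_init__(self):
        if self.total <= 0:
            raise ValueError("total population must be positive")
        if not 0 < self.rural_share < 1:
            raise ValueError("rural share must be in (0, 1)")

    def populations(self, year: int) -> tuple[float, float]:
        """(rural, urban) population in a given year."""
        dt = year - self.base_year
        total = self.total * (1 + self.growth_rate) ** dt
        share = self.rural_share * (1 - self.urbanization_rate) ** dt
        rural = total * share
        return rural, total - rural


@dataclass
class WorkforceTrajectory:
    """Yearly stratum counts (and optionally densities) as a DataFrame."""

    df: pd.DataFrame
    rr: float

    def counts(self, stratum: str) -> np.ndarray:
        return self.df[stratum].to_numpy()

    @property
    def years(self) -> np.ndarray:
        return self.df["year"].to_numpy()


def project(params: WorkforceParams, rr: float, horizon: int,
            demography: Demography | None = None) -> WorkforceTrajectory:
    """Project stratum counts forward ``horizon`` years at relative risk ``rr``.

    Timing convention: attrition applies to the existing stock first, the
    year's entrants are added at year end and face attrition from the
    following year.  Rural entrants are capped at the total public entrants.
    """
    if not 0 <= rr <= 2:
        raise ValueError("relative risk must be in [0, 2]")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    g = params.graduates_per_year
    private_in = g * (1 - params.public_share)
    public_in = g * params.public_share
    rural_share_in = min(params.rural_given_public * rr, 1.0)
    rural_in = public_in * rural_share_in
    urban_in = public_in - rural_in

    rows = [{"year": params.start_year, **params.stocks,
             "new_public_rural": 0.0}]
    state = dict(params.stocks)
    for k in range(1, horizon + 1):
        keep = 1 - params.attrition
        state = {s: state[s] * keep for s in STRATA}
        state["private"] += private_in
        state["public_urban"] += urban_in
        state["public_rural"] += rural_in
        rows.append({"year": params.start_year + k, **state,
                     "new_public_rural": rural_in})
    df = pd.DataFrame(rows)
    df["total"] = df[list(STRATA)].sum(axis=1)
    traj = WorkforceTrajectory(df=df, rr=rr)
    if demography is not None:
        traj = density(traj, demography)
    return traj


def density(trajectory: WorkforceTrajectory, demography: Demography,
            ) -> WorkforceTrajectory:
    """Attach rural/urban physician densities per 10,000 population.

    Rural density counts public rural physicians against the rural
    population; urban density counts private plus public urban physicians
    against the urban population.
    """
    df = trajectory.df.copy()
    pops = np.array([demography.populations(int(y)) for y in df["year"]])
    if np.any(pops <= 0):
        raise ValueError("population must be positive in every projected year")
    df["rural_population"] = pops[:, 0]
    df["urban_population"] = pops[:, 1]
    df["rural_density"] = 1e4 * df["public_rural"] / df["rural_population"]
    df["urban_density"] = (
        1e4 * (df["private"] + df["public_urban"]) / df["urban_population"]
    )
    return WorkforceTrajectory(df=df, rr=trajectory.rr)
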