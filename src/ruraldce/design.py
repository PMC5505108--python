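"""Choice-experiment designs: attribute spaces, balanced designs, diagnostics,
and simulation of respondents from a random-coefficient logit process.

The attribute space here describes a job-posting choice experiment: each
alternative is a hypothetical posting defined by one level of every attribute
(salary increase, housing benefit, transport benefit, career promotion timing,
continuing-education timing, facility quality).  Designs are sets of tasks,
each task a forced choice among ``n_alternatives`` postings.

The design generator is a best-of-N search over random level-balanced designs
scored by D-efficiency of the coded information matrix — a transparent,
reproducible stand-in for commercial conjoint design software.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Attribute",
    "AttributeSpace",
    "ChoiceDesign",
    "DesignDiagnostics",
    "DgpParams",
    "ChoiceData",
    "build_attribute_space",
    "generate_design",
    "design_diagnostics",
    "simulate_respondents",
]


@dataclass(frozen=True)
class Attribute:
    """One job attribute: named levels, a reference level, optional numeric values.

    When ``values`` is given the attribute is coded as a single column holding
    the numeric value of the assigned level (used for salary, where the value
    is the proportional pay increase so the coefficient is "per 100% of
    salary").  Otherwise the attribute is dummy coded against the reference
    level, one column per non-reference level.
    """

    name: str
    levels: tuple[str, ...]
    reference: int = 0
    values: tuple[float, ...] | None = None

    def __post_init__(self):
        if len(self.levels) < 2:
            raise ValueError(
                f"attribute {self.name!r} needs >=2 levels, got {len(self.levels)}"
            )
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"attribute {self.name!r} has duplicate level labels")
        if not 0 <= self.reference < len(self.levels):
            raise ValueError(f"attribute {self.name!r}: reference index out of range")
        if self.values is not None and len(self.values) != len(self.levels):
            raise ValueError(
                f"attribute {self.name!r}: values length != number of levels"
            )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def columns(self) -> list[str]:
        if self.values is not None:
            return [self.name]
        return [
            f"{self.name}:{lev}"
            for i, lev in enumerate(self.levels)
            if i != self.reference
        ]

    def code(self, level_index: int) -> np.ndarray:
        if self.values is not None:
            return np.array([self.values[level_index]], dtype=float)
        out = np.zeros(self.n_levels - 1)
        j = 0
        for i in range(self.n_levels):
            if i == self.reference:
                continue
            if i == level_index:
                out[j] = 1.0
            j += 1
        return out


@dataclass(frozen=True)
class AttributeSpace:
    """Ordered collection of attributes plus the induced coding map."""

    attributes: tuple[Attribute, ...]

    @property
    def n_attributes(self) -> int:
        return len(self.attributes)

    @property
    def level_counts(self) -> tuple[int, ...]:
        return tuple(a.n_levels for a in self.attributes)

    @property
    def column_names(self) -> list[str]:
        cols: list[str] = []
        for a in self.attributes:
            cols.extend(a.columns())
        return cols

    @property
    def n_columns(self) -> int:
        return len(self.column_names)

    def code_alternative(self, levels: tuple[int, ...]) -> np.ndarray:
        """Coded covariate row for one alternative (level index per attribute)."""
        if len(levels) != self.n_attributes:
            raise ValueError("level assignment length != number of attributes")
        return np.concatenate(
            [a.code(i) for a, i in zip(self.attributes, levels)]
        )

    def level_index(self, attr_name: str, label: str) -> int:
        for a in self.attributes:
            if a.name == attr_name:
                try:
                    return a.levels.index(label)
                except ValueError:
                    raise KeyError(
                        f"unknown level {label!r} for attribute {attr_name!r}"
                    ) from None
        raise KeyError(f"unknown attribute {attr_name!r}")


def build_attribute_space(config: dict) -> AttributeSpace:
    """Build an :class:`AttributeSpace` from a config mapping.

    ``config['attributes']`` is a list of dicts with keys ``name``, ``levels``
    and optionally ``reference`` (level label, defaults to the first level)
    and ``values`` (numeric coding).
    """
    attrs = []
    for spec in config["attributes"]:
        levels = tuple(spec["levels"])
        ref_label = spec.get("reference", levels[0])
        if ref_label not in levels:
            raise ValueError(
                f"attribute {spec['name']!r}: reference {ref_label!r} not a level"
            )
        attrs.append(
            Attribute(
                name=spec["name"],
                levels=levels,
                reference=levels.index(ref_label),
                values=tuple(spec["values"]) if "values" in spec else None,
            )
        )
    return AttributeSpace(attributes=tuple(attrs))


# ---------------------------------------------------------------------------
# Designs


@dataclass(frozen=True)
class ChoiceDesign:
    """A set of choice tasks; each task is a tuple of coded-level alternatives.

    ``tasks[t][j]`` is the level-index tuple of alternative ``j`` in task ``t``.
    """

    tasks: tuple[tuple[tuple[int, ...], ...], ...]

    @property
    def n_tasks(self) -> int:
        return len(self.tasks)

    @property
    def n_alternatives(self) -> int:
        return len(self.tasks[0]) if self.tasks else 0

    def coded(self, space: AttributeSpace) -> np.ndarray:
        """Array (n_tasks, n_alternatives, n_columns) of coded covariates."""
        return np.array(
            [[space.code_alternative(alt) for alt in task] for task in self.tasks]
        )


@dataclass
class DesignDiagnostics:
    level_counts: dict[str, dict[str, int]]
    balance_deviation: int
    d_efficiency: float
    warnings: list[str] = field(default_factory=list)


def d_efficiency(design: ChoiceDesign, space: AttributeSpace) -> float:
    """Determinant-based efficiency of the design's information matrix.

    Alternatives are coded, centered within task (the information matrix of
    the multinomial logit at zero coefficients is proportional to the
    within-task-centered cross-product), and the efficiency is
    ``det(M)**(1/K)`` with ``M`` the per-row normalized information matrix.
    Invariant to task ordering by construction.
    """
    X = design.coded(space)  # (T, J, K)
    Xc = X - X.mean(axis=1, keepdims=True)
    n_rows = X.shape[0] * X.shape[1]
    M = np.einsum("tjk,tjl->kl", Xc, Xc) / n_rows
    det = np.linalg.det(M)
    if det <= 0:
        return 0.0
    return float(det ** (1.0 / space.n_columns))


def _balanced_level_sequence(n_levels: int, n_slots: int, rng) -> np.ndarray:
    reps = [n_slots // n_levels + (1 if i < n_slots % n_levels else 0)
            for i in range(n_levels)]
    seq = np.repeat(np.arange(n_levels), reps)
    rng.shuffle(seq)
    return seq


def _random_balanced_design(space, n_tasks, n_alternatives, rng, max_repair=50):
    n_slots = n_tasks * n_alternatives
    for _ in range(max_repair):
        cols = [
            _balanced_level_sequence(a.n_levels, n_slots, rng)
            for a in space.attributes
        ]
        grid = np.stack(cols, axis=1).reshape(n_tasks, n_alternatives, -1)
        ok = True
        for t in range(n_tasks):
            alts = {tuple(grid[t, j]) for j in range(n_alternatives)}
            if len(alts) < n_alternatives:
                ok = False
                break
        if ok:
            return ChoiceDesign(
                tasks=tuple(
                    tuple(tuple(int(v) for v in grid[t, j])
                          for j in range(n_alternatives))
                    for t in range(n_tasks)
                )
            )
    # fall back: perturb duplicate alternatives instead of rejecting
    for t in range(n_tasks):
        seen = set()
        for j in range(n_alternatives):
            while tuple(grid[t, j]) in seen:
                k = rng.integers(space.n_attributes)
                grid[t, j, k] = rng.integers(space.attributes[k].n_levels)
            seen.add(tuple(grid[t, j]))
    return ChoiceDesign(
        tasks=tuple(
            tuple(tuple(int(v) for v in grid[t, j]) for j in range(n_alternatives))
            for t in range(n_tasks)
        )
    )


def generate_design(
    space: AttributeSpace,
    n_tasks: int,
    n_alternatives: int = 2,
    seed: int = 0,
    n_candidates: int = 200,
) -> ChoiceDesign:
    """Best of ``n_candidates`` random level-balanced designs by D-efficiency.

    Deterministic given ``seed``.  When exact level balance is impossible for
    the requested size, levels are spread as evenly as possible and a warning
    is attached by :func:`design_diagnostics`.
    """
    if n_tasks < 1:
        raise ValueError("n_tasks must be >= 1")
    if n_alternatives < 2:
        raise ValueError("n_alternatives must be >= 2")
    rng = np.random.default_rng(seed)
    best, best_eff = None, -np.inf
    for _ in range(n_candidates):
        cand = _random_balanced_design(space, n_tasks, n_alternatives, rng)
        eff = d_efficiency(cand, space)
        if eff > best_eff:
            best, best_eff = cand, eff
    return best


def design_diagnostics(design: ChoiceDesign, space: AttributeSpace) -> DesignDiagnostics:
    """Level-frequency counts, balance deviation and D-efficiency."""
    counts: dict[str, dict[str, int]] = {}
    notes: list[str] = []
    n_slots = design.n_tasks * design.n_alternatives
    for k, a in enumerate(space.attributes):
        c = {lev: 0 for lev in a.levels}
        for task in design.tasks:
            for alt in task:
                idx = alt[k]
                if not 0 <= idx < a.n_levels:
                    raise ValueError(
                        f"design references unknown level index {idx} "
                        f"for attribute {a.name!r}"
                    )
                c[a.levels[idx]] += 1
        counts[a.name] = c
        if n_slots % a.n_levels:
            notes.append(
                f"attribute {a.name!r}: exact level balance impossible for "
                f"{n_slots} slots over {a.n_levels} levels"
            )
    dev = max(
        max(c.values()) - min(c.values()) for c in counts.values()
    )
    return DesignDiagnostics(
        level_counts=counts,
        balance_deviation=int(dev),
        d_efficiency=d_efficiency(design, space),
        warnings=notes,
    )


# ---------------------------------------------------------------------------
# Data-generating process and simulation


@dataclass(frozen=True)
class DgpParams:
    """Random-coefficient logit data-generating process.

    ``means`` / ``sds`` are per coded column of the attribute space;
    an SD of 0 makes that coefficient fixed across respondents (the salary
    coefficient is fixed by default in the packaged fixture).
    """

    means: tuple[float, ...]
    sds: tuple[float, ...]

    def __post_init__(self):
        if len(self.means) != len(self.sds):
            raise ValueError("means and sds must have equal length")
        if any(s < 0 for s in self.sds):
            raise ValueError("coefficient SDs must be >= 0")

    @property
    def n_params(self) -> int:
        return len(self.means)


@dataclass
class ChoiceData:
    """Long-format choice records: one row per respondent × task × alternative."""

    df: pd.DataFrame
    space: AttributeSpace
    n_respondents: int
    n_tasks: int
    n_alternatives: int

    REQUIRED = ("respondent_id", "task_id", "alt_id", "chosen")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"choice data missing columns: {missing}")
        per_task = self.df.groupby(["respondent_id", "task_id"])["chosen"].sum()
        if not (per_task == 1).all():
            raise ValueError("each (respondent, task) must have exactly one chosen=1")

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, space: AttributeSpace) -> "ChoiceData":
        df = pd.read_csv(path)
        return cls(
            df=df,
            space=space,
            n_respondents=df["respondent_id"].nunique(),
            n_tasks=df["task_id"].nunique(),
            n_alternatives=df["alt_id"].nunique(),
        )

    def coded_arrays(self):
        """Arrays for estimation of a binary forced choice.

        Returns ``(Xdiff, y)`` with ``Xdiff`` of shape
        (n_respondents, n_tasks, n_columns): coded covariates of the first
        alternative minus the second, and ``y`` = 1 when the first alternative
        was chosen.
        """
        if self.n_alternatives != 2:
            raise NotImplementedError(
                "coded_arrays supports binary choice tasks only"
            )
        attr_names = [a.name for a in self.space.attributes]
        df = self.df.sort_values(["respondent_id", "task_id", "alt_id"])
        lev_idx = np.stack(
            [
                df[name].map(
                    {lev: i for i, lev in enumerate(a.levels)}
                ).to_numpy()
                for name, a in zip(attr_names, self.space.attributes)
            ],
            axis=1,
        )
        if np.isnan(lev_idx.astype(float)).any():
            raise ValueError("choice data contains level labels unknown to the space")
        X = np.array(
            [self.space.code_alternative(tuple(r)) for r in lev_idx]
        ).reshape(self.n_respondents, self.n_tasks, 2, -1)
        chosen = df["chosen"].to_numpy().reshape(
            self.n_respondents, self.n_tasks, 2
        )
        Xdiff = X[:, :, 0, :] - X[:, :, 1, :]
        y = chosen[:, :, 0].astype(float)
        return Xdiff, y


def simulate_respondents(
    design: ChoiceDesign,
    dgp: DgpParams,
    n_respondents: int,
    seed: int = 0,
    space: AttributeSpace | None = None,
) -> ChoiceData:
    """Simulate choices from the random-coefficient logit process.

    Each respondent draws one coefficient vector from independent normals
    ``N(mean_k, sd_k)``, evaluates the utility of every alternative in every
    task, and the chosen flag is drawn from the implied logit probabilities.
    Byte-identical output for identical ``(seed, params)``.
    """
    if space is None:
        raise ValueError("an AttributeSpace is required to code the design")
    K = space.n_columns
    if dgp.n_params != K:
        raise ValueError(
            f"DGP has {dgp.n_params} coefficients but the coded design has {K} columns"
        )
    rng = np.random.default_rng(seed)
    X = design.coded(space)  # (T, J, K)
    T, J, _ = X.shape
    means = np.asarray(dgp.means)
    sds = np.asarray(dgp.sds)

    betas = means + sds * rng.standard_normal((n_respondents, K))
    U = np.einsum("tjk,nk->ntj", X, betas)  # (N, T, J)
    U -= U.max(axis=2, keepdims=True)
    P = np.exp(U)
    P /= P.sum(axis=2, keepdims=True)
    # inverse-CDF draw of the chosen alternative per (respondent, task)
    cum = np.cumsum(P, axis=2)
    u = rng.random((n_respondents, T, 1))
    choice = (u > cum).sum(axis=2)

    attr_names = [a.name for a in space.attributes]
    rows = {
        "respondent_id": np.repeat(np.arange(n_respondents), T * J),
        "task_id": np.tile(np.repeat(np.arange(T), J), n_respondents),
        "alt_id": np.tile(np.arange(J), n_respondents * T),
    }
    df = pd.DataFrame(rows)
    level_labels = np.empty((T * J, len(attr_names)), dtype=object)
    for t in range(T):
        for j in range(J):
            for k, a in enumerate(space.attributes):
                level_labels[t * J + j, k] = a.levels[design.tasks[t][j][k]]
    tiled = np.tile(level_labels, (n_respondents, 1))
    for k, name in enumerate(attr_names):
        df[name] = tiled[:, k]
    chosen = np.zeros((n_respondents, T, J), dtype=int)
    np.put_along_axis(chosen, choice[:, :, None], 1, axis=2)
    df["chosen"] = chosen.reshape(-1)
    return ChoiceData(
        df=df,
        space=space,
        n_respondents=n_respondents,
        n_tasks=T,
        n_alternatives=J,
    )
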