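"""Conditional and mixed (random-coefficient) logit estimation.

The model: respondent ``n`` choosing in task ``t`` between two job postings
``A`` and ``B`` derives utility difference ``(x_A - x_B)' beta_n + eps``.
In the conditional logit ``beta_n = beta`` for everyone and the choice
probability is the logistic function of the utility difference.  In the mixed
logit each coefficient flagged random varies across respondents as
``beta_nk = b_k + s_k z_nk`` with ``z_nk`` standard normal; the respondent
likelihood integrates the product of task probabilities over that
distribution and is approximated by simulation:

    L_n = (1/R) sum_r prod_t P_nt(beta_nr)

with per-respondent blocks of scrambled Halton draws.  Maximization uses an
analytic gradient; standard errors come from the inverse observed Hessian of
the simulated log-likelihood (finite differences of the analytic gradient).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit, log_expit, logsumexp
from scipy.stats import norm, qmc

import statsmodels.api as sm

from .design import ChoiceData

__all__ = [
    "ModelSpec",
    "EstimationResult",
    "simulated_log_likelihood",
    "fit_conditional_logit",
    "fit_mixed_logit",
    "predict_choice_prob",
]


@dataclass(frozen=True)
class ModelSpec:
    """Estimation specification.

    ``random`` maps coefficient (column) names to True where the coefficient
    follows a normal mixing distribution; unnamed columns are fixed.  A spec
    with no random coefficients defines a conditional logit.
    """

    columns: tuple[str, ...]
    random: tuple[bool, ...]
    n_draws: int = 500
    draw_scheme: str = "halton"  # 'halton' | 'random'
    seed: int = 0
    maxiter: int = 500
    tol: float = 1e-8

    def __post_init__(self):
        if len(self.columns) < 1:
            raise ValueError("at least one coefficient required")
        if len(self.random) != len(self.columns):
            raise ValueError("random flags must match columns")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.draw_scheme not in ("halton", "random"):
            raise ValueError(f"unknown draw scheme {self.draw_scheme!r}")

    @property
    def n_random(self) -> int:
        return int(sum(self.random))

    @property
    def random_index(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.random))

    @classmethod
    def for_space(cls, space, random_all_but=("salary",), **kw) -> "ModelSpec":
        cols = tuple(space.column_names)
        rnd = tuple(not any(c == b or c.startswith(b + ":") for b in random_all_but)
                    for c in cols)
        return cls(columns=cols, random=rnd, **kw)


@dataclass
class EstimationResult:
    """Fitted coefficients of a (mixed) logit model.

    ``means``/``se_means`` cover every coefficient; ``sds``/``se_sds`` cover
    the random subset (sign-normalized to be >= 0).  ``cov`` is the full
    parameter covariance in the order (means..., sds...).
    """

    columns: tuple[str, ...]
    means: np.ndarray
    se_means: np.ndarray
    random_columns: tuple[str, ...]
    sds: np.ndarray
    se_sds: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    n_respondents: int
    n_choices: int
    flags: list[str] = field(default_factory=list)

    def coef(self, name: str) -> tuple[float, float]:
        """(mean, sd) for a coefficient; sd is 0 for fixed coefficients."""
        i = self.columns.index(name)
        sd = 0.0
        if name in self.random_columns:
            sd = float(self.sds[self.random_columns.index(name)])
        return float(self.means[i]), sd

    def vcov(self, name_a: str, name_b: str) -> float:
        """Covariance between two *mean* coefficients."""
        return float(self.cov[self.columns.index(name_a), self.columns.index(name_b)])

    @property
    def param_names(self) -> list[str]:
        return list(self.columns) + [f"sd:{c}" for c in self.random_columns]

    def to_dict(self) -> dict:
        return {
            "columns": list(self.columns),
            "means": self.means.tolist(),
            "se_means": self.se_means.tolist(),
            "random_columns": list(self.random_columns),
            "sds": self.sds.tolist(),
            "se_sds": self.se_sds.tolist(),
            "cov": self.cov.tolist(),
            "loglik": self.loglik,
            "converged": self.converged,
            "n_respondents": self.n_respondents,
            "n_choices": self.n_choices,
            "flags": self.flags,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "EstimationResult":
        return cls(
            columns=tuple(d["columns"]),
            means=np.asarray(d["means"], dtype=float),
            se_means=np.asarray(d["se_means"], dtype=float),
            random_columns=tuple(d["random_columns"]),
            sds=np.asarray(d["sds"], dtype=float),
            se_sds=np.asarray(d["se_sds"], dtype=float),
            cov=np.asarray(d["cov"], dtype=float),
            loglik=float(d["loglik"]),
            converged=bool(d["converged"]),
            n_respondents=int(d["n_respondents"]),
            n_choices=int(d["n_choices"]),
            flags=list(d.get("flags", [])),
        )

    @classmethod
    def from_json(cls, path) -> "EstimationResult":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def from_parameter_table(cls, table: dict[str, tuple[float, float]],
                             n_respondents: int = 0,
                             se: dict[str, float] | None = None,
                             cov: np.ndarray | None = None) -> "EstimationResult":
        """Build a result object from an external (mean, sd) table.

        Used to drive downstream stages from published coefficient tables
        without re-estimation.
        """
        cols = tuple(table)
        means = np.array([table[c][0] for c in cols])
        rnd = tuple(c for c in cols if table[c][1] > 0)
        sds = np.array([table[c][1] for c in rnd])
        se_means = np.array([(se or {}).get(c, np.nan) for c in cols])
        k = len(cols) + len(rnd)
        if cov is None:
            cov = np.full((k, k), np.nan)
            var = se_means**2
            cov[np.diag_indices(len(cols))] = var
        return cls(
            columns=cols, means=means, se_means=se_means,
            random_columns=rnd, sds=sds, se_sds=np.full(len(rnd), np.nan),
            cov=cov, loglik=np.nan, converged=True,
            n_respondents=n_respondents, n_choices=0,
        )


# ---------------------------------------------------------------------------
# Simulated likelihood


def _draws(n_respondents: int, n_random: int, spec: ModelSpec) -> np.ndarray:
    """Standard-normal mixing draws, shape (N, R, Kr); Halton by default."""
    R = spec.n_draws
    if n_random == 0:
        return np.zeros((n_respondents, R, 0))
    if spec.draw_scheme == "halton":
        sampler = qmc.Halton(d=n_random, scramble=True, seed=spec.seed)
        u = sampler.random(n_respondents * R)
    else:
        u = np.random.default_rng(spec.seed).random((n_respondents * R, n_random))
    u = np.clip(u, 1e-12, 1 - 1e-12)
    return norm.ppf(u).reshape(n_respondents, R, n_random)


def _sim_loglik_grad(params, Xd, y, spec, Z):
    """Simulated log-likelihood and its analytic gradient.

    Xd: (N, T, K) differenced covariates; y in {0,1}: first alternative chosen.
    params = (means..., sds of random coefficients...).
    """
    N, T, K = Xd.shape
    Kr = spec.n_random
    b, s = params[:K], params[K:]
    ridx = spec.random_index
    sgn = 2.0 * y - 1.0  # (N, T)

    U = Xd @ b  # (N, T)
    if Kr:
        V = np.einsum("ntk,nrk->ntr", Xd[:, :, ridx], Z * s)  # (N, T, R)
        tval = sgn[:, :, None] * (U[:, :, None] + V)
    else:
        tval = (sgn * U)[:, :, None]
    if not np.all(np.isfinite(tval)):
        bad = [n for n, v in zip(spec.columns, b) if not np.isfinite(v)]
        raise ValueError(f"non-finite utilities; offending parameters: {bad or params}")
    logP = log_expit(tval)  # (N, T, R)
    S = logP.sum(axis=1)  # (N, R)
    lse = logsumexp(S, axis=1)  # (N,)
    ll = float(np.sum(lse) - N * np.log(S.shape[1]))

    w = np.exp(S - lse[:, None])  # (N, R), sums to R-normalized weights
    w /= w.sum(axis=1, keepdims=True)
    q = (1.0 - np.exp(logP)) * sgn[:, :, None]  # (N, T, R)
    qw = np.einsum("nr,ntr->nt", w, q)  # weight-averaged residual
    g_b = np.einsum("nt,ntk->k", qw, Xd)
    if Kr:
        g_s = np.einsum("nr,ntr,ntk,nrk->k", w, q, Xd[:, :, ridx], Z,
                        optimize=True)
    else:
        g_s = np.zeros(0)
    return ll, np.concatenate([g_b, g_s])


def simulated_log_likelihood(params, data: ChoiceData, spec: ModelSpec) -> float:
    """Simulated log-likelihood at ``params`` (means then random-coefficient SDs).

    The per-respondent likelihood averages, over the spec's draws, the product
    over tasks of logit choice probabilities; deterministic given the spec
    seed.
    """
    params = np.asarray(params, dtype=float)
    Xd, y = data.coded_arrays()
    K = Xd.shape[2]
    if params.size != K + spec.n_random:
        raise ValueError(
            f"expected {K + spec.n_random} parameters, got {params.size}"
        )
    Z = _draws(Xd.shape[0], spec.n_random, spec)
    ll, _ = _sim_loglik_grad(params, Xd, y, spec, Z)
    return ll


# ---------------------------------------------------------------------------
# Fitting


def _check_identification(Xd, y, flags):
    # a coded column whose sign never varies against the choice indicates
    # separation / a level never (or always) chosen
    sgn = 2.0 * y - 1.0
    aligned = Xd * sgn[:, :, None]
    for k in range(Xd.shape[2]):
        col = aligned[:, :, k].ravel()
        nz = col[col != 0]
        if nz.size == 0 or (nz > 0).all() or (nz < 0).all():
            flags.append(f"possible non-identification: column index {k}")


def fit_conditional_logit(data: ChoiceData, spec: ModelSpec | None = None,
                          ) -> EstimationResult:
    """Fixed-coefficient logit on within-task differenced covariates.

    For binary forced choices the conditional logit reduces to a logistic
    regression of the first-alternative indicator on the coded covariate
    difference, with no intercept.
    """
    Xd, y = data.coded_arrays()
    N, T, K = Xd.shape
    flags: list[str] = []
    _check_identification(Xd, y, flags)
    Xf = Xd.reshape(N * T, K)
    yf = y.ravel()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(yf, Xf).fit(disp=0, maxiter=200)
            params = res.params
            cov_b = np.asarray(res.cov_params())
            se = res.bse
            ll = float(res.llf)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception as exc:  # separation can make the MLE diverge
            flags.append(f"conditional logit failed: {exc}")
            params = np.zeros(K)
            cov_b = np.full((K, K), np.nan)
            se = np.full(K, np.nan)
            ll = np.nan
            converged = False
    if np.any(np.abs(params) > 30):
        flags.append("extreme coefficient magnitude; separation suspected")
        converged = False
    cols = tuple(spec.columns) if spec is not None else tuple(data.space.column_names)
    return EstimationResult(
        columns=cols,
        means=np.asarray(params, dtype=float),
        se_means=np.asarray(se, dtype=float),
        random_columns=(),
        sds=np.zeros(0),
        se_sds=np.zeros(0),
        cov=cov_b,
        loglik=ll,
        converged=converged,
        n_respondents=N,
        n_choices=N * T,
        flags=flags,
    )


def _numeric_hessian(fun_grad, x, eps=1e-5):
    """Centered finite differences of an analytic gradient."""
    k = x.size
    H = np.zeros((k, k))
    for i in range(k):
        e = np.zeros(k)
        e[i] = eps
        _, gp = fun_grad(x + e)
        _, gm = fun_grad(x - e)
        H[i] = (gp - gm) / (2 * eps)
    return 0.5 * (H + H.T)


def fit_mixed_logit(data: ChoiceData, spec: ModelSpec,
                    start: np.ndarray | None = None) -> EstimationResult:
    """Maximum simulated likelihood fit of the random-coefficient logit.

    Starting values default to the conditional-logit means and 0.1 for each
    random-coefficient SD.  SDs are reported as absolute values.  On hitting
    the iteration cap the result is returned with ``converged=False``.
    """
    if spec.n_random == 0:
        return fit_conditional_logit(data, spec)
    if spec.n_draws < 100:
        warnings.warn("fewer than 100 simulation draws; estimates may be noisy")
    Xd, y = data.coded_arrays()
    N, T, K = Xd.shape
    Kr = spec.n_random
    flags: list[str] = []
    _check_identification(Xd, y, flags)
    Z = _draws(N, Kr, spec)

    if start is None:
        cl = fit_conditional_logit(data, spec)
        start = np.concatenate([cl.means, np.full(Kr, 0.1)])
        flags.extend(f"start: {f}" for f in cl.flags)
    start = np.asarray(start, dtype=float)
    if start.size != K + Kr:
        raise ValueError(f"start must have {K + Kr} entries")

    def negll(p):
        ll, g = _sim_loglik_grad(p, Xd, y, spec, Z)
        return -ll, -g

    opt = optimize.minimize(
        negll, start, jac=True, method="L-BFGS-B",
        options={"maxiter": spec.maxiter, "ftol": spec.tol, "gtol": 1e-6},
    )
    p = opt.x
    converged = bool(opt.success)
    if not converged:
        flags.append(f"optimizer: {opt.message}")

    def fg(x):
        return _sim_loglik_grad(x, Xd, y, spec, Z)

    H = -_numeric_hessian(fg, p)  # observed information of the simulated LL
    try:
        cov = np.linalg.inv(H)
        if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
            raise np.linalg.LinAlgError("indefinite information matrix")
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
        flags.append("information matrix not positive definite; pseudo-inverse SEs")

    # sign-normalize SDs (mixing distribution is symmetric in s)
    sflip = np.sign(p[K:])
    sflip[sflip == 0] = 1.0
    Jac = np.ones(K + Kr)
    Jac[K:] = sflip
    p = p.copy()
    p[K:] = np.abs(p[K:])
    cov = cov * np.outer(Jac, Jac)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))

    rnd_cols = tuple(np.asarray(spec.columns)[spec.random_index])
    return EstimationResult(
        columns=tuple(spec.columns),
        means=p[:K],
        se_means=se[:K],
        random_columns=rnd_cols,
        sds=p[K:],
        se_sds=se[K:],
        cov=cov,
        loglik=float(-opt.fun),
        converged=converged,
        n_respondents=N,
        n_choices=N * T,
        flags=flags,
    )


def predict_choice_prob(result: EstimationResult, x_first: np.ndarray,
                        x_second: np.ndarray, method: str = "plugin",
                        n_draws: int = 100_000, seed: int = 0) -> float:
    """Probability of choosing the first of two coded alternatives.

    ``plugin`` evaluates the logistic at the mean utility difference;
    ``simulated`` integrates over the random-coefficient distribution by
    Monte Carlo.
    """
    dx = np.asarray(x_first, dtype=float) - np.asarray(x_second, dtype=float)
    if dx.size != len(result.columns):
        raise ValueError("alternative coding does not match the fitted space")
    mean = float(dx @ result.means)
    if method == "plugin":
        return float(expit(mean))
    if method == "simulated":
        sd_full = np.zeros(len(result.columns))
        for j, c in enumerate(result.random_columns):
            sd_full[result.columns.index(c)] = result.sds[j]
        sd = float(np.sqrt(np.sum((dx * sd_full) ** 2)))
        rng = np.random.default_rng(seed)
        return float(expit(mean + sd * rng.standard_normal(n_draws)).mean())
    raise ValueError(f"unknown method {method!r}")
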