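"""From-scratch inference procedures used by the audit.

Implements exactly the tools the analysis needs, on numpy/scipy numerical
primitives only (least squares, ``gammaln``, chi-square/normal tails, BFGS):

* Gaussian (OLS) and binomial (logistic, logit link) regression with a
  candidate grid over Journal and polynomial-vs-factor Year forms, ranked
  by AIC;
* likelihood-ratio tests between nested fits;
* the Conway-Maxwell-Poisson (CMP) distribution and a log-link CMP
  regression for underdispersed gene counts, with a dispersion diagnostic
  against the Poisson special case;
* the two-sided Fisher exact test for 2x2 tables by hypergeometric
  enumeration in log space.

Conventions
-----------
AIC = -2*loglik + 2*k with k counting every estimated parameter, including
the Gaussian error variance for OLS (the R ``AIC()`` convention). Term-level
p-values for categorical blocks use likelihood-ratio chi-square tests.
The CMP model places the log link on the rate parameter lambda, the
classical formulation: pmf(y) proportional to lambda^y / (y!)^nu, with
nu > 1 underdispersed, nu = 1 Poisson, nu < 1 overdispersed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "ModelSpec",
    "ModelFitResult",
    "ConvergenceError",
    "RankDeficientError",
    "default_model_grid",
    "ols_fit",
    "logistic_fit",
    "aic_model_select",
    "SelectionResult",
    "lr_test",
    "LRTestResult",
    "cmp_log_z",
    "cmp_log_pmf",
    "cmp_pmf_table",
    "cmp_mean_var",
    "CmpModel",
    "cmp_regression_fit",
    "dispersion_check",
    "DispersionResult",
    "ContingencyTable2x2",
    "FisherResult",
    "fisher_exact_2x2",
]


class ConvergenceError(RuntimeError):
    """An iterative fit failed to converge (e.g. logistic separation)."""


class RankDeficientError(ValueError):
    """Design matrix is rank deficient; names the offending columns."""


# --------------------------------------------------------------------------
# model specification and design matrices
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """One candidate regression model over Journal and Year.

    ``year_form`` is a polynomial degree (1-4), ``"factor"`` (each year its
    own level), or ``None`` (no year term). ``interaction`` crosses the
    journal dummies with every year column. Year is centred at its sample
    mean before taking powers, for numerical conditioning only (the model
    space is unchanged).
    """

    response: str
    year_form: int | Literal["factor"] | None = 1
    interaction: bool = False
    include_journal: bool = True

    def __post_init__(self):
        if isinstance(self.year_form, int) and self.year_form < 1:
            raise ValueError("polynomial degree must be >= 1")
        if self.interaction and (self.year_form is None or not self.include_journal):
            raise ValueError("interaction requires both journal and year terms")

    def label(self) -> str:
        parts = []
        if self.include_journal:
            parts.append("journal")
        if self.year_form == "factor":
            parts.append("year(factor)")
        elif self.year_form is not None:
            parts.append(f"year(poly{self.year_form})")
        if self.interaction:
            parts.append("journal:year")
        return " + ".join(parts) if parts else "intercept-only"

    def build_design(self, data: pd.DataFrame) -> tuple[np.ndarray, list[str], dict]:
        """Return (X, column names, term -> column-slice mapping)."""
        n = len(data)
        cols: list[np.ndarray] = [np.ones(n)]
        names: list[str] = ["intercept"]
        terms: dict[str, list[int]] = {}

        journal_cols: list[np.ndarray] = []
        journal_names: list[str] = []
        if self.include_journal:
            levels = sorted(data["journal"].astype(str).unique())
            for lev in levels[1:]:
                journal_cols.append((data["journal"].astype(str) == lev).to_numpy(float))
                journal_names.append(f"journal[{lev}]")
            terms["journal"] = list(
                range(len(cols), len(cols) + len(journal_cols))
            )
            cols.extend(journal_cols)
            names.extend(journal_names)

        year_cols: list[np.ndarray] = []
        year_names: list[str] = []
        if self.year_form is not None:
            year = data["year"].to_numpy(float)
            if self.year_form == "factor":
                levels = sorted(np.unique(year))
                for lev in levels[1:]:
                    year_cols.append((year == lev).astype(float))
                    year_names.append(f"year[{int(lev)}]")
            else:
                yc = year - year.mean()
                for d in range(1, self.year_form + 1):
                    year_cols.append(yc**d)
                    year_names.append(f"year^{d}" if d > 1 else "year")
            terms["year"] = list(range(len(cols), len(cols) + len(year_cols)))
            cols.extend(year_cols)
            names.extend(year_names)

        if self.interaction:
            start = len(cols)
            for jc, jn in zip(journal_cols, journal_names):
                for yc_, yn in zip(year_cols, year_names):
                    cols.append(jc * yc_)
                    names.append(f"{jn}:{yn}")
            terms["journal:year"] = list(range(start, len(cols)))

        return np.column_stack(cols), names, terms


def default_model_grid(response: str) -> list[ModelSpec]:
    """The candidate grid: Year linear through quartic or as a factor,
    each with and without the Journal x Year interaction, Journal always in."""
    grid: list[ModelSpec] = []
    forms: list[int | str] = [1, 2, 3, 4, "factor"]
    for interaction in (False, True):
        for form in forms:
            grid.append(
                ModelSpec(response=response, year_form=form, interaction=interaction)
            )
    return grid


@dataclass(frozen=True)
class ModelFitResult:
    """Fitted-model container shared by the Gaussian and binomial families."""

    spec: ModelSpec
    family: str
    param_names: tuple[str, ...]
    params: np.ndarray
    cov: np.ndarray
    loglik: float
    k_params: int
    nobs: int
    term_pvalues: dict[str, float] = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k_params

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        """Per-coefficient Wald p-values (normal reference)."""
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    def param(self, name: str) -> float:
        return float(self.params[self.param_names.index(name)])


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns with negligible contribution via the QR diagonal
        _, rmat = np.linalg.qr(X)
        diag = np.abs(np.diag(rmat))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[i] for i in range(X.shape[1]) if i < len(diag) and diag[i] <= tol]
        raise RankDeficientError(
            f"design matrix rank {rank} < {X.shape[1]} columns; "
            f"collinear terms: {bad or 'undetermined'}"
        )


def _gaussian_loglik(resid: np.ndarray) -> float:
    n = resid.size
    rss = float(resid @ resid)
    if rss <= 0.0:
        # perfect fit: likelihood unbounded; return a large finite guard value
        rss = n * np.finfo(float).tiny
    sigma2 = rss / n
    return -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)


def _ols_core(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ll = _gaussian_loglik(resid)
    n, p = X.shape
    rss = float(resid @ resid)
    s2 = rss / max(n - p, 1)
    cov = s2 * np.linalg.pinv(X.T @ X)
    return beta, ll, cov


def ols_fit(
    spec: ModelSpec, data: pd.DataFrame, term_tests: bool = True
) -> ModelFitResult:
    """Ordinary least squares with Gaussian ML log-likelihood and AIC.

    ``k_params`` counts the coefficients plus the error variance. Term-level
    p-values (one per categorical/polynomial block) are likelihood-ratio
    chi-square tests refitting without the block.
    """
    X, names, terms = spec.build_design(data)
    y = data[spec.response].to_numpy(float)
    n, p = X.shape
    if n < p:
        raise ValueError(f"n={n} must be at least the number of coefficients p={p}")
    _check_rank(X, names)
    beta, ll, cov = _ols_core(X, y)
    term_p: dict[str, float] = {}
    if term_tests:
        for term, idx in terms.items():
            keep = [i for i in range(p) if i not in idx]
            _, ll0, _ = _ols_core(X[:, keep], y)
            stat = max(2.0 * (ll - ll0), 0.0)
            term_p[term] = float(stats.chi2.sf(stat, df=len(idx)))
    return ModelFitResult(
        spec=spec,
        family="gaussian",
        param_names=tuple(names),
        params=beta,
        cov=cov,
        loglik=ll,
        k_params=p + 1,
        nobs=n,
        term_pvalues=term_p,
    )


def _logistic_core(
    X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10
) -> tuple[np.ndarray, float, np.ndarray]:
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = special.expit(eta)
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        z = eta + (y - mu) / w
        wx = X * w[:, None]
        beta_new, *_ = np.linalg.lstsq(wx.T @ X, wx.T @ z, rcond=None)
        eta_new = np.clip(X @ beta_new, -30.0, 30.0)
        ll = float(np.sum(y * eta_new - np.log1p(np.exp(eta_new))))
        beta = beta_new
        if abs(ll - ll_old) < tol * (abs(ll) + 1.0):
            break
        ll_old = ll
    else:
        raise ConvergenceError(
            "logistic regression did not converge (possible complete separation)"
        )
    if np.max(np.abs(beta)) > 1e3:
        raise ConvergenceError(
            "logistic coefficients diverged (complete or quasi-complete separation)"
        )
    eta = np.clip(X @ beta, -30.0, 30.0)
    mu = special.expit(eta)
    if np.all(np.abs(y - mu) < 1e-6):
        raise ConvergenceError(
            "fitted probabilities collapsed to 0/1: complete separation"
        )
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    cov = np.linalg.pinv((X * w[:, None]).T @ X)
    return beta, ll, cov


def logistic_fit(
    spec: ModelSpec, data: pd.DataFrame, term_tests: bool = True
) -> ModelFitResult:
    """Maximum-likelihood logistic regression (logit link) via IRLS.

    The response must be coded 0/1 and contain both classes. Complete
    separation is reported as :class:`ConvergenceError`.
    """
    X, names, terms = spec.build_design(data)
    y = data[spec.response].to_numpy(float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binary response must be coded 0/1")
    if y.min() == y.max():
        raise ValueError("degenerate response: all values identical")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n={n} must exceed number of coefficients p={p}")
    _check_rank(X, names)
    beta, ll, cov = _logistic_core(X, y)
    term_p: dict[str, float] = {}
    if term_tests:
        for term, idx in terms.items():
            keep = [i for i in range(p) if i not in idx]
            _, ll0, _ = _logistic_core(X[:, keep], y)
            stat = max(2.0 * (ll - ll0), 0.0)
            term_p[term] = float(stats.chi2.sf(stat, df=len(idx)))
    return ModelFitResult(
        spec=spec,
        family="binomial",
        param_names=tuple(names),
        params=beta,
        cov=cov,
        loglik=ll,
        k_params=p,
        nobs=n,
        term_pvalues=term_p,
    )


@dataclass(frozen=True)
class SelectionResult:
    best: ModelFitResult
    ranking: pd.DataFrame  # label, year_form, interaction, k, loglik, aic, delta_aic, status
    fits: tuple[ModelFitResult | None, ...]


def aic_model_select(
    candidates: Sequence[ModelSpec],
    data: pd.DataFrame,
    family: Literal["gaussian", "binomial"] = "gaussian",
) -> SelectionResult:
    """Fit every candidate and return the lowest-AIC model plus the ranking.

    Candidates that fail to fit are excluded with their error recorded.
    Ties (|dAIC| < 1e-6) break toward fewer parameters, then listed order.
    """
    if len(candidates) < 1:
        raise ValueError("need at least one candidate model")
    fit_fn = ols_fit if family == "gaussian" else logistic_fit
    fits: list[ModelFitResult | None] = []
    rows = []
    errors = []
    for i, spec in enumerate(candidates):
        try:
            fit = fit_fn(spec, data, term_tests=False)
            fits.append(fit)
            rows.append(
                {
                    "model": spec.label(),
                    "year_form": str(spec.year_form),
                    "interaction": spec.interaction,
                    "k": fit.k_params,
                    "loglik": fit.loglik,
                    "aic": fit.aic,
                    "status": "ok",
                }
            )
        except (ValueError, ConvergenceError, RankDeficientError) as exc:
            fits.append(None)
            errors.append(f"{spec.label()}: {exc}")
            rows.append(
                {
                    "model": spec.label(),
                    "year_form": str(spec.year_form),
                    "interaction": spec.interaction,
                    "k": np.nan,
                    "loglik": np.nan,
                    "aic": np.nan,
                    "status": f"failed: {exc}",
                }
            )
    ok = [(i, f) for i, f in enumerate(fits) if f is not None]
    if not ok:
        raise ValueError("all candidate models failed: " + "; ".join(errors))
    min_aic = min(f.aic for _, f in ok)
    best_idx, best = min(
        ok, key=lambda t: (t[1].aic > min_aic + 1e-6, t[1].k_params, t[0])
    )
    ranking = pd.DataFrame(rows)
    ranking["delta_aic"] = ranking["aic"] - min_aic
    ranking = ranking.sort_values(
        ["aic", "k"], kind="stable", na_position="last"
    ).reset_index(drop=True)
    return SelectionResult(best=best, ranking=ranking, fits=tuple(fits))


@dataclass(frozen=True)
class LRTestResult:
    statistic: float
    df: int
    pvalue: float


def lr_test(nested: ModelFitResult, full: ModelFitResult) -> LRTestResult:
    """Likelihood-ratio chi-square test of a nested model against a fuller one."""
    if nested.nobs != full.nobs or nested.family != full.family:
        raise ValueError("models were fitted to different data or families")
    if nested.k_params > full.k_params:
        raise ValueError("'nested' must not have more parameters than 'full'")
    if not set(nested.param_names) <= set(full.param_names):
        raise ValueError("models are not nested (coefficient sets do not nest)")
    stat = max(2.0 * (full.loglik - nested.loglik), 0.0)
    df = full.k_params - nested.k_params
    if df == 0:
        # identical models: no evidence either way
        return LRTestResult(statistic=stat, df=0, pvalue=1.0 if stat < 1e-8 else 0.0)
    return LRTestResult(
        statistic=stat, df=df, pvalue=float(stats.chi2.sf(stat, df=df))
    )


# --------------------------------------------------------------------------
# Conway-Maxwell-Poisson
# --------------------------------------------------------------------------

_Z_REL_TOL_LOG = math.log(1e-12)
_Z_MAX_TERMS = 100_000


def cmp_log_z(lam: float, nu: float) -> float:
    """log of the CMP normalizing constant Z(lambda, nu) = sum_j lambda^j/(j!)^nu.

    Terms are accumulated in log space until a term falls below the running
    sum times 1e-12 (past the mode), with a hard cap of 100000 terms.
    """
    if lam <= 0 or nu <= 0:
        raise ValueError("lam and nu must be positive")
    log_lam = math.log(lam)
    # mode of the series is near lambda**(1/nu); computed in log space so
    # extreme (lam, nu) proposals from an optimizer fail cleanly, not overflow
    log_mode = log_lam / nu
    if log_mode > math.log(_Z_MAX_TERMS):
        raise RuntimeError(
            f"CMP normalizing series needs more than {_Z_MAX_TERMS} terms "
            f"(lam={lam}, nu={nu})"
        )
    mode = math.exp(log_mode)
    log_sum = 0.0  # j = 0 term is 1
    for j in range(1, _Z_MAX_TERMS):
        log_term = j * log_lam - nu * special.gammaln(j + 1)
        log_sum = np.logaddexp(log_sum, log_term)
        if j > mode and log_term < log_sum + _Z_REL_TOL_LOG:
            return float(log_sum)
    raise RuntimeError(
        f"CMP normalizing series did not converge within {_Z_MAX_TERMS} terms "
        f"(lam={lam}, nu={nu})"
    )


def cmp_log_pmf(y: int | np.ndarray, lam: float, nu: float) -> float | np.ndarray:
    """CMP log pmf: y*log(lam) - nu*log(y!) - log Z(lam, nu)."""
    y_arr = np.asarray(y)
    if not np.issubdtype(y_arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(y_arr, 1), 0)):
            raise ValueError("y must be a non-negative integer")
        y_arr = y_arr.astype(int)
    if np.any(y_arr < 0):
        raise ValueError("y must be a non-negative integer")
    log_z = cmp_log_z(lam, nu)
    out = y_arr * math.log(lam) - nu * special.gammaln(y_arr + 1) - log_z
    return float(out) if np.isscalar(y) else out


def cmp_pmf_table(lam: float, nu: float, tail: float = 1e-12) -> np.ndarray:
    """pmf over 0..K where K leaves at most ``tail`` probability beyond."""
    log_z = cmp_log_z(lam, nu)
    log_lam = math.log(lam)
    mode = math.exp(math.log(lam) / nu)
    probs = []
    cum = 0.0
    j = 0
    while j < _Z_MAX_TERMS:
        p = math.exp(j * log_lam - nu * special.gammaln(j + 1) - log_z)
        probs.append(p)
        cum += p
        if j > mode and cum >= 1.0 - tail:
            break
        j += 1
    return np.array(probs)


def cmp_mean_var(lam: float, nu: float) -> tuple[float, float]:
    """Exact mean and variance via the truncated pmf table."""
    p = cmp_pmf_table(lam, nu)
    ys = np.arange(p.size)
    m = float(ys @ p)
    v = float((ys - m) ** 2 @ p)
    return m, v


@dataclass(frozen=True)
class CmpModel:
    """Fitted log-link CMP regression: lambda_i = exp(x_i' beta), shared nu."""

    param_names: tuple[str, ...]
    beta: np.ndarray
    nu: float
    cov: np.ndarray  # over (beta, log nu)
    loglik: float
    nobs: int
    converged: bool

    @property
    def k_params(self) -> int:
        return len(self.beta) + 1

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k_params

    def coef_ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        i = self.param_names.index(name)
        z = stats.norm.ppf(0.5 + level / 2.0)
        se = math.sqrt(self.cov[i, i])
        return float(self.beta[i] - z * se), float(self.beta[i] + z * se)

    def rate_ratio(self, name: str = "group") -> float:
        """exp(beta) for a covariate: fold-change in the rate parameter."""
        return math.exp(self.beta[self.param_names.index(name)])

    def rate_ratio_ci(self, name: str = "group", level: float = 0.95) -> tuple[float, float]:
        lo, hi = self.coef_ci(name, level)
        return math.exp(lo), math.exp(hi)


def _cmp_negloglik(theta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    beta, log_nu = theta[:-1], theta[-1]
    if abs(log_nu) > 8.0:  # keep the optimizer out of absurd dispersion regions
        return 1e12
    nu = math.exp(log_nu)
    eta = X @ beta
    if np.max(np.abs(eta)) > 30.0:
        return 1e12
    uniq, inv = np.unique(np.round(eta, 12), return_inverse=True)
    try:
        log_zs = np.array([cmp_log_z(math.exp(e), nu) for e in uniq])
    except RuntimeError:
        return 1e12
    ll = float(y @ eta - nu * np.sum(special.gammaln(y + 1)) - np.sum(log_zs[inv]))
    return -ll


def _numerical_hessian(
    fn: Callable[[np.ndarray], float], x: np.ndarray, rel_step: float = 1e-4
) -> np.ndarray:
    p = x.size
    h = rel_step * (1.0 + np.abs(x))
    hess = np.empty((p, p))
    f0 = fn(x)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                val = (fn(x + ei) - 2.0 * f0 + fn(x - ei)) / (h[i] * h[i])
            else:
                val = (
                    fn(x + ei + ej) - fn(x + ei - ej) - fn(x - ei + ej) + fn(x - ei - ej)
                ) / (4.0 * h[i] * h[j])
            hess[i, j] = hess[j, i] = val
    return hess


def _poisson_irls(X: np.ndarray, y: np.ndarray, max_iter: int = 100) -> np.ndarray:
    beta = np.zeros(X.shape[1])
    beta[0] = math.log(max(float(y.mean()), 1e-3))
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = np.exp(eta)
        z = eta + (y - mu) / mu
        wx = X * mu[:, None]
        beta_new, *_ = np.linalg.lstsq(wx.T @ X, wx.T @ z, rcond=None)
        if np.max(np.abs(beta_new - beta)) < 1e-10:
            beta = beta_new
            break
        beta = beta_new
    return beta


def _as_design(
    group: np.ndarray, extra: np.ndarray | None
) -> tuple[np.ndarray, tuple[str, ...]]:
    n = group.size
    cols = [np.ones(n), group.astype(float)]
    names = ["intercept", "group"]
    if extra is not None:
        extra = np.atleast_2d(np.asarray(extra, float))
        if extra.shape[0] != n:
            extra = extra.T
        for j in range(extra.shape[1]):
            cols.append(extra[:, j])
            names.append(f"x{j + 1}")
    return np.column_stack(cols), tuple(names)


def cmp_regression_fit(
    counts: Sequence[int] | np.ndarray,
    group: Sequence[int] | np.ndarray,
    extra: np.ndarray | None = None,
    fix_nu: float | None = None,
    max_iter: int = 500,
) -> CmpModel:
    """Joint ML fit of the log-link CMP regression by quasi-Newton search.

    ``counts ~ CMP(lambda_i, nu)`` with ``log lambda_i = b0 + b1*group (+ extras)``.
    Optimizes over (beta, log nu) with BFGS from several dispersion starts
    (nu0 in {0.5, 1, 2}); covariance is the inverse observed information
    (central-difference Hessian). ``fix_nu`` pins the dispersion (nu=1 gives
    Poisson regression), used by the dispersion diagnostic.

    Raises ``ValueError`` for a constant group covariate or degenerate
    (all-identical) counts, :class:`ConvergenceError` when no start converges.
    """
    y = np.asarray(counts, float)
    g = np.asarray(group, float)
    if y.size != g.size:
        raise ValueError("counts and group must have the same length")
    if np.any(y < 0) or not np.all(np.equal(np.mod(y, 1), 0)):
        raise ValueError("counts must be non-negative integers")
    if np.ptp(g) == 0:
        raise ValueError("group covariate is constant: contrast is inestimable")
    if min(np.sum(g == v) for v in np.unique(g)) < 2:
        raise ValueError("each group level needs at least 2 records")
    if np.ptp(y) == 0:
        raise ValueError("degenerate counts: all observations identical")
    X, names = _as_design(g, extra)
    _check_rank(X, list(names))
    beta0 = _poisson_irls(X, y)

    if fix_nu is not None:
        nll = lambda b: _cmp_negloglik(np.append(b, math.log(fix_nu)), X, y)
        res = optimize.minimize(
            nll, beta0, method="BFGS", options={"maxiter": max_iter, "gtol": 1e-9}
        )
        if not res.success and not res.status == 2:  # status 2: precision loss, usually benign
            raise ConvergenceError(f"CMP fit (nu fixed) failed: {res.message}")
        hess = _numerical_hessian(nll, res.x)
        cov_b = np.linalg.pinv(hess)
        cov = np.zeros((len(names) + 1, len(names) + 1))
        cov[: len(names), : len(names)] = cov_b
        return CmpModel(
            param_names=names,
            beta=res.x,
            nu=fix_nu,
            cov=cov,
            loglik=-res.fun,
            nobs=y.size,
            converged=bool(res.success or res.status == 2),
        )

    best = None
    for nu0 in (0.5, 1.0, 2.0):
        theta0 = np.append(beta0, math.log(nu0))
        res = optimize.minimize(
            _cmp_negloglik,
            theta0,
            args=(X, y),
            method="BFGS",
            options={"maxiter": max_iter, "gtol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise ConvergenceError("CMP regression failed from every start")
    if not (best.success or best.status == 2):
        raise ConvergenceError(f"CMP regression did not converge: {best.message}")
    hess = _numerical_hessian(lambda t: _cmp_negloglik(t, X, y), best.x)
    cov = np.linalg.pinv(hess)
    return CmpModel(
        param_names=names,
        beta=best.x[:-1],
        nu=math.exp(best.x[-1]),
        cov=cov,
        loglik=-best.fun,
        nobs=y.size,
        converged=bool(best.success or best.status == 2),
    )


@dataclass(frozen=True)
class DispersionResult:
    verdict: Literal["underdispersed", "equidispersed", "overdispersed"]
    nu_hat: float
    statistic: float
    pvalue: float


def dispersion_check(
    counts: Sequence[int] | np.ndarray,
    group: Sequence[int] | np.ndarray,
    alpha: float = 0.05,
) -> DispersionResult:
    """Likelihood-ratio test of Poisson (nu = 1) against free CMP dispersion.

    Verdict is "underdispersed" when nu-hat > 1 and the LRT rejects at
    ``alpha`` (one degree of freedom), "overdispersed" for nu-hat < 1 with
    rejection, else "equidispersed".
    """
    free = cmp_regression_fit(counts, group)
    poisson = cmp_regression_fit(counts, group, fix_nu=1.0)
    stat = max(2.0 * (free.loglik - poisson.loglik), 0.0)
    p = float(stats.chi2.sf(stat, df=1))
    if p < alpha:
        verdict = "underdispersed" if free.nu > 1.0 else "overdispersed"
    else:
        verdict = "equidispersed"
    return DispersionResult(verdict=verdict, nu_hat=free.nu, statistic=stat, pvalue=p)


# --------------------------------------------------------------------------
# Fisher exact test
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 integer table; rows/cols labelled for report output."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("row1", "row2")
    col_labels: tuple[str, str] = ("col1", "col2")

    def __post_init__(self):
        cells = (self.a, self.b, self.c, self.d)
        if any((not isinstance(x, (int, np.integer))) or x < 0 for x in cells):
            raise ValueError("cells must be non-negative integers")
        if sum(cells) == 0:
            raise ValueError("table must have at least one positive margin")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class FisherResult:
    pvalue: float
    odds_ratio: float  # sample OR, inf when b*c == 0 and a*d > 0
    table: ContingencyTable2x2


def _log_hypergeom_pmf(k: np.ndarray, r1: int, r2: int, c1: int) -> np.ndarray:
    n = r1 + r2
    return (
        special.gammaln(r1 + 1)
        - special.gammaln(k + 1)
        - special.gammaln(r1 - k + 1)
        + special.gammaln(r2 + 1)
        - special.gammaln(c1 - k + 1)
        - special.gammaln(r2 - (c1 - k) + 1)
        - (special.gammaln(n + 1) - special.gammaln(c1 + 1) - special.gammaln(n - c1 + 1))
    )


def fisher_exact_2x2(table: ContingencyTable2x2 | Sequence[Sequence[int]]) -> FisherResult:
    """Two-sided Fisher exact test by full hypergeometric enumeration.

    With margins fixed, the two-sided p-value sums the point probabilities
    of every table no more probable than the observed one (the convention
    of mainstream statistical software; a relative tolerance of 1e-7
    guards the <= comparison). Computed in log space; exact for any cell
    sizes the log-gamma function can represent.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1 = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or b + d == 0:
        # a zero margin: only one table possible
        or_ = _sample_or(a, b, c, d)
        return FisherResult(pvalue=1.0, odds_ratio=or_, table=table)
    kmin = max(0, c1 - r2)
    kmax = min(r1, c1)
    ks = np.arange(kmin, kmax + 1)
    logp = _log_hypergeom_pmf(ks, r1, r2, c1)
    log_obs = float(logp[ks == a][0])
    keep = logp <= log_obs + math.log(1.0 + 1e-7)
    if keep.all():
        p = 1.0
    else:
        p = float(np.exp(special.logsumexp(logp[keep])))
    return FisherResult(
        pvalue=min(p, 1.0), odds_ratio=_sample_or(a, b, c, d), table=table
    )


def _sample_or(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)
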