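"""Cumulative-logit (proportional-odds) regression for ordinal RPE.

Model
-----
For an ordinal outcome with observed categories c_1 < ... < c_K and a
covariate vector x, the cumulative-logit model is

    P(Y <= c_j | x) = F(zeta_j - x' beta),     j = 1, ..., K-1,

with F the standard logistic CDF, strictly increasing cutpoints zeta and
a single coefficient vector beta shared across cutpoints (the
proportional-odds assumption).  exp(beta_k) is the odds ratio for higher
outcome categories per unit increase of covariate k.

Fitting maximises the likelihood with an analytic gradient on an
unconstrained reparameterisation of the cutpoints (first cutpoint free,
positive increments through exponentials).  Standard errors come from the
inverse observed information at the optimum, evaluated in the original
(beta, zeta) coordinates; confidence intervals are Wald intervals.

The five covariates of the anchor models are fixed by design — male sex,
treadmill ergometry, age (years), VO2max (ml/kg/min) and the number of
completed stages — with no variable selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .errors import DomainError, FitFailedError

__all__ = [
    "COVARIATES",
    "ModelSpec",
    "OrdinalFit",
    "ProbabilityProfile",
    "negative_log_likelihood",
    "fit_cumulative_logit",
    "odds_ratio_table",
    "predict_probabilities",
    "find_crossovers",
]

COVARIATES = ("male", "treadmill", "age", "vo2max", "n_stages")

_P_FLOOR = 1e-300  # guards log of an underflowed category probability


@dataclass(frozen=True)
class ModelSpec:
    """One anchor model: outcome column plus the fixed covariate set."""

    outcome: str
    covariates: tuple[str, ...] = COVARIATES


@dataclass
class OrdinalFit:
    """A fitted cumulative-logit model (or an honest failure record)."""

    beta: np.ndarray
    zeta: np.ndarray
    loglik: float
    vcov: np.ndarray  # covariance of (beta, zeta), beta block first
    covariate_names: tuple[str, ...]
    category_labels: np.ndarray
    converged: bool
    n_used: int
    failure: str | None = None

    @property
    def n_params(self) -> int:
        return len(self.beta) + len(self.zeta)

    def beta_se(self) -> np.ndarray:
        p = len(self.beta)
        return np.sqrt(np.diag(self.vcov)[:p])


def _check_zeta(zeta: np.ndarray) -> None:
    if len(zeta) >= 2 and np.any(np.diff(zeta) <= 0):
        raise DomainError("cutpoints must be strictly increasing")


def _nll_grad(beta, zeta, X, y, n_categories):
    """Negative log-likelihood and its gradient in (beta, zeta)."""
    eta = X @ beta
    z = np.concatenate(([-np.inf], zeta, [np.inf]))
    upper = z[y + 1] - eta
    lower = z[y] - eta
    Fu = expit(upper)
    Fl = expit(lower)
    p = np.clip(Fu - Fl, _P_FLOOR, None)
    nll = -np.log(p).sum()

    fu = Fu * (1.0 - Fu)  # logistic density at the upper cut
    fl = Fl * (1.0 - Fl)
    g_beta = X.T @ ((fu - fl) / p)

    n_cuts = n_categories - 1
    g_zeta = np.zeros(n_cuts)
    has_upper = y <= n_cuts - 1
    g_zeta -= np.bincount(y[has_upper], weights=(fu / p)[has_upper], minlength=n_cuts)
    has_lower = y >= 1
    g_zeta += np.bincount(y[has_lower] - 1, weights=(fl / p)[has_lower], minlength=n_cuts)
    return nll, g_beta, g_zeta


def negative_log_likelihood(beta, zeta, X, y) -> float:
    """Cumulative-logit negative log-likelihood.

    ``y`` holds 0-based category indices; ``zeta`` must be strictly
    increasing with one fewer entries than there are categories.
    """
    beta = np.asarray(beta, dtype=float)
    zeta = np.asarray(zeta, dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_zeta(zeta)
    nll, _, _ = _nll_grad(beta, zeta, X, y, len(zeta) + 1)
    return float(nll)


def _pack(beta, zeta):
    incr = np.diff(zeta)
    return np.concatenate([beta, [zeta[0]], np.log(incr)])


def _unpack(theta, n_beta):
    beta = theta[:n_beta]
    zeta0 = theta[n_beta]
    incr = np.exp(theta[n_beta + 1:])
    zeta = zeta0 + np.concatenate([[0.0], np.cumsum(incr)])
    return beta, zeta


def _objective(theta, X, y, n_beta, n_categories):
    beta, zeta = _unpack(theta, n_beta)
    nll, g_beta, g_zeta = _nll_grad(beta, zeta, X, y, n_categories)
    # chain rule through the (zeta_1, log increments) reparameterisation
    g_theta = np.empty_like(theta)
    g_theta[:n_beta] = g_beta
    g_theta[n_beta] = g_zeta.sum()
    if len(g_zeta) > 1:
        tail = np.cumsum(g_zeta[::-1])[::-1]  # tail[j] = sum_{m >= j} g_zeta[m]
        g_theta[n_beta + 1:] = np.exp(theta[n_beta + 1:]) * tail[1:]
    return nll, g_theta


def _observed_information(beta, zeta, X, y, n_categories, step=1e-5):
    """Hessian of the NLL in (beta, zeta) via central differences of the
    analytic gradient."""
    point = np.concatenate([beta, zeta])
    n = len(point)
    n_beta = len(beta)

    def grad(v):
        _, gb, gz = _nll_grad(v[:n_beta], v[n_beta:], X, y, n_categories)
        return np.concatenate([gb, gz])

    hess = np.empty((n, n))
    for j in range(n):
        h = step * (1.0 + abs(point[j]))
        up = point.copy()
        up[j] += h
        dn = point.copy()
        dn[j] -= h
        hess[:, j] = (grad(up) - grad(dn)) / (2.0 * h)
    return (hess + hess.T) / 2.0


def _failed(names, labels, n_used, reason) -> OrdinalFit:
    k = max(len(labels) - 1, 0)
    p = len(names)
    return OrdinalFit(
        beta=np.full(p, np.nan),
        zeta=np.full(k, np.nan),
        loglik=np.nan,
        vcov=np.full((p + k, p + k), np.nan),
        covariate_names=tuple(names),
        category_labels=np.asarray(labels),
        converged=False,
        n_used=n_used,
        failure=reason,
    )


def fit_cumulative_logit(
    spec: ModelSpec,
    data: pd.DataFrame,
    maxiter: int = 500,
) -> OrdinalFit:
    """Maximum-likelihood fit of one anchor model on complete cases.

    ``data`` must contain the outcome column and numeric covariate
    columns named in ``spec``.  Rows with a missing outcome or covariate
    are dropped (and reflected in ``n_used``).  Ordinal levels absent from
    the data are dropped from the cutpoint set; the observed levels are
    recorded in ``category_labels``.  Degenerate designs (a constant
    covariate, fewer than two outcome categories, singular information)
    yield a non-converged fit carrying diagnostics instead of raising.
    """
    cols = [spec.outcome, *spec.covariates]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise DomainError(f"data lacks column(s): {', '.join(missing)}")
    frame = data[cols].dropna()
    n = len(frame)

    labels, y = np.unique(frame[spec.outcome].to_numpy(), return_inverse=True)
    X = frame[list(spec.covariates)].to_numpy(dtype=float)
    n_cat = len(labels)
    n_beta = X.shape[1]

    if n_cat < 2:
        return _failed(spec.covariates, labels, n, "fewer than two outcome categories")
    if n <= n_beta + n_cat - 1:
        return _failed(spec.covariates, labels, n, "fewer observations than parameters")
    constant = [name for name, col in zip(spec.covariates, X.T) if np.ptp(col) == 0]
    if constant:
        return _failed(
            spec.covariates, labels, n, f"constant covariate(s): {', '.join(constant)}"
        )

    # optimize on standardized covariates (unit scale conditions the
    # quasi-Newton steps); estimates are mapped back afterwards
    mu = X.mean(axis=0)
    scale = X.std(axis=0)
    Xs = (X - mu) / scale

    # init: cutpoints from marginal cumulative frequencies, beta = 0
    cum = np.cumsum(np.bincount(y, minlength=n_cat))[:-1] / n
    zeta0 = np.log(cum / (1.0 - cum))
    theta0 = _pack(np.zeros(n_beta), zeta0)

    res = minimize(
        _objective,
        theta0,
        args=(Xs, y, n_beta, n_cat),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7},
    )
    beta_s, zeta_s = _unpack(res.x, n_beta)
    beta = beta_s / scale
    zeta = zeta_s + float(mu @ beta)

    info = _observed_information(beta, zeta, X, y, n_cat)
    try:
        vcov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return _failed(spec.covariates, labels, n, "singular observed information")
    diag = np.diag(vcov)
    converged = bool(res.success) and np.all(diag[:n_beta] > 0)
    failure = None if converged else f"optimizer: {res.message}"

    return OrdinalFit(
        beta=beta,
        zeta=zeta,
        loglik=-float(res.fun),
        vcov=vcov,
        covariate_names=tuple(spec.covariates),
        category_labels=labels,
        converged=converged,
        n_used=n,
        failure=failure,
    )


def odds_ratio_table(fit: OrdinalFit, z_crit: float = 1.959963984540054) -> pd.DataFrame:
    """Per-covariate odds ratios with Wald 95% confidence intervals."""
    if not fit.converged:
        raise FitFailedError(f"cannot tabulate a failed fit: {fit.failure}")
    se = fit.beta_se()
    return pd.DataFrame(
        {
            "covariate": list(fit.covariate_names),
            "beta": fit.beta,
            "se": se,
            "or": np.exp(fit.beta),
            "ci_low": np.exp(fit.beta - z_crit * se),
            "ci_high": np.exp(fit.beta + z_crit * se),
        }
    ).set_index("covariate")


def _profile_vector(fit: OrdinalFit, profile) -> np.ndarray:
    if isinstance(profile, dict):
        missing = [c for c in fit.covariate_names if c not in profile]
        if missing:
            raise DomainError(f"profile lacks covariate(s): {', '.join(missing)}")
        x = np.asarray([profile[c] for c in fit.covariate_names], dtype=float)
    else:
        x = np.asarray(profile, dtype=float)
    if x.shape != (len(fit.covariate_names),):
        raise DomainError(
            f"profile has {x.size} values, model has {len(fit.covariate_names)} covariates"
        )
    return x


def predict_probabilities(fit: OrdinalFit, profile) -> np.ndarray:
    """Category probabilities for one covariate profile (sums to 1)."""
    if not fit.converged:
        raise FitFailedError(f"cannot predict from a failed fit: {fit.failure}")
    x = _profile_vector(fit, profile)
    eta = float(x @ fit.beta)
    z = np.concatenate(([-np.inf], fit.zeta, [np.inf]))
    return np.diff(expit(z - eta))


@dataclass
class ProbabilityProfile:
    """Predicted category probabilities along one covariate grid.

    ``crossovers`` lists (grid midpoint, category before, category after)
    wherever the most-probable category changes; ties within a grid point
    break toward the lower category.
    """

    vary: str
    grid: np.ndarray
    fixed: dict[str, float]
    category_labels: np.ndarray
    probabilities: np.ndarray  # shape (len(grid), n_categories)
    most_probable: np.ndarray
    crossovers: list[tuple[float, float, float]] = field(default_factory=list)


def find_crossovers(fit: OrdinalFit, vary: str, grid, fixed: dict) -> ProbabilityProfile:
    """Most-probable-category profile along ``vary`` with other covariates
    fixed (the non-varying continuous covariates at their cohort means)."""
    if vary not in fit.covariate_names:
        raise DomainError(f"unknown covariate {vary!r}")
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2:
        raise DomainError("grid must be one-dimensional with at least two points")

    probs = np.empty((len(grid), len(fit.category_labels)))
    for t, value in enumerate(grid):
        profile = dict(fixed)
        profile[vary] = value
        probs[t] = predict_probabilities(fit, profile)
    # argmax returns the first (= lowest) category on exact ties
    most = fit.category_labels[np.argmax(probs, axis=1)]

    crossovers = []
    for t in range(1, len(grid)):
        if most[t] != most[t - 1]:
            mid = (grid[t - 1] + grid[t]) / 2.0
            crossovers.append((float(mid), float(most[t - 1]), float(most[t])))
    return ProbabilityProfile(
        vary=vary,
        grid=grid,
        fixed=dict(fixed),
        category_labels=fit.category_labels,
        probabilities=probs,
        most_probable=most,
        crossovers=crossovers,
    )
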