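"""Censored-normal (Tobit) regression for the second-stage analysis.

Efficiency scores live in [0, 1] and pile up at 1 for frontier units, so an
ordinary least-squares fit of scores on exogenous covariates is biased.  The
Tobit model treats the observed response as a latent normal variable
``y* = X b + e``, ``e ~ N(0, sigma^2)``, censored at known bounds: interior
observations contribute the normal density, observations at a bound
contribute the corresponding tail mass.  Estimation is by maximum
likelihood; standard errors come from the observed information at the
optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.tools.numdiff import approx_hess

_BOUND_EPS = 1e-12


class TobitError(ValueError):
    pass


@dataclass
class TobitDesign:
    """Response, covariate matrix (including any intercept column) and bounds."""

    y: np.ndarray
    X: np.ndarray
    lower: float = 0.0
    upper: float = 1.0

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.y.shape[0]:
            raise TobitError("X and y have different numbers of rows")
        if np.isnan(self.y).any() or np.isnan(self.X).any():
            raise TobitError("missing values in the design")
        if not self.lower < self.upper:
            raise TobitError("need lower < upper")
        if (self.y < self.lower - _BOUND_EPS).any() or (self.y > self.upper + _BOUND_EPS).any():
            raise TobitError("responses outside [lower, upper]")

    @property
    def masks(self):
        at_lower = self.y <= self.lower + _BOUND_EPS
        at_upper = self.y >= self.upper - _BOUND_EPS
        return ~(at_lower | at_upper), at_lower, at_upper


@dataclass
class TobitFit:
    beta: np.ndarray
    sigma: float
    se: np.ndarray           # p+1 entries: coefficients then sigma
    z: np.ndarray
    pvalues: np.ndarray
    loglik: float
    converged: bool
    n_censored: tuple[int, int]   # (at lower, at upper)
    n_obs: int
    design: TobitDesign


def tobit_loglik(beta, sigma, design: TobitDesign) -> float:
    """Log-likelihood of the two-sided censored normal regression."""
    if sigma <= 0:
        raise TobitError("sigma must be positive")
    beta = np.asarray(beta, dtype=float)
    xb = design.X @ beta
    interior, at_lower, at_upper = design.masks
    ll = 0.0
    if interior.any():
        r = (design.y[interior] - xb[interior]) / sigma
        ll += float(np.sum(norm.logpdf(r) - np.log(sigma)))
    if at_upper.any():
        ll += float(np.sum(norm.logsf((design.upper - xb[at_upper]) / sigma)))
    if at_lower.any():
        ll += float(np.sum(norm.logcdf((design.lower - xb[at_lower]) / sigma)))
    return ll


def _loglik_grad(beta, sigma, design: TobitDesign):
    """Analytic gradient of the log-likelihood in (beta, sigma)."""
    xb = design.X @ beta
    interior, at_lower, at_upper = design.masks
    gb = np.zeros(design.X.shape[1])
    gs = 0.0
    if interior.any():
        r = (design.y[interior] - xb[interior]) / sigma
        gb += design.X[interior].T @ r / sigma
        gs += float(np.sum(r * r - 1.0)) / sigma
    if at_upper.any():
        z = (design.upper - xb[at_upper]) / sigma
        haz = np.exp(norm.logpdf(z) - norm.logsf(z))   # phi/(1-Phi)
        gb += design.X[at_upper].T @ haz / sigma
        gs += float(np.sum(haz * z)) / sigma
    if at_lower.any():
        z = (design.lower - xb[at_lower]) / sigma
        haz = np.exp(norm.logpdf(z) - norm.logcdf(z))  # phi/Phi
        gb -= design.X[at_lower].T @ haz / sigma
        gs -= float(np.sum(haz * z)) / sigma
    return gb, gs


def fit_tobit(design: TobitDesign, gtol: float = 1e-10, maxiter: int = 500) -> TobitFit:
    """Maximum-likelihood Tobit fit.

    Quasi-Newton (BFGS) on (beta, log sigma) from the least-squares start;
    convergence requires a scaled gradient norm <= 1e-6.  Standard errors are
    square roots of the diagonal of the inverse observed information in
    (beta, sigma).
    """
    n, p = design.X.shape
    if n <= p + 1:
        raise TobitError(f"need n > p + 1 observations (n={n}, p={p})")
    if np.linalg.matrix_rank(design.X) < p:
        raise TobitError("covariate matrix is rank deficient")
    interior, at_lower, at_upper = design.masks
    n_cens = (int(at_lower.sum()), int(at_upper.sum()))
    if not interior.any():
        raise TobitError("all observations censored: parameters not identified")

    beta0, *_ = np.linalg.lstsq(design.X, design.y, rcond=None)
    resid = design.y - design.X @ beta0
    sigma0 = float(np.std(resid, ddof=min(p, n - 1)))
    if sigma0 < 1e-10:
        # exact linear fit: likelihood unbounded in sigma, return degenerate MLE
        warnings.warn("zero residual variance: returning the exact least-squares fit",
                      RuntimeWarning, stacklevel=2)
        se = np.full(p + 1, np.nan)
        return TobitFit(beta0, sigma0, se, np.full(p + 1, np.nan),
                        np.full(p + 1, np.nan), np.inf, True, n_cens, n, design)

    def negll(theta):
        return -tobit_loglik(theta[:p], np.exp(theta[p]), design)

    def negll_grad(theta):
        sigma = np.exp(theta[p])
        gb, gs = _loglik_grad(theta[:p], sigma, design)
        return -np.concatenate([gb, [gs * sigma]])  # chain rule for log sigma

    x0 = np.concatenate([beta0, [np.log(sigma0)]])
    res = optimize.minimize(negll, x0, jac=negll_grad, method="BFGS",
                            options={"gtol": gtol, "maxiter": maxiter})
    gnorm = float(np.max(np.abs(negll_grad(res.x))))
    for _ in range(2):  # restart resets the Hessian approximation if BFGS
        if gnorm <= 1e-6 * max(1.0, abs(float(res.fun))):  # stalled on precision loss
            break
        res2 = optimize.minimize(negll, res.x, jac=negll_grad, method="Newton-CG",
                                 options={"maxiter": 100})
        if res2.fun <= res.fun:
            res = res2
        gnorm = float(np.max(np.abs(negll_grad(res.x))))
    beta = res.x[:p]
    sigma = float(np.exp(res.x[p]))
    ll = -float(res.fun)
    converged = gnorm <= 1e-6 * max(1.0, abs(ll))
    if not converged:
        warnings.warn(f"Tobit fit did not converge (scaled gradient {gnorm:.3g})",
                      RuntimeWarning, stacklevel=2)

    def negll_sigma(theta):  # (beta, sigma) parametrization for the information matrix
        return -tobit_loglik(theta[:p], theta[p], design)

    H = approx_hess(np.concatenate([beta, [sigma]]), negll_sigma)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p + 1, np.nan)
    est = np.concatenate([beta, [sigma]])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, est / se, np.nan)
    pvals = 2.0 * norm.sf(np.abs(z))
    return TobitFit(beta, sigma, se, z, pvals, ll, converged, n_cens, n, design)


def tobit_report(fit: TobitFit, names: list[str] | None = None) -> pd.DataFrame:
    """Coefficient table: Coefficient, Std. Error, z-Statistic, Prob.

    One row per covariate plus a row for sigma.  The frame's ``attrs`` carry
    the log-likelihood and two R-squared surrogates (no standard R-squared
    exists for a censored-likelihood fit): McFadden's pseudo R-squared
    against an intercept-only fit, and the squared correlation between the
    linear predictor and the observed response.
    """
    p = len(fit.beta)
    if names is None:
        names = [f"x{i}" for i in range(p)]
    if len(names) != p:
        raise TobitError(f"expected {p} names, got {len(names)}")
    table = pd.DataFrame({
        "Coefficient": np.concatenate([fit.beta, [fit.sigma]]),
        "Std. Error": fit.se,
        "z-Statistic": fit.z,
        "Prob.": fit.pvalues,
    }, index=list(names) + ["sigma"])

    table.attrs["loglik"] = fit.loglik
    xb = fit.design.X @ fit.beta
    if np.std(xb) > 0 and np.std(fit.design.y) > 0:
        table.attrs["r2_linear_pred"] = float(np.corrcoef(xb, fit.design.y)[0, 1] ** 2)
    else:
        table.attrs["r2_linear_pred"] = np.nan
    try:
        null_design = TobitDesign(fit.design.y, np.ones((fit.n_obs, 1)),
                                  fit.design.lower, fit.design.upper)
        ll0 = fit_tobit(null_design).loglik
        table.attrs["pseudo_r2_mcfadden"] = (
            1.0 - fit.loglik / ll0 if ll0 not in (0.0,) else np.nan
        )
    except TobitError:
        table.attrs["pseudo_r2_mcfadden"] = np.nan
    return table


class TobitRegressor(BaseEstimator, RegressorMixin):
    """Scikit-learn style interface to the censored-normal regression.

    Parameters
    ----------
    lower, upper : float, default (0.0, 1.0)
        Censoring bounds.  Efficiency scores are censored only at 1 in
        practice, but both bounds are handled.
    fit_intercept : bool, default True

    Attributes
    ----------
    coef_ : covariate coefficients (excluding intercept)
    intercept_ : float
    sigma_ : residual scale
    se_, zvalues_, pvalues_ : inference arrays ordered (intercept, coef..., sigma)
    loglik_, converged_, n_censored_
    """

    def __init__(self, lower: float = 0.0, upper: float = 1.0, fit_intercept: bool = True):
        self.lower = lower
        self.upper = upper
        self.fit_intercept = fit_intercept

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        Xd = np.column_stack([np.ones(len(y)), X]) if self.fit_intercept else X
        design = TobitDesign(y, Xd, self.lower, self.upper)
        fit = fit_tobit(design)
        self.fit_ = fit
        if self.fit_intercept:
            self.intercept_ = float(fit.beta[0])
            self.coef_ = fit.beta[1:]
        else:
            self.intercept_ = 0.0
            self.coef_ = fit.beta
        self.sigma_ = fit.sigma
        self.se_ = fit.se
        self.zvalues_ = fit.z
        self.pvalues_ = fit.pvalues
        self.loglik_ = fit.loglik
        self.converged_ = fit.converged
        self.n_censored_ = fit.n_censored
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X, kind: str = "latent"):
        """Predict the latent mean ``X b`` or the censored expectation.

        ``kind="censored"`` returns E[y | X] under censoring at the bounds.
        """
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "fit_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        mu = self.intercept_ + X @ self.coef_
        if kind == "latent":
            return mu
        if kind != "censored":
            raise ValueError("kind must be 'latent' or 'censored'")
        s = self.sigma_
        if s <= 0:
            return np.clip(mu, self.lower, self.upper)
        a = (self.lower - mu) / s
        b = (self.upper - mu) / s
        return (self.lower * norm.cdf(a)
                + self.upper * norm.sf(b)
                + mu * (norm.cdf(b) - norm.cdf(a))
                + s * (norm.pdf(a) - norm.pdf(b)))

    def report(self, names: list[str] | None = None) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "fit_")
        p = len(self.fit_.beta)
        if names is None:
            names = [f"x{i + 1}" for i in range(p - 1)] if self.fit_intercept \
                else [f"x{i + 1}" for i in range(p)]
        full = (["_CONS"] + list(names)) if self.fit_intercept else list(names)
        return tobit_report(self.fit_, full)
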