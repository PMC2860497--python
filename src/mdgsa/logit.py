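"""Logistic-regression core of the multidimensional gene-set analysis.

The probability that a gene belongs to a functional module F is modelled on
the logit scale as a function of its ranking statistic(s):

    univariate:  logit P(gene in F) = c + alpha * X
    bivariate:   logit P(gene in F) = c + alpha * X + beta * Y + gamma * X*Y

alpha and beta are the main effects (log odds ratio of membership per unit
of each statistic) and gamma is the interaction effect.  With gamma = 0 the
fitted surface over the (X, Y) plane is a plane; with gamma != 0 it is a
hyperbolic paraboloid whose saddle point sits at (-beta/gamma, -alpha/gamma),
and the module concentrates in the quadrant opposite the saddle.

Fitting is maximum likelihood via iteratively reweighted least squares
(IRLS), initialised at the null model and declared converged when the
deviance changes by less than 1e-8 (at most 25 iterations).  Complete or
quasi-complete separation does not raise: the fit is returned with
``converged=False`` so extreme modules stay visible in the output.  Wald
z-tests against the standard normal give per-coefficient p-values, which
are then Benjamini-Hochberg adjusted within each coefficient family
(all modules' alphas together, all betas together, all gammas together).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .exceptions import (
    CollinearityError,
    DegenerateCovariateError,
    DegenerateSetError,
    InvalidPValueError,
    InvalidStandardErrorError,
    WrongModelError,
)
from .geneset_io import MembershipVector

logger = logging.getLogger(__name__)

__all__ = [
    "ModelFit",
    "SaddlePoint",
    "fit_univariate",
    "fit_bivariate",
    "wald_pvalue",
    "bh_adjust",
    "saddle_point",
]

MAX_ITER = 25
DEVIANCE_TOL = 1e-8
_MU_EPS = 1e-10


@dataclass
class ModelFit:
    """Maximum-likelihood logistic fit for one gene set.

    ``beta``, ``gamma`` and their standard errors / p-values are ``None``
    for a univariate fit.  Coefficients are log odds ratios per unit of the
    corresponding covariate (X, Y, or the product X*Y).
    """

    intercept: float
    alpha: float
    beta: float | None
    gamma: float | None
    se_intercept: float
    se_alpha: float
    se_beta: float | None
    se_gamma: float | None
    p_alpha: float
    p_beta: float | None
    p_gamma: float | None
    converged: bool
    n_iterations: int
    deviance: float
    null_deviance: float

    @property
    def is_bivariate(self) -> bool:
        return self.beta is not None


@dataclass
class SaddlePoint:
    """Stationary point of the fitted membership-probability surface."""

    x0: float
    y0: float
    defined: bool


def _as_indicator(member) -> np.ndarray:
    if isinstance(member, MembershipVector):
        y = member.indicator.astype(np.float64)
    else:
        y = np.asarray(member, dtype=np.float64)
    if y.ndim != 1 or not np.all((y == 0) | (y == 1)):
        raise ValueError("membership must be a 1-D 0/1 vector")
    n1 = y.sum()
    if n1 == 0 or n1 == y.size:
        raise DegenerateSetError("membership indicator has a single class")
    return y


def _deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, _MU_EPS, 1.0 - _MU_EPS)
    return float(-2.0 * np.sum(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)))


def _irls(X: np.ndarray, y: np.ndarray, ridge: float = 0.0):
    """IRLS for the binomial GLM with logit link.

    Returns (coef, se, converged, n_iter, deviance, null_deviance).  ``ridge``
    adds an L2 penalty on the slope coefficients only (0 disables it); it is
    an optional stabiliser for separated fits, off by default.
    """
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise CollinearityError("design matrix is rank-deficient")
    pbar = y.mean()
    coef = np.zeros(k)
    coef[0] = np.log(pbar / (1.0 - pbar))
    null_dev = _deviance(y, np.full(n, pbar))
    dev = null_dev
    penalty = np.zeros((k, k))
    if ridge > 0:
        penalty[1:, 1:] = ridge * np.eye(k - 1)
    converged = False
    n_iter = 0
    xtwx = None
    for n_iter in range(1, MAX_ITER + 1):
        eta = X @ coef
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), _MU_EPS, None)
        z = eta + (y - mu) / w
        xw = X * w[:, None]
        xtwx = X.T @ xw + penalty
        try:
            coef_new = np.linalg.solve(xtwx, xw.T @ z)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - rank checked above
            raise CollinearityError("weighted normal equations are singular") from exc
        dev_new = _deviance(y, expit(X @ coef_new))
        coef = coef_new
        if abs(dev - dev_new) < DEVIANCE_TOL:
            dev = dev_new
            converged = True
            break
        dev = dev_new
    if not converged:
        logger.warning(
            "IRLS did not converge in %d iterations (possible separation); "
            "coefficients reported with converged=False",
            MAX_ITER,
        )
    mu = expit(X @ coef)
    w = np.clip(mu * (1.0 - mu), _MU_EPS, None)
    xtwx = X.T @ (X * w[:, None]) + penalty
    cov = np.linalg.inv(xtwx)
    se = np.sqrt(np.diag(cov))
    return coef, se, converged, n_iter, dev, null_dev


def _check_covariate(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite values in {name}")
    if x.std() == 0:
        raise DegenerateCovariateError(f"covariate {name} has zero variance")
    return x


def fit_univariate(x, member, ridge: float = 0.0) -> ModelFit:
    """Fit ``logit P(member) = c + alpha * x`` by maximum likelihood."""
    y = _as_indicator(member)
    x = _check_covariate(np.ravel(x), "x")
    if x.size != y.size:
        raise ValueError("x and membership differ in length")
    X = np.column_stack([np.ones_like(x), x])
    coef, se, conv, n_iter, dev, null_dev = _irls(X, y, ridge=ridge)
    return ModelFit(
        intercept=float(coef[0]),
        alpha=float(coef[1]),
        beta=None,
        gamma=None,
        se_intercept=float(se[0]),
        se_alpha=float(se[1]),
        se_beta=None,
        se_gamma=None,
        p_alpha=wald_pvalue(float(coef[1]), float(se[1])),
        p_beta=None,
        p_gamma=None,
        converged=conv,
        n_iterations=n_iter,
        deviance=dev,
        null_deviance=null_dev,
    )


def fit_bivariate(xy, member, ridge: float = 0.0) -> ModelFit:
    """Fit ``logit P(member) = c + alpha*X + beta*Y + gamma*X*Y``.

    ``xy`` is an (n, 2) matrix whose columns are the two ranking statistics;
    the interaction column is formed from them as supplied (i.e. after any
    transformation the caller applied).
    """
    y = _as_indicator(member)
    xy = np.asarray(xy, dtype=np.float64)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("xy must be an (n, 2) matrix")
    if xy.shape[0] != y.size:
        raise ValueError("xy and membership differ in length")
    xv = _check_covariate(xy[:, 0], "X")
    yv = _check_covariate(xy[:, 1], "Y")
    X = np.column_stack([np.ones_like(xv), xv, yv, xv * yv])
    coef, se, conv, n_iter, dev, null_dev = _irls(X, y, ridge=ridge)
    return ModelFit(
        intercept=float(coef[0]),
        alpha=float(coef[1]),
        beta=float(coef[2]),
        gamma=float(coef[3]),
        se_intercept=float(se[0]),
        se_alpha=float(se[1]),
        se_beta=float(se[2]),
        se_gamma=float(se[3]),
        p_alpha=wald_pvalue(float(coef[1]), float(se[1])),
        p_beta=wald_pvalue(float(coef[2]), float(se[2])),
        p_gamma=wald_pvalue(float(coef[3]), float(se[3])),
        converged=conv,
        n_iterations=n_iter,
        deviance=dev,
        null_deviance=null_dev,
    )


def wald_pvalue(coef: float, se: float) -> float:
    """Two-sided Wald p-value, ``2 * (1 - Phi(|coef/se|))``."""
    if not se > 0:
        raise InvalidStandardErrorError(f"standard error must be positive, got {se}")
    return float(2.0 * norm.sf(abs(coef / se)))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InvalidPValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def saddle_point(fit: ModelFit) -> SaddlePoint:
    """Saddle point ``(-beta/gamma, -alpha/gamma)`` of a bivariate fit.

    Undefined (``defined=False``) exactly when gamma is zero, in which case
    the fitted surface is a plane with no stationary point.
    """
    if not fit.is_bivariate:
        raise WrongModelError("saddle_point requires a bivariate fit")
    if fit.gamma == 0:
        return SaddlePoint(x0=float("nan"), y0=float("nan"), defined=False)
    return SaddlePoint(
        x0=-fit.beta / fit.gamma, y0=-fit.alpha / fit.gamma, defined=True
    )
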