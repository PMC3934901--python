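"""Poisson generalized linear model fitting by Fisher-scoring IRLS.

Implements the log-link Poisson regression at the heart of the analysis
(and an identity-link additive-risk variant as an extension), with exact
log-likelihood (including the log y! term, so AIC values are absolute),
Wald inference, likelihood-ratio tests, and an optional family-clustered
sandwich covariance.

The model for subject i is

    y_i ~ Poisson(lambda_i),   g(lambda_i) = x_i' beta

with g = log (default) or identity.  IRLS iterates weighted least squares
on the working response; the deviance is monitored and step-halving is
applied whenever a full Fisher step would increase it (or, for the
identity link, leave the mean space).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, special, stats

logger = logging.getLogger(__name__)

_ETA_MAX = 30.0  # exp overflow guard on the linear predictor


class GlmError(ValueError):
    """Raised for unusable designs or infeasible fits."""


class ConvergenceWarning(UserWarning):
    """Fit returned without meeting the convergence tolerance."""


@dataclasses.dataclass
class DesignResponse:
    """Design matrix + count response for one model.

    ``X`` has an all-ones first column (intercept); ``kept_rows`` are the
    positional indices, in the originating cohort, of the complete-case
    subjects behind each row; ``groups`` (optional) are family codes for
    cluster-robust covariances.
    """

    X: np.ndarray
    y: np.ndarray
    labels: tuple[str, ...]
    kept_rows: np.ndarray
    groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise GlmError("X and y shapes disagree")
        if np.isnan(self.X).any() or np.isnan(self.y).any():
            raise GlmError("design contains missing values; drop incomplete rows")
        if (self.y < 0).any() or not np.allclose(self.y, np.round(self.y)):
            raise GlmError("y must be nonnegative integer counts")
        if len(self.labels) != self.X.shape[1]:
            raise GlmError("one label per design column required")
        self.kept_rows = np.asarray(self.kept_rows, dtype=int)

    def subset(self, columns: Sequence[str]) -> "DesignResponse":
        """Column-subset design on the same rows (for nested-model ladders)."""
        idx = [self.labels.index(c) for c in columns]
        return DesignResponse(
            X=self.X[:, idx],
            y=self.y,
            labels=tuple(columns),
            kept_rows=self.kept_rows,
            groups=self.groups,
        )


@dataclasses.dataclass
class GlmFit:
    """A fitted Poisson GLM."""

    coefficients: pd.Series
    covariance: pd.DataFrame
    loglik: float
    aic: float
    n_iter: int
    converged: bool
    link: str
    n_obs: int
    deviance: float
    deviance_trace: tuple[float, ...]
    kept_rows: np.ndarray
    robust_covariance: pd.DataFrame | None = None

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.coefficients.index)

    @property
    def n_params(self) -> int:
        return len(self.coefficients)

    def se(self, robust: bool = False) -> pd.Series:
        cov = self._cov(robust)
        return pd.Series(np.sqrt(np.diag(cov.to_numpy())), index=self.labels)

    def wald_p(self, robust: bool = False) -> pd.Series:
        z = self.coefficients / self.se(robust)
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.labels)

    def _cov(self, robust: bool) -> pd.DataFrame:
        if robust:
            if self.robust_covariance is None:
                raise GlmError("fit was not computed with robust=True")
            return self.robust_covariance
        return self.covariance

    def predict_mean(self, x: np.ndarray) -> np.ndarray:
        """Fitted Poisson rate(s) at covariate row(s) ``x``."""
        eta = np.atleast_2d(np.asarray(x, dtype=float)) @ self.coefficients.to_numpy()
        return np.exp(eta) if self.link == "log" else eta


def poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    """Exact Poisson log-likelihood sum(y log mu - mu - log y!)."""
    mu = np.maximum(mu, 1e-300)
    return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))


def poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    """2 sum[y log(y/mu) - (y - mu)], with y log y := 0 at y = 0."""
    mu = np.maximum(mu, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def _check_rank(X: np.ndarray, labels: Sequence[str]) -> None:
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(r))
    tol = d.max() * max(X.shape) * np.finfo(float).eps if d.size else 0.0
    rank = int((d > tol).sum())
    if rank < X.shape[1]:
        bad = [labels[j] for j in piv[rank:]]
        raise GlmError(
            f"design is rank deficient; collinear column(s): {', '.join(bad)}"
        )


def _mu(eta: np.ndarray, link: str) -> np.ndarray:
    if link == "log":
        return np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))
    return eta


def fit_poisson(
    design: DesignResponse,
    link: str = "log",
    tol: float = 1e-8,
    max_iter: int = 100,
    robust: bool = False,
) -> GlmFit:
    """Maximum-likelihood Poisson fit by IRLS (Fisher scoring).

    Convergence is declared when the relative deviance change falls below
    ``tol``; the deviance is non-increasing across iterations by
    construction (a full step that would increase it is halved, for the
    identity link also until all fitted means are positive).  The reported
    covariance is the inverse Fisher information at the optimum; with
    ``robust=True`` a family-clustered sandwich covariance is additionally
    computed from ``design.groups`` (an extension beyond the source
    analysis, which treats subjects as independent).
    """
    if link not in ("log", "identity"):
        raise GlmError(f"unknown link {link!r}")
    X, y = design.X, design.y
    n, p = X.shape
    _check_rank(X, design.labels)

    beta = np.zeros(p)
    beta[0] = np.log(y.mean() + 0.5) if link == "log" else y.mean() + 0.5
    eta = X @ beta
    mu = _mu(eta, link)
    dev = poisson_deviance(y, mu)
    trace = [dev]

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if link == "log":
            w = mu
            z = eta + (y - mu) / np.maximum(mu, 1e-10)
        else:
            w = 1.0 / np.maximum(mu, 1e-10)
            z = y.astype(float)
        xw = X * w[:, None]
        try:
            beta_new = linalg.solve(X.T @ xw, xw.T @ z, assume_a="pos")
        except linalg.LinAlgError as exc:  # pragma: no cover - guarded by rank check
            raise GlmError(f"weighted least squares failed: {exc}") from exc

        step = beta_new - beta
        frac = 1.0
        for _ in range(40):
            cand = beta + frac * step
            eta_c = X @ cand
            mu_c = _mu(eta_c, link)
            if link == "identity" and (mu_c <= 0).any():
                frac /= 2.0
                continue
            dev_c = poisson_deviance(y, mu_c)
            if dev_c <= dev * (1 + 1e-12) + 1e-12:
                break
            frac /= 2.0
        else:
            if link == "identity" and (_mu(X @ (beta + frac * step), link) <= 0).any():
                raise GlmError(
                    "identity link: no feasible step keeps fitted means positive"
                )
            cand, eta_c, mu_c, dev_c = beta, eta, mu, dev  # stuck at current point

        beta, eta, mu = cand, eta_c, mu_c
        logger.debug("IRLS iter %d: deviance %.10g (step %.3g)", it, dev_c, frac)
        rel = abs(dev - dev_c) / (abs(dev_c) + 0.1)
        dev = dev_c
        trace.append(dev)
        if rel < tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"IRLS did not converge in {max_iter} iterations "
            f"(last relative deviance change {rel:.2e})",
            ConvergenceWarning,
            stacklevel=2,
        )

    w = mu if link == "log" else 1.0 / np.maximum(mu, 1e-10)
    info = X.T @ (X * w[:, None])
    cov = linalg.inv(info)
    ll = poisson_loglik(y, mu)
    labels = list(design.labels)

    robust_cov = None
    if robust:
        if design.groups is None:
            raise GlmError("robust=True requires design.groups (family codes)")
        resid = y - mu
        score_x = X if link == "log" else X / np.maximum(mu, 1e-10)[:, None]
        sdf = pd.DataFrame(score_x * resid[:, None])
        meat_rows = sdf.groupby(np.asarray(design.groups), sort=False).sum().to_numpy()
        meat = meat_rows.T @ meat_rows
        robust_cov = pd.DataFrame(cov @ meat @ cov, index=labels, columns=labels)

    return GlmFit(
        coefficients=pd.Series(beta, index=labels),
        covariance=pd.DataFrame(cov, index=labels, columns=labels),
        loglik=ll,
        aic=-2.0 * ll + 2.0 * p,
        n_iter=it,
        converged=converged,
        link=link,
        n_obs=n,
        deviance=dev,
        deviance_trace=tuple(trace),
        kept_rows=design.kept_rows,
        robust_covariance=robust_cov,
    )


def score_vector(fit: GlmFit, design: DesignResponse) -> np.ndarray:
    """Gradient of the log-likelihood at the fitted coefficients."""
    mu = fit.predict_mean(design.X)
    if fit.link == "log":
        return design.X.T @ (design.y - mu)
    return design.X.T @ ((design.y - mu) / np.maximum(mu, 1e-10))


@dataclasses.dataclass(frozen=True)
class RateRatio:
    term: str
    point: float
    lower: float
    upper: float
    p: float


def rate_ratio(
    fit: GlmFit, coefficient: str, level: float = 0.95, robust: bool = False
) -> RateRatio:
    """exp(beta) with Wald CI and two-sided p for one log-link coefficient.

    The source tables label these "odds ratios"; from a log-link Poisson
    model they are rate ratios, and that is how this package names them.
    """
    if fit.link != "log":
        raise GlmError("rate ratios are only defined for log-link fits")
    if coefficient not in fit.labels:
        raise GlmError(f"no coefficient {coefficient!r} in fit")
    b = float(fit.coefficients[coefficient])
    se = float(fit.se(robust)[coefficient])
    zq = stats.norm.ppf(0.5 + level / 2.0)
    p = 2 * stats.norm.sf(abs(b / se)) if se > 0 else np.nan
    with np.errstate(over="ignore"):  # huge se -> infinite upper bound
        return RateRatio(
            term=coefficient,
            point=float(np.exp(b)),
            lower=float(np.exp(b - zq * se)),
            upper=float(np.exp(b + zq * se)),
            p=float(p),
        )


@dataclasses.dataclass(frozen=True)
class LrtResult:
    chi2: float
    df: int
    p: float


def lrt(nested: GlmFit, full: GlmFit) -> LrtResult:
    """Likelihood-ratio test of a nested model against a fuller one.

    ``chi2 = 2 (loglik_full - loglik_nested)`` (clipped at 0) referred to
    chi-square with df = difference in coefficient count.  Both fits must
    be on the same complete-case rows and the nested labels must be a
    subset of the full labels (equality gives chi2 = 0, df = 0, p = 1).
    """
    if not np.array_equal(nested.kept_rows, full.kept_rows):
        raise GlmError(
            "fits use different complete-case rows; refit both on the common set"
        )
    if not set(nested.labels) <= set(full.labels):
        raise GlmError(
            f"models are not nested: {set(nested.labels) - set(full.labels)} "
            "only in the smaller model"
        )
    df = full.n_params - nested.n_params
    chi2 = max(0.0, 2.0 * (full.loglik - nested.loglik))
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return LrtResult(chi2=float(chi2), df=int(df), p=p)
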