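"""Negative-binomial probability kernel and GLM-NB fitter.

The classifier models an observed tag count ``y`` with mean
``mu = exp(beta0 + beta1 * ln(N_total))`` and overdispersion ``theta``
(variance ``mu + mu**2 / theta``). This module provides the log-pmf and
cdf in that (mu, theta) parameterization and a maximum-likelihood fitter
for the two-coefficient log-link regression, used in both the
negative-cell space (X vs N_total) and the positive-cell space
(N_total - X vs N_total).

Fitting alternates iteratively reweighted least squares for the linear
coefficients at fixed theta with a safeguarded 1-D Newton update of
ln(theta), stopping on a relative log-likelihood change below ``tol``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = ["GlmNbFit", "nb_log_pmf", "nb_cdf", "fit_glm_nb"]

THETA_MIN = 1e-3
THETA_MAX = 1e5


@dataclass
class GlmNbFit:
    """A fitted NB regression ln(mu) = beta0 + beta1 * ln(N_total)."""

    beta0: float
    beta1: float
    theta: float
    space: str = "negative"  # {"negative", "positive"}
    converged: bool = True
    n_obs: int = 0
    loglik: float = float("nan")
    theta_at_bound: bool = False

    def mean(self, log_total: np.ndarray) -> np.ndarray:
        """Fitted mean at the given ln(N_total) values."""
        eta = self.beta0 + self.beta1 * np.asarray(log_total, dtype=float)
        return np.exp(np.clip(eta, -700, 700))


def _check_counts(y) -> np.ndarray:
    y = np.asarray(y)
    if y.size and (np.any(y < 0) or not np.allclose(y, np.round(y))):
        raise ValueError("counts must be nonnegative integers")
    return y.astype(np.int64)


def nb_log_pmf(y, mu, theta: float) -> np.ndarray:
    """Log pmf of NB(mu, theta); variance mu + mu**2/theta.

    scipy's nbinom(n, p) maps to this parameterization through
    n = theta, p = theta / (theta + mu).
    """
    y = _check_counts(y)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0) or theta <= 0:
        raise ValueError("mu and theta must be positive")
    return stats.nbinom.logpmf(y, theta, theta / (theta + mu))


def nb_cdf(y, mu, theta: float) -> np.ndarray:
    """CDF of NB(mu, theta) at integer y; F(-1) = 0."""
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0) or theta <= 0:
        raise ValueError("mu and theta must be positive")
    y = np.floor(np.asarray(y, dtype=float))
    return stats.nbinom.cdf(y, theta, theta / (theta + mu))


def _nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    return float(np.sum(nb_log_pmf(y, mu, theta)))


def _theta_score(y: np.ndarray, mu: np.ndarray, theta: float) -> tuple[float, float]:
    """First and second derivative of the NB log-likelihood in theta."""
    t = theta
    s = np.sum(
        special.digamma(y + t)
        - special.digamma(t)
        + np.log(t)
        + 1.0
        - np.log(t + mu)
        - (y + t) / (t + mu)
    )
    h = np.sum(
        special.polygamma(1, y + t)
        - special.polygamma(1, t)
        + 1.0 / t
        - 2.0 / (t + mu)
        + (y + t) / (t + mu) ** 2
    )
    return float(s), float(h)


def _update_theta(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """Safeguarded Newton steps on ln(theta) for the profile likelihood."""
    lt = np.log(theta)
    for _ in range(25):
        t = np.exp(lt)
        s, h = _theta_score(y, mu, t)
        # chain rule: d/dlt = t*s ; d2/dlt2 = t*s + t^2*h
        g = t * s
        hh = t * s + t * t * h
        if hh >= 0 or not np.isfinite(hh):  # fall back to damped gradient
            step = np.sign(g) * min(abs(g), 1.0)
        else:
            step = -g / hh
            step = np.clip(step, -2.0, 2.0)
        lt_new = np.clip(lt + step, np.log(THETA_MIN), np.log(THETA_MAX))
        if abs(lt_new - lt) < 1e-10:
            lt = lt_new
            break
        lt = lt_new
    return float(np.exp(lt))


def _theta_moments(y: np.ndarray, mu: np.ndarray) -> float:
    """Method-of-moments start for theta."""
    resid = (y - mu) ** 2 - mu
    denom = float(np.sum(resid))
    if denom <= 0:
        return 100.0  # data look Poisson-ish; start near equidispersion
    return float(np.clip(np.sum(mu**2) / denom, THETA_MIN, THETA_MAX))


def fit_glm_nb(
    y,
    log_total,
    *,
    space: str = "negative",
    fit_slope: bool = True,
    min_obs: int = 20,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> GlmNbFit:
    """Maximum-likelihood fit of the NB-GLM ln(mu) = beta0 + beta1*ln(N_total).

    Deterministic given inputs. A degenerate design (constant ln(N_total)
    with a slope requested) falls back to an intercept-only fit with
    ``converged=False``. Non-convergence after ``max_iter`` outer
    iterations returns the best iterate flagged unconverged.
    """
    y = _check_counts(y)
    x = np.asarray(log_total, dtype=float)
    if y.shape != x.shape:
        raise ValueError("y and log_total have different lengths")
    if y.size < min_obs:
        raise ValueError(f"need at least {min_obs} observations, got {y.size}")
    if not np.any(y > 0):
        raise ValueError("all counts are zero; NB mean is not identifiable")

    degenerate = False
    if fit_slope and np.ptp(x) < 1e-12:
        fit_slope = False
        degenerate = True

    X = np.column_stack([np.ones_like(x), x]) if fit_slope else np.ones((y.size, 1))

    # initialize on the log scale
    beta = np.linalg.lstsq(X, np.log(y + 0.5), rcond=None)[0]
    eta = X @ beta
    mu = np.exp(np.clip(eta, -700, 30))
    theta = _theta_moments(y, mu)

    ll = _nb_loglik(y, mu, theta)
    converged = False
    for _ in range(max_iter):
        # IRLS for beta at fixed theta (log link, NB variance)
        for _ in range(25):
            w = mu / (1.0 + mu / theta)
            z = eta + (y - mu) / mu
            WX = X * w[:, None]
            beta_new, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ z, rcond=None)
            eta_new = np.clip(X @ beta_new, -700, 30)
            if np.max(np.abs(eta_new - eta)) < 1e-10:
                beta, eta = beta_new, eta_new
                mu = np.exp(eta)
                break
            beta, eta = beta_new, eta_new
            mu = np.exp(eta)
        theta = _update_theta(y, mu, theta)
        ll_new = _nb_loglik(y, mu, theta)
        if abs(ll_new - ll) <= tol * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new

    beta0 = float(beta[0])
    beta1 = float(beta[1]) if fit_slope else 0.0
    at_bound = theta <= THETA_MIN * (1 + 1e-9) or theta >= THETA_MAX * (1 - 1e-9)
    return GlmNbFit(
        beta0=beta0,
        beta1=beta1,
        theta=float(theta),
        space=space,
        converged=converged and not degenerate and not at_bound,
        n_obs=int(y.size),
        loglik=ll,
        theta_at_bound=at_bound,
    )
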