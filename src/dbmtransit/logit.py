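"""Damped-Newton maximum likelihood for binary logit models.

This is the estimation engine behind the covariate-adjusted transition
models and the univariate baseline screens.  It maximises the Bernoulli
log-likelihood by Newton steps on the score / observed information, with
step-halving so the log-likelihood never decreases, and reports Wald
standard errors from the inverse observed information at the optimum.

Complete separation is detected as coefficients diverging past a bound
(default |beta| > 15) and reported as non-estimable rather than returning
arbitrarily large odds ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # sum y*eta - log(1 + exp(eta)), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


@dataclass
class LogitFit:
    """Result of one binary logit maximum-likelihood fit."""

    params: np.ndarray
    bse: np.ndarray
    cov_params: np.ndarray
    llf: float
    n_obs: int
    n_events: int
    converged: bool
    estimable: bool
    reason: str
    n_iter: int
    max_score: float

    @property
    def df_model(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        return 2.0 * self.df_model - 2.0 * self.llf


def _failed(k: int, n: int, events: int, reason: str) -> LogitFit:
    nan = np.full(k, np.nan)
    return LogitFit(
        params=nan,
        bse=nan.copy(),
        cov_params=np.full((k, k), np.nan),
        llf=np.nan,
        n_obs=n,
        n_events=events,
        converged=False,
        estimable=False,
        reason=reason,
        n_iter=0,
        max_score=np.nan,
    )


def fit_logit(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    grad_tol: float = 1e-8,
    step_tol: float = 1e-10,
    separation_bound: float = 15.0,
) -> LogitFit:
    """Fit logit(P(y=1)) = X beta by damped Newton iterations.

    Convergence when the maximum absolute score falls below ``grad_tol``
    or the maximum parameter change below ``step_tol``; at most
    ``max_iter`` iterations.  Fits with zero events, zero non-events, a
    singular information matrix, or coefficients diverging past
    ``separation_bound`` are flagged non-estimable.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    events = int(y.sum())
    if events == 0 or events == n:
        return _failed(k, n, events, "no events" if events == 0 else "no non-events")

    beta = np.zeros(k)
    eta = X @ beta
    ll = _loglik(eta, y)
    converged = False
    n_iter = 0
    max_score = np.inf
    for n_iter in range(1, max_iter + 1):
        p = 1.0 / (1.0 + np.exp(-eta))
        score = X.T @ (y - p)
        max_score = float(np.max(np.abs(score)))
        if max_score < grad_tol:
            converged = True
            break
        w = p * (1.0 - p)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            return _failed(k, n, events, "singular information matrix")

        # step-halving: the log-likelihood must not decrease
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = _loglik(X @ cand, y)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            break  # no improving step found; treat current point as final
        delta = float(np.max(np.abs(scale * step)))
        beta = beta + scale * step
        eta = X @ beta
        ll = ll_new
        if np.max(np.abs(beta)) > separation_bound:
            return _failed(k, n, events, "complete separation (diverging coefficients)")
        if delta < step_tol:
            converged = True
            break

    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return _failed(k, n, events, "singular information matrix at optimum")
    bse = np.sqrt(np.diag(cov))
    return LogitFit(
        params=beta,
        bse=bse,
        cov_params=cov,
        llf=ll,
        n_obs=n,
        n_events=events,
        converged=converged,
        estimable=True,
        reason="",
        n_iter=n_iter,
        max_score=max_score,
    )


def wald_ci(beta: float, se: float, z: float = 1.96) -> tuple[float, float]:
    """95% Wald interval on the log-odds scale (conventional z = 1.96)."""
    return beta - z * se, beta + z * se
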