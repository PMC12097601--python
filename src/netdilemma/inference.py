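"""Fit behavioral models to round logs and detect qualitative signatures.

Two tools:

* :func:`fit_conditional` — maximum-likelihood fit of the 3-parameter
  logistic conditional-cooperation model
  ``P(C_t) = logistic(alpha + beta * f_{t-1} + gamma * 1{a_{t-1}=C})``
  to one player's round history, with Wald standard errors.  Perfectly
  separated or constant-response data is flagged (``boundary=True``) and a
  ridge-penalized fallback estimate is reported instead of a divergent one.
* :func:`detect_period_two` — flags exact C/D alternation and scores soft
  cycling via the lag-1 autocorrelation of the action series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .agents import C
from .engine import ExperimentLog

__all__ = [
    "ConditionalFit",
    "fit_conditional",
    "fit_conditional_arrays",
    "detect_period_two",
    "conditional_design",
    "fits_to_dataframe",
]

RIDGE_PENALTY = 1e-4
_BOUNDARY_NORM = 15.0  # |coef| beyond this on 0/1-scaled covariates ~ separation


@dataclass(frozen=True)
class ConditionalFit:
    alpha: float
    beta: float
    gamma: float
    log_likelihood: float
    covariance: np.ndarray  # 3x3
    n_obs: int
    boundary: bool = False
    converged: bool = True

    @property
    def params(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma])

    @property
    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))

    def wald_interval(self, index: int, level: float = 0.95) -> Tuple[float, float]:
        from scipy import stats

        z = stats.norm.ppf(0.5 + level / 2.0)
        se = self.standard_errors[index]
        center = self.params[index]
        return (center - z * se, center + z * se)


def _nll(theta: np.ndarray, X: np.ndarray, y: np.ndarray, ridge: float) -> float:
    z = X @ theta
    # log(1+exp(z)) computed stably
    ll = y @ z - np.logaddexp(0.0, z).sum()
    return -ll + 0.5 * ridge * theta @ theta


def _grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray, ridge: float) -> np.ndarray:
    p = 1.0 / (1.0 + np.exp(-(X @ theta)))
    return -(X.T @ (y - p)) + ridge * theta


def _hess(theta: np.ndarray, X: np.ndarray, y: np.ndarray, ridge: float) -> np.ndarray:
    p = 1.0 / (1.0 + np.exp(-(X @ theta)))
    w = p * (1.0 - p)
    return (X.T * w) @ X + ridge * np.eye(X.shape[1])


def _maximize(X: np.ndarray, y: np.ndarray, ridge: float):
    res = optimize.minimize(
        _nll,
        np.zeros(X.shape[1]),
        args=(X, y, ridge),
        jac=_grad,
        hess=_hess,
        method="trust-ncg",
        options={"gtol": 1e-8, "maxiter": 500},
    )
    # trust-ncg can stall on its trust radius with the gradient already
    # negligible; judge convergence by the score itself
    gnorm = float(np.max(np.abs(_grad(res.x, X, y, ridge))))
    res.success = bool(res.success or gnorm < 1e-5 * max(1.0, len(y) / 100.0))
    return res


def conditional_design(
    log: ExperimentLog, player: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Design matrix ``[1, frac_coop_neighbors_last, own_last_C]`` and
    response ``1{action=C}`` for rounds 1..T-1 of one player."""
    if len(log.records) < 2:
        raise ValueError("need at least 2 rounds to fit")
    rows, ys = [], []
    for t in range(1, len(log.records)):
        prev = log.records[t - 1]
        nbrs = prev.topology.neighbors(player)
        frac = sum(prev.actions[j] == C for j in nbrs) / len(nbrs)
        own_c = 1.0 if prev.actions[player] == C else 0.0
        rows.append([1.0, frac, own_c])
        ys.append(1.0 if log.records[t].actions[player] == C else 0.0)
    return np.asarray(rows), np.asarray(ys)


def fit_conditional_arrays(
    frac_last: Sequence[float],
    own_last_c: Sequence[float],
    response_c: Sequence[float],
) -> ConditionalFit:
    """Fit the logistic model from raw per-round arrays."""
    X = np.column_stack(
        [
            np.ones(len(frac_last)),
            np.asarray(frac_last, dtype=float),
            np.asarray(own_last_c, dtype=float),
        ]
    )
    y = np.asarray(response_c, dtype=float)
    return _fit(X, y)


def _fit(X: np.ndarray, y: np.ndarray) -> ConditionalFit:
    n = len(y)
    boundary = bool(y.min() == y.max())  # constant responses: guaranteed separation
    res = None
    if not boundary:
        res = _maximize(X, y, ridge=0.0)
        theta = res.x
        if (not res.success) or np.max(np.abs(theta)) > _BOUNDARY_NORM:
            boundary = True
    if boundary:
        res = _maximize(X, y, ridge=RIDGE_PENALTY)
    theta = res.x
    H = _hess(theta, X, y, ridge=RIDGE_PENALTY if boundary else 0.0)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    cov = (cov + cov.T) / 2.0
    z = X @ theta
    loglik = float(y @ z - np.logaddexp(0.0, z).sum())
    return ConditionalFit(
        alpha=float(theta[0]),
        beta=float(theta[1]),
        gamma=float(theta[2]),
        log_likelihood=loglik,
        covariance=cov,
        n_obs=n,
        boundary=boundary,
        converged=bool(res.success),
    )


def fit_conditional(log: ExperimentLog, player: int) -> ConditionalFit:
    """Maximum-likelihood conditional-cooperation fit for one player."""
    X, y = conditional_design(log, player)
    return _fit(X, y)


def fits_to_dataframe(fits: Sequence[ConditionalFit]) -> pd.DataFrame:
    """Fit-export table: player, estimates, Wald SEs, log-likelihood, flags."""
    rows = []
    for player, f in enumerate(fits):
        se = f.standard_errors
        rows.append(
            {
                "player": player,
                "alpha": f.alpha,
                "beta": f.beta,
                "gamma": f.gamma,
                "se_alpha": se[0],
                "se_beta": se[1],
                "se_gamma": se[2],
                "loglik": f.log_likelihood,
                "n_obs": f.n_obs,
                "flags": "boundary" if f.boundary else "",
            }
        )
    return pd.DataFrame(rows)


def detect_period_two(series: Sequence) -> dict:
    """Detect period-two cycling in an action series.

    ``series`` holds C/D labels or 0/1 cooperation indicators.  Returns
    ``is_cyclic`` (exact alternation over the whole series) and ``score``,
    the lag-1 autocorrelation in [-1, 1] (-1 for perfect alternation; 0 by
    convention for a constant series).
    """
    x = np.asarray([1.0 if s in (C, 1, 1.0, True) else 0.0 for s in series])
    if x.size < 4:
        raise ValueError("series must have length >= 4")
    is_cyclic = bool(np.all(x[1:] != x[:-1]))
    var = x.var()
    if var == 0.0:
        return {"is_cyclic": False, "score": 0.0}
    dev = x - x.mean()
    score = float(np.mean(dev[:-1] * dev[1:]) / var)
    return {"is_cyclic": is_cyclic, "score": float(np.clip(score, -1.0, 1.0))}
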