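"""Proportional-odds cumulative-link (logit) model, fit by maximum likelihood.

P(y <= s | x) = logistic(c_s - beta . x) with strictly increasing cutpoints
c_1 < ... < c_{R-1}.  Ordering is enforced by optimizing over c_1 and the log
increments.  Complete separation (or any optimizer failure) triggers a ridge
refit (penalty 1e-4 on beta) flagged as non-converged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from ..gpor.types import OrdinalDataset

_P_FLOOR = 1e-300


@dataclass(frozen=True)
class OrdinalLogisticModel:
    beta: np.ndarray  # (D,)
    cutpoints: np.ndarray  # (R-1,) strictly increasing
    converged: bool
    loglik: float
    r: int

    def __post_init__(self) -> None:
        if self.cutpoints.size > 1 and np.any(np.diff(self.cutpoints) <= 0):
            raise ValueError("cutpoints must be strictly increasing")


def _label_probs(x: np.ndarray, beta: np.ndarray, cutpoints: np.ndarray) -> np.ndarray:
    """(N, R) category probabilities under the cumulative-logit link."""
    lin = x @ beta if x.shape[1] else np.zeros(x.shape[0])
    z = cutpoints[None, :] - lin[:, None]
    cdf = np.concatenate(
        [np.zeros((x.shape[0], 1)), expit(z), np.ones((x.shape[0], 1))], axis=1
    )
    return np.maximum(np.diff(cdf, axis=1), _P_FLOOR)


def _unpack(theta: np.ndarray, d: int) -> tuple:
    beta = theta[:d]
    c1 = theta[d]
    incs = np.exp(np.clip(theta[d + 1 :], -20, 20))
    cut = c1 + np.concatenate([[0.0], np.cumsum(incs)])
    return beta, cut


def fit_ordinal_logistic(
    data: OrdinalDataset, ridge: float = 0.0, max_iter: int = 500
) -> OrdinalLogisticModel:
    """ML fit; falls back to ridge 1e-4 (flagged) on separation or failure."""
    n, d, r = data.n, data.d, data.r
    if np.unique(data.y).size < 2:
        raise ValueError("need at least 2 distinct labels to fit")
    if n < d + r - 1:
        raise ValueError(f"need N >= D + R - 1 = {d + r - 1} observations, got {n}")

    def neg_loglik(theta: np.ndarray) -> float:
        beta, cut = _unpack(theta, d)
        probs = _label_probs(data.x, beta, cut)
        ll = float(np.sum(np.log(probs[np.arange(n), data.y - 1])))
        return -ll + ridge * float(beta @ beta)

    # start from the intercept-only ML solution (empirical cumulative logits)
    counts = np.bincount(data.y, minlength=r + 1)[1:]
    cum = np.clip(np.cumsum(counts)[:-1] / n, 1e-3, 1 - 1e-3)
    c0 = np.log(cum / (1 - cum))
    c0 = np.maximum.accumulate(c0) + np.arange(r - 1) * 1e-6
    theta0 = np.concatenate([np.zeros(d), [c0[0]], np.log(np.maximum(np.diff(c0), 1e-6))])

    res = minimize(neg_loglik, theta0, method="BFGS", options={"maxiter": max_iter})
    beta, cut = _unpack(res.x, d)
    separated = bool(np.any(np.abs(beta) > 10))  # inputs are in SD units
    if (not res.success or separated or not np.isfinite(res.fun)) and ridge == 0.0:
        fallback = fit_ordinal_logistic(data, ridge=1e-4, max_iter=max_iter)
        return OrdinalLogisticModel(
            beta=fallback.beta,
            cutpoints=fallback.cutpoints,
            converged=False,
            loglik=fallback.loglik,
            r=r,
        )
    probs = _label_probs(data.x, beta, cut)
    loglik = float(np.sum(np.log(probs[np.arange(n), data.y - 1])))
    return OrdinalLogisticModel(
        beta=beta, cutpoints=cut, converged=bool(res.success), loglik=loglik, r=r
    )


def predict_ologit(model: OrdinalLogisticModel, x) -> tuple:
    """Category probabilities and modal labels (ties to the smaller label)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    probs = _label_probs(x, model.beta, model.cutpoints)
    return probs, np.argmax(probs, axis=1) + 1
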