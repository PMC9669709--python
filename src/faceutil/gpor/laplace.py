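"""MAP estimation of the latent vector and Laplace approximation of the evidence.

The posterior over the latent values f at the training inputs is

    log P(f | D) = sum_i log P(y_i | f_i) - 1/2 f^T K^{-1} f + const.

The likelihood is log-concave, so the objective has a unique maximum found by
Newton's method with step halving (each iterate must not decrease the
objective).  The Laplace evidence is the objective at the MAP minus half the
log-determinant of (I + K Lambda).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve, solve_triangular

from .kernel import ard_kernel, chol_with_jitter
from .likelihood import label_log_likelihood_terms
from .types import GporHyperparams, OrdinalDataset


class MapConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class LaplaceFit:
    """MAP solution plus the factorizations needed for prediction and evidence."""

    f_map: np.ndarray
    lambda_map: np.ndarray
    k: np.ndarray  # kernel matrix including jitter
    chol_k: np.ndarray
    alpha: np.ndarray  # K^{-1} f_map
    log_lik: float  # sum_i log P(y_i | f_map_i)
    log_evidence: float
    iterations: int
    jitter: float


def _objective(logp_sum: float, f: np.ndarray, alpha: np.ndarray) -> float:
    return logp_sum - 0.5 * float(f @ alpha)


def map_estimate(
    data: OrdinalDataset,
    hyper: GporHyperparams,
    tol: float = 1e-6,
    max_iter: int = 100,
    jitter0: float = 1e-6,
) -> LaplaceFit:
    """Newton-Raphson MAP of the latent vector from f = 0.

    Converges when the gradient infinity-norm drops below ``tol``.  Raises
    :class:`MapConvergenceError` (carrying the iteration trace) otherwise.
    """
    n = data.n
    if n == 0:
        return LaplaceFit(
            f_map=np.zeros(0),
            lambda_map=np.zeros(0),
            k=np.zeros((0, 0)),
            chol_k=np.zeros((0, 0)),
            alpha=np.zeros(0),
            log_lik=0.0,
            log_evidence=0.0,
            iterations=0,
            jitter=0.0,
        )

    k_raw = ard_kernel(data.x, data.x, hyper.eta)
    chol_k, jitter = chol_with_jitter(k_raw, jitter0=jitter0)
    k = k_raw + jitter * np.eye(n)

    f = np.zeros(n)
    alpha = np.zeros(n)
    logp, grad, lam = label_log_likelihood_terms(f, data.y, hyper)
    obj = _objective(float(logp.sum()), f, alpha)
    trace = [obj]
    iterations = 0
    converged = False

    for iterations in range(1, max_iter + 1):
        # Newton step in the stable parameterization (Rasmussen & Williams 3.1)
        w_sqrt = np.sqrt(lam)
        b_mat = np.eye(n) + w_sqrt[:, None] * k * w_sqrt[None, :]
        chol_b = np.linalg.cholesky(b_mat)
        b_vec = lam * f + grad
        inner = w_sqrt * (k @ b_vec)
        a_new = b_vec - w_sqrt * cho_solve((chol_b, True), inner)
        f_new = k @ a_new

        # step halving: never accept an objective decrease
        step = 1.0
        for _ in range(40):
            f_try = f + step * (f_new - f)
            alpha_try = cho_solve((chol_k, True), f_try)
            logp_try, grad_try, lam_try = label_log_likelihood_terms(f_try, data.y, hyper)
            obj_try = _objective(float(logp_try.sum()), f_try, alpha_try)
            if np.isfinite(obj_try) and obj_try >= obj - 1e-12:
                break
            step *= 0.5
        else:
            raise MapConvergenceError("step halving failed to find an ascent step", trace)

        f, alpha = f_try, alpha_try
        logp, grad, lam = logp_try, grad_try, lam_try
        obj = obj_try
        trace.append(obj)
        if np.max(np.abs(grad - alpha)) < tol:
            converged = True
            break

    if not converged:
        raise MapConvergenceError(
            f"MAP Newton iteration did not converge in {max_iter} steps", trace
        )

    w_sqrt = np.sqrt(lam)
    b_mat = np.eye(n) + w_sqrt[:, None] * k * w_sqrt[None, :]
    chol_b = np.linalg.cholesky(b_mat)
    log_det = 2.0 * float(np.sum(np.log(np.diag(chol_b))))
    log_lik = float(logp.sum())
    log_ev = log_lik - 0.5 * float(f @ alpha) - 0.5 * log_det
    return LaplaceFit(
        f_map=f,
        lambda_map=lam,
        k=k,
        chol_k=chol_k,
        alpha=alpha,
        log_lik=log_lik,
        log_evidence=log_ev,
        iterations=iterations,
        jitter=jitter,
    )


def log_evidence(data: OrdinalDataset, hyper: GporHyperparams, **kwargs) -> float:
    """Laplace approximation of log P(D) under the given hyperparameters."""
    return map_estimate(data, hyper, **kwargs).log_evidence


def posterior_cov_factor(fit: LaplaceFit):
    """Cholesky of B = I + W^{1/2} K W^{1/2}; used for predictive variance."""
    n = fit.f_map.size
    w_sqrt = np.sqrt(fit.lambda_map)
    b_mat = np.eye(n) + w_sqrt[:, None] * fit.k * w_sqrt[None, :]
    return np.linalg.cholesky(b_mat), w_sqrt


def laplace_posterior_cov(fit: LaplaceFit) -> np.ndarray:
    """Full covariance (K^{-1} + Lambda)^{-1} of the Laplace posterior over f."""
    n = fit.f_map.size
    chol_b, w_sqrt = posterior_cov_factor(fit)
    v = solve_triangular(chol_b, w_sqrt[:, None] * fit.k, lower=True)
    return fit.k - v.T @ v
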