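"""Squared-exponential kernel with one relevance weight per input dimension."""

from __future__ import annotations

import numpy as np


def ard_kernel(x1, x2, eta) -> np.ndarray:
    """Entries exp(-1/2 * sum_d eta_d (x1_d - x2_d)^2).

    Unit diagonal when ``x1 is x2``; symmetric PSD by construction.
    """
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    if x1.shape[1] != x2.shape[1]:
        raise ValueError(f"dimension mismatch: {x1.shape[1]} vs {x2.shape[1]}")
    if eta.size != x1.shape[1]:
        raise ValueError(f"eta has {eta.size} weights for {x1.shape[1]}-D inputs")
    if np.any(eta < 0):
        raise ValueError("eta must be nonnegative")
    sq = eta[None, None, :] * (x1[:, None, :] - x2[None, :, :]) ** 2
    return np.exp(-0.5 * sq.sum(axis=-1))


def chol_with_jitter(k: np.ndarray, jitter0: float = 1e-6, jitter_max: float = 1e-2):
    """Cholesky of k + jitter*I, escalating jitter tenfold until it succeeds.

    Returns (lower factor, jitter used).  Raises if jitter_max is exceeded.
    """
    n = k.shape[0]
    jitter = jitter0
    while jitter <= jitter_max * (1 + 1e-12):
        try:
            return np.linalg.cholesky(k + jitter * np.eye(n)), jitter
        except np.linalg.LinAlgError:
            jitter *= 10.0
    raise np.linalg.LinAlgError(
        f"kernel matrix not positive definite even with jitter {jitter_max}"
    )
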