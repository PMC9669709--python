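"""Ordinal probit likelihood: label probabilities and their log-derivatives.

A label s is observed when the noisy latent f + delta falls between ordered
thresholds b_{s-1} and b_s, delta ~ N(0, sigma^2), so

    P(s | f) = Phi((b_s - f)/sigma) - Phi((b_{s-1} - f)/sigma)

with b_0 = -inf and b_R = +inf.  The Gaussian-CDF differences are evaluated in
whichever tail is better conditioned and floored at 1e-300 before logs.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr

_FLOOR = 1e-300
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _npdf(z: np.ndarray) -> np.ndarray:
    out = np.zeros_like(z)
    finite = np.isfinite(z)
    out[finite] = _INV_SQRT_2PI * np.exp(-0.5 * z[finite] ** 2)
    return out


def _cdf_diff(z_hi: np.ndarray, z_lo: np.ndarray) -> np.ndarray:
    """Phi(z_hi) - Phi(z_lo), computed in the smaller tail for accuracy."""
    direct = ndtr(z_hi) - ndtr(z_lo)
    flipped = ndtr(-z_lo) - ndtr(-z_hi)
    use_flip = np.where(np.isfinite(z_lo), z_lo, 0.0) > 0
    return np.maximum(np.where(use_flip, flipped, direct), _FLOOR)


def ordinal_label_probs(f, hyper) -> np.ndarray:
    """Probability vector over labels 1..R at latent value(s) f.

    Returns shape (R,) for scalar f, else (len(f), R).  Rows sum to 1 up to
    telescoping of the Gaussian CDF.
    """
    scalar = np.isscalar(f) or np.ndim(f) == 0
    f_arr = np.atleast_1d(np.asarray(f, dtype=float))
    b_aug = hyper.b_augmented()
    z = (b_aug[None, :] - f_arr[:, None]) / hyper.sigma
    probs = _cdf_diff(z[:, 1:], z[:, :-1])
    return probs[0] if scalar else probs


def label_log_likelihood_terms(f: np.ndarray, y: np.ndarray, hyper):
    """Per-observation (log p, d log p / df, -d^2 log p / df^2).

    The curvature term lam is nonnegative (the likelihood is log-concave in f);
    tiny negative values from floating point are clipped.
    """
    f = np.asarray(f, dtype=float)
    y = np.asarray(y, dtype=int)
    b_aug = hyper.b_augmented()
    sigma = hyper.sigma
    z_hi = (b_aug[y] - f) / sigma
    z_lo = (b_aug[y - 1] - f) / sigma
    p = _cdf_diff(z_hi, z_lo)
    logp = np.log(p)
    pdf_hi = _npdf(z_hi)
    pdf_lo = _npdf(z_lo)
    grad = (pdf_lo - pdf_hi) / (sigma * p)
    zphi_hi = np.where(np.isfinite(z_hi), z_hi, 0.0) * pdf_hi
    zphi_lo = np.where(np.isfinite(z_lo), z_lo, 0.0) * pdf_lo
    lam = (zphi_hi - zphi_lo) / (sigma**2 * p) + grad**2
    return logp, grad, np.clip(lam, 0.0, None)
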