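"""Ground-truth latent utility functions for simulated raters."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class TrueUtility:
    """Closed-form latent utility on the stimulus box.

    kinds:
      * ``quadratic_peak``: amplitude - curvature * ||x - peak||^2
      * ``bimodal``: pointwise max of two Gaussian bumps (peaks/heights/width)
      * ``gp_sample``: seeded stationary random function (random Fourier
        features of an RBF kernel), scaled to ``amplitude``
    """

    kind: str
    params: dict = field(default_factory=dict)
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("quadratic_peak", "bimodal", "gp_sample"):
            raise ValueError(f"unknown utility kind {self.kind!r}")


def _rff(params: dict, amplitude: float):
    d = int(params.get("n_dims", 3))
    lengthscale = float(params.get("lengthscale", 1.0))
    m = int(params.get("n_features", 128))
    rng = np.random.default_rng(int(params.get("seed", 0)))
    omega = rng.normal(scale=1.0 / lengthscale, size=(m, d))
    phase = rng.uniform(0, 2 * np.pi, size=m)
    return omega, phase, amplitude * np.sqrt(2.0 / m)


def evaluate_true_utility(u: TrueUtility, x) -> np.ndarray:
    """Vectorized evaluation; scalar in -> scalar out."""
    scalar = np.ndim(x) == 1
    pts = np.atleast_2d(np.asarray(x, dtype=float))
    if u.kind == "quadratic_peak":
        peak = np.asarray(u.params.get("peak", np.zeros(pts.shape[1])), dtype=float)
        curv = float(u.params.get("curvature", 0.3))
        vals = u.amplitude - curv * np.sum((pts - peak) ** 2, axis=1)
    elif u.kind == "bimodal":
        p1 = np.asarray(u.params["peak1"], dtype=float)
        p2 = np.asarray(u.params["peak2"], dtype=float)
        h1 = float(u.params.get("height1", u.amplitude))
        h2 = float(u.params.get("height2", u.amplitude))
        w = float(u.params.get("width", 0.6))
        g1 = h1 * np.exp(-np.sum((pts - p1) ** 2, axis=1) / (2 * w**2))
        g2 = h2 * np.exp(-np.sum((pts - p2) ** 2, axis=1) / (2 * w**2))
        vals = np.maximum(g1, g2)
    else:  # gp_sample: marginal variance ~ amplitude^2, RBF-like smoothness
        omega, phase, scale = _rff(u.params, u.amplitude)
        vals = scale * np.cos(pts @ omega.T + phase).sum(axis=1)
    if not np.all(np.isfinite(vals)):
        raise ValueError("utility evaluated to a non-finite value")
    return float(vals[0]) if scalar else vals
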