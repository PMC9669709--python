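"""Evidence-based hyperparameter selection.

The Laplace log-evidence is maximized over (log eta, log sigma, b_1,
log-increments of b) by L-BFGS-B from several seeded starting points.  The
log/increment parameterization keeps eta and sigma positive and the
thresholds strictly ordered without explicit constraints.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtri

from .laplace import MapConvergenceError, map_estimate
from .types import GporHyperparams, OrdinalDataset

_LOG_CLIP = 12.0


class HyperFitError(RuntimeError):
    def __init__(self, message: str, diagnostics: list):
        super().__init__(message)
        self.diagnostics = diagnostics


def _pack(hyper: GporHyperparams) -> np.ndarray:
    incs = np.diff(hyper.b)
    return np.concatenate(
        [
            np.log(np.clip(hyper.eta, 1e-8, None)),
            [np.log(hyper.sigma)],
            [hyper.b[0]],
            np.log(np.clip(incs, 1e-8, None)),
        ]
    )


def _unpack(theta: np.ndarray, d: int, r: int) -> GporHyperparams:
    theta = np.clip(theta, -_LOG_CLIP, _LOG_CLIP)
    eta = np.exp(theta[:d])
    sigma = float(np.exp(theta[d]))
    b1 = float(theta[d + 1])
    incs = np.exp(theta[d + 2 :])
    b = b1 + np.concatenate([[0.0], np.cumsum(incs)])
    return GporHyperparams(eta=eta, sigma=sigma, b=b[: r - 1])


def default_init(data: OrdinalDataset) -> GporHyperparams:
    """Moment-based starting point: unit-ish length scales, probit thresholds
    matched to the empirical label frequencies."""
    d, r = data.d, data.r
    spans = np.ptp(data.x, axis=0) if data.n > 1 else np.ones(d)
    spans = np.where(spans > 1e-6, spans, 1.0)
    eta = 2.0 / spans**2
    counts = np.bincount(data.y, minlength=r + 1)[1:]
    cum = np.clip(np.cumsum(counts)[:-1] / max(data.n, 1), 0.02, 0.98)
    b = ndtri(cum)
    b = np.maximum.accumulate(b)
    b += np.arange(r - 1) * 1e-3  # enforce strict ordering on flat stretches
    return GporHyperparams(eta=eta, sigma=1.0, b=b)


def fit_hyperparams(
    data: OrdinalDataset,
    init: GporHyperparams | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    maxiter: int = 100,
) -> GporHyperparams:
    """Best hyperparameters over ``n_restarts`` seeded L-BFGS-B runs.

    Deterministic for a fixed (data, init, n_restarts, seed).
    """
    if data.n == 0:
        raise ValueError("cannot fit hyperparameters to an empty dataset")
    d, r = data.d, data.r
    base = init if init is not None else default_init(data)
    rng = np.random.default_rng(seed)

    def neg_evidence(theta: np.ndarray) -> float:
        try:
            hyper = _unpack(theta, d, r)
            return -map_estimate(data, hyper).log_evidence
        except (MapConvergenceError, np.linalg.LinAlgError, ValueError):
            return 1e10

    theta0 = _pack(base)
    starts = [theta0]
    for _ in range(max(n_restarts - 1, 0)):
        jitter = rng.normal(scale=0.5, size=theta0.size)
        starts.append(theta0 + jitter)

    best = None
    diagnostics = []
    for start in starts:
        try:
            res = minimize(
                neg_evidence,
                start,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-9},
            )
        except Exception as exc:  # pragma: no cover - optimizer internals
            diagnostics.append(repr(exc))
            continue
        if not np.isfinite(res.fun) or res.fun >= 1e9:
            diagnostics.append(f"non-finite objective from start {start}")
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise HyperFitError("all hyperparameter restarts failed", diagnostics)
    return _unpack(best.x, d, r)
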