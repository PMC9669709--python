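"""Core data containers for ordinal Gaussian-process regression."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class OrdinalDataset:
    """Paired stimulus coordinates (SD units) and Likert labels in 1..R."""

    x: np.ndarray  # (N, D)
    y: np.ndarray  # (N,) integers in 1..R
    r: int

    def __post_init__(self) -> None:
        x = np.atleast_2d(np.asarray(self.x, dtype=float))
        y = np.asarray(self.y, dtype=int)
        if x.shape[0] == 0:
            x = x.reshape(0, x.shape[1] if x.ndim == 2 else 0)
        if y.ndim != 1 or x.shape[0] != y.size:
            raise ValueError(f"x has {x.shape[0]} rows but y has {y.size} entries")
        if self.r < 2:
            raise ValueError("need at least 2 ordinal categories")
        if y.size and (y.min() < 1 or y.max() > self.r):
            raise ValueError(f"labels must lie in 1..{self.r}")
        if not np.all(np.isfinite(x)):
            raise ValueError("stimulus coordinates must be finite")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def d(self) -> int:
        return self.x.shape[1]

    def subset(self, idx) -> "OrdinalDataset":
        idx = np.asarray(idx)
        return OrdinalDataset(x=self.x[idx], y=self.y[idx], r=self.r)


@dataclass(frozen=True)
class GporHyperparams:
    """ARD weights, latent noise SD, and ordered category thresholds."""

    eta: np.ndarray  # (D,) nonnegative
    sigma: float  # > 0
    b: np.ndarray  # (R-1,) strictly increasing

    def __post_init__(self) -> None:
        eta = np.atleast_1d(np.asarray(self.eta, dtype=float))
        b = np.atleast_1d(np.asarray(self.b, dtype=float))
        if np.any(eta < 0) or not np.all(np.isfinite(eta)):
            raise ValueError("eta entries must be finite and nonnegative")
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError("sigma must be a positive finite scalar")
        if b.size and (np.any(np.diff(b) <= 0) or not np.all(np.isfinite(b))):
            raise ValueError("thresholds must be finite and strictly increasing")
        object.__setattr__(self, "eta", eta)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "sigma", float(self.sigma))

    @property
    def n_categories(self) -> int:
        return self.b.size + 1

    def b_augmented(self) -> np.ndarray:
        """Thresholds padded with -inf / +inf sentinels (b_0 and b_R)."""
        return np.concatenate([[-np.inf], self.b, [np.inf]])


@dataclass(frozen=True)
class PredictiveDistribution:
    """Gaussian predictive over the latent utility at query points."""

    mu: np.ndarray
    var: np.ndarray

    def __post_init__(self) -> None:
        mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        var = np.atleast_1d(np.asarray(self.var, dtype=float))
        if mu.shape != var.shape:
            raise ValueError("mu and var must have matching shapes")
        if np.any(var < 0):
            raise ValueError("predictive variance must be nonnegative")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "var", var)
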