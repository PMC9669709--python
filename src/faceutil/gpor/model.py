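"""Fitted ordinal-GP model and its predictive distributions.

Predictive mean at a query x*: mu = k*^T K^{-1} f_MAP.  Predictive variance:
K(x*,x*) - k*^T (K + Lambda^{-1})^{-1} k*, evaluated through the symmetric
form with Lambda^{1/2} so near-zero curvature entries never get inverted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import ndtr

from .kernel import ard_kernel
from .laplace import LaplaceFit, map_estimate, posterior_cov_factor
from .types import GporHyperparams, OrdinalDataset, PredictiveDistribution


@dataclass(frozen=True)
class GporModel:
    data: OrdinalDataset
    hyper: GporHyperparams
    fit: LaplaceFit

    @property
    def f_map(self) -> np.ndarray:
        return self.fit.f_map

    @property
    def lambda_map(self) -> np.ndarray:
        return self.fit.lambda_map

    @property
    def k(self) -> np.ndarray:
        return self.fit.k

    @property
    def log_evidence(self) -> float:
        return self.fit.log_evidence

    def to_json(self, path) -> None:
        payload = {
            "eta": self.hyper.eta.tolist(),
            "sigma": self.hyper.sigma,
            "b": self.hyper.b.tolist(),
            "r": self.data.r,
            "x": self.data.x.tolist(),
            "y": self.data.y.tolist(),
            "f_map": self.f_map.tolist(),
            "log_evidence": self.log_evidence,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GporModel":
        with open(path) as fh:
            payload = json.load(fh)
        data = OrdinalDataset(
            x=np.asarray(payload["x"], dtype=float).reshape(len(payload["y"]), -1),
            y=np.asarray(payload["y"]),
            r=int(payload["r"]),
        )
        hyper = GporHyperparams(
            eta=np.asarray(payload["eta"]), sigma=payload["sigma"], b=np.asarray(payload["b"])
        )
        return fit_gpor(data, hyper)


def fit_gpor(data: OrdinalDataset, hyper: GporHyperparams, **map_kwargs) -> GporModel:
    """Run MAP/Laplace inference at fixed hyperparameters."""
    if data.n and hyper.eta.size != data.d:
        raise ValueError(f"eta has {hyper.eta.size} weights for {data.d}-D inputs")
    if hyper.n_categories != data.r:
        raise ValueError(
            f"hyper has {hyper.n_categories} categories but data declares {data.r}"
        )
    return GporModel(data=data, hyper=hyper, fit=map_estimate(data, hyper, **map_kwargs))


def predict_latent(model: GporModel, x_star) -> PredictiveDistribution:
    """Gaussian predictive over the latent utility at query points."""
    x_star = np.atleast_2d(np.asarray(x_star, dtype=float))
    if model.data.n == 0:
        return PredictiveDistribution(
            mu=np.zeros(x_star.shape[0]), var=np.ones(x_star.shape[0])
        )
    k_star = ard_kernel(x_star, model.data.x, model.hyper.eta)  # (M, N)
    mu = k_star @ model.fit.alpha
    chol_b, w_sqrt = posterior_cov_factor(model.fit)
    v = solve_triangular(chol_b, (w_sqrt[:, None] * k_star.T), lower=True)
    var = 1.0 - np.sum(v**2, axis=0)  # prior variance K(x,x) = 1
    if np.any(var < -1e-8):
        warnings.warn(
            f"predictive variance clipped from {var.min():.3e}; numerical issue",
            RuntimeWarning,
        )
    return PredictiveDistribution(mu=mu, var=np.clip(var, 0.0, None))


def predict_labels(model: GporModel, x_star):
    """Label probabilities and modal predictions at query points.

    Integrates the ordinal likelihood over the Gaussian predictive in closed
    form: P(s) = Phi((b_s - mu)/sqrt(sigma^2 + var)) differences.  Ties in the
    argmax resolve to the smaller label.
    """
    pred = predict_latent(model, x_star)
    b_aug = model.hyper.b_augmented()
    scale = np.sqrt(model.hyper.sigma**2 + pred.var)
    z = (b_aug[None, :] - pred.mu[:, None]) / scale[:, None]
    cdf = ndtr(z)
    probs = np.maximum(cdf[:, 1:] - cdf[:, :-1], 0.0)
    probs /= probs.sum(axis=1, keepdims=True)
    y_hat = np.argmax(probs, axis=1) + 1  # argmax returns the first (smallest) max
    return probs, y_hat
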