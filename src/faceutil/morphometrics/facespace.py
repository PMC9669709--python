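"""PCA shape space over aligned landmark configurations.

Coordinates handed to downstream models are expressed in per-component
standard-deviation units, so a score of +2 means "two SDs of the population
along that component".
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .landmarks import LandmarkConfiguration


@dataclass(frozen=True)
class FaceSpace:
    """Mean shape, orthonormal loadings, per-component score SDs and variance ratios."""

    mean_shape: LandmarkConfiguration
    loadings: np.ndarray  # (n_pcs, 2K), rows orthonormal
    pc_sd: np.ndarray  # (n_pcs,)
    explained_ratio: np.ndarray  # (n_pcs,)

    def __post_init__(self) -> None:
        loadings = np.atleast_2d(np.asarray(self.loadings, dtype=float))
        pc_sd = np.asarray(self.pc_sd, dtype=float)
        ratio = np.asarray(self.explained_ratio, dtype=float)
        if loadings.shape[0] != pc_sd.size or pc_sd.size != ratio.size:
            raise ValueError("loadings, pc_sd and explained_ratio sizes disagree")
        if loadings.shape[1] != 2 * self.mean_shape.n_landmarks:
            raise ValueError("loading length must be 2 * n_landmarks")
        if np.any(pc_sd <= 0):
            raise ValueError("pc_sd must be strictly positive")
        if np.any(ratio < 0) or np.any(ratio > 1) or ratio.sum() > 1 + 1e-9:
            raise ValueError("explained_ratio entries must lie in [0,1] and sum to <= 1")
        if np.any(np.diff(ratio) > 1e-12):
            raise ValueError("explained_ratio must be nonincreasing")
        gram = loadings @ loadings.T
        if not np.allclose(gram, np.eye(loadings.shape[0]), atol=1e-8):
            raise ValueError("loadings must be mutually orthonormal")
        object.__setattr__(self, "loadings", loadings)
        object.__setattr__(self, "pc_sd", pc_sd)
        object.__setattr__(self, "explained_ratio", ratio)

    @property
    def n_pcs(self) -> int:
        return self.loadings.shape[0]

    def to_json(self, path) -> None:
        payload = {
            "mean_shape": self.mean_shape.points.tolist(),
            "mean_label": self.mean_shape.label,
            "loadings": self.loadings.tolist(),
            "pc_sd": self.pc_sd.tolist(),
            "explained_ratio": self.explained_ratio.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FaceSpace":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            mean_shape=LandmarkConfiguration(
                points=np.asarray(payload["mean_shape"]), label=payload.get("mean_label", "mean")
            ),
            loadings=np.asarray(payload["loadings"]),
            pc_sd=np.asarray(payload["pc_sd"]),
            explained_ratio=np.asarray(payload["explained_ratio"]),
        )


def fit_face_space(aligned: list, n_pcs: int) -> FaceSpace:
    """Eigendecompose the covariance of flattened coordinates (divisor n-1).

    ``aligned`` should already be superimposed (and symmetrized if asymmetry is
    to be excluded).  Raises if ``n_pcs`` exceeds the achievable rank.
    """
    if len(aligned) < 2:
        raise ValueError("need at least 2 configurations")
    x = np.stack([c.flatten() for c in aligned])
    n, p = x.shape
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    if n_pcs > min(n - 1, p):
        raise ValueError(f"n_pcs={n_pcs} exceeds min(n-1, 2K)={min(n - 1, p)}")
    mu = x.mean(axis=0)
    xc = x - mu
    cov = xc.T @ xc / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = float(evals.sum())
    rank = int(np.sum(evals > max(total, 1e-300) * 1e-12))
    if n_pcs > rank:
        raise ValueError(f"n_pcs={n_pcs} exceeds achievable rank {rank}")
    return FaceSpace(
        mean_shape=LandmarkConfiguration.from_flat(mu, label="mean"),
        loadings=evecs[:, :n_pcs].T,
        pc_sd=np.sqrt(evals[:n_pcs]),
        explained_ratio=evals[:n_pcs] / total,
    )


def scores_to_landmarks(space: FaceSpace, scores_sd) -> LandmarkConfiguration:
    """Reconstruct a shape from component scores given in SD units."""
    scores_sd = np.atleast_1d(np.asarray(scores_sd, dtype=float))
    if scores_sd.size > space.n_pcs:
        raise ValueError(f"got {scores_sd.size} scores for a {space.n_pcs}-PC space")
    d = scores_sd.size
    flat = space.mean_shape.flatten() + (scores_sd * space.pc_sd[:d]) @ space.loadings[:d]
    return LandmarkConfiguration.from_flat(flat, label="reconstruction")


def landmarks_to_scores(space: FaceSpace, config: LandmarkConfiguration) -> np.ndarray:
    """Project a shape onto the space; returns scores in SD units."""
    diff = config.flatten() - space.mean_shape.flatten()
    return (space.loadings @ diff) / space.pc_sd
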