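"""Generalized Procrustes alignment of 2-D landmark configurations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks import LandmarkConfiguration, center_and_scale


@dataclass(frozen=True)
class ProcrustesResult:
    aligned: list
    mean_shape: LandmarkConfiguration
    iterations: int
    converged: bool


def optimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation R (det = +1) minimizing ||a @ R.T - b||_F over proper rotations.

    Points are rows; the rotated copy of ``a`` is ``a @ R.T``.  Reflections are
    excluded so landmark chirality is preserved.
    """
    m = a.T @ b
    u, _, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, d])
    return vt.T @ corr @ u.T


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Norm of the residual after rotating ``a`` onto ``b`` (both pre-standardized)."""
    rot = optimal_rotation(a, b)
    return float(np.linalg.norm(a @ rot.T - b))


def gpa_align(
    configs: list,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> ProcrustesResult:
    """Iteratively superimpose configurations: center, scale to unit centroid
    size, rotate each onto the running mean, and re-normalize the mean until
    its Procrustes displacement falls below ``tol``.
    """
    if len(configs) < 2:
        raise ValueError("need at least 2 configurations to align")
    k = configs[0].n_landmarks
    if any(c.n_landmarks != k for c in configs):
        raise ValueError("all configurations must share the same landmark count")

    std = [center_and_scale(c) for c in configs]
    pts = [c.points for c in std]
    mean = pts[0].copy()

    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        pts = [p @ optimal_rotation(p, mean).T for p in pts]
        new_mean = np.mean(pts, axis=0)
        new_mean -= new_mean.mean(axis=0)
        new_mean /= np.linalg.norm(new_mean)
        delta = procrustes_distance(new_mean, mean)
        mean = new_mean
        if delta < tol:
            converged = True
            break

    aligned = [c.with_points(p) for c, p in zip(std, pts)]
    mean_cfg = LandmarkConfiguration(points=mean, label="mean")
    return ProcrustesResult(
        aligned=aligned, mean_shape=mean_cfg, iterations=iterations, converged=converged
    )
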