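"""Thin-plate spline warps between landmark configurations.

Radial kernel U(r) = r^2 log(r^2) with U(0) = 0.  With zero regularization the
warp interpolates the target landmarks exactly; the nonaffine weights are
orthogonal to the affine polynomial terms (side conditions), and the bending
energy w^T U w is nonnegative on that subspace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks import LandmarkConfiguration


class SingularTpsError(np.linalg.LinAlgError):
    """Raised when the TPS system is singular (e.g. collinear source landmarks)."""


def _radial(r2: np.ndarray) -> np.ndarray:
    out = np.zeros_like(r2)
    mask = r2 > 0
    out[mask] = r2[mask] * np.log(r2[mask])
    return out


def _kernel_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1)
    return _radial(d2)


@dataclass(frozen=True)
class TpsWarp:
    source: LandmarkConfiguration
    target: LandmarkConfiguration
    affine: np.ndarray  # (3, 2): constant, x, y rows
    nonaffine: np.ndarray  # (K, 2) radial weights
    bending_energy: float


def tps_fit(
    source: LandmarkConfiguration,
    target: LandmarkConfiguration,
    lambda_reg: float = 0.0,
) -> TpsWarp:
    """Solve the TPS linear system for a warp carrying source landmarks to target."""
    if source.n_landmarks != target.n_landmarks:
        raise ValueError("source and target must have equal landmark counts")
    if lambda_reg < 0:
        raise ValueError("lambda_reg must be nonnegative")
    s = source.points
    k = s.shape[0]

    # collinearity check: the affine block P must have rank 3
    p = np.column_stack([np.ones(k), s])
    if np.linalg.matrix_rank(p, tol=1e-10 * max(1.0, np.abs(s).max())) < 3:
        raise SingularTpsError("source landmarks are collinear; TPS system is singular")

    u = _kernel_matrix(s, s) + lambda_reg * np.eye(k)
    lhs = np.zeros((k + 3, k + 3))
    lhs[:k, :k] = u
    lhs[:k, k:] = p
    lhs[k:, :k] = p.T
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = target.points
    try:
        sol = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rank check above
        raise SingularTpsError(str(exc)) from exc

    w = sol[:k]
    affine = sol[k:]
    bend = float(np.einsum("id,ij,jd->", w, u - lambda_reg * np.eye(k), w))
    return TpsWarp(
        source=source,
        target=target,
        affine=affine,
        nonaffine=w,
        bending_energy=max(bend, 0.0),
    )


def tps_apply(warp: TpsWarp, points) -> np.ndarray:
    """Evaluate the warp (affine + radial terms) at arbitrary 2-D points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 2:
        raise ValueError("points must have shape (M, 2)")
    u = _kernel_matrix(pts, warp.source.points)
    poly = np.column_stack([np.ones(pts.shape[0]), pts])
    return u @ warp.nonaffine + poly @ warp.affine


def warp_grid(warp: TpsWarp, grid_x: np.ndarray, grid_y: np.ndarray) -> np.ndarray:
    """Warp a rectangular lattice; returns an array of shape (ny, nx, 2).

    Used for deforming synthetic grayscale grids in stimulus generation.
    """
    xx, yy = np.meshgrid(grid_x, grid_y)
    flat = np.column_stack([xx.ravel(), yy.ravel()])
    return tps_apply(warp, flat).reshape(len(grid_y), len(grid_x), 2)
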