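"""Standard evaluation grid, equal-weight pooling, extrema, and tail probability.

Each participant's latent utility is evaluated on a lexicographically ordered
lattice (by default -2..+2 SD per dimension at step 0.4: 11 values per axis,
11^D points).  Pooling treats participants as an equal-weight Gaussian
mixture at each grid point:

    mu_S  = mean of participant means
    var_S = mean of (mu^2 + var) - mu_S^2

which is the exact mixture variance, never below the mean within-participant
variance (law of total variance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.special import ndtr


@dataclass(frozen=True)
class GridSpec:
    n_dims: int = 3
    bound: float = 2.0
    step: float = 0.4

    def __post_init__(self) -> None:
        if self.n_dims < 1:
            raise ValueError("n_dims must be >= 1")
        if self.bound <= 0 or self.step <= 0:
            raise ValueError("bound and step must be positive")
        span = 2.0 * self.bound
        n = span / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"step {self.step} does not divide span {span}")

    @property
    def axis(self) -> np.ndarray:
        n = int(round(2.0 * self.bound / self.step))
        return np.linspace(-self.bound, self.bound, n + 1)

    @property
    def n_points(self) -> int:
        return len(self.axis) ** self.n_dims


def build_grid(spec: GridSpec) -> np.ndarray:
    """All lattice points in lexicographic order, shape (n_points, n_dims)."""
    return np.array(list(product(spec.axis, repeat=spec.n_dims)))


@dataclass(frozen=True)
class UtilityGrid:
    coords: np.ndarray  # (P, D), lexicographic
    mu: np.ndarray  # (P,)
    var: np.ndarray  # (P,)

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        mu = np.asarray(self.mu, dtype=float)
        var = np.asarray(self.var, dtype=float)
        if not (coords.shape[0] == mu.size == var.size):
            raise ValueError("coords, mu, var lengths disagree")
        if np.any(var < 0):
            raise ValueError("variances must be nonnegative")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "var", var)


@dataclass(frozen=True)
class AveragedUtility:
    coords: np.ndarray
    mu_s: np.ndarray
    var_s: np.ndarray
    m: int
    x_star: np.ndarray
    x_minus: np.ndarray


def evaluate_on_grid(model, spec: GridSpec) -> UtilityGrid:
    """Latent predictive mean/variance at every point of the standard lattice."""
    from ..gpor.model import predict_latent

    coords = build_grid(spec)
    pred = predict_latent(model, coords)
    return UtilityGrid(coords=coords, mu=pred.mu, var=pred.var)


def locate_extrema(coords: np.ndarray, mu_s: np.ndarray):
    """Argmax / argmin of the pooled mean; ties go to the first (lexicographically
    smallest) grid point."""
    if mu_s.size == 0:
        raise ValueError("empty grid")
    return coords[int(np.argmax(mu_s))], coords[int(np.argmin(mu_s))]


def average_utilities(grids: list) -> AveragedUtility:
    """Equal-weight Gaussian-mixture moments across participants' grids."""
    if not grids:
        raise ValueError("need at least one participant grid")
    coords = grids[0].coords
    for g in grids[1:]:
        if g.coords.shape != coords.shape or not np.allclose(g.coords, coords):
            raise ValueError("participant grids are not on identical coordinates")
    m = len(grids)
    mus = np.stack([g.mu for g in grids])
    vars_ = np.stack([g.var for g in grids])
    mu_s = mus.mean(axis=0)
    # algebraically identical to mean(mu^2 + var) - mu_S^2, but written as
    # within-variance + between-variance so the law of total variance holds
    # exactly in floating point as well
    var_s = vars_.mean(axis=0) + ((mus - mu_s) ** 2).mean(axis=0)
    x_star, x_minus = locate_extrema(coords, mu_s)
    return AveragedUtility(
        coords=coords, mu_s=mu_s, var_s=var_s, m=m, x_star=x_star, x_minus=x_minus
    )


def exceedance_probability(mu: float, var: float) -> float:
    """P(f <= 0) under a Gaussian predictive N(mu, var).

    Degenerate var = 0 collapses to an indicator of the sign of mu (with a
    warning); mu = 0, var = 0 counts as exceeded.
    """
    if var < 0:
        raise ValueError("variance must be nonnegative")
    if var == 0:
        warnings.warn("degenerate predictive (var = 0); returning 0/1 indicator")
        return 1.0 if mu <= 0 else 0.0
    return float(ndtr(-mu / np.sqrt(var)))


def write_grid_csv(path, grid) -> None:
    d = grid.coords.shape[1]
    df = pd.DataFrame(grid.coords, columns=[f"pc{i + 1}" for i in range(d)])
    if isinstance(grid, AveragedUtility):
        df["mu"], df["var"] = grid.mu_s, grid.var_s
    else:
        df["mu"], df["var"] = grid.mu, grid.var
    df.to_csv(path, index=False)


def read_grid_csv(path) -> UtilityGrid:
    df = pd.read_csv(path)
    pcs = [c for c in df.columns if c.startswith("pc")]
    return UtilityGrid(
        coords=df[pcs].to_numpy(float), mu=df["mu"].to_numpy(float), var=df["var"].to_numpy(float)
    )
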