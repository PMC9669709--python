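"""Landmark configurations, bilateral symmetry maps, and shape standardization.

A configuration is an ordered set of K two-dimensional landmarks.  Ordering is
fixed across a population so that flattened coordinate vectors are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DegenerateShapeError(ValueError):
    """Raised when a configuration has no spatial extent (all points coincide)."""


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One shape: an ordered (K, 2) array of landmark coordinates plus a label."""

    points: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must have shape (K, 2), got {pts.shape}")
        if pts.shape[0] < 3:
            raise ValueError(f"need at least 3 landmarks, got {pts.shape[0]}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("landmark coordinates must be finite")
        object.__setattr__(self, "points", pts)

    @property
    def n_landmarks(self) -> int:
        return self.points.shape[0]

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def centroid_size(self, convention: str = "root") -> float:
        """Scale of the configuration about its centroid.

        ``root`` (default) is sqrt(sum of squared centroid distances); ``raw``
        is the un-rooted sum, kept for sensitivity checks.
        """
        sq = float(np.sum((self.points - self.centroid()) ** 2))
        if convention == "root":
            return float(np.sqrt(sq))
        if convention == "raw":
            return sq
        raise ValueError(f"unknown centroid-size convention {convention!r}")

    def flatten(self) -> np.ndarray:
        """Row-major (x1, y1, x2, y2, ...) coordinate vector of length 2K."""
        return self.points.ravel().copy()

    @classmethod
    def from_flat(cls, flat: np.ndarray, label: str = "") -> "LandmarkConfiguration":
        flat = np.asarray(flat, dtype=float)
        if flat.ndim != 1 or flat.size % 2 != 0:
            raise ValueError("flat vector must be 1-D with even length")
        return cls(points=flat.reshape(-1, 2), label=label)

    def with_points(self, points: np.ndarray) -> "LandmarkConfiguration":
        return LandmarkConfiguration(points=points, label=self.label)


@dataclass(frozen=True)
class SymmetryMap:
    """Bilateral landmark correspondence: mirrored pairs plus midline indices."""

    pairs: tuple = field(default_factory=tuple)
    midline: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        pairs = tuple((int(a), int(b)) for a, b in self.pairs)
        midline = tuple(int(i) for i in self.midline)
        seen: set[int] = set()
        for a, b in pairs:
            if a == b:
                raise ValueError(f"pair ({a}, {b}) maps a landmark to itself")
            for i in (a, b):
                if i in seen:
                    raise ValueError(f"index {i} appears more than once in symmetry map")
                seen.add(i)
        for i in midline:
            if i in seen:
                raise ValueError(f"index {i} appears more than once in symmetry map")
            seen.add(i)
        if any(i < 0 for i in seen):
            raise ValueError("symmetry map indices must be nonnegative")
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "midline", midline)

    @property
    def n_landmarks(self) -> int:
        return 2 * len(self.pairs) + len(self.midline)

    def validate_for(self, k: int) -> None:
        covered = {i for pair in self.pairs for i in pair} | set(self.midline)
        if covered != set(range(k)):
            raise ValueError(
                f"symmetry map covers indices {sorted(covered)} but configuration has {k} landmarks"
            )

    def relabel_indices(self, k: int) -> np.ndarray:
        """Permutation sending each landmark to its mirror partner (midline fixed)."""
        self.validate_for(k)
        perm = np.arange(k)
        for a, b in self.pairs:
            perm[a], perm[b] = b, a
        return perm


def center_and_scale(
    config: LandmarkConfiguration, convention: str = "root"
) -> LandmarkConfiguration:
    """Translate the centroid to the origin and rescale to unit centroid size."""
    centered = config.points - config.centroid()
    size = float(np.sqrt(np.sum(centered**2)))
    if size < 1e-12:
        raise DegenerateShapeError(
            f"configuration {config.label!r} is degenerate: all landmarks coincide"
        )
    if convention == "raw":
        size = size**2
    elif convention != "root":
        raise ValueError(f"unknown centroid-size convention {convention!r}")
    return config.with_points(centered / size)


def reflect_relabel(config: LandmarkConfiguration, sym: SymmetryMap) -> LandmarkConfiguration:
    """Mirror about the vertical axis (x -> -x) and swap left/right labels.

    This operator is an involution; a configuration is bilaterally symmetric
    under ``sym`` exactly when it is a fixed point.
    """
    perm = sym.relabel_indices(config.n_landmarks)
    mirrored = config.points * np.array([-1.0, 1.0])
    return config.with_points(mirrored[perm])


def _rotation_matrix(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def symmetrize(config: LandmarkConfiguration, sym: SymmetryMap) -> LandmarkConfiguration:
    """Average a configuration with its mirrored, relabeled copy.

    The mirrored copy is rotated onto the original by orthogonal Procrustes
    (rotation only) before averaging, and the average is then counter-rotated
    by half the Procrustes angle so the output is an exact fixed point of
    :func:`reflect_relabel`.  The centroid's y-coordinate is preserved; the
    x-coordinate is set to zero (a symmetric shape has none).
    """
    from .procrustes import optimal_rotation

    sym.validate_for(config.n_landmarks)
    centroid = config.centroid()
    c0 = config.points - centroid
    refl = reflect_relabel(config.with_points(c0), sym).points
    rot = optimal_rotation(refl, c0)  # rotate refl toward c0
    theta = float(np.arctan2(rot[1, 0], rot[0, 0]))
    avg = 0.5 * (c0 + refl @ rot.T)
    out = avg @ _rotation_matrix(-theta / 2.0).T
    out = out + np.array([0.0, centroid[1]])
    return config.with_points(out)


def asymmetric_component(config: LandmarkConfiguration, sym: SymmetryMap) -> np.ndarray:
    """(config - mirrored copy)/2: zero exactly when the shape is symmetric."""
    refl = reflect_relabel(config, sym)
    return 0.5 * (config.points - refl.points)
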