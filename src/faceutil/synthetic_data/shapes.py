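"""Synthetic landmark populations with a planted low-rank covariance.

Faces are built from a bilaterally symmetric template (an elliptical outline
with mirrored feature clusters), perturbed along a few orthonormal symmetric
loadings with prescribed score SDs, plus small isotropic digitization noise
and an optional random similarity transform per face.  Symmetrization and
Procrustes alignment are then near-lossless, and PCA of the population
recovers the planted variance ratios.
"""

from __future__ import annotations

import numpy as np

from ..morphometrics.landmarks import LandmarkConfiguration, SymmetryMap, reflect_relabel


def default_symmetry_map(n_landmarks: int) -> SymmetryMap:
    """Pair landmark i with i + K//2; one trailing midline point if K is odd."""
    half = n_landmarks // 2
    pairs = tuple((i, i + half) for i in range(half))
    midline = (n_landmarks - 1,) if n_landmarks % 2 else ()
    return SymmetryMap(pairs=pairs, midline=midline)


def template_face(n_landmarks: int, scale: float = 100.0) -> LandmarkConfiguration:
    """Deterministic symmetric template: left half on an ellipse-plus-features
    layout, right half its mirror, optional single midline point at the chin."""
    if n_landmarks < 4:
        raise ValueError("template needs at least 4 landmarks")
    half = n_landmarks // 2
    # left-half points: outline arc plus interior feature rows (eye, nose, mouth)
    t = np.linspace(0.15, 0.85, half) * np.pi
    outline = np.column_stack([-np.abs(np.sin(t)) * 0.9, np.cos(t) * 1.2])
    rows = np.tile(np.array([[-0.45, 0.45], [-0.2, 0.0], [-0.3, -0.55]]), (half // 3 + 1, 1))
    interior = rows[:half] * (1.0 + 0.08 * np.linspace(0, 1, half)[:, None])
    left = 0.5 * outline + 0.5 * interior
    left[:, 0] = -np.abs(left[:, 0]) - 0.05  # keep strictly on the left
    right = left * np.array([-1.0, 1.0])
    pts = np.vstack([left, right])
    if n_landmarks % 2:
        pts = np.vstack([pts, [[0.0, -1.3]]])
    pts = pts - pts.mean(axis=0)
    pts *= scale / np.sqrt(np.sum(pts**2))
    return LandmarkConfiguration(points=pts, label="template")


def _symmetrize_vector(v: np.ndarray, sym: SymmetryMap, k: int) -> np.ndarray:
    refl = reflect_relabel(LandmarkConfiguration(points=v.reshape(k, 2)), sym)
    return 0.5 * (v + refl.points.ravel())


def _similarity_directions(template: np.ndarray) -> np.ndarray:
    """Orthonormal span of translation/scale/rotation at the template.

    Procrustes standardization removes variation along these directions, so
    planted factors must avoid them or their variance is silently eaten.
    """
    k = template.shape[0]
    centered = template - template.mean(axis=0)
    dirs = [
        np.tile([1.0, 0.0], k),  # x-translation
        np.tile([0.0, 1.0], k),  # y-translation
        centered.ravel(),  # scale
        np.column_stack([-centered[:, 1], centered[:, 0]]).ravel(),  # rotation
    ]
    out = []
    for v in dirs:
        for u in out:
            v = v - (v @ u) * u
        out.append(v / np.linalg.norm(v))
    return np.stack(out)


def _symmetric_loadings(
    template: np.ndarray,
    n_factors: int,
    sym: SymmetryMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """Orthonormal (n_factors, 2K) rows: fixed points of reflect+relabel,
    orthogonal to the template's similarity-transform directions."""
    k = template.shape[0]
    forbidden = list(_similarity_directions(template))
    loadings = []
    attempts = 0
    while len(loadings) < n_factors:
        attempts += 1
        if attempts > 50 * n_factors:
            raise RuntimeError("failed to build orthonormal symmetric loadings")
        v = _symmetrize_vector(rng.normal(size=2 * k), sym, k)
        for u in forbidden + loadings:
            v = v - (v @ u) * u
        norm = np.linalg.norm(v)
        if norm < 1e-8:
            continue
        loadings.append(v / norm)
    return np.stack(loadings)


def generate_shape_population(
    n_faces: int,
    n_landmarks: int,
    factor_sds,
    noise_sd: float = 0.0,
    symmetry_map: SymmetryMap | None = None,
    seed: int = 0,
    transform_jitter: bool = True,
    template_scale: float = 100.0,
) -> list:
    """Sample a population of landmark configurations with planted PC structure."""
    factor_sds = np.atleast_1d(np.asarray(factor_sds, dtype=float))
    if factor_sds.size and np.any(np.diff(factor_sds) > 0):
        raise ValueError("factor_sds must be nonincreasing")
    if n_faces <= factor_sds.size:
        raise ValueError("need more faces than planted factors")
    sym = symmetry_map if symmetry_map is not None else default_symmetry_map(n_landmarks)
    if sym.n_landmarks != n_landmarks:
        raise ValueError(
            f"symmetry map covers {sym.n_landmarks} landmarks, population has {n_landmarks}"
        )
    sym.validate_for(n_landmarks)

    rng = np.random.default_rng(seed)
    template = template_face(n_landmarks, scale=template_scale)
    loadings = _symmetric_loadings(template.points, factor_sds.size, sym, rng)

    configs = []
    for i in range(n_faces):
        scores = rng.normal(size=factor_sds.size) * factor_sds
        flat = template.flatten() + scores @ loadings
        flat = flat + noise_sd * rng.normal(size=flat.size)
        pts = flat.reshape(n_landmarks, 2)
        if transform_jitter:
            theta = rng.uniform(-np.pi, np.pi)
            c, s = np.cos(theta), np.sin(theta)
            rot = np.array([[c, -s], [s, c]])
            scale = np.exp(rng.normal(scale=0.1))
            shift = rng.normal(scale=0.2 * template_scale, size=2)
            pts = pts @ rot.T * scale + shift
        configs.append(LandmarkConfiguration(points=pts, label=f"face_{i:04d}"))
    return configs
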