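"""Simulated raters: latent utility + Gaussian noise + ordered thresholds.

A response to stimulus x is the category s with b_{s-1} < u(x) + delta <= b_s,
delta drawn from the participant's own seeded noise stream, which makes whole
response sequences reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .utilities import TrueUtility, evaluate_true_utility

DEFAULT_THRESHOLDS = (-1.5, -0.5, 0.5, 1.5)


@dataclass
class SimulatedParticipant:
    utility: TrueUtility
    thresholds: np.ndarray = field(default_factory=lambda: np.asarray(DEFAULT_THRESHOLDS))
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        b = np.atleast_1d(np.asarray(self.thresholds, dtype=float))
        if np.any(np.diff(b) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        self.thresholds = b
        self._rng = np.random.default_rng(self.seed)

    @property
    def r(self) -> int:
        return self.thresholds.size + 1

    def reset(self) -> None:
        """Rewind the noise stream to the start of the session."""
        self._rng = np.random.default_rng(self.seed)

    def __call__(self, x) -> int:
        return simulate_response(self, x)


def simulate_response(p: SimulatedParticipant, x) -> int:
    """One Likert response: threshold the noisy latent utility."""
    v = evaluate_true_utility(p.utility, np.asarray(x, dtype=float))
    v = v + p._rng.normal(scale=p.noise_sd)
    # b_{s-1} < v <= b_s  ->  label s
    return int(np.searchsorted(p.thresholds, v, side="left")) + 1


def label_distribution(p: SimulatedParticipant, x) -> np.ndarray:
    """Analytic response probabilities at x (for goodness-of-fit checks)."""
    from scipy.special import ndtr

    v = evaluate_true_utility(p.utility, np.asarray(x, dtype=float))
    b_aug = np.concatenate([[-np.inf], p.thresholds, [np.inf]])
    cdf = ndtr((b_aug - v) / p.noise_sd)
    return np.diff(cdf)
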