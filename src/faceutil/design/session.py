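"""Rating-session driver: practice draws, random exploration, UCB exploitation.

A session mimics a live rating protocol: practice trials are drawn from the same
random stream but discarded; the first block of test trials is sampled
uniformly in the +/- bound box; each subsequent trial is placed at the UCB
argmax of a model refit on the accumulated history.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..gpor.hyperfit import default_init, fit_hyperparams
from ..gpor.model import fit_gpor
from ..gpor.types import OrdinalDataset
from .acquisition import select_next_stimulus


@dataclass(frozen=True)
class SessionConfig:
    n_practice: int = 20
    n_random: int = 45
    n_adaptive: int = 15
    n_dims: int = 3
    bounds: float = 2.0
    grid_step: float = 0.4
    r: int = 5
    seed: int = 0
    ucb_beta: str = "log_over_n"
    # hyperparameter refitting during the adaptive phase:
    #   "every" - full evidence maximization before each selection
    #   "once"  - evidence maximization at the start of the adaptive phase only
    #   "never" - moment-based defaults throughout (latent MAP still refit)
    refit_hyper: str = "every"
    n_restarts: int = 2
    hyper_maxiter: int = 60

    def __post_init__(self) -> None:
        if self.n_random < 0 or self.n_adaptive < 0 or self.n_practice < 0:
            raise ValueError("trial counts must be nonnegative")
        if self.refit_hyper not in ("every", "once", "never"):
            raise ValueError(f"unknown refit_hyper policy {self.refit_hyper!r}")
        span = 2.0 * self.bounds
        if abs(span / self.grid_step - round(span / self.grid_step)) > 1e-9:
            raise ValueError("grid_step must divide the bounds span")


@dataclass
class ExperimentState:
    config: SessionConfig
    x_history: list = field(default_factory=list)
    y_history: list = field(default_factory=list)
    rng: np.random.Generator = None

    def __post_init__(self) -> None:
        if self.rng is None:
            self.rng = np.random.default_rng(self.config.seed)

    @property
    def trial_index(self) -> int:
        return len(self.y_history)

    @property
    def phase(self) -> str:
        return "adaptive" if self.trial_index >= self.config.n_random else "random"

    def history(self) -> OrdinalDataset:
        x = (
            np.asarray(self.x_history)
            if self.x_history
            else np.zeros((0, self.config.n_dims))
        )
        return OrdinalDataset(x=x, y=np.asarray(self.y_history, dtype=int), r=self.config.r)

    def record(self, x: np.ndarray, y: int) -> None:
        if not (1 <= y <= self.config.r):
            raise ValueError(f"responder returned label {y} outside 1..{self.config.r}")
        self.x_history.append(np.asarray(x, dtype=float))
        self.y_history.append(int(y))


def random_stimulus(state: ExperimentState) -> np.ndarray:
    """Continuous uniform draw per dimension from the seeded session stream."""
    cfg = state.config
    return state.rng.uniform(-cfg.bounds, cfg.bounds, size=cfg.n_dims)


def run_session(responder, config: SessionConfig) -> OrdinalDataset:
    """Run one participant through the full session; returns the test trials.

    ``responder`` maps a coordinate to a label in 1..R.  Practice responses are
    collected (they advance the responder's noise stream, as in a live
    session) but excluded from the returned dataset.
    """
    state = ExperimentState(config=config)
    for _ in range(config.n_practice):
        x = state.rng.uniform(-config.bounds, config.bounds, size=config.n_dims)
        y = int(responder(x))
        if not (1 <= y <= config.r):
            raise ValueError(f"responder returned label {y} outside 1..{config.r}")

    for _ in range(config.n_random):
        x = random_stimulus(state)
        state.record(x, int(responder(x)))

    hyper = None
    for i in range(config.n_adaptive):
        data = state.history()
        if config.refit_hyper == "every" or (config.refit_hyper == "once" and hyper is None):
            hyper = fit_hyperparams(
                data,
                n_restarts=config.n_restarts,
                seed=config.seed,
                maxiter=config.hyper_maxiter,
            )
        elif config.refit_hyper == "never" and hyper is None:
            hyper = default_init(data)
        model = fit_gpor(data, hyper)
        x = select_next_stimulus(state, model)
        state.record(x, int(responder(x)))

    return state.history()
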