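"""Upper-confidence-bound acquisition over the candidate lattice.

The exploration coefficient is beta(N) = log(N)/N by default (so later trials
exploit more); the conventional sqrt(log N / N) schedule is available as
``sqrt_log_over_n``.
"""

from __future__ import annotations

import numpy as np


def ucb_scores(mu, sigma, n: int, beta: str = "log_over_n") -> np.ndarray:
    """Elementwise mu + beta(N) * sigma."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if mu.shape != sigma.shape:
        raise ValueError("mu and sigma must have matching shapes")
    if np.any(sigma < 0):
        raise ValueError("sigma must be nonnegative")
    if n < 1:
        raise ValueError("trial count N must be >= 1 (coefficient undefined at 0)")
    if beta == "log_over_n":
        coef = np.log(n) / n
    elif beta == "sqrt_log_over_n":
        coef = np.sqrt(np.log(n) / n)
    else:
        raise ValueError(f"unknown beta schedule {beta!r}")
    return mu + coef * sigma


def select_next_stimulus(state, model) -> np.ndarray:
    """Grid point with maximal UCB given the response history; ties resolve to
    the lexicographically smallest candidate."""
    from ..aggregation.grid import GridSpec, build_grid
    from ..gpor.model import predict_latent

    if state.phase != "adaptive":
        raise ValueError("adaptive selection requested outside the adaptive phase")
    if model is None or model.data.n == 0:
        raise ValueError("select_next_stimulus requires a model fitted on history")
    cfg = state.config
    spec = GridSpec(n_dims=cfg.n_dims, bound=cfg.bounds, step=cfg.grid_step)
    grid = build_grid(spec)
    pred = predict_latent(model, grid)
    scores = ucb_scores(pred.mu, np.sqrt(pred.var), n=state.trial_index, beta=cfg.ucb_beta)
    return grid[int(np.argmax(scores))]  # first max = lexicographically smallest
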