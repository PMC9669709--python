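"""Whole-study simulation: many raters sharing a jittered peak utility.

Defaults encode the standard design scale (40 raters, 20 practice + 45 random + 15
adaptive trials on a 5-point scale).  Rater i derives all randomness from
SeedSequence([seed + i]) so adding raters never reshuffles existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..design.session import SessionConfig, run_session
from .participants import DEFAULT_THRESHOLDS, SimulatedParticipant
from .utilities import TrueUtility


@dataclass(frozen=True)
class ParticipantSpec:
    """Population model for simulated raters: a shared peak plus per-rater
    Gaussian jitter of the peak location (SD in PC-SD units per dimension)."""

    shared_peak: tuple = (-0.8, -0.4, 0.8)
    peak_jitter_sd: float = 0.3
    amplitude: float = 2.0
    curvature: float = 0.3
    noise_sd: float = 1.0
    thresholds: tuple = DEFAULT_THRESHOLDS


@dataclass(frozen=True)
class StudyResult:
    datasets: list  # one OrdinalDataset per rater
    participants: list  # the SimulatedParticipant objects (ground truth)
    true_peaks: np.ndarray  # (M, D)


def make_participant(spec: ParticipantSpec, seed: int, bound: float = 2.0):
    """One simulated rater; the peak jitter and noise stream both derive from
    ``seed`` via independent SeedSequence children."""
    ss = np.random.SeedSequence(seed)
    jitter_ss, noise_ss = ss.spawn(2)
    rng = np.random.default_rng(jitter_ss)
    shared = np.asarray(spec.shared_peak, dtype=float)
    peak = np.clip(shared + rng.normal(scale=spec.peak_jitter_sd, size=shared.size),
                   -bound, bound)
    utility = TrueUtility(
        kind="quadratic_peak",
        params={"peak": peak, "curvature": spec.curvature},
        amplitude=spec.amplitude,
    )
    participant = SimulatedParticipant(
        utility=utility,
        thresholds=np.asarray(spec.thresholds),
        noise_sd=spec.noise_sd,
        seed=noise_ss,  # default_rng accepts a SeedSequence; reset() still works
    )
    return participant, peak


def simulate_study(
    m: int,
    session_config: SessionConfig | None = None,
    participant_spec: ParticipantSpec | None = None,
    seed: int = 0,
) -> StudyResult:
    """Run ``m`` simulated raters through full sessions."""
    if m < 1:
        raise ValueError("need at least one participant")
    spec = participant_spec if participant_spec is not None else ParticipantSpec()
    base_cfg = session_config if session_config is not None else SessionConfig()

    datasets = []
    participants = []
    peaks = []
    for i in range(m):
        pid_seed = seed + i
        participant, peak = make_participant(spec, pid_seed, bound=base_cfg.bounds)
        cfg = SessionConfig(
            n_practice=base_cfg.n_practice,
            n_random=base_cfg.n_random,
            n_adaptive=base_cfg.n_adaptive,
            n_dims=base_cfg.n_dims,
            bounds=base_cfg.bounds,
            grid_step=base_cfg.grid_step,
            r=base_cfg.r,
            seed=pid_seed,
            ucb_beta=base_cfg.ucb_beta,
            refit_hyper=base_cfg.refit_hyper,
            n_restarts=base_cfg.n_restarts,
            hyper_maxiter=base_cfg.hyper_maxiter,
        )
        datasets.append(run_session(participant, cfg))
        participants.append(participant)
        peaks.append(peak)
    return StudyResult(
        datasets=datasets, participants=participants, true_peaks=np.asarray(peaks)
    )
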