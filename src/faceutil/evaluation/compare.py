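"""Paired comparison of per-participant error vectors."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PairedComparison:
    t: float
    df: int
    p_value: float
    cohen_d: float
    mean_diff: float
    degenerate: bool  # zero-variance nonzero difference (infinite t)


def compare_models(errors_a, errors_b) -> PairedComparison:
    """Two-sided paired t-test and paired Cohen's d on A - B.

    Identical inputs give t = 0, d = 0.  A constant nonzero difference has no
    sampling variance; it is reported as signed-infinite t with the
    ``degenerate`` flag set.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("error vectors must be equal-length 1-D arrays")
    if a.size < 2:
        raise ValueError("need at least 2 participants")
    diff = a - b
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    df = a.size - 1
    if sd <= 1e-12 * max(abs(mean), 1.0):  # constant difference up to rounding
        if mean == 0.0:
            return PairedComparison(0.0, df, 1.0, 0.0, 0.0, False)
        t = np.inf if mean > 0 else -np.inf
        return PairedComparison(float(t), df, 0.0, float(np.sign(mean) * np.inf), mean, True)
    t = mean / (sd / np.sqrt(a.size))
    p = 2.0 * stats.t.sf(abs(t), df)
    return PairedComparison(float(t), df, float(p), mean / sd, mean, False)
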