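"""Ordinal prediction error metrics."""

from __future__ import annotations

import numpy as np


def compute_mze_mae(pred, truth) -> tuple:
    """Mean zero-one error and mean absolute error over label pairs.

    Labels are treated as consecutive integers; MZE is the fraction of
    predictions differing from the truth, MAE the mean absolute label gap.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.ndim != 1 or pred.size == 0:
        raise ValueError("pred and truth must be equal-length nonempty 1-D arrays")
    mze = float(np.mean(pred != truth))
    mae = float(np.mean(np.abs(pred.astype(float) - truth.astype(float))))
    return mze, mae
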