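"""Ratings-table I/O: long CSV with participant_id, trial, pc1..pcD, rating."""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .types import OrdinalDataset


def _pc_columns(df: pd.DataFrame) -> list:
    cols = [c for c in df.columns if re.fullmatch(r"pc\d+", c)]
    return sorted(cols, key=lambda c: int(c[2:]))


def read_ratings_csv(path, r: int = 5) -> dict:
    """Returns {participant_id: OrdinalDataset}, trials in recorded order."""
    df = pd.read_csv(path)
    pcs = _pc_columns(df)
    if not pcs or "rating" not in df.columns or "participant_id" not in df.columns:
        raise ValueError(f"{path}: expected participant_id, trial, pc1..pcD, rating columns")
    if "trial" in df.columns:
        df = df.sort_values(["participant_id", "trial"], kind="stable")
    out = {}
    for pid, grp in df.groupby("participant_id", sort=False):
        out[str(pid)] = OrdinalDataset(
            x=grp[pcs].to_numpy(float), y=grp["rating"].to_numpy(int), r=r
        )
    return out


def write_ratings_csv(path, datasets: dict) -> None:
    rows = []
    for pid, data in datasets.items():
        for t in range(data.n):
            row = {"participant_id": pid, "trial": t}
            row.update({f"pc{d + 1}": data.x[t, d] for d in range(data.d)})
            row["rating"] = int(data.y[t])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
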