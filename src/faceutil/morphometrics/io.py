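"""Readers and writers for landmark data.

Two plain-text formats are supported:

* the classic landmark record format used by morphometrics digitizers::

      LM=3
      0.0 0.0
      1.0 0.0
      0.0 1.0
      ID=face_001

* long-format CSV with columns ``face_id, landmark_id, x, y``.

Symmetry maps are stored as JSON with ``pairs`` and ``midline`` lists.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .landmarks import LandmarkConfiguration, SymmetryMap


def read_landmark_file(path) -> list:
    """Parse LM=/ID= records into configurations (multiple specimens per file)."""
    configs = []
    points: list = []
    expected = 0
    label = ""
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.upper().startswith("LM="):
            if points:
                raise ValueError(f"{path}: new LM record before previous one was closed by ID=")
            expected = int(line.split("=", 1)[1])
            points = []
        elif line.upper().startswith("ID="):
            label = line.split("=", 1)[1].strip()
            if len(points) != expected:
                raise ValueError(
                    f"{path}: specimen {label!r} has {len(points)} points, expected {expected}"
                )
            configs.append(LandmarkConfiguration(points=np.asarray(points), label=label))
            points = []
            expected = 0
        elif line.upper().startswith(("SCALE=", "IMAGE=")):
            continue  # common auxiliary records; ignored
        else:
            xy = line.split()
            if len(xy) != 2:
                raise ValueError(f"{path}: cannot parse coordinate line {line!r}")
            points.append([float(xy[0]), float(xy[1])])
    if points:
        raise ValueError(f"{path}: trailing LM record without closing ID=")
    return configs


def write_landmark_file(path, configs: list) -> None:
    lines = []
    for cfg in configs:
        lines.append(f"LM={cfg.n_landmarks}")
        lines.extend(f"{x:.10g} {y:.10g}" for x, y in cfg.points)
        lines.append(f"ID={cfg.label}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_landmark_csv(path) -> list:
    """Long-format CSV (face_id, landmark_id, x, y) -> list of configurations."""
    df = pd.read_csv(path)
    required = {"face_id", "landmark_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    configs = []
    for face_id, grp in df.groupby("face_id", sort=False):
        grp = grp.sort_values("landmark_id")
        configs.append(
            LandmarkConfiguration(points=grp[["x", "y"]].to_numpy(), label=str(face_id))
        )
    return configs


def write_landmark_csv(path, configs: list) -> None:
    rows = [
        {"face_id": cfg.label, "landmark_id": i, "x": x, "y": y}
        for cfg in configs
        for i, (x, y) in enumerate(cfg.points)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_symmetry_map(path) -> SymmetryMap:
    with open(path) as fh:
        payload = json.load(fh)
    return SymmetryMap(
        pairs=tuple(tuple(p) for p in payload.get("pairs", [])),
        midline=tuple(payload.get("midline", [])),
    )


def write_symmetry_map(path, sym: SymmetryMap) -> None:
    with open(path, "w") as fh:
        json.dump({"pairs": [list(p) for p in sym.pairs], "midline": list(sym.midline)}, fh)
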