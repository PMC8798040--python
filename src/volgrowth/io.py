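"""Tabular storage for trajectory datasets.

A dataset directory holds two plain CSV files:

``trajectories.csv``
    One row per cell per frame: ``cell_id,frame,time_h,volume_um3,valid``.
    Frames are 0-based and contiguous per cell; times are hours on a
    uniform grid.
``annotations.csv``
    One row per cell: ``cell_id,parent_id,t_birth,t_g1s,t_mitosis,
    overshoot_start,overshoot_end,birth_volume`` with missing values as
    empty fields.

An optional ``dataset.json`` sidecar stores the frame interval and free-text
provenance (source, seed, filters applied).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ANNOTATION_COLUMNS, TRAJECTORY_COLUMNS


class DatasetError(ValueError):
    """Schema or consistency violation in a trajectory dataset."""


@dataclass
class Dataset:
    """Trajectory table + per-cell annotations + acquisition metadata."""

    trajectories: pd.DataFrame
    annotations: pd.DataFrame
    frame_interval: float
    provenance: dict = field(default_factory=dict)

    def copy(self) -> "Dataset":
        return Dataset(
            self.trajectories.copy(),
            self.annotations.copy(),
            self.frame_interval,
            dict(self.provenance),
        )

    @property
    def n_cells(self) -> int:
        return self.trajectories["cell_id"].nunique()


def validate_dataset(dataset: Dataset, spacing_rtol: float = 0.01) -> list[str]:
    """Return a list of violation messages (empty when the dataset is valid).

    Checks: required columns, duplicate (cell_id, frame) rows, contiguous
    frame indices per cell, time stamps on a uniform grid consistent with
    ``frame_interval`` (max deviation < ``spacing_rtol`` of the interval),
    annotation event ordering, and that every annotated cell appears in the
    trajectory table.
    """
    problems: list[str] = []
    traj, ann = dataset.trajectories, dataset.annotations
    missing = [c for c in TRAJECTORY_COLUMNS if c not in traj.columns]
    if missing:
        return [f"trajectories: missing columns {missing}"]
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        return [f"annotations: missing columns {missing}"]

    dup = traj.duplicated(subset=["cell_id", "frame"])
    for idx in traj.index[dup]:
        row = traj.loc[idx]
        problems.append(
            f"trajectories row {idx}: duplicate (cell_id, frame) = "
            f"({row['cell_id']}, {row['frame']})"
        )
    if problems:
        return problems

    dt = dataset.frame_interval
    for cell_id, grp in traj.groupby("cell_id", sort=False):
        frames = grp["frame"].to_numpy()
        if len(frames) > 1 and not np.array_equal(
            frames, np.arange(frames[0], frames[0] + len(frames))
        ):
            problems.append(f"cell {cell_id}: frame indices not contiguous")
        dev = np.abs(grp["time_h"].to_numpy() - frames * dt)
        if dev.max(initial=0.0) > spacing_rtol * dt:
            problems.append(
                f"cell {cell_id}: time stamps deviate from the uniform "
                f"frame grid by up to {dev.max():.4g} h"
            )

    known = set(traj["cell_id"])
    for cell_id in ann["cell_id"]:
        if cell_id not in known:
            problems.append(f"annotated cell {cell_id} absent from trajectories")
    for _, row in ann.iterrows():
        tb, tg, tm = row["t_birth"], row["t_g1s"], row["t_mitosis"]
        if pd.notna(tg) and pd.notna(tb) and tg < tb:
            problems.append(f"cell {row['cell_id']}: t_g1s < t_birth")
        if pd.notna(tm) and pd.notna(tg) and tm < tg:
            problems.append(f"cell {row['cell_id']}: t_mitosis < t_g1s")
    return problems


def make_dataset(
    trajectories: pd.DataFrame,
    annotations: pd.DataFrame,
    frame_interval: float,
    provenance: dict | None = None,
) -> Dataset:
    """Assemble and validate a :class:`Dataset`; nonpositive volumes are
    flagged ``valid=False`` rather than dropped."""
    traj = trajectories.copy()
    missing = [c for c in TRAJECTORY_COLUMNS
               if c != "valid" and c not in traj.columns]
    if missing:
        raise DatasetError(f"trajectories: missing columns {missing}")
    if "valid" not in traj.columns:
        traj["valid"] = True
    traj.loc[~(traj["volume_um3"] > 0), "valid"] = False
    ds = Dataset(traj, annotations.copy(), frame_interval, provenance or {})
    problems = validate_dataset(ds)
    if problems:
        raise DatasetError("; ".join(problems))
    return ds


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset directory (CSV at full float precision)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    dataset.trajectories[TRAJECTORY_COLUMNS].to_csv(
        path / "trajectories.csv", index=False, float_format="%.12g"
    )
    dataset.annotations[ANNOTATION_COLUMNS].to_csv(
        path / "annotations.csv", index=False, float_format="%.12g"
    )
    meta = {
        "frame_interval": dataset.frame_interval,
        "provenance": dataset.provenance,
    }
    (path / "dataset.json").write_text(json.dumps(meta, indent=2))


def read_dataset(path: str | Path) -> Dataset:
    """Read and validate a dataset directory written by :func:`write_dataset`."""
    path = Path(path)
    traj_path = path / "trajectories.csv"
    ann_path = path / "annotations.csv"
    if not traj_path.exists() or not ann_path.exists():
        raise DatasetError(
            f"{path} must contain trajectories.csv and annotations.csv"
        )
    traj = pd.read_csv(traj_path, dtype={"cell_id": str})
    ann = pd.read_csv(ann_path, dtype={"cell_id": str, "parent_id": str})
    meta_path = path / "dataset.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        frame_interval = float(meta["frame_interval"])
        provenance = meta.get("provenance", {})
    else:
        diffs = traj.sort_values(["cell_id", "frame"]).groupby("cell_id")[
            "time_h"
        ].diff()
        frame_interval = float(diffs.median())
        provenance = {"source": str(path)}
    if "valid" in traj.columns:
        traj["valid"] = traj["valid"].astype(bool)
    return make_dataset(traj, ann, frame_interval, provenance)
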