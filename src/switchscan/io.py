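"""CSV/YAML round-tripping for angle tables, features, labels, properties, reports."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dos import FEATURE_NAMES, AngleDoS
from .geometry import AngleSeries, AtomTriplet

__all__ = [
    "PipelineConfig",
    "write_angle_table",
    "read_angle_table",
    "write_dos_csv",
    "write_features_csv",
    "read_features_csv",
    "read_labels_csv",
    "read_property_csv",
]

ANGLE_TABLE_COLUMNS = (
    "residue_index",
    "residue_name",
    "atom_a",
    "vertex",
    "atom_b",
    "trajectory_id",
    "frame",
    "angle_rad",
)

_FLOAT_FMT = "%.12g"  # round-trips float64 angle values to < 1e-9


def write_angle_table(
    series_list: list[tuple[str, AngleSeries]], path: str | Path
) -> None:
    """Write (residue_name, AngleSeries) pairs as a long-format CSV.

    Trajectory boundaries are encoded by the trajectory_id column; frames
    are 0-based within the pooled series.
    """
    frames = []
    for residue_name, s in series_list:
        t = s.triplet
        traj_id = np.empty(s.n_frames, dtype=int)
        for k, (lo, hi) in enumerate(sorted(s.segments)):
            traj_id[lo:hi] = k
        frames.append(
            pd.DataFrame(
                {
                    "residue_index": t.residue_index,
                    "residue_name": residue_name,
                    "atom_a": t.atom_a,
                    "vertex": t.vertex,
                    "atom_b": t.atom_b,
                    "trajectory_id": traj_id,
                    "frame": np.arange(s.n_frames),
                    "angle_rad": s.values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_angle_table(path: str | Path) -> list[tuple[str, AngleSeries]]:
    """Read an angle table CSV back into (residue_name, AngleSeries) pairs.

    Validation errors report the offending CSV line (1-based, header = 1).
    """
    df = pd.read_csv(path)
    missing = [c for c in ANGLE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"angle table {path} is missing columns: {missing}")
    bad = df.index[(df["angle_rad"] < 0) | (df["angle_rad"] > np.pi + 1e-9)]
    if len(bad):
        raise ValueError(
            f"angle table {path} line {int(bad[0]) + 2}: angle_rad outside [0, pi]"
        )
    out: list[tuple[str, AngleSeries]] = []
    keys = ["residue_index", "residue_name", "atom_a", "vertex", "atom_b"]
    for (res_idx, res_name, a, v, b), grp in df.groupby(keys, sort=False):
        grp = grp.sort_values("frame")
        if not (grp["frame"].to_numpy() == np.arange(len(grp))).all():
            raise ValueError(
                f"angle table {path}: frames of {res_name}{res_idx} {a}-{v}-{b} "
                "are not contiguous from 0"
            )
        segments = []
        tid = grp["trajectory_id"].to_numpy()
        start = 0
        for i in range(1, len(tid) + 1):
            if i == len(tid) or tid[i] != tid[start]:
                segments.append((start, i))
                start = i
        series = AngleSeries(
            AtomTriplet(int(res_idx), str(a), str(v), str(b)),
            grp["angle_rad"].to_numpy(float),
            segments,
        )
        out.append((str(res_name), series))
    return out


def write_dos_csv(dos: AngleDoS, path: str | Path) -> None:
    pd.DataFrame(
        {
            "bin_left": dos.bin_edges[:-1],
            "bin_right": dos.bin_edges[1:],
            "mass": dos.mass,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_features_csv(rows: list[dict], path: str | Path) -> None:
    """Write one feature row per (residue, triplet): identifiers + 14 features."""
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_features_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"feature table {path} is missing columns: {missing}")
    return df


def read_labels_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ("identifier", "label")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"label table {path} is missing columns: {missing}")
    if not df["label"].isin((0, 1)).all():
        raise ValueError(f"label table {path}: labels must be 0 or 1")
    return df


def read_property_csv(path: str | Path) -> np.ndarray:
    """Per-frame global property series: columns frame, trajectory_id, value."""
    df = pd.read_csv(path)
    missing = [c for c in ("frame", "value") if c not in df.columns]
    if missing:
        raise ValueError(f"property table {path} is missing columns: {missing}")
    df = df.sort_values("frame")
    return df["value"].to_numpy(float)


@dataclass
class PipelineConfig:
    """Fully serializable description of one pipeline run."""

    topology: str | None = None
    trajectories: list[str] = field(default_factory=list)
    selection_table: str | None = None       # path; None = built-in
    n_bins: int = 90
    smooth_window: int = 5
    min_prominence: float = 0.05
    min_separation_bins: int = 5
    classifier_kind: str = "random_forest"   # or decision_tree / gradient_boosted / heuristic
    classifier_model: str | None = None      # path to a saved model; None = train on synthetic corpus
    corpus_per_class: int = 200
    corpus_n_frames: int = 2000
    n_folds: int = 5
    seed: int = 0
    property_series: str | None = None       # optional per-frame property CSV
    output_dir: str = "switchscan_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
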