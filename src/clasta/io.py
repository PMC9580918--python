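"""Readers, writers and configuration handling.

Interchange formats are deliberately plain: localization maps and
trajectory groups travel as headed CSV, results as JSON, configurations
as YAML or JSON mirroring the dataclass field names.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fret import AcquisitionConfig, GroupConfig, TwoStateModel
from .permutation import TrajectoryGroup
from .smlm import BlinkModel, LocalizationMap, SmlmConfig

__all__ = [
    "read_localization_csv",
    "write_localization_csv",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "load_config",
    "smlm_config_from_dict",
    "group_config_from_dict",
    "config_digest",
    "RunRecord",
    "write_json",
]

LOCALIZATION_COLUMNS = ("x_nm", "y_nm", "channel")
TRAJECTORY_COLUMNS = ("trajectory_id", "frame", "efficiency")


def read_localization_csv(path: str | Path,
                          roi: tuple[float, float] | None = None) -> LocalizationMap:
    """Read a localization map from ``x_nm,y_nm,channel`` CSV.

    An optional ``frame`` column is ignored.  When no ROI is supplied, a
    bounding box strictly containing every point is inferred.
    """
    df = pd.read_csv(path)
    for col in LOCALIZATION_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    for col in ("x_nm", "y_nm"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # 1-based, after the header line
            raise ValueError(f"non-numeric {col} value on line {line} of {path}")
        df[col] = values
    if df[["x_nm", "y_nm"]].isna().any().any():
        raise ValueError(f"missing coordinate value in {path}")
    return LocalizationMap.from_dataframe(df, roi=roi)


def write_localization_csv(loc_map: LocalizationMap, path: str | Path) -> None:
    loc_map.to_dataframe().to_csv(path, index=False)


def read_trajectory_csv(path: str | Path) -> TrajectoryGroup:
    """Read a trajectory group from ``trajectory_id,frame,efficiency`` CSV.

    Rows are grouped by trajectory id and sorted by frame; a duplicated
    (trajectory_id, frame) pair is an error.
    """
    df = pd.read_csv(path)
    for col in TRAJECTORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    if len(df) == 0:
        raise ValueError(f"empty trajectory file: {path}")
    if df.duplicated(subset=["trajectory_id", "frame"]).any():
        dup = df[df.duplicated(subset=["trajectory_id", "frame"])].iloc[0]
        raise ValueError(
            f"duplicate (trajectory_id, frame) = "
            f"({dup['trajectory_id']}, {dup['frame']}) in {path}")
    trajectories = [
        np.asarray(sub.sort_values("frame")["efficiency"], float)
        for _, sub in df.groupby("trajectory_id", sort=True)
    ]
    return TrajectoryGroup(trajectories=trajectories,
                           group_label=str(Path(path).stem))


def write_trajectory_csv(group: TrajectoryGroup, path: str | Path) -> None:
    rows = []
    for tid, traj in enumerate(group.trajectories):
        for frame, eff in enumerate(traj):
            rows.append((tid, frame, eff))
    pd.DataFrame(rows, columns=list(TRAJECTORY_COLUMNS)).to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a JSON superset
    if not isinstance(data, dict):
        raise ValueError(f"configuration in {path} must be a mapping")
    return data


def smlm_config_from_dict(data: dict) -> SmlmConfig:
    data = dict(data)
    blink = data.pop("blink_model", None)
    if isinstance(blink, dict):
        if "empirical_counts" in blink and blink["empirical_counts"] is not None:
            blink = dict(blink)
            blink["empirical_counts"] = {
                int(k): float(v) for k, v in blink["empirical_counts"].items()}
        data["blink_model"] = BlinkModel(**blink)
    return SmlmConfig(**data)


def group_config_from_dict(data: dict) -> GroupConfig:
    data = dict(data)
    if isinstance(data.get("model"), dict):
        data["model"] = TwoStateModel(**data["model"])
    if isinstance(data.get("acq"), dict):
        data["acq"] = AcquisitionConfig(**data["acq"])
    return GroupConfig(**data)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def config_digest(config) -> str:
    """SHA-256 of the canonical JSON form; stable under key reordering."""
    payload = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


@dataclass(frozen=True)
class RunRecord:
    """Provenance of one CLI invocation."""

    command: str
    config_digest: str
    seed: int | None
    outputs: tuple[str, ...] = ()


def write_json(data: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(data), indent=2, sort_keys=True) + "\n")
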