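"""Delimited-text readers and writers for trial logs, profiles and fits.

Everything is plain CSV with a header row and a decimal point, so outputs
diff cleanly and can be inspected with any spreadsheet or text tool.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ErrorProfile, TargetSpec, Trajectory

__all__ = [
    "write_trial_log",
    "read_trial_log",
    "read_trial_logs",
    "write_error_profile",
    "read_error_profile",
    "write_templates",
    "write_trajectory",
    "read_trajectory",
    "write_manifest",
]

TRIAL_LOG_COLUMNS = [
    "subject_id", "group", "index", "phase", "phase_index", "target_deg",
    "rotation_on", "augment_mode", "is_catch", "trajectory_error_m",
    "peak_speed_mps",
]


def write_trial_log(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, columns=TRIAL_LOG_COLUMNS)


def read_trial_log(path) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # surface the offending file
        raise ValueError(f"cannot parse trial log {path}: {exc}") from exc
    missing = set(TRIAL_LOG_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"trial log {path} lacks columns {sorted(missing)}")
    return frame


def read_trial_logs(directory) -> pd.DataFrame:
    """Concatenate every ``*_trials.csv`` log in a directory."""
    paths = sorted(Path(directory).glob("*_trials.csv"))
    if not paths:
        raise FileNotFoundError(f"no trial logs (*_trials.csv) in {directory}")
    return pd.concat([read_trial_log(p) for p in paths], ignore_index=True)


def write_error_profile(profile: ErrorProfile, path) -> None:
    pd.DataFrame({"r_m": profile.r_grid, "eps_m": profile.eps}).to_csv(path, index=False)


def read_error_profile(path, target: TargetSpec) -> ErrorProfile:
    frame = pd.read_csv(path)
    return ErrorProfile(frame["r_m"].to_numpy(), frame["eps_m"].to_numpy(), target)


def write_templates(templates, out_dir, subject_id: str) -> list[Path]:
    """One profile file per training target, named by target angle."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for angle in templates:
        p = out_dir / f"{subject_id}_template_{angle:+.0f}deg.csv"
        write_error_profile(templates[angle], p)
        paths.append(p)
    return paths


def write_trajectory(traj: Trajectory, path, trial_id: int = 0) -> None:
    pd.DataFrame(
        {"trial_id": trial_id, "t": traj.t, "x": traj.x, "y": traj.y}
    ).to_csv(path, index=False)


def read_trajectory(path, start, target: TargetSpec) -> Trajectory:
    frame = pd.read_csv(path)
    return Trajectory(
        t=frame["t"].to_numpy(), x=frame["x"].to_numpy(), y=frame["y"].to_numpy(),
        start=np.asarray(start, dtype=float), target=target,
    )


def write_manifest(path, config_hash: str, seed: int, extra: dict | None = None) -> None:
    payload = {"config_hash": config_hash, "seed": seed}
    payload.update(extra or {})
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
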