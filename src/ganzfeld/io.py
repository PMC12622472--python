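"""Session directory I/O.

A session directory holds delimited-text streams sharing one clock::

    <participant>/
        gaze.tsv            timestamp_s, per-eye angles (or 3-D directions),
                            pupil areas, validity flags
        gyro.tsv            timestamp_s, gyro_{x,y,z}_dps
        dial.tsv            timestamp_s, dial_value
        eeg_data.txt        plain numeric matrix, one row per channel (uV)
        eeg_channels.json   {"fs_hz": 250, "channel_names": [...], "t0_s": 0}
        meta.json           participant id and free-form metadata (optional)
        ground_truth.yaml   generator manifest (synthetic sessions only)

Missing gaze samples are empty fields/NaN.  On load all streams are sorted
by timestamp, duplicate timestamps dropped (first kept), and re-expressed
relative to the earliest sample across streams (t = 0).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .config import AnalysisConfig
from .datatypes import (
    DialTrace,
    EEGRecording,
    Event,
    EventSchedule,
    GazeRecording,
    GroundTruth,
    GyroRecording,
    IAFProfile,
    Session,
)

__all__ = [
    "load_session",
    "save_session",
    "save_tables",
    "load_table",
    "save_ground_truth",
    "load_ground_truth",
]

log = logging.getLogger(__name__)

_STREAM_FILES = {
    "gaze": "gaze.tsv",
    "gyro": "gyro.tsv",
    "dial": "dial.tsv",
    "eeg": "eeg_data.txt",
    "eeg sidecar": "eeg_channels.json",
}


def _read_stream_table(path: Path, stream: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    before = len(df)
    df = df.sort_values("timestamp_s", kind="stable")
    df = df.drop_duplicates(subset="timestamp_s", keep="first").reset_index(drop=True)
    if len(df) != before:
        log.info("%s: dropped %d duplicate-timestamp rows", stream, before - len(df))
    if df.empty:
        raise ValueError(f"{stream} stream is empty")
    return df


def _check_rate(df: pd.DataFrame, declared_fs: Optional[float], stream: str) -> None:
    if declared_fs is None or len(df) < 3:
        return
    med = float(np.median(np.diff(df["timestamp_s"].to_numpy())))
    if med <= 0:
        return
    if abs(1.0 / med - declared_fs) / declared_fs > 0.10:
        log.warning(
            "%s: declared rate %.6g Hz but median interval implies %.6g Hz",
            stream, declared_fs, 1.0 / med,
        )


def load_session(dir_path, config: Optional[AnalysisConfig] = None) -> Session:
    """Load one session directory into a :class:`Session`.

    Raises ``FileNotFoundError`` naming the missing stream; logs a warning
    when a declared sampling rate disagrees with the median inter-sample
    interval by more than 10 %.
    """
    d = Path(dir_path)
    for stream, fname in _STREAM_FILES.items():
        if not (d / fname).exists():
            raise FileNotFoundError(f"{stream} stream missing: {d / fname}")

    gaze_df = _read_stream_table(d / "gaze.tsv", "gaze")
    gyro_df = _read_stream_table(d / "gyro.tsv", "gyro")
    dial_df = _read_stream_table(d / "dial.tsv", "dial")

    sidecar = json.loads((d / "eeg_channels.json").read_text())
    eeg_data = np.loadtxt(d / "eeg_data.txt", ndmin=2)
    if eeg_data.size == 0:
        raise ValueError("eeg stream is empty")
    eeg = EEGRecording(
        channel_names=list(sidecar["channel_names"]),
        fs_hz=float(sidecar["fs_hz"]),
        data=eeg_data,
        t0_s=float(sidecar.get("t0_s", 0.0)),
    )

    # unify the clock: t = 0 at the first sample of the earliest stream
    t_min = min(
        float(gaze_df.timestamp_s.iloc[0]),
        float(gyro_df.timestamp_s.iloc[0]),
        float(dial_df.timestamp_s.iloc[0]),
        eeg.t0_s,
    )
    for df in (gaze_df, gyro_df, dial_df):
        df["timestamp_s"] = df["timestamp_s"] - t_min
    eeg.t0_s -= t_min

    if "left_angle_x_deg" in gaze_df.columns:
        gaze = GazeRecording.from_frame(gaze_df)
    elif "left_dir_x" in gaze_df.columns:
        from .gaze import to_direction_angles

        dirs = {
            eye: gaze_df[[f"{eye}_dir_x", f"{eye}_dir_y", f"{eye}_dir_z"]].to_numpy(float)
            for eye in ("left", "right")
        }
        gaze = to_direction_angles(
            gaze_df["timestamp_s"].to_numpy(float),
            dirs,
            {eye: gaze_df[f"{eye}_pupil_area"].to_numpy(float) for eye in ("left", "right")},
            {eye: gaze_df[f"validity_{eye}"].to_numpy(float) > 0.5 for eye in ("left", "right")},
        )
    else:
        raise ValueError("gaze table has neither angle nor direction columns")

    _check_rate(gaze_df, None, "gaze")
    med_eeg = 1.0 / eeg.fs_hz
    declared = sidecar.get("fs_hz")
    if declared and abs(float(declared) * med_eeg - 1.0) > 0.10:
        log.warning("eeg: sidecar rate inconsistent")

    meta = {}
    participant_id = d.name
    meta_path = d / "meta.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        participant_id = meta.pop("participant_id", participant_id)

    return Session(
        participant_id=participant_id,
        gaze=gaze,
        gyro=GyroRecording.from_frame(gyro_df),
        dial=DialTrace.from_frame(dial_df),
        eeg=eeg,
        meta=meta,
    )


def save_session(session: Session, parent_dir, truth: Optional[GroundTruth] = None) -> Path:
    """Write a session directory (plus ground-truth manifest if given)."""
    d = Path(parent_dir) / session.participant_id
    d.mkdir(parents=True, exist_ok=True)
    session.gaze.to_frame().to_csv(d / "gaze.tsv", sep="\t", index=False)
    session.gyro.to_frame().to_csv(d / "gyro.tsv", sep="\t", index=False)
    session.dial.to_frame().to_csv(d / "dial.tsv", sep="\t", index=False)
    np.savetxt(d / "eeg_data.txt", session.eeg.data, fmt="%.6e")
    (d / "eeg_channels.json").write_text(
        json.dumps(
            {
                "fs_hz": session.eeg.fs_hz,
                "channel_names": session.eeg.channel_names,
                "t0_s": session.eeg.t0_s,
            }
        )
    )
    (d / "meta.json").write_text(
        json.dumps({"participant_id": session.participant_id, **session.meta})
    )
    if truth is not None:
        save_ground_truth(truth, d / "ground_truth.yaml")
    return d


def save_tables(table: pd.DataFrame, path) -> Path:
    """Write a result table as delimited text at full float precision.

    Reading the file back yields a table equal to the original within
    1e-12 (floats are written with round-trip precision).
    """
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty result table")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)
    return path


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ----------------------------------------------------------------------
# ground-truth manifest
# ----------------------------------------------------------------------

def save_ground_truth(truth: GroundTruth, path) -> Path:
    d = {
        "session_length_s": truth.schedule.session_length_s,
        "events": [
            {
                "label": e.label,
                "onset_s": e.onset_s,
                "offset_s": e.offset_s,
                "intensity": e.intensity,
            }
            for e in truth.schedule.events
        ],
        "blink_intervals": [list(iv) for iv in truth.blink_intervals],
        "headmove_intervals": [list(iv) for iv in truth.headmove_intervals],
        "gaze_sd_by_epoch": dict(truth.gaze_sd_by_epoch),
        "alpha_amp_by_epoch": dict(truth.alpha_amp_by_epoch),
        "theta_amp_by_epoch": dict(truth.theta_amp_by_epoch),
        "iaf_profile": dataclasses.asdict(truth.iaf_profile),
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(d, sort_keys=True))
    return path


def load_ground_truth(path) -> GroundTruth:
    d = yaml.safe_load(Path(path).read_text())
    schedule = EventSchedule(
        events=[Event(**e) for e in d["events"]],
        session_length_s=d["session_length_s"],
    )
    return GroundTruth(
        schedule=schedule,
        blink_intervals=[tuple(iv) for iv in d["blink_intervals"]],
        headmove_intervals=[tuple(iv) for iv in d["headmove_intervals"]],
        gaze_sd_by_epoch=d["gaze_sd_by_epoch"],
        alpha_amp_by_epoch=d["alpha_amp_by_epoch"],
        theta_amp_by_epoch=d["theta_amp_by_epoch"],
        iaf_profile=IAFProfile(**d["iaf_profile"]),
    )
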