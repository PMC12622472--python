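"""In-memory containers for the co-registered session streams.

All timestamps are in seconds on one session-relative clock (t = 0 at the
first sample of the earliest stream).  Angles are degrees, angular velocity
degrees/second, EEG microvolts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "GazeRecording",
    "GyroRecording",
    "DialTrace",
    "EEGRecording",
    "SampleMask",
    "Event",
    "EventSchedule",
    "IAFProfile",
    "GroundTruth",
    "Session",
]

EYES = ("left", "right")
AXES = ("x", "y")
EPOCH_TYPES = ("baseline", "hallucination", "decay", "pre_decay")


@dataclass
class GazeRecording:
    """Timestamped per-eye gaze direction angles, pupil area and validity.

    ``angles`` maps ``(eye, axis)`` -> array of gaze direction in degrees
    relative to the forward (z) axis; missing samples are NaN with the
    matching ``valid`` flag false.
    """

    timestamp_s: np.ndarray
    angles: Dict[Tuple[str, str], np.ndarray]
    pupil_area: Dict[str, np.ndarray]
    valid: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        n = len(self.timestamp_s)
        for arr in list(self.angles.values()) + list(self.pupil_area.values()):
            if len(arr) != n:
                raise ValueError("gaze stream arrays must share one length")
        if n >= 2 and not np.all(np.diff(self.timestamp_s) > 0):
            raise ValueError("gaze timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamp_s)

    @property
    def fs(self) -> float:
        """Nominal sampling rate from the median inter-sample interval."""
        return 1.0 / float(np.median(np.diff(self.timestamp_s)))

    def missing(self, eye: str, axis: str) -> np.ndarray:
        """Boolean: sample missing on this coordinate (NaN or invalid)."""
        return ~self.valid[eye] | ~np.isfinite(self.angles[(eye, axis)])

    def copy(self) -> "GazeRecording":
        return GazeRecording(
            self.timestamp_s.copy(),
            {k: v.copy() for k, v in self.angles.items()},
            {k: v.copy() for k, v in self.pupil_area.items()},
            {k: v.copy() for k, v in self.valid.items()},
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {"timestamp_s": self.timestamp_s}
        for eye in EYES:
            for axis in AXES:
                cols[f"{eye}_angle_{axis}_deg"] = self.angles[(eye, axis)]
            cols[f"{eye}_pupil_area"] = self.pupil_area[eye]
            cols[f"validity_{eye}"] = self.valid[eye].astype(int)
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GazeRecording":
        angles = {
            (eye, axis): df[f"{eye}_angle_{axis}_deg"].to_numpy(float)
            for eye in EYES
            for axis in AXES
        }
        pupil = {eye: df[f"{eye}_pupil_area"].to_numpy(float) for eye in EYES}
        valid = {eye: df[f"validity_{eye}"].to_numpy(float) > 0.5 for eye in EYES}
        return cls(df["timestamp_s"].to_numpy(float), angles, pupil, valid)


@dataclass
class GyroRecording:
    """Timestamped 3-axis angular velocity (x = pitch, y = yaw, z = roll)."""

    timestamp_s: np.ndarray
    omega: Dict[str, np.ndarray]  # axis -> deg/s

    def __post_init__(self) -> None:
        if len(self.timestamp_s) >= 2 and not np.all(np.diff(self.timestamp_s) > 0):
            raise ValueError("gyro timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamp_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp_s": self.timestamp_s,
                "gyro_x_dps": self.omega["x"],
                "gyro_y_dps": self.omega["y"],
                "gyro_z_dps": self.omega["z"],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GyroRecording":
        return cls(
            df["timestamp_s"].to_numpy(float),
            {ax: df[f"gyro_{ax}_dps"].to_numpy(float) for ax in ("x", "y", "z")},
        )


@dataclass
class DialTrace:
    """Continuous self-report dial: positive = hallucination, negative = decay."""

    timestamp_s: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        if len(self.timestamp_s) >= 2 and not np.all(np.diff(self.timestamp_s) > 0):
            raise ValueError("dial timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamp_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp_s": self.timestamp_s, "dial_value": self.value})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DialTrace":
        return cls(df["timestamp_s"].to_numpy(float), df["dial_value"].to_numpy(float))


@dataclass
class EEGRecording:
    """Multichannel EEG voltage time series (channels x samples, microvolts)."""

    channel_names: List[str]
    fs_hz: float
    data: np.ndarray
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise ValueError("EEG data must be (n_channels, n_samples)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def time(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.fs_hz

    def segment(self, t_start: float, t_end: float) -> np.ndarray:
        """Samples with t_start <= t < t_end (half-open, session clock)."""
        i0 = int(np.ceil((t_start - self.t0_s) * self.fs_hz - 1e-9))
        i1 = int(np.ceil((t_end - self.t0_s) * self.fs_hz - 1e-9))
        if i0 < 0 or i1 > self.n_samples:
            raise ValueError("segment outside the recording")
        return self.data[:, i0:i1]

    def copy(self) -> "EEGRecording":
        return EEGRecording(list(self.channel_names), self.fs_hz, self.data.copy(), self.t0_s)


@dataclass
class SampleMask:
    """Per-gaze-sample artifact flags.  Flags are only ever set, never cleared."""

    blink: np.ndarray
    head_movement: np.ndarray
    invalid: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.blink) == len(self.head_movement) == len(self.invalid)):
            raise ValueError("mask arrays must share one length")

    def __len__(self) -> int:
        return len(self.blink)

    @property
    def masked(self) -> np.ndarray:
        return self.blink | self.head_movement | self.invalid

    @property
    def retained(self) -> np.ndarray:
        return ~self.masked

    @classmethod
    def empty(cls, n: int) -> "SampleMask":
        return cls(np.zeros(n, bool), np.zeros(n, bool), np.zeros(n, bool))


@dataclass
class Event:
    label: str            # "hallucination" or "decay"
    onset_s: float
    offset_s: float
    intensity: float      # dial units; > 0 hallucination, < 0 decay


@dataclass
class EventSchedule:
    """Non-overlapping, time-sorted perceptual events within one session."""

    events: List[Event]
    session_length_s: float

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.onset_s)
        prev_end = -np.inf
        for ev in self.events:
            if ev.label not in ("hallucination", "decay"):
                raise ValueError(f"unknown event label {ev.label!r}")
            if not 0.0 <= ev.onset_s < ev.offset_s <= self.session_length_s:
                raise ValueError("event outside session bounds")
            if ev.onset_s < prev_end:
                raise ValueError("events must not overlap")
            if ev.label == "hallucination" and ev.intensity <= 0:
                raise ValueError("hallucination intensity must be > 0")
            if ev.label == "decay" and ev.intensity >= 0:
                raise ValueError("decay intensity must be < 0")
            prev_end = ev.offset_s

    def of_label(self, label: str) -> List[Event]:
        return [e for e in self.events if e.label == label]


@dataclass
class IAFProfile:
    """Alpha-frequency ground truth: a baseline frequency plus a smooth
    Gaussian bump of height ``peak_delta_hz`` centred ``peak_time_s`` seconds
    relative to each hallucination onset (negative = before the report).
    ``peak_width_s`` is the Gaussian sigma; the default gives a bump of
    roughly 3 s full width at half maximum."""

    baseline_hz: float = 10.0
    peak_delta_hz: float = 1.5
    peak_time_s: float = -13.0
    peak_width_s: float = 1.3  # sigma; FWHM = 2.355 * sigma ~ 3 s


@dataclass
class GroundTruth:
    """Everything the synthetic-session generator injects, for recovery tests."""

    schedule: EventSchedule
    blink_intervals: List[Tuple[float, float]] = field(default_factory=list)
    headmove_intervals: List[Tuple[float, float]] = field(default_factory=list)
    gaze_sd_by_epoch: Dict[str, float] = field(
        default_factory=lambda: {
            "baseline": 1.0,
            "hallucination": 0.9,
            "decay": 0.5,
            "pre_decay": 0.5,
        }
    )
    alpha_amp_by_epoch: Dict[str, float] = field(
        default_factory=lambda: {"baseline": 2.0, "hallucination": 1.5, "decay": 2.6}
    )
    theta_amp_by_epoch: Dict[str, float] = field(
        default_factory=lambda: {"baseline": 1.5, "hallucination": 1.1, "decay": 1.9}
    )
    iaf_profile: IAFProfile = field(default_factory=IAFProfile)

    def __post_init__(self) -> None:
        for k, v in self.gaze_sd_by_epoch.items():
            if v <= 0:
                raise ValueError(f"gaze SD for {k} must be > 0")
        L = self.schedule.session_length_s
        for s, e in list(self.blink_intervals) + list(self.headmove_intervals):
            if not 0.0 <= s < e <= L:
                raise ValueError("artifact interval outside session")


@dataclass
class Session:
    """One participant's co-registered streams on a shared session clock."""

    participant_id: str
    gaze: GazeRecording
    gyro: GyroRecording
    dial: DialTrace
    eeg: EEGRecording
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, stream in (
            ("gaze", self.gaze),
            ("gyro", self.gyro),
            ("dial", self.dial),
        ):
            if len(stream) == 0:
                raise ValueError(f"{name} stream is empty")
        if self.eeg.n_samples == 0:
            raise ValueError("eeg stream is empty")
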