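"""Eye-tracking preprocessing and per-epoch gaze dispersion.

The pipeline quantifies the amount of eye movement directly from raw gaze
samples (no fixation/saccade classification):

1. per-eye, per-axis gaze angles are low-pass filtered (zero-phase
   Butterworth, 35 Hz default); pupil area at 4 Hz;
2. blinks are detected by a 100 ms moving window (50 ms steps) flagged when
   at least 70 % of a coordinate's samples are missing or the within-window
   pupil-area change is unrealistically high; blink intervals are padded by
   100 ms on both sides;
3. gaze is centred per eye/axis on the median over all blink-free valid
   samples of the entire recording;
4. head movements are detected from the gyroscope (resampled onto the gaze
   clock with a monotone Hermite spline, smoothed at 10 Hz, thresholded at
   4 deg/s) with an 8 deg eye-direction-range veto over 200 ms windows;
5. recordings with more than 60 % of samples masked are excluded;
6. gaze dispersion is the sample SD of retained centred samples per
   epoch x eye x axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import PchipInterpolator
from scipy.stats import median_abs_deviation

from .config import AnalysisConfig
from .datatypes import AXES, EYES, GazeRecording, GyroRecording, SampleMask

__all__ = [
    "to_direction_angles",
    "lowpass_filter",
    "detect_blinks",
    "interpolate_gyro",
    "detect_head_movements",
    "center_gaze",
    "compute_exclusion",
    "epoch_dispersion",
    "preprocess_gaze",
    "window_grid",
    "merge_intervals",
]

log = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# angles and filtering
# ----------------------------------------------------------------------

def to_direction_angles(
    timestamp_s: np.ndarray,
    directions: Dict[str, np.ndarray],
    pupil_area: Dict[str, np.ndarray],
    valid: Dict[str, np.ndarray],
) -> GazeRecording:
    """Convert per-eye 3-D gaze direction vectors to x/y angles in degrees.

    ``directions[eye]`` is an (n, 3) array of (x, y, z) direction components;
    the angle on each axis is atan(component / z) in degrees.  Samples that
    are invalid or have non-positive z become NaN with ``valid`` false.
    """
    angles: Dict[Tuple[str, str], np.ndarray] = {}
    out_valid: Dict[str, np.ndarray] = {}
    for eye in EYES:
        vec = np.asarray(directions[eye], dtype=float)
        ok = np.asarray(valid[eye], dtype=bool) & np.isfinite(vec).all(axis=1)
        ok &= vec[:, 2] > 0
        z = np.where(ok, vec[:, 2], np.nan)
        ax = np.degrees(np.arctan2(vec[:, 0], z))
        ay = np.degrees(np.arctan2(vec[:, 1], z))
        ax[~ok] = np.nan
        ay[~ok] = np.nan
        angles[(eye, "x")] = ax
        angles[(eye, "y")] = ay
        out_valid[eye] = ok
    return GazeRecording(np.asarray(timestamp_s, float), angles, dict(pupil_area), out_valid)


def _bridge_nans(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate across NaN runs (edges held at nearest value)."""
    x = np.asarray(x, float)
    bad = ~np.isfinite(x)
    if not bad.any():
        return x.copy(), bad
    if bad.all():
        return np.zeros_like(x), bad
    idx = np.arange(len(x))
    filled = x.copy()
    filled[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return filled, bad


def lowpass_filter(
    x: np.ndarray, fs: float, cutoff_hz: float, order: int = 2
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    NaN runs are bridged by linear interpolation before filtering and
    restored to NaN afterwards, so IIR state never crosses missing data
    unbridged while missingness is preserved.
    """
    if cutoff_hz >= fs / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist ({fs / 2} Hz)")
    filled, bad = _bridge_nans(x)
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, filled)
    y[bad] = np.nan
    return y


# ----------------------------------------------------------------------
# sliding-window grid
# ----------------------------------------------------------------------

def window_grid(
    timestamps: np.ndarray, width_s: float, step_s: float
) -> np.ndarray:
    """Window start times for a sliding window over a recording.

    Windows start at the first timestamp and advance by ``step_s``; window i
    covers samples with ``start_i <= t < start_i + width_s``.  A trailing
    window covering less than half the width of remaining data is dropped.
    """
    t0, t_last = float(timestamps[0]), float(timestamps[-1])
    if t_last - t0 < width_s - 1e-12 and t_last - t0 < width_s / 2:
        raise ValueError("recording shorter than one analysis window")
    n = int(np.floor((t_last - t0) / step_s + 1e-9)) + 1
    starts = t0 + step_s * np.arange(n)
    keep = (t_last - starts) >= width_s / 2 - 1e-12
    return starts[keep]


def merge_intervals(
    intervals: Sequence[Tuple[float, float]]
) -> List[Tuple[float, float]]:
    """Merge overlapping or touching half-open intervals."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1] + 1e-12:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


# ----------------------------------------------------------------------
# blink detection
# ----------------------------------------------------------------------

def detect_blinks(
    gaze: GazeRecording,
    pupil_series: Dict[str, np.ndarray],
    config: AnalysisConfig,
) -> Tuple[List[Tuple[float, float]], SampleMask]:
    """Detect blinks with a moving window over each eye-direction coordinate.

    A window is flagged if at least ``blink_missing_frac`` of any
    coordinate's samples are missing, or if the maximum absolute per-sample
    pupil-area change within the window exceeds ``pupil_change_mad_k`` times
    the median absolute deviation of all per-sample changes of that eye's
    recording.  Flagged windows are merged into intervals and padded by
    ``blink_pad_ms`` on both sides; the returned mask is true inside the
    padded intervals.
    """
    t = gaze.timestamp_s
    width = config.blink_window_ms / 1000.0
    step = config.blink_step_ms / 1000.0
    starts = window_grid(t, width, step)

    missing = {
        (eye, axis): gaze.missing(eye, axis) for eye in EYES for axis in AXES
    }
    # per-sample pupil change, attached to the later sample of each pair
    change: Dict[str, np.ndarray] = {}
    thresh: Dict[str, float] = {}
    for eye in EYES:
        d = np.diff(np.asarray(pupil_series[eye], float))
        d = np.concatenate([[0.0], d])
        d[~np.isfinite(d)] = 0.0
        change[eye] = np.abs(d)
        finite = d[1:][np.isfinite(d[1:])]
        mad = float(median_abs_deviation(finite)) if finite.size else 0.0
        thresh[eye] = config.pupil_change_mad_k * mad

    flagged = np.zeros(len(starts), dtype=bool)
    # windows may have ragged sample counts on irregular clocks: loop windows,
    # vectorised inside; 1 ns tolerance absorbs float jitter on the boundaries
    left = np.searchsorted(t, starts - 1e-9, side="left")
    right = np.searchsorted(t, starts + width - 1e-9, side="left")
    for i, (a, b) in enumerate(zip(left, right)):
        if b <= a:
            continue
        n = b - a
        for key, miss in missing.items():
            if miss[a:b].sum() / n >= config.blink_missing_frac - 1e-12:
                flagged[i] = True
                break
        if not flagged[i]:
            for eye in EYES:
                # the change at a window's first sample reaches back to the
                # previous sample; skip it so the criterion is within-window
                seg = change[eye][a + 1 : b]
                if seg.size and np.max(seg) > thresh[eye]:
                    flagged[i] = True
                    break

    raw = [(s, s + width) for s, f in zip(starts, flagged) if f]
    merged = merge_intervals(raw)
    pad = config.blink_pad_ms / 1000.0
    padded = merge_intervals([(s - pad, e + pad) for s, e in merged])

    blink = np.zeros(len(t), dtype=bool)
    for s, e in padded:
        blink[(t >= s - 1e-9) & (t < e - 1e-9)] = True
    invalid = np.zeros(len(t), dtype=bool)
    for eye in EYES:
        for axis in AXES:
            invalid |= missing[(eye, axis)]
    mask = SampleMask(blink=blink, head_movement=np.zeros(len(t), bool), invalid=invalid)
    return padded, mask


# ----------------------------------------------------------------------
# gyroscope alignment and head movements
# ----------------------------------------------------------------------

def interpolate_gyro(
    gyro: GyroRecording, target_timestamps: np.ndarray
) -> Dict[str, np.ndarray]:
    """Resample gyro onto target timestamps with a monotone Hermite spline.

    Shape-preserving cubic (PCHIP) interpolation per axis: it passes through
    the knots and never overshoots the local data range.  Targets outside
    the gyro time span are clamped to the edges.
    """
    if len(gyro) < 2:
        raise ValueError("need at least 2 gyro samples to interpolate")
    tt = np.clip(target_timestamps, gyro.timestamp_s[0], gyro.timestamp_s[-1])
    return {
        ax: PchipInterpolator(gyro.timestamp_s, gyro.omega[ax])(tt)
        for ax in ("x", "y", "z")
    }


def detect_head_movements(
    gyro_smoothed: Dict[str, np.ndarray],
    gaze: GazeRecording,
    config: AnalysisConfig,
) -> SampleMask:
    """Flag head movements from thresholded gyroscope + eye-range veto.

    A sample is gyro-flagged when the absolute angular velocity exceeds
    ``gyro_thresh_dps`` on at least one axis (``per_axis`` mode) or when the
    sum of absolute velocities does (``summed`` mode).  For every 200 ms
    window (100 ms step) containing a gyro-flagged sample, the range
    (max - min) of each of the four gaze coordinates is computed; if the
    maximum range exceeds ``eye_range_thresh_deg`` the whole window is
    flagged as head movement.
    """
    t = gaze.timestamp_s
    thr = config.gyro_thresh_dps
    if config.gyro_combine_mode == "per_axis":
        sample_flag = np.zeros(len(t), dtype=bool)
        for ax in ("x", "y", "z"):
            sample_flag |= np.abs(gyro_smoothed[ax]) > thr
    else:
        total = sum(np.abs(gyro_smoothed[ax]) for ax in ("x", "y", "z"))
        sample_flag = total > thr

    width = config.headmove_window_ms / 1000.0
    step = config.headmove_step_ms / 1000.0
    starts = window_grid(t, width, step)
    left = np.searchsorted(t, starts - 1e-9, side="left")
    right = np.searchsorted(t, starts + width - 1e-9, side="left")

    head = np.zeros(len(t), dtype=bool)
    coords = [gaze.angles[(eye, axis)] for eye in EYES for axis in AXES]
    for a, b in zip(left, right):
        if b <= a or not sample_flag[a:b].any():
            continue
        max_range = 0.0
        for c in coords:
            seg = c[a:b]
            seg = seg[np.isfinite(seg)]
            if seg.size:
                max_range = max(max_range, float(seg.max() - seg.min()))
        if max_range > config.eye_range_thresh_deg:
            head[a:b] = True
    return SampleMask(
        blink=np.zeros(len(t), bool), head_movement=head, invalid=np.zeros(len(t), bool)
    )


# ----------------------------------------------------------------------
# centring, exclusion, dispersion
# ----------------------------------------------------------------------

def center_gaze(
    gaze: GazeRecording, blink_mask: SampleMask
) -> Tuple[GazeRecording, Dict[Tuple[str, str], float]]:
    """Centre each eye/axis on its median over blink-free valid samples.

    The median is estimated over the entire recording (excluding blinks and
    invalid samples) and subtracted from every sample of that coordinate.
    """
    out = gaze.copy()
    medians: Dict[Tuple[str, str], float] = {}
    for eye in EYES:
        for axis in AXES:
            vals = gaze.angles[(eye, axis)]
            usable = ~blink_mask.blink & ~gaze.missing(eye, axis)
            if not usable.any():
                raise ValueError(f"no usable samples to centre {eye}/{axis}")
            med = float(np.median(vals[usable]))
            medians[(eye, axis)] = med
            out.angles[(eye, axis)] = vals - med
    log.info("gaze medians: %s", {f"{e}_{a}": round(m, 4) for (e, a), m in medians.items()})
    return out, medians


@dataclass
class ExclusionResult:
    fraction_masked: float
    excluded: bool


def compute_exclusion(mask: SampleMask, config: AnalysisConfig) -> ExclusionResult:
    """Participant exclusion rule: strictly more than ``exclusion_frac`` of
    samples masked (blink, head movement or invalid) excludes the recording."""
    if len(mask) == 0:
        raise ValueError("empty mask")
    frac = float(mask.masked.mean())
    return ExclusionResult(fraction_masked=frac, excluded=frac > config.exclusion_frac)


def epoch_dispersion(
    centered: GazeRecording,
    mask: SampleMask,
    epochs: pd.DataFrame,
    participant: str = "p0",
) -> pd.DataFrame:
    """Sample SD of retained centred gaze per epoch x eye x axis.

    Epochs are half-open [t_start_s, t_end_s) intervals.  Epochs with fewer
    than two retained samples on a coordinate yield no record for it.
    """
    t = centered.timestamp_s
    retained = mask.retained
    rows = []
    for _, ep in epochs.iterrows():
        sel = (t >= ep.t_start_s) & (t < ep.t_end_s) & retained
        for eye in EYES:
            for axis in AXES:
                vals = centered.angles[(eye, axis)][sel]
                vals = vals[np.isfinite(vals)]
                if len(vals) < 2:
                    log.info(
                        "epoch %s %s/%s: %d retained samples, no SD",
                        ep.epoch_id, eye, axis, len(vals),
                    )
                    continue
                rows.append(
                    {
                        "participant": participant,
                        "epoch_id": ep.epoch_id,
                        "epoch_type": ep.epoch_type,
                        "eye": eye,
                        "axis": axis,
                        "sd_deg": float(np.std(vals, ddof=1)),
                        "n_retained": int(len(vals)),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "participant", "epoch_id", "epoch_type", "eye", "axis", "sd_deg", "n_retained",
        ],
    )


# ----------------------------------------------------------------------
# full per-session pipeline
# ----------------------------------------------------------------------

@dataclass
class GazePreprocessResult:
    gaze: GazeRecording                      # filtered + centred
    mask: SampleMask
    blink_intervals: List[Tuple[float, float]]
    medians: Dict[Tuple[str, str], float]
    exclusion: ExclusionResult


def preprocess_gaze(
    gaze: GazeRecording, gyro: GyroRecording, config: AnalysisConfig
) -> GazePreprocessResult:
    """Run the fixed-order gaze pipeline:
    filter -> blink mask -> centre (blink-free median) -> head-movement mask.
    """
    fs = gaze.fs
    config.validate(fs_gaze=fs)

    filtered = gaze.copy()
    for eye in EYES:
        for axis in AXES:
            filtered.angles[(eye, axis)] = lowpass_filter(
                gaze.angles[(eye, axis)], fs, config.gaze_lowpass_hz, config.filter_order
            )
    pupil_filtered = {
        eye: lowpass_filter(gaze.pupil_area[eye], fs, config.pupil_lowpass_hz, config.filter_order)
        for eye in EYES
    }

    blink_intervals, mask = detect_blinks(filtered, pupil_filtered, config)
    centered, medians = center_gaze(filtered, mask)

    gyro_on_gaze = interpolate_gyro(gyro, gaze.timestamp_s)
    gyro_smoothed = {
        ax: lowpass_filter(v, fs, config.gyro_lowpass_hz, config.filter_order)
        for ax, v in gyro_on_gaze.items()
    }
    head = detect_head_movements(gyro_smoothed, centered, config)
    mask = SampleMask(blink=mask.blink, head_movement=head.head_movement, invalid=mask.invalid)

    exclusion = compute_exclusion(mask, config)
    log.info(
        "gaze preprocessing: %d samples, %.1f%% masked (%d blink, %d head, %d invalid)%s",
        len(mask),
        100 * exclusion.fraction_masked,
        int(mask.blink.sum()),
        int(mask.head_movement.sum()),
        int(mask.invalid.sum()),
        " -> EXCLUDED" if exclusion.excluded else "",
    )
    return GazePreprocessResult(
        gaze=centered,
        mask=mask,
        blink_intervals=blink_intervals,
        medians=medians,
        exclusion=exclusion,
    )
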