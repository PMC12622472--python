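"""Independent brute-force re-implementations of the windowed detectors.

These enumerate every sliding window with plain Python loops, straight from
the written contracts, and exist only to cross-check the vectorised
production detectors.
"""

import numpy as np
from scipy.stats import median_abs_deviation

from ganzfeld.datatypes import AXES, EYES


def window_starts(t, width, step):
    t0, tlast = float(t[0]), float(t[-1])
    starts = []
    i = 0
    while True:
        s = t0 + i * step
        if s > tlast + 1e-12:
            break
        if (tlast - s) >= width / 2 - 1e-12:
            starts.append(s)
        i += 1
    return starts


def in_window(ti, s, width):
    """Window membership with the same 1 ns boundary tolerance as the
    production detectors."""
    return s - 1e-9 <= ti < s + width - 1e-9


def brute_blink_mask(gaze, pupil_series, config):
    """Blink mask by exhaustive window enumeration."""
    t = gaze.timestamp_s
    width = config.blink_window_ms / 1000.0
    step = config.blink_step_ms / 1000.0
    pad = config.blink_pad_ms / 1000.0

    missing = {(e, a): gaze.missing(e, a) for e in EYES for a in AXES}
    change, thresh = {}, {}
    for eye in EYES:
        d = np.concatenate([[0.0], np.diff(np.asarray(pupil_series[eye], float))])
        d[~np.isfinite(d)] = 0.0
        change[eye] = np.abs(d)
        finite = d[1:][np.isfinite(d[1:])]
        mad = float(median_abs_deviation(finite)) if finite.size else 0.0
        thresh[eye] = config.pupil_change_mad_k * mad

    flagged_windows = []
    for s in window_starts(t, width, step):
        idx = [i for i in range(len(t)) if in_window(t[i], s, width)]
        if not idx:
            continue
        hit = False
        for key in missing:
            frac = sum(missing[key][i] for i in idx) / len(idx)
            if frac >= config.blink_missing_frac - 1e-12:
                hit = True
        if not hit:
            for eye in EYES:
                inner = [change[eye][i] for i in idx[1:]]
                if inner and max(inner) > thresh[eye]:
                    hit = True
        if hit:
            flagged_windows.append((s, s + width))

    # merge, pad, merge
    ivs = sorted(flagged_windows)
    merged = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1e-12:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    padded = sorted([s - pad, e + pad] for s, e in merged)
    merged2 = []
    for s, e in padded:
        if merged2 and s <= merged2[-1][1] + 1e-12:
            merged2[-1][1] = max(merged2[-1][1], e)
        else:
            merged2.append([s, e])

    mask = np.zeros(len(t), bool)
    for s, e in merged2:
        for i in range(len(t)):
            if s - 1e-9 <= t[i] < e - 1e-9:
                mask[i] = True
    return mask


def brute_head_mask(gyro_smoothed, gaze, config):
    """Head-movement mask by exhaustive window enumeration."""
    t = gaze.timestamp_s
    width = config.headmove_window_ms / 1000.0
    step = config.headmove_step_ms / 1000.0

    flags = []
    for i in range(len(t)):
        if config.gyro_combine_mode == "per_axis":
            flags.append(
                any(abs(gyro_smoothed[a][i]) > config.gyro_thresh_dps for a in "xyz")
            )
        else:
            flags.append(
                sum(abs(gyro_smoothed[a][i]) for a in "xyz") > config.gyro_thresh_dps
            )

    mask = np.zeros(len(t), bool)
    for s in window_starts(t, width, step):
        idx = [i for i in range(len(t)) if in_window(t[i], s, width)]
        if not idx or not any(flags[i] for i in idx):
            continue
        max_range = 0.0
        for eye in EYES:
            for axis in AXES:
                vals = [
                    gaze.angles[(eye, axis)][i]
                    for i in idx
                    if np.isfinite(gaze.angles[(eye, axis)][i])
                ]
                if vals:
                    max_range = max(max_range, max(vals) - min(vals))
        if max_range > config.eye_range_thresh_deg:
            for i in idx:
                mask[i] = True
    return mask
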