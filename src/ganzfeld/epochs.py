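"""Perceptual epoching from the continuous self-report dial.

The dial is a signed trace with a neutral reference at zero: sustained
positive excursions report hallucinations, negative excursions report decays
of colour/brightness.  Events are maximal intervals beyond a small
hysteresis band, debounced by a minimum duration; baselines are maximal
neutral intervals of at least the baseline minimum duration.

Two epoch variants are derived:

* eye-tracking epochs cover the events themselves plus a 2 s pre-decay
  window before each decay onset;
* EEG epochs are fixed-length windows anchored strictly before event onsets
  (hallucination [-20, -10] s, decay [-5, -1] s, IAF [-25, -5] s) or at
  baseline starts ([0, 6] s), so that dial-turning motor activity never
  contaminates the spectral estimates.  Windows leaving the recording or
  intersecting any reported event (or an already-emitted window of a
  different event) are dropped.
"""

from __future__ import annotations

import logging
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .datatypes import DialTrace, Event, EventSchedule

__all__ = ["dial_to_events", "make_eye_epochs", "make_eeg_epochs"]

log = logging.getLogger(__name__)

EPOCH_COLUMNS = ["epoch_id", "epoch_type", "t_start_s", "t_end_s", "source_event_id"]


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """(first, last) index pairs of maximal true runs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts, ends))


def dial_to_events(
    dial: DialTrace, config: AnalysisConfig
) -> Tuple[EventSchedule, List[Tuple[float, float]]]:
    """Segment the dial trace into labelled events and baseline intervals.

    Hallucination events are maximal intervals with value > +hysteresis,
    decay events with value < -hysteresis; events shorter than
    ``dial_min_event_s`` are discarded.  Baselines are maximal intervals with
    |value| <= hysteresis lasting at least ``baseline_min_s``.  Onsets and
    offsets sit at the first/last crossing sample (offset extended by one
    sample interval so intervals are half-open).
    """
    t = dial.timestamp_s
    v = dial.value
    h = config.dial_hysteresis
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    session_end = float(t[-1]) + dt

    events: List[Event] = []
    for sign, label in ((+1, "hallucination"), (-1, "decay")):
        for i0, i1 in _runs(sign * v > h):
            onset = float(t[i0])
            offset = min(float(t[i1]) + dt, session_end)
            if offset - onset < config.dial_min_event_s:
                continue
            peak = float(v[i0 : i1 + 1][np.argmax(np.abs(v[i0 : i1 + 1]))])
            events.append(Event(label=label, onset_s=onset, offset_s=offset, intensity=peak))

    baselines: List[Tuple[float, float]] = []
    for i0, i1 in _runs(np.abs(v) <= h):
        s = float(t[i0])
        e = min(float(t[i1]) + dt, session_end)
        if e - s >= config.baseline_min_s:
            baselines.append((s, e))

    schedule = EventSchedule(events=events, session_length_s=session_end)
    log.info(
        "dial segmentation: %d hallucinations, %d decays, %d baselines",
        len(schedule.of_label("hallucination")),
        len(schedule.of_label("decay")),
        len(baselines),
    )
    return schedule, baselines


def _overlaps(a0: float, a1: float, b0: float, b1: float) -> bool:
    """Half-open interval intersection."""
    return a0 < b1 and b0 < a1


def make_eye_epochs(
    schedule: EventSchedule,
    baselines: List[Tuple[float, float]],
    config: Optional[AnalysisConfig] = None,
) -> pd.DataFrame:
    """Eye-tracking epochs: full event intervals, baseline intervals, and a
    2 s pre-decay window before each decay onset.

    A pre-decay window is dropped when it starts before the session or
    overlaps any preceding reported event.
    """
    config = config or AnalysisConfig()
    rows = []
    for k, ev in enumerate(schedule.events):
        rows.append(
            {
                "epoch_id": f"{ev.label[:4]}_{k:03d}",
                "epoch_type": ev.label,
                "t_start_s": ev.onset_s,
                "t_end_s": ev.offset_s,
                "source_event_id": k,
            }
        )
    for j, (s, e) in enumerate(baselines):
        rows.append(
            {
                "epoch_id": f"base_{j:03d}",
                "epoch_type": "baseline",
                "t_start_s": s,
                "t_end_s": e,
                "source_event_id": -1,
            }
        )
    for k, ev in enumerate(schedule.events):
        if ev.label != "decay":
            continue
        s = ev.onset_s - config.pre_decay_s
        if s < 0:
            log.info("pre-decay before session start dropped (decay at %.2f s)", ev.onset_s)
            continue
        clash = any(
            _overlaps(s, ev.onset_s, other.onset_s, other.offset_s)
            for other in schedule.events
            if other is not ev
        )
        if clash:
            log.info("pre-decay overlapping a preceding event dropped (decay at %.2f s)", ev.onset_s)
            continue
        rows.append(
            {
                "epoch_id": f"pred_{k:03d}",
                "epoch_type": "pre_decay",
                "t_start_s": s,
                "t_end_s": ev.onset_s,
                "source_event_id": k,
            }
        )
    df = pd.DataFrame(rows, columns=EPOCH_COLUMNS)
    return df.sort_values("t_start_s", kind="stable").reset_index(drop=True)


def make_eeg_epochs(
    schedule: EventSchedule,
    baselines: List[Tuple[float, float]],
    variant: str = "spectral",
    config: Optional[AnalysisConfig] = None,
    recording_span: Optional[Tuple[float, float]] = None,
) -> pd.DataFrame:
    """Fixed-length EEG analysis windows anchored on event onsets.

    ``variant="spectral"`` emits hallucination, decay and baseline windows
    with the offsets in ``config.epoch_windows``; ``variant="iaf"`` emits one
    window per hallucination.  Windows extending outside the recording span
    or intersecting any reported event interval are dropped; among emitted
    windows, a later window overlapping an earlier-kept window of a
    different source event is dropped (automated overlap removal).
    """
    if variant not in ("spectral", "iaf"):
        raise ValueError("variant must be 'spectral' or 'iaf'")
    config = config or AnalysisConfig()
    span = recording_span or (0.0, schedule.session_length_s)

    candidates = []  # (t_start, t_end, epoch_type, source_event_id, epoch_id)
    if variant == "spectral":
        for k, ev in enumerate(schedule.events):
            off0, off1 = config.epoch_windows[ev.label]
            candidates.append(
                (ev.onset_s + off0, ev.onset_s + off1, ev.label, k, f"{ev.label[:4]}_{k:03d}_eeg")
            )
        off0, off1 = config.epoch_windows["baseline"]
        for j, (s, _e) in enumerate(baselines):
            candidates.append((s + off0, s + off1, "baseline", -1 - j, f"base_{j:03d}_eeg"))
    else:
        off0, off1 = config.epoch_windows["iaf"]
        for k, ev in enumerate(schedule.events):
            if ev.label != "hallucination":
                continue
            candidates.append(
                (ev.onset_s + off0, ev.onset_s + off1, "iaf", k, f"iaf_{k:03d}")
            )

    candidates.sort(key=lambda c: c[0])
    kept: List[Tuple[float, float, str, int, str]] = []
    n_dropped = 0
    for c in candidates:
        t0, t1, etype, src, eid = c
        if t0 < span[0] - 1e-9 or t1 > span[1] + 1e-9:
            n_dropped += 1
            continue
        if any(_overlaps(t0, t1, ev.onset_s, ev.offset_s) for ev in schedule.events):
            n_dropped += 1
            continue
        if any(_overlaps(t0, t1, k0, k1) for k0, k1, _t, ks, _i in kept if ks != src):
            n_dropped += 1
            continue
        kept.append(c)
    if n_dropped:
        log.info("%s epoching: dropped %d windows (bounds/overlap)", variant, n_dropped)

    rows = [
        {"epoch_id": eid, "epoch_type": etype, "t_start_s": t0, "t_end_s": t1, "source_event_id": src}
        for t0, t1, etype, src, eid in kept
    ]
    return pd.DataFrame(rows, columns=EPOCH_COLUMNS)
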