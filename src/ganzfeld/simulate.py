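"""Synthetic co-registered Ganzfeld sessions with known ground truth.

The generator emulates the study conditions end to end so every pipeline
stage can be tested without any recording:

* a piecewise dial trace defining hallucination/decay events (ramped,
  jittered, zero at the neutral point between events);
* fixational gaze jitter (smoothed Gaussian noise) whose SD is set per
  perceptual epoch type, with blinks inserted as missing gaze samples plus a
  sharp pupil-area transient, and head rotations visible coherently in the
  gyroscope and as matched gaze excursions;
* EEG as pink (1/f) background plus alpha and theta oscillations whose
  amplitude varies by epoch type and whose alpha frequency follows a smooth
  pre-hallucination bump, plus 50 Hz line and 62.5 Hz impedance tones.

Event schedules leave enough event-free time before each onset for the
fixed pre-onset EEG analysis windows, mirroring sessions in which
well-separated reports occur.  Default stream rates are 100 Hz gaze/gyro,
50 Hz dial and 250 Hz EEG over 24 channels; session length follows from the
scheduled events (a full study session is 25 minutes, short schedules are
used for desk-scale runs).
"""

from __future__ import annotations

import logging
import warnings
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import signal

from .config import DEFAULT_EPOCH_WINDOWS
from .datatypes import (
    AXES,
    EYES,
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
    "make_schedule",
    "default_ground_truth",
    "simulate_dial",
    "simulate_gaze_and_gyro",
    "simulate_eeg",
    "simulate_session",
    "draw_participant_truth",
    "simulate_cohort",
]

log = logging.getLogger(__name__)

#: 10-20 labels of the 24-channel cap emulated by the generator.
CHANNEL_NAMES_24 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8", "O1", "Oz", "O2", "M1", "M2", "AFz", "POz",
]


# ----------------------------------------------------------------------
# schedules and ground truth
# ----------------------------------------------------------------------

def make_schedule(
    rng: np.random.Generator,
    n_hallucinations: int = 3,
    n_decays: int = 3,
    hall_gap_s: Tuple[float, float] = (27.0, 33.0),
    decay_gap_s: Tuple[float, float] = (12.0, 16.0),
    hall_dur_s: Tuple[float, float] = (15.0, 22.0),
    decay_dur_s: Tuple[float, float] = (8.0, 14.0),
    intensity: float = 5.0,
    tail_s: float = 10.0,
) -> EventSchedule:
    """Alternating hallucination/decay schedule with analysis-safe gaps.

    The event-free gap before each hallucination onset is at least 27 s (so
    the [-25, -5] and [-20, -10] s windows stay clear of other events) and at
    least 12 s before each decay onset (clearing the [-5, -1] s window and a
    6 s baseline window at the gap start).
    """
    labels = []
    for i in range(max(n_hallucinations, n_decays)):
        if i < n_hallucinations:
            labels.append("hallucination")
        if i < n_decays:
            labels.append("decay")
    events: List[Event] = []
    t = 0.0
    for lab in labels:
        gap = rng.uniform(*(hall_gap_s if lab == "hallucination" else decay_gap_s))
        dur = rng.uniform(*(hall_dur_s if lab == "hallucination" else decay_dur_s))
        onset = t + gap
        sign = 1.0 if lab == "hallucination" else -1.0
        events.append(Event(lab, onset, onset + dur, sign * intensity))
        t = onset + dur
    return EventSchedule(events=events, session_length_s=t + tail_s)


def draw_artifact_intervals(
    rng: np.random.Generator,
    session_length_s: float,
    blink_rate_per_min: float = 12.0,
    headmove_rate_per_min: float = 2.0,
) -> Tuple[List[Tuple[float, float]], List[Tuple[float, float]]]:
    """Blink and head-movement intervals at realistic rates and durations
    (blinks 150-300 ms roughly every 5 s; head movements 0.6-1.2 s a couple
    of times per minute)."""
    blinks: List[Tuple[float, float]] = []
    t = float(rng.uniform(1.0, 3.0))
    while True:
        dur = float(rng.uniform(0.15, 0.30))
        if t + dur > session_length_s - 0.5:
            break
        blinks.append((t, t + dur))
        t += dur + max(1.0, float(rng.exponential(60.0 / blink_rate_per_min)))

    heads: List[Tuple[float, float]] = []
    t = float(rng.uniform(5.0, 15.0))
    while True:
        dur = float(rng.uniform(0.6, 1.2))
        if t + dur > session_length_s - 0.5:
            break
        heads.append((t, t + dur))
        t += dur + max(5.0, float(rng.exponential(60.0 / headmove_rate_per_min)))
    return blinks, heads


def default_ground_truth(
    seed: int = 0,
    n_hallucinations: int = 3,
    n_decays: int = 3,
    blink_rate_per_min: float = 12.0,
    headmove_rate_per_min: float = 2.0,
    **schedule_kwargs,
) -> GroundTruth:
    """Ground truth under the default study conditions: reduced gaze
    dispersion in decay/pre-decay, alpha/theta power up in decay and down in
    hallucination relative to baseline, and a +1.5 Hz alpha-frequency bump
    peaking 13 s before hallucination onsets."""
    rng = np.random.default_rng(seed)
    schedule = make_schedule(rng, n_hallucinations, n_decays, **schedule_kwargs)
    blinks, heads = draw_artifact_intervals(
        rng, schedule.session_length_s, blink_rate_per_min, headmove_rate_per_min
    )
    return GroundTruth(schedule=schedule, blink_intervals=blinks, headmove_intervals=heads)


# ----------------------------------------------------------------------
# dial
# ----------------------------------------------------------------------

def simulate_dial(
    schedule: EventSchedule,
    fs: float = 50.0,
    jitter: float = 0.02,
    seed: int = 0,
    ramp_s: float = 0.05,
) -> DialTrace:
    """Dial trace: zero outside events, ramped +/- intensity inside.

    The ramp is fast relative to the dial sampling interval so event onsets
    and offsets recovered by thresholding land within one sample.
    """
    if fs < 10:
        raise ValueError("dial sampling rate must be at least 10 Hz")
    rng = np.random.default_rng(seed)
    n = int(round(schedule.session_length_s * fs))
    t = np.arange(n) / fs
    v = np.zeros(n)
    for ev in schedule.events:
        sel = (t >= ev.onset_s) & (t < ev.offset_s)
        ts = t[sel]
        ramp = np.minimum(1.0, np.minimum((ts - ev.onset_s), (ev.offset_s - ts)) / ramp_s)
        v[sel] = ev.intensity * np.maximum(ramp, 0.5)
    v += jitter * rng.standard_normal(n)
    return DialTrace(timestamp_s=t, value=v)


# ----------------------------------------------------------------------
# gaze + gyro
# ----------------------------------------------------------------------

def _smoothed_unit_noise(
    n: int, fs: float, rng: np.random.Generator, bandwidth_hz: float
) -> np.ndarray:
    """Low-pass-filtered Gaussian noise rescaled to unit sample SD."""
    sos = signal.butter(2, bandwidth_hz, btype="low", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return y / y.std()


def _gaze_sd_envelope(
    t: np.ndarray, truth: GroundTruth, pre_decay_s: float = 2.0
) -> np.ndarray:
    sd = np.full(len(t), truth.gaze_sd_by_epoch["baseline"])
    for ev in truth.schedule.events:
        if ev.label == "decay":
            sd[(t >= ev.onset_s - pre_decay_s) & (t < ev.onset_s)] = truth.gaze_sd_by_epoch[
                "pre_decay"
            ]
    for ev in truth.schedule.events:
        sd[(t >= ev.onset_s) & (t < ev.offset_s)] = truth.gaze_sd_by_epoch[ev.label]
    return sd


def simulate_gaze_and_gyro(
    truth: GroundTruth,
    fs_gaze: float = 100.0,
    fs_gyro: float = 100.0,
    seed: int = 0,
    jitter_bandwidth_hz: float = 15.0,
    headmove_slope_dps: float = 60.0,
    gyro_noise_dps: float = 1.0,
) -> Tuple[GazeRecording, GyroRecording]:
    """Gaze and gyro streams realising the ground truth.

    Gaze per eye/axis is smoothed Gaussian jitter whose SD follows the
    epoch-type envelope; blinks blank the gaze (NaN + invalid) and imprint a
    sharp dip-and-recover transient on the pupil area.  Head movements are
    brisk out-and-back rotations at constant angular speed
    (``headmove_slope_dps``): the gyroscope sees a square-wave velocity and
    the gaze a matched triangular excursion whose amplitude scales with the
    movement duration.
    """
    rng = np.random.default_rng(seed)
    L = truth.schedule.session_length_s
    n = int(round(L * fs_gaze))
    t = np.arange(n) / fs_gaze
    sd_env = _gaze_sd_envelope(t, truth)

    angles: Dict[Tuple[str, str], np.ndarray] = {}
    for eye in EYES:
        for axis in AXES:
            noise = _smoothed_unit_noise(n, fs_gaze, rng, jitter_bandwidth_hz)
            angles[(eye, axis)] = noise * sd_env + rng.normal(0.0, 1.0)

    # head movements: coherent triangular gaze excursion, alternating axes
    for k, (s, e) in enumerate(truth.headmove_intervals):
        sel = (t >= s) & (t < e)
        u = (t[sel] - s) / (e - s)
        prof = 1.0 - np.abs(2.0 * u - 1.0)          # triangle, constant |slope|
        amp = headmove_slope_dps * (e - s) / 2.0
        axis = AXES[k % 2]
        for eye in EYES:
            angles[(eye, axis)][sel] += amp * prof

    valid = {eye: np.ones(n, dtype=bool) for eye in EYES}
    for s, e in truth.blink_intervals:
        sel = (t >= s) & (t < e)
        for eye in EYES:
            valid[eye][sel] = False
            for axis in AXES:
                angles[(eye, axis)][sel] = np.nan

    pupil: Dict[str, np.ndarray] = {}
    for eye in EYES:
        base = (
            50.0
            + 3.0 * np.sin(2 * np.pi * 0.05 * t + rng.uniform(0, 2 * np.pi))
            + 0.05 * rng.standard_normal(n)
        )
        for s, e in truth.blink_intervals:
            s0, e0 = s - 0.05, e + 0.05
            sel = (t >= s0) & (t < e0)
            base[sel] *= 1.0 - 0.8 * np.sin(np.pi * (t[sel] - s0) / (e0 - s0))
        pupil[eye] = base

    gaze = GazeRecording(timestamp_s=t, angles=angles, pupil_area=pupil, valid=valid)

    ng = int(round(L * fs_gyro))
    tg = np.arange(ng) / fs_gyro
    omega = {ax: gyro_noise_dps * rng.standard_normal(ng) for ax in ("x", "y", "z")}
    for k, (s, e) in enumerate(truth.headmove_intervals):
        sel = (tg >= s) & (tg < e)
        u = (tg[sel] - s) / (e - s)
        omega[("x", "y", "z")[k % 3]][sel] += headmove_slope_dps * np.where(u < 0.5, 1.0, -1.0)
    gyro = GyroRecording(timestamp_s=tg, omega=omega)
    return gaze, gyro


# ----------------------------------------------------------------------
# EEG
# ----------------------------------------------------------------------

def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD 1/f noise by spectral shaping with random phases."""
    spec = rng.standard_normal(n // 2 + 1) + 1j * rng.standard_normal(n // 2 + 1)
    f = np.fft.rfftfreq(n, d=1.0)
    spec[1:] /= np.sqrt(f[1:])
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _amp_envelope(
    t: np.ndarray,
    schedule: EventSchedule,
    amp_by_epoch: Mapping[str, float],
    windows: Mapping[str, Tuple[float, float]],
) -> np.ndarray:
    """Baseline amplitude everywhere, event-type amplitude inside the EEG
    analysis window anchored on each event onset."""
    amp = np.full(len(t), amp_by_epoch["baseline"])
    for ev in schedule.events:
        off0, off1 = windows[ev.label]
        sel = (t >= ev.onset_s + off0) & (t < ev.onset_s + off1)
        amp[sel] = amp_by_epoch[ev.label]
    return amp


def simulate_eeg(
    truth: GroundTruth,
    n_channels: int = 24,
    fs: float = 250.0,
    seed: int = 0,
    pink_sd_uv: float = 1.5,
    theta_hz: float = 5.5,
    line_amp_uv: float = 3.0,
    impedance_amp_uv: float = 1.5,
    alpha_freq_spread_hz: float = 0.3,
    epoch_windows: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> EEGRecording:
    """EEG realising the spectral ground truth.

    Each channel is pink noise plus an alpha oscillation (instantaneous
    frequency = baseline plus a Gaussian bump before each hallucination
    onset; amplitude per epoch type), a theta oscillation, and common 50 Hz
    line and 62.5 Hz impedance tones.  Channels carry random gains, phases
    and a small alpha-frequency offset (``alpha_freq_spread_hz``), so the
    oscillations survive average-referencing and the channel-averaged alpha
    peak has a realistic finite bandwidth rather than a single-bin line.
    """
    if n_channels < 1:
        raise ValueError("need at least one channel")
    windows = dict(epoch_windows or DEFAULT_EPOCH_WINDOWS)
    prof = truth.iaf_profile
    if not -25.0 < prof.peak_time_s < -5.0:
        warnings.warn(
            f"alpha peak time {prof.peak_time_s} s outside the analysed (-25, -5) s window"
        )
    rng = np.random.default_rng(seed)
    L = truth.schedule.session_length_s
    n = int(round(L * fs))
    t = np.arange(n) / fs

    f_inst = np.full(n, prof.baseline_hz)
    for ev in truth.schedule.of_label("hallucination"):
        center = ev.onset_s + prof.peak_time_s
        f_inst += prof.peak_delta_hz * np.exp(
            -0.5 * ((t - center) / prof.peak_width_s) ** 2
        )
    phase_alpha = 2 * np.pi * np.cumsum(f_inst) / fs
    alpha_env = _amp_envelope(t, truth.schedule, truth.alpha_amp_by_epoch, windows)
    theta_env = _amp_envelope(t, truth.schedule, truth.theta_amp_by_epoch, windows)
    line = np.sin(2 * np.pi * 50.0 * t)
    imped = np.sin(2 * np.pi * 62.5 * t)

    names = (
        CHANNEL_NAMES_24[:n_channels]
        if n_channels <= 24
        else CHANNEL_NAMES_24 + [f"EX{i}" for i in range(n_channels - 24)]
    )
    data = np.empty((n_channels, n))
    for c in range(n_channels):
        gain = lambda sd: max(0.3, float(rng.normal(1.0, sd)))  # noqa: E731
        df_c = rng.normal(0.0, alpha_freq_spread_hz) if alpha_freq_spread_hz > 0 else 0.0
        x = alpha_env * gain(0.15) * np.sin(
            phase_alpha + 2 * np.pi * df_c * t + rng.uniform(0, 2 * np.pi)
        )
        x = x + theta_env * gain(0.15) * np.sin(
            2 * np.pi * theta_hz * t + rng.uniform(0, 2 * np.pi)
        )
        if pink_sd_uv > 0:
            x = x + pink_sd_uv * _pink_noise(n, rng)
        if line_amp_uv > 0:
            x = x + line_amp_uv * gain(0.1) * line
        if impedance_amp_uv > 0:
            x = x + impedance_amp_uv * gain(0.1) * imped
        data[c] = x
    return EEGRecording(channel_names=names, fs_hz=fs, data=data)


# ----------------------------------------------------------------------
# sessions and cohorts
# ----------------------------------------------------------------------

def simulate_session(
    truth: GroundTruth,
    participant_id: str = "p000",
    seed: int = 0,
    fs_gaze: float = 100.0,
    fs_gyro: float = 100.0,
    fs_dial: float = 50.0,
    fs_eeg: float = 250.0,
    n_channels: int = 24,
    **eeg_kwargs,
) -> Session:
    """One participant's co-registered session from a ground truth."""
    ss = np.random.SeedSequence(seed)
    s_dial, s_gaze, s_eeg = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    dial = simulate_dial(truth.schedule, fs=fs_dial, seed=s_dial)
    gaze, gyro = simulate_gaze_and_gyro(truth, fs_gaze=fs_gaze, fs_gyro=fs_gyro, seed=s_gaze)
    eeg = simulate_eeg(truth, n_channels=n_channels, fs=fs_eeg, seed=s_eeg, **eeg_kwargs)
    return Session(
        participant_id=participant_id,
        gaze=gaze,
        gyro=gyro,
        dial=dial,
        eeg=eeg,
        meta={"synthetic": True, "seed": seed},
    )


DEFAULT_BETWEEN_SUBJECT_SD = {
    "gaze_sd": 0.10,      # lognormal sigma on the per-epoch gaze SDs
    "band_amp": 0.10,     # lognormal sigma on alpha/theta amplitudes
    "iaf_hz": 0.4,        # additive SD on the baseline alpha frequency
    "peak_time_s": 1.0,   # additive SD on the alpha-bump timing
}


def draw_participant_truth(
    template: GroundTruth,
    between_subject_sd: Optional[Mapping[str, float]] = None,
    rng: Optional[np.random.Generator] = None,
    redraw_artifacts: bool = True,
) -> GroundTruth:
    """Participant-specific ground truth drawn around a template.

    Positive quantities (gaze SDs, band amplitudes) get multiplicative
    lognormal perturbations; the alpha baseline frequency and bump time get
    additive Gaussian ones.  The event schedule is shared (the template
    defines the session design), but blink and head-movement intervals are
    re-drawn per participant by default — artifacts are not synchronised
    across people.  With all SDs zero the participant's parameters equal
    the template's.
    """
    sd = dict(DEFAULT_BETWEEN_SUBJECT_SD)
    sd.update(between_subject_sd or {})
    rng = rng or np.random.default_rng(0)
    if redraw_artifacts:
        blinks, heads = draw_artifact_intervals(rng, template.schedule.session_length_s)
    else:
        blinks = list(template.blink_intervals)
        heads = list(template.headmove_intervals)

    def lognorm(x: float, sigma: float) -> float:
        return float(x * np.exp(rng.normal(0.0, sigma))) if sigma > 0 else x

    def norm(x: float, sigma: float) -> float:
        return float(x + rng.normal(0.0, sigma)) if sigma > 0 else x

    prof = template.iaf_profile
    peak_time = float(np.clip(norm(prof.peak_time_s, sd["peak_time_s"]), -19.9, -8.1))
    return GroundTruth(
        schedule=template.schedule,
        blink_intervals=blinks,
        headmove_intervals=heads,
        gaze_sd_by_epoch={
            k: lognorm(v, sd["gaze_sd"]) for k, v in template.gaze_sd_by_epoch.items()
        },
        alpha_amp_by_epoch={
            k: lognorm(v, sd["band_amp"]) for k, v in template.alpha_amp_by_epoch.items()
        },
        theta_amp_by_epoch={
            k: lognorm(v, sd["band_amp"]) for k, v in template.theta_amp_by_epoch.items()
        },
        iaf_profile=IAFProfile(
            baseline_hz=norm(prof.baseline_hz, sd["iaf_hz"]),
            peak_delta_hz=prof.peak_delta_hz,
            peak_time_s=peak_time,
            peak_width_s=prof.peak_width_s,
        ),
    )


def simulate_cohort(
    n_participants: int,
    out_dir,
    truth_template: Optional[GroundTruth] = None,
    between_subject_sd: Optional[Mapping[str, float]] = None,
    seed: int = 0,
    **session_kwargs,
) -> List:
    """Write per-participant session directories plus ground-truth manifests.

    Returns the list of session directory paths; each is loadable with
    :func:`ganzfeld.io.load_session`.
    """
    from . import io as gio

    if n_participants < 2:
        raise ValueError("a cohort needs at least 2 participants")
    template = truth_template or default_ground_truth(seed=seed)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_participants)
    dirs = []
    for i, child in enumerate(children):
        pid = f"p{i:03d}"
        rng = np.random.default_rng(child)
        truth = draw_participant_truth(template, between_subject_sd, rng)
        sess_seed = int(child.generate_state(2)[1] % (2**31))
        session = simulate_session(truth, participant_id=pid, seed=sess_seed, **session_kwargs)
        d = gio.save_session(session, out_dir, truth=truth)
        dirs.append(d)
    log.info("simulated cohort of %d participants under %s", n_participants, out_dir)
    return dirs
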