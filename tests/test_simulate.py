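"""Synthetic-session generator: dial, gaze/gyro, EEG, ground-truth recovery."""

import numpy as np
import pytest

from ganzfeld.config import AnalysisConfig
from ganzfeld.datatypes import Event, EventSchedule, GroundTruth, IAFProfile
from ganzfeld.epochs import dial_to_events
from ganzfeld.gaze import detect_blinks, detect_head_movements, interpolate_gyro, lowpass_filter
from ganzfeld.iaf import detrend_loglog, peak_alpha_frequency, smooth_spectrum
from ganzfeld.simulate import (
    default_ground_truth,
    draw_participant_truth,
    make_schedule,
    simulate_dial,
    simulate_eeg,
    simulate_gaze_and_gyro,
)
from ganzfeld.spectral import epoch_power_spectrum, preprocess_eeg


def _schedule(events, length):
    return EventSchedule(events=events, session_length_s=length)


def _truth(schedule, **kw):
    return GroundTruth(schedule=schedule, **kw)


# ----------------------------------------------------------------------
# dial
# ----------------------------------------------------------------------

def test_empty_schedule_gives_flat_trace():
    dial = simulate_dial(_schedule([], 60.0), seed=0, jitter=0.0)
    assert np.allclose(dial.value, 0.0)


@pytest.mark.parametrize(
    "event",
    [Event("hallucination", 100.0, 120.0, 5.0), Event("decay", 200.0, 211.0, -5.0)],
)
def test_dial_sign_matches_event_and_threshold_scan_recovers_it(event):
    dial = simulate_dial(_schedule([event], 300.0), seed=1)
    t, v = dial.timestamp_s, dial.value
    inside = (t >= event.onset_s) & (t < event.offset_s)
    sign = np.sign(event.intensity)
    assert (sign * v[inside] > 0.5).all()
    assert np.abs(v[~inside]).max() < 0.2  # jitter stays within hysteresis

    schedule, _ = dial_to_events(dial, AnalysisConfig())
    assert len(schedule.events) == 1
    dt = 1 / 50.0
    assert schedule.events[0].onset_s == pytest.approx(event.onset_s, abs=dt + 1e-9)
    assert schedule.events[0].offset_s == pytest.approx(event.offset_s, abs=dt + 1e-9)


def test_dial_round_trip_on_random_schedules():
    cfg = AnalysisConfig()
    for seed in range(5):
        rng = np.random.default_rng(seed)
        schedule = make_schedule(rng, n_hallucinations=2, n_decays=2)
        dial = simulate_dial(schedule, seed=seed)
        recovered, _ = dial_to_events(dial, cfg)
        assert [e.label for e in recovered.events] == [e.label for e in schedule.events]
        dt = 1 / 50.0
        for rec, true in zip(recovered.events, schedule.events):
            assert abs(rec.onset_s - true.onset_s) <= dt + 1e-9
            assert abs(rec.offset_s - true.offset_s) <= dt + 1e-9


def test_dial_requires_minimum_rate():
    with pytest.raises(ValueError):
        simulate_dial(_schedule([], 10.0), fs=5.0)


def test_overlapping_events_rejected_by_schedule():
    with pytest.raises(ValueError, match="overlap"):
        _schedule(
            [Event("hallucination", 10.0, 30.0, 5.0), Event("decay", 25.0, 40.0, -5.0)],
            60.0,
        )


# ----------------------------------------------------------------------
# gaze + gyro
# ----------------------------------------------------------------------

def test_clean_gaze_matches_target_sd():
    sched = _schedule([], 120.0)
    truth = _truth(sched, gaze_sd_by_epoch={k: 1.0 for k in
                                            ("baseline", "hallucination", "decay", "pre_decay")})
    gaze, _ = simulate_gaze_and_gyro(truth, seed=2)
    assert all(v.all() for v in gaze.valid.values())  # no missing samples
    for key, vals in gaze.angles.items():
        assert np.std(vals) == pytest.approx(1.0, rel=0.10)


def test_blink_blanks_gaze_exactly_on_interval():
    sched = _schedule([], 60.0)
    truth = _truth(sched, blink_intervals=[(10.0, 10.2)])
    gaze, _ = simulate_gaze_and_gyro(truth, seed=3)
    t = gaze.timestamp_s
    inside = (t >= 10.0) & (t < 10.2)
    assert np.isnan(gaze.angles[("left", "x")][inside]).all()
    assert not np.isnan(gaze.angles[("left", "x")][~inside]).any()
    assert not gaze.valid["left"][inside].any()


def test_decay_sd_ratio_recovered():
    events = [Event("decay", 60.0, 100.0, -5.0)]
    sched = _schedule(events, 160.0)
    truth = _truth(
        sched,
        gaze_sd_by_epoch={"baseline": 1.0, "hallucination": 1.0, "decay": 0.5, "pre_decay": 0.5},
    )
    gaze, _ = simulate_gaze_and_gyro(truth, seed=4)
    t = gaze.timestamp_s
    x = gaze.angles[("left", "x")]
    ratio = np.std(x[(t >= 62) & (t < 98)]) / np.std(x[(t >= 5) & (t < 55)])
    assert ratio == pytest.approx(0.5, abs=0.1)


def test_artifact_interval_outside_session_rejected():
    with pytest.raises(ValueError):
        _truth(_schedule([], 30.0), blink_intervals=[(29.5, 31.0)])


def test_injected_artifacts_recovered_with_high_f1(config):
    # interval-level F1 of both detectors against the generator manifest
    truth = default_ground_truth(seed=9, n_hallucinations=2, n_decays=2)
    gaze, gyro = simulate_gaze_and_gyro(truth, seed=10)
    fs = gaze.fs
    filtered = gaze.copy()
    for key in filtered.angles:
        filtered.angles[key] = lowpass_filter(gaze.angles[key], fs, 35.0, 2)
    pupil = {e: lowpass_filter(gaze.pupil_area[e], fs, 4.0, 2) for e in ("left", "right")}
    blink_ivs, _ = detect_blinks(filtered, pupil, config)

    def interval_f1(pred, true):
        if not pred or not true:
            return 0.0
        tp = sum(any(p[0] < t[1] and t[0] < p[1] for p in pred) for t in true)
        matched = sum(any(p[0] < t[1] and t[0] < p[1] for t in true) for p in pred)
        prec, rec = matched / len(pred), tp / len(true)
        return 2 * prec * rec / (prec + rec) if prec + rec else 0.0

    assert interval_f1(blink_ivs, truth.blink_intervals) >= 0.9

    gyro_on = interpolate_gyro(gyro, gaze.timestamp_s)
    gyro_sm = {ax: lowpass_filter(v, fs, 10.0, 2) for ax, v in gyro_on.items()}
    head = detect_head_movements(gyro_sm, filtered, config).head_movement
    t = gaze.timestamp_s
    runs = []
    in_run = False
    for i, flag in enumerate(head):
        if flag and not in_run:
            start, in_run = t[i], True
        if not flag and in_run:
            runs.append((start, t[i]))
            in_run = False
    if in_run:
        runs.append((start, t[-1]))
    assert interval_f1(runs, truth.headmove_intervals) >= 0.9


# ----------------------------------------------------------------------
# EEG
# ----------------------------------------------------------------------

def _pure_alpha_truth(sched, amp=2.0):
    return _truth(
        sched,
        alpha_amp_by_epoch={"baseline": amp, "hallucination": amp, "decay": amp},
        theta_amp_by_epoch={"baseline": 0.0, "hallucination": 0.0, "decay": 0.0},
        iaf_profile=IAFProfile(baseline_hz=10.0, peak_delta_hz=0.0),
    )


def test_noise_free_alpha_peaks_at_10hz():
    truth = _pure_alpha_truth(_schedule([], 30.0))
    eeg = simulate_eeg(truth, n_channels=4, seed=5, pink_sd_uv=0.0,
                       line_amp_uv=0.0, impedance_amp_uv=0.0, alpha_freq_spread_hz=0.0)
    spec = epoch_power_spectrum(eeg.data[:, : int(10 * eeg.fs_hz)], eeg.fs_hz)
    assert spec.freqs_hz[np.argmax(spec.channel_mean())] == pytest.approx(10.0)


def test_alpha_amplitude_ratio_recovered_in_band_power():
    # decay:baseline amplitude 1.5 -> power ratio 1.5^2, equal-length windows
    ev = Event("decay", 60.0, 75.0, -5.0)
    sched = _schedule([ev], 120.0)
    truth = _truth(
        sched,
        alpha_amp_by_epoch={"baseline": 2.0, "hallucination": 2.0, "decay": 3.0},
        theta_amp_by_epoch={"baseline": 0.0, "hallucination": 0.0, "decay": 0.0},
        iaf_profile=IAFProfile(peak_delta_hz=0.0),
    )
    eeg = simulate_eeg(truth, n_channels=4, seed=6, pink_sd_uv=0.0,
                       line_amp_uv=0.0, impedance_amp_uv=0.0, alpha_freq_spread_hz=0.0)
    fs = eeg.fs_hz
    # decay analysis window [onset-5, onset-1); baseline segment of equal length
    decay_seg = eeg.data[:, int((ev.onset_s - 5) * fs) : int((ev.onset_s - 1) * fs)]
    base_seg = eeg.data[:, int(10 * fs) : int(14 * fs)]
    p_decay = epoch_power_spectrum(decay_seg, fs).channel_mean().max()
    p_base = epoch_power_spectrum(base_seg, fs).channel_mean().max()
    assert p_decay / p_base == pytest.approx(1.5**2, rel=0.15)


def test_notch_preprocessing_removes_line_tone_from_synthetic_eeg():
    truth = _pure_alpha_truth(_schedule([], 30.0))
    eeg = simulate_eeg(truth, n_channels=4, seed=7, pink_sd_uv=0.5,
                       line_amp_uv=3.0, impedance_amp_uv=0.0)
    clean = preprocess_eeg(eeg)
    fs = eeg.fs_hz
    seg = slice(int(5 * fs), int(25 * fs))
    def bin_power(d):
        spec = epoch_power_spectrum(d[:, seg], fs)
        return spec.channel_mean()[np.argmin(np.abs(spec.freqs_hz - 50.0))]
    assert bin_power(clean.data) <= 0.05 * bin_power(eeg.data)


def test_out_of_window_alpha_peak_time_warns():
    sched = _schedule([Event("hallucination", 60.0, 80.0, 5.0)], 120.0)
    truth = _truth(sched, iaf_profile=IAFProfile(peak_time_s=-3.0))
    with pytest.warns(UserWarning, match="outside"):
        simulate_eeg(truth, n_channels=1, seed=8)


def test_stationary_alpha_baseline_frequency_recovered_within_one_bin(config):
    # long stationary segment -> detrended, smoothed peak at baseline_hz
    truth = _truth(
        _schedule([], 40.0),
        iaf_profile=IAFProfile(baseline_hz=10.5, peak_delta_hz=0.0),
    )
    eeg = simulate_eeg(truth, n_channels=8, seed=9)
    fs = eeg.fs_hz
    win = int(2 * fs)
    acc = None
    for k in range(15):
        spec = epoch_power_spectrum(eeg.data[:, k * win : (k + 1) * win], fs)
        p = spec.channel_mean()
        acc = p if acc is None else acc + p
    detrended = detrend_loglog(spec.freqs_hz, acc / 15, config.detrend_band_hz)
    smoothed = smooth_spectrum(detrended[1:], config.smooth_span_bins)
    iaf = peak_alpha_frequency(spec.freqs_hz[1:], smoothed, config.iaf_search_hz)
    assert abs(iaf - 10.5) <= 0.5 + 1e-9


# ----------------------------------------------------------------------
# participant draws
# ----------------------------------------------------------------------

def test_zero_between_subject_sd_reproduces_template():
    template = default_ground_truth(seed=12)
    zero_sd = {"gaze_sd": 0.0, "band_amp": 0.0, "iaf_hz": 0.0, "peak_time_s": 0.0}
    a = draw_participant_truth(template, zero_sd, np.random.default_rng(1))
    b = draw_participant_truth(template, zero_sd, np.random.default_rng(2))
    assert a.gaze_sd_by_epoch == template.gaze_sd_by_epoch
    assert a.alpha_amp_by_epoch == b.alpha_amp_by_epoch == template.alpha_amp_by_epoch
    assert a.iaf_profile == template.iaf_profile
    assert a.schedule.events == template.schedule.events


def test_nonzero_between_subject_sd_perturbs_parameters():
    template = default_ground_truth(seed=12)
    a = draw_participant_truth(template, rng=np.random.default_rng(1))
    assert a.gaze_sd_by_epoch["baseline"] != template.gaze_sd_by_epoch["baseline"]
    assert a.schedule.events == template.schedule.events  # shared design
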