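"""Gaze preprocessing: angles, filtering, masking, centring, dispersion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ganzfeld.config import AnalysisConfig
from ganzfeld.datatypes import GyroRecording, SampleMask
from ganzfeld.gaze import (
    center_gaze,
    compute_exclusion,
    detect_blinks,
    detect_head_movements,
    epoch_dispersion,
    interpolate_gyro,
    lowpass_filter,
    to_direction_angles,
)

from conftest import make_gaze


# ----------------------------------------------------------------------
# direction angles
# ----------------------------------------------------------------------

@pytest.mark.parametrize(
    "vec, expect_x, expect_y",
    [
        ((0.0, 0.0, 1.0), 0.0, 0.0),
        ((1.0, 0.0, 1.0), 45.0, 0.0),
        ((0.0, -1.0, 1.0), 0.0, -45.0),
    ],
)
def test_direction_angles(vec, expect_x, expect_y):
    t = np.array([0.0])
    dirs = {eye: np.array([vec]) for eye in ("left", "right")}
    pupil = {eye: np.array([50.0]) for eye in ("left", "right")}
    valid = {eye: np.array([True]) for eye in ("left", "right")}
    rec = to_direction_angles(t, dirs, pupil, valid)
    assert rec.angles[("left", "x")][0] == pytest.approx(expect_x)
    assert rec.angles[("left", "y")][0] == pytest.approx(expect_y)


def test_direction_angles_degenerate_z_becomes_missing():
    t = np.array([0.0, 0.01])
    dirs = {eye: np.array([[0.0, 0.0, 0.0], [0.0, 0.0, -1.0]]) for eye in ("left", "right")}
    pupil = {eye: np.full(2, 50.0) for eye in ("left", "right")}
    valid = {eye: np.array([True, True]) for eye in ("left", "right")}
    rec = to_direction_angles(t, dirs, pupil, valid)
    assert np.isnan(rec.angles[("left", "x")]).all()
    assert not rec.valid["left"].any()


# ----------------------------------------------------------------------
# zero-phase low-pass filter
# ----------------------------------------------------------------------

def test_lowpass_dc_gain_unity():
    fs = 100.0
    x = np.full(1000, 3.0)
    y = lowpass_filter(x, fs, 35.0, 2)
    assert np.allclose(y, 3.0, atol=1e-9)


def test_lowpass_gain_at_cutoff_and_passband():
    # analytic two-pass Butterworth magnitude: 1 / (1 + (f/fc)^(2*order))
    fs = 2000.0
    t = np.arange(int(20 * fs)) / fs
    mid = slice(len(t) // 4, 3 * len(t) // 4)
    y = lowpass_filter(np.sin(2 * np.pi * 35.0 * t), fs, 35.0, 2)
    assert np.max(np.abs(y[mid])) == pytest.approx(0.5, abs=0.02)
    fs = 100.0
    t = np.arange(int(30 * fs)) / fs
    y = lowpass_filter(np.sin(2 * np.pi * 5.0 * t), fs, 35.0, 2)
    mid = slice(len(t) // 4, 3 * len(t) // 4)
    assert np.max(np.abs(y[mid])) >= 0.99


def test_lowpass_rejects_cutoff_at_nyquist():
    with pytest.raises(ValueError):
        lowpass_filter(np.zeros(100), 100.0, 50.0, 2)


def test_lowpass_preserves_nans_and_bridges_gaps():
    fs = 100.0
    x = np.sin(2 * np.pi * 1.0 * np.arange(500) / fs)
    x[200:220] = np.nan
    y = lowpass_filter(x, fs, 35.0, 2)
    assert np.isnan(y[200:220]).all()
    assert np.isfinite(np.delete(y, slice(200, 220))).all()


# ----------------------------------------------------------------------
# blink detection
# ----------------------------------------------------------------------

def test_no_blinks_on_clean_recording(config):
    t = np.arange(0, 5, 0.01)
    gaze = make_gaze(t)
    intervals, mask = detect_blinks(gaze, gaze.pupil_area, config)
    assert intervals == []
    assert not mask.blink.any()


def test_blink_interval_from_missing_run(config):
    # 150 ms of missing gaze at t = 10 s -> padded interval [9.9, 10.25]
    t = np.arange(0, 20, 0.01)
    missing = (t >= 10.0) & (t < 10.15)
    gaze = make_gaze(t, missing=missing)
    intervals, mask = detect_blinks(gaze, gaze.pupil_area, config)
    assert len(intervals) == 1
    s, e = intervals[0]
    assert s <= 9.9 + 1e-9 and e >= 10.25 - 1e-9      # covers the padded blink
    assert s >= 9.85 - 1e-9 and e <= 10.30 + 1e-9     # no wild overreach
    assert mask.blink[(t >= 9.95) & (t < 10.2)].all()


def test_short_gap_below_missing_fraction_not_a_blink(config):
    # 30 ms gap: max window missing fraction 30 % < 70 %
    t = np.arange(0, 20, 0.01)
    missing = (t >= 10.0) & (t < 10.03)
    gaze = make_gaze(t, missing=missing)
    intervals, _ = detect_blinks(gaze, gaze.pupil_area, config)
    assert intervals == []


def test_pupil_transient_triggers_blink(config):
    # pupil criterion alone: sharp dip with fully valid gaze
    t = np.arange(0, 20, 0.01)
    rng = np.random.default_rng(0)
    pupil = 50.0 + 0.05 * rng.standard_normal(len(t))
    dip = (t >= 10.0) & (t < 10.2)
    pupil[dip] -= 30.0
    gaze = make_gaze(t, pupil=pupil)
    intervals, _ = detect_blinks(gaze, gaze.pupil_area, config)
    assert len(intervals) == 1
    s, e = intervals[0]
    assert s < 10.0 and e > 10.2


def test_blink_detection_needs_one_window(config):
    t = np.arange(0, 0.03, 0.01)
    gaze = make_gaze(t)
    with pytest.raises(ValueError):
        detect_blinks(gaze, gaze.pupil_area, config)


# ----------------------------------------------------------------------
# gyro interpolation
# ----------------------------------------------------------------------

def test_gyro_interpolation_passes_through_knots_and_linear_data():
    t = np.arange(0, 1, 0.1)
    gyro = GyroRecording(t, {ax: 3.0 * t for ax in "xyz"})
    at_knots = interpolate_gyro(gyro, t)
    assert np.allclose(at_knots["x"], 3.0 * t)
    mid = t[:-1] + 0.05
    interp = interpolate_gyro(gyro, mid)
    assert np.allclose(interp["y"], 3.0 * mid)


def test_gyro_interpolation_requires_two_samples():
    gyro = GyroRecording(np.array([0.0]), {ax: np.array([1.0]) for ax in "xyz"})
    with pytest.raises(ValueError):
        interpolate_gyro(gyro, np.array([0.0]))


@settings(deadline=None, max_examples=30, derandomize=True)
@given(step_at=st.integers(min_value=1, max_value=18))
def test_gyro_interpolation_never_overshoots_step(step_at):
    # monotone Hermite: values for a 0 -> 1 step stay inside [0, 1]
    t = np.arange(20.0)
    vals = np.where(t < step_at, 0.0, 1.0)
    gyro = GyroRecording(t, {ax: vals.copy() for ax in "xyz"})
    fine = np.linspace(0, 19, 571)
    out = interpolate_gyro(gyro, fine)
    assert (out["x"] >= -1e-12).all() and (out["x"] <= 1 + 1e-12).all()


# ----------------------------------------------------------------------
# head movements
# ----------------------------------------------------------------------

def _quiet_gyro(n):
    return {ax: np.zeros(n) for ax in "xyz"}


def test_no_head_movement_with_silent_gyro(config):
    t = np.arange(0, 5, 0.01)
    gaze = make_gaze(t)
    mask = detect_head_movements(_quiet_gyro(len(t)), gaze, config)
    assert not mask.head_movement.any()


def test_head_movement_flags_cover_rotation(config):
    # 300 ms rotation at 20 deg/s with a 10 deg gaze excursion
    t = np.arange(0, 10, 0.01)
    rot = (t >= 5.0) & (t < 5.3)
    gyro = _quiet_gyro(len(t))
    gyro["y"][rot] = 20.0
    excursion = np.zeros(len(t))
    excursion[rot] = 10.0 * np.sin(np.pi * (t[rot] - 5.0) / 0.3)
    gaze = make_gaze(t, angle=excursion)
    mask = detect_head_movements(gyro, gaze, config)
    flagged_t = t[mask.head_movement]
    assert flagged_t.size
    assert flagged_t.min() >= 5.0 - 0.2 - 1e-9 and flagged_t.max() <= 5.3 + 0.2 + 1e-9
    assert mask.head_movement[(t >= 5.05) & (t < 5.25)].all()


def test_eye_range_veto_blocks_small_gaze(config):
    # gyro above threshold but gaze range far below 8 degrees
    t = np.arange(0, 10, 0.01)
    gyro = _quiet_gyro(len(t))
    gyro["x"][(t >= 5.0) & (t < 5.3)] = 5.0
    gaze = make_gaze(t, angle=0.5 * np.sin(2 * np.pi * 0.2 * t))
    mask = detect_head_movements(gyro, gaze, config)
    assert not mask.head_movement.any()


def test_summed_gyro_mode_combines_axes(config):
    t = np.arange(0, 10, 0.01)
    gyro = {ax: np.zeros(len(t)) for ax in "xyz"}
    for ax in "xyz":  # each axis below threshold, sum above
        gyro[ax][(t >= 5.0) & (t < 5.3)] = 2.0
    excursion = np.zeros(len(t))
    excursion[(t >= 5.0) & (t < 5.3)] = 10.0
    gaze = make_gaze(t, angle=excursion)
    cfg = AnalysisConfig(gyro_combine_mode="summed")
    assert detect_head_movements(gyro, gaze, cfg).head_movement.any()
    assert not detect_head_movements(gyro, gaze, config).head_movement.any()


# ----------------------------------------------------------------------
# brute-force oracle equivalence (small traces)
# ----------------------------------------------------------------------

def test_detectors_match_brute_force_small(config):
    from _oracles import brute_blink_mask, brute_head_mask

    rng = np.random.default_rng(7)
    t = np.arange(0, 6, 0.01)
    missing = np.zeros(len(t), bool)
    missing[(t >= 2.0) & (t < 2.18)] = True
    missing[(t >= 4.5) & (t < 4.56)] = True
    pupil = 50 + 0.05 * rng.standard_normal(len(t))
    pupil[(t >= 1.0) & (t < 1.1)] -= 20
    gaze = make_gaze(t, angle=rng.standard_normal(len(t)), pupil=pupil, missing=missing)

    _, mask = detect_blinks(gaze, gaze.pupil_area, config)
    assert np.array_equal(mask.blink, brute_blink_mask(gaze, gaze.pupil_area, config))

    gyro = {ax: 2.0 * rng.standard_normal(len(t)) for ax in "xyz"}
    gyro["z"][(t >= 3.0) & (t < 3.4)] += 15.0
    head = detect_head_movements(gyro, gaze, config)
    assert np.array_equal(head.head_movement, brute_head_mask(gyro, gaze, config))


# ----------------------------------------------------------------------
# centring, exclusion, dispersion
# ----------------------------------------------------------------------

def test_centering_subtracts_blink_free_median():
    t = np.arange(0, 0.03, 0.01)
    gaze = make_gaze(t)
    for eye in ("left", "right"):
        for axis in ("x", "y"):
            gaze.angles[(eye, axis)] = np.array([0.0, 0.0, 10.0])
    blink = SampleMask.empty(3)
    blink.blink[2] = True  # the 10-degree sample sits inside a blink
    centered, medians = center_gaze(gaze, blink)
    assert medians[("left", "x")] == 0.0
    assert np.allclose(centered.angles[("left", "x")], [0.0, 0.0, 10.0])

    gaze2 = make_gaze(t)
    for key in gaze2.angles:
        gaze2.angles[key] = np.array([1.0, 2.0, 3.0])
    centered2, _ = center_gaze(gaze2, SampleMask.empty(3))
    assert np.allclose(centered2.angles[("right", "y")], [-1.0, 0.0, 1.0])


def test_exclusion_is_strictly_greater_than_60_percent(config):
    def frac_mask(frac, n=100):
        m = SampleMask.empty(n)
        m.blink[: int(round(frac * n))] = True
        return m

    assert compute_exclusion(frac_mask(0.61), config).excluded
    assert not compute_exclusion(frac_mask(0.60), config).excluded
    assert not compute_exclusion(frac_mask(0.0), config).excluded


def _epochs(*rows):
    return pd.DataFrame(
        [
            {"epoch_id": f"e{i}", "epoch_type": r[0], "t_start_s": r[1], "t_end_s": r[2],
             "source_event_id": i}
            for i, r in enumerate(rows)
        ]
    )


def test_dispersion_closed_forms(config):
    t = np.arange(0, 0.03, 0.01)
    gaze = make_gaze(t)
    for key in gaze.angles:
        gaze.angles[key] = np.array([-1.0, 0.0, 1.0])
    recs = epoch_dispersion(gaze, SampleMask.empty(3), _epochs(("baseline", 0.0, 0.03)))
    assert np.allclose(recs.sd_deg, 1.0)
    assert (recs.n_retained == 3).all()

    const = make_gaze(t, angle=2.5)
    recs = epoch_dispersion(const, SampleMask.empty(3), _epochs(("decay", 0.0, 0.03)))
    assert np.allclose(recs.sd_deg, 0.0)


def test_dispersion_uses_only_retained_samples(config):
    rng = np.random.default_rng(3)
    t = np.arange(0, 1.0, 0.01)
    vals = rng.standard_normal(len(t))
    gaze = make_gaze(t, angle=vals)
    mask = SampleMask.empty(len(t))
    mask.head_movement[::2] = True  # mask half the epoch
    recs = epoch_dispersion(gaze, mask, _epochs(("hallucination", 0.0, 1.0)))
    expected = np.std(vals[1::2], ddof=1)
    assert np.allclose(recs.sd_deg, expected)


def test_dispersion_skips_epochs_with_fewer_than_two_samples(config):
    t = np.arange(0, 1.0, 0.01)
    gaze = make_gaze(t, angle=1.0)
    mask = SampleMask.empty(len(t))
    mask.blink[:] = True
    mask.blink[50] = False
    recs = epoch_dispersion(gaze, mask, _epochs(("baseline", 0.0, 1.0)))
    assert recs.empty


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    shift=st.floats(-50, 50, allow_nan=False),
    gain=st.floats(0.1, 10, allow_nan=False),
)
def test_dispersion_translation_invariant_and_scales(shift, gain):
    rng = np.random.default_rng(11)
    t = np.arange(0, 2.0, 0.01)
    vals = rng.standard_normal(len(t))
    mask = SampleMask.empty(len(t))
    base = epoch_dispersion(make_gaze(t, angle=vals), mask, _epochs(("baseline", 0.0, 2.0)))
    moved = epoch_dispersion(
        make_gaze(t, angle=gain * vals + shift), mask, _epochs(("baseline", 0.0, 2.0))
    )
    assert np.allclose(moved.sd_deg, gain * base.sd_deg, rtol=1e-9)
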