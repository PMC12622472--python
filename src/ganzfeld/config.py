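"""Analysis configuration.

All tunable thresholds of the pipeline live in one flat dataclass so that the
default construction reproduces the reference analysis with zero
configuration.  The config round-trips through a flat YAML document (one key
per scalar; band intervals and epoch windows as two-element lists).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Tuple

import yaml

__all__ = ["AnalysisConfig", "load_config", "save_config"]

#: EEG analysis windows, in seconds relative to the event anchor.
#: hallucination / decay / iaf anchor on the event *onset*; baseline anchors
#: on the baseline-interval start.
DEFAULT_EPOCH_WINDOWS: Dict[str, Tuple[float, float]] = {
    "hallucination": (-20.0, -10.0),
    "decay": (-5.0, -1.0),
    "baseline": (0.0, 6.0),
    "iaf": (-25.0, -5.0),
}


@dataclass
class AnalysisConfig:
    # -- gaze / gyro filtering ------------------------------------------------
    gaze_lowpass_hz: float = 35.0      # low-pass on each eye-direction axis
    pupil_lowpass_hz: float = 4.0      # low-pass on pupil area
    gyro_lowpass_hz: float = 10.0      # low-pass on resampled gyroscope
    filter_order: int = 2              # Butterworth order (applied twice: zero phase)

    # -- blink detection ------------------------------------------------------
    blink_window_ms: float = 100.0
    blink_step_ms: float = 50.0
    blink_missing_frac: float = 0.70   # window flagged if >= this fraction missing
    blink_pad_ms: float = 100.0        # padding around merged blink intervals
    pupil_change_mad_k: float = 5.0    # "unrealistic" pupil change: k * MAD of diffs

    # -- head-movement detection ---------------------------------------------
    gyro_thresh_dps: float = 4.0
    gyro_combine_mode: str = "per_axis"   # or "summed"
    headmove_window_ms: float = 200.0
    headmove_step_ms: float = 100.0
    eye_range_thresh_deg: float = 8.0

    # -- participant exclusion ------------------------------------------------
    exclusion_frac: float = 0.60       # excluded iff masked fraction > this (strict)

    # -- spectral bands -------------------------------------------------------
    alpha_band_hz: Tuple[float, float] = (8.0, 12.0)   # [lo, hi)
    theta_band_hz: Tuple[float, float] = (3.0, 8.0)    # [lo, hi)
    iaf_search_hz: Tuple[float, float] = (7.0, 13.0)   # closed interval
    detrend_band_hz: Tuple[float, float] = (0.5, 5.5)

    # -- EEG preprocessing ----------------------------------------------------
    eeg_highpass_hz: float = 0.5
    notch_bands_hz: Tuple[Tuple[float, float], ...] = ((49.0, 51.0), (62.0, 63.0))
    artifact_reject_uv: float | None = None   # drop epochs with |x| above this
    spectral_norm: str = "amplitude"   # "amplitude" (2|X|/N) or "raw" (|X|^2/N)

    # -- IAF sliding window ---------------------------------------------------
    iaf_window_s: float = 2.0
    iaf_step_s: float = 1.0
    smooth_span_bins: int = 7

    # -- epoching -------------------------------------------------------------
    epoch_windows: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EPOCH_WINDOWS)
    )
    dial_hysteresis: float = 0.2       # dial units; events need |value| > this
    dial_min_event_s: float = 1.0
    baseline_min_s: float = 6.0
    pre_decay_s: float = 2.0           # pre-decay epoch length

    rng_seed: int = 0

    # ------------------------------------------------------------------

    def validate(self, fs_gaze: float | None = None, fs_eeg: float | None = None) -> None:
        """Raise ``ValueError`` on an internally inconsistent configuration.

        Stream sampling rates, when given, are checked against the filter
        cutoffs (every cutoff must lie strictly below the Nyquist frequency
        of the stream it filters).
        """
        if not 0.0 < self.blink_missing_frac <= 1.0:
            raise ValueError("blink_missing_frac must be in (0, 1]")
        if not 0.0 < self.exclusion_frac < 1.0:
            raise ValueError("exclusion_frac must be in (0, 1)")
        for name in ("alpha_band_hz", "theta_band_hz", "iaf_search_hz", "detrend_band_hz"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be an ordered non-empty interval")
        if self.gyro_combine_mode not in ("per_axis", "summed"):
            raise ValueError("gyro_combine_mode must be 'per_axis' or 'summed'")
        if self.spectral_norm not in ("amplitude", "raw"):
            raise ValueError("spectral_norm must be 'amplitude' or 'raw'")
        if self.smooth_span_bins < 1 or self.smooth_span_bins % 2 == 0:
            raise ValueError("smooth_span_bins must be odd and >= 1")
        if self.iaf_window_s <= 0 or self.iaf_step_s <= 0:
            raise ValueError("iaf window/step must be positive")
        # IAF search band must be resolvable at the window's bin spacing
        if self.iaf_search_hz[0] < 1.0 / self.iaf_window_s:
            raise ValueError("iaf_search_hz below the resolution of iaf_window_s")
        if fs_gaze is not None:
            for cut in (self.gaze_lowpass_hz, self.pupil_lowpass_hz, self.gyro_lowpass_hz):
                if cut >= fs_gaze / 2:
                    raise ValueError(
                        f"cutoff {cut} Hz not below Nyquist of {fs_gaze} Hz stream"
                    )
        if fs_eeg is not None:
            top = max(self.alpha_band_hz[1], self.theta_band_hz[1], self.iaf_search_hz[1])
            if top >= fs_eeg / 2:
                raise ValueError("analysis bands exceed EEG Nyquist frequency")

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["notch_bands_hz"] = [list(b) for b in self.notch_bands_hz]
        d["epoch_windows"] = {k: list(v) for k, v in self.epoch_windows.items()}
        for name in ("alpha_band_hz", "theta_band_hz", "iaf_search_hz", "detrend_band_hz"):
            d[name] = list(getattr(self, name))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        kw = dict(d)
        for name in ("alpha_band_hz", "theta_band_hz", "iaf_search_hz", "detrend_band_hz"):
            if name in kw:
                kw[name] = tuple(kw[name])
        if "notch_bands_hz" in kw:
            kw["notch_bands_hz"] = tuple(tuple(b) for b in kw["notch_bands_hz"])
        if "epoch_windows" in kw:
            kw["epoch_windows"] = {k: tuple(v) for k, v in kw["epoch_windows"].items()}
        unknown = set(kw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kw)

    def content_hash(self) -> str:
        """Stable hash of the configuration, for run logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> AnalysisConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    cfg = AnalysisConfig.from_dict(d)
    cfg.validate()
    return cfg


def save_config(config: AnalysisConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return path
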