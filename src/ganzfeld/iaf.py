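"""Sliding-window individual alpha frequency (IAF) before hallucination onset.

Each 20 s pre-hallucination epoch ([-25, -5] s relative to the reported
onset) is segmented into 2 s windows advancing by 1 s (19 positions, centres
-24 ... -6 s).  Per window position the single-FFT power spectrum is averaged
over all epochs and channels of a participant, the aperiodic background is
removed by subtracting a least-squares line fit in log-log space over
0.5-5.5 Hz, the detrended log-power is smoothed with a 7-bin moving average,
and the IAF is the frequency of maximum power within 7-13 Hz.  The maximum
IAF over the epoch ("fastest alpha") and the time at which it is attained
summarise each participant; group summaries report median and SEM.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .spectral import epoch_power_spectrum

__all__ = [
    "window_spectra",
    "detrend_loglog",
    "smooth_spectrum",
    "peak_alpha_frequency",
    "iaf_timecourse",
    "IAFSeries",
    "group_iaf_summary",
    "GroupIAFSummary",
]

log = logging.getLogger(__name__)


def window_spectra(
    iaf_epochs: Sequence[np.ndarray],
    fs: float,
    config: Optional[AnalysisConfig] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-window-position spectra averaged over epochs and channels.

    ``iaf_epochs`` is a list of (n_channels, n_samples) segments covering the
    [-25, -5] s pre-hallucination interval.  Returns ``(freqs, centers,
    powers)`` where ``powers`` is (n_windows, n_bins): the power spectrum per
    sliding-window position, averaged across all epochs and channels, and
    ``centers`` are window-centre times in seconds relative to onset.
    """
    config = config or AnalysisConfig()
    if not iaf_epochs:
        raise ValueError("no complete pre-hallucination epochs")
    win_n = int(round(config.iaf_window_s * fs))
    step_n = int(round(config.iaf_step_s * fs))
    epoch_off0, epoch_off1 = config.epoch_windows["iaf"]
    n_epoch = int(round((epoch_off1 - epoch_off0) * fs))
    n_windows = (n_epoch - win_n) // step_n + 1
    centers = epoch_off0 + config.iaf_window_s / 2 + config.iaf_step_s * np.arange(n_windows)

    freqs = np.fft.rfftfreq(win_n, d=1.0 / fs)
    acc = np.zeros((n_windows, len(freqs)))
    for seg in iaf_epochs:
        seg = np.atleast_2d(seg)
        if seg.shape[1] != n_epoch:
            raise ValueError(
                f"epoch has {seg.shape[1]} samples, expected {n_epoch} "
                f"({epoch_off1 - epoch_off0:.0f} s at {fs} Hz)"
            )
        for w in range(n_windows):
            spec = epoch_power_spectrum(seg[:, w * step_n : w * step_n + win_n], fs)
            acc[w] += spec.power.mean(axis=0)
    return freqs, centers, acc / len(iaf_epochs)


def detrend_loglog(
    freqs: np.ndarray, power: np.ndarray, fit_band: Tuple[float, float] = (0.5, 5.5)
) -> np.ndarray:
    """Remove the aperiodic 1/f background by a line fit in log-log space.

    A least-squares line is fitted to log10(power) versus log10(frequency)
    over bins within ``fit_band`` and subtracted (extrapolated) over all
    positive frequencies.  Returns log10-power units; the DC bin is NaN.
    Zero-power bins are floored at machine epsilon with a warning.
    """
    freqs = np.asarray(freqs, float)
    power = np.asarray(power, float).copy()
    if (power <= 0).any():
        warnings.warn("non-positive spectral bins floored at machine epsilon")
        power = np.maximum(power, np.finfo(float).tiny)
    pos = freqs > 0
    fit = pos & (freqs >= fit_band[0] - 1e-9) & (freqs <= fit_band[1] + 1e-9)
    if fit.sum() < 3:
        raise ValueError("fewer than 3 bins in the detrending band")
    logf = np.log10(freqs[fit])
    logp = np.log10(power[fit])
    slope, intercept = np.polyfit(logf, logp, 1)
    out = np.full_like(power, np.nan)
    out[pos] = np.log10(power[pos]) - (slope * np.log10(freqs[pos]) + intercept)
    return out


def smooth_spectrum(values: np.ndarray, span_bins: int = 7) -> np.ndarray:
    """Centred moving average over ``span_bins`` frequency points.

    Edges use shrinking (still centred) windows.  The span must be odd.
    """
    if span_bins < 1 or span_bins % 2 == 0:
        raise ValueError("span must be odd and >= 1")
    v = np.asarray(values, float)
    half = span_bins // 2
    out = np.empty_like(v)
    for i in range(len(v)):
        lo = max(0, i - half)
        hi = min(len(v), i + half + 1)
        k = min(i - lo, hi - 1 - i)  # keep the window centred at the edges
        out[i] = v[i - k : i + k + 1].mean()
    return out


def peak_alpha_frequency(
    freqs: np.ndarray, values: np.ndarray, search_band: Tuple[float, float] = (7.0, 13.0)
) -> float:
    """Bin-centre frequency of maximum power within the closed search band.

    Ties break toward the lower frequency.
    """
    sel = (freqs >= search_band[0] - 1e-9) & (freqs <= search_band[1] + 1e-9)
    if not sel.any():
        raise ValueError(f"no bins inside search band {search_band}")
    f = freqs[sel]
    v = values[sel]
    return float(f[int(np.argmax(v))])


@dataclass
class IAFSeries:
    """Per-participant IAF time course and its summary metrics."""

    participant: str
    window_center_s: np.ndarray
    iaf_hz: np.ndarray

    @property
    def max_iaf_hz(self) -> float:
        return float(np.max(self.iaf_hz))

    @property
    def t_max_s(self) -> float:
        """Centre time of the first window attaining the maximum IAF."""
        return float(self.window_center_s[int(np.argmax(self.iaf_hz))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant": self.participant,
                "window_center_s": self.window_center_s,
                "iaf_hz": self.iaf_hz,
            }
        )


def iaf_timecourse(
    iaf_epochs: Sequence[np.ndarray],
    fs: float,
    config: Optional[AnalysisConfig] = None,
    participant: str = "p0",
) -> IAFSeries:
    """IAF per sliding-window position for one participant.

    Chains :func:`window_spectra`, :func:`detrend_loglog`,
    :func:`smooth_spectrum` and :func:`peak_alpha_frequency`.
    """
    config = config or AnalysisConfig()
    freqs, centers, powers = window_spectra(iaf_epochs, fs, config)
    iafs = np.empty(len(centers))
    for w in range(len(centers)):
        detrended = detrend_loglog(freqs, powers[w], config.detrend_band_hz)
        smoothed = smooth_spectrum(detrended[1:], config.smooth_span_bins)
        iafs[w] = peak_alpha_frequency(freqs[1:], smoothed, config.iaf_search_hz)
    return IAFSeries(participant=participant, window_center_s=centers, iaf_hz=iafs)


@dataclass
class GroupIAFSummary:
    n_participants: int
    median_max_iaf_hz: float
    sem_max_iaf_hz: float
    median_t_max_s: float
    mean_t_max_s: float
    sem_t_max_s: float
    grand_average: pd.DataFrame  # columns window_center_s, mean_iaf_hz

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "median_max_iaf_hz": self.median_max_iaf_hz,
            "sem_max_iaf_hz": self.sem_max_iaf_hz,
            "median_t_max_s": self.median_t_max_s,
            "mean_t_max_s": self.mean_t_max_s,
            "sem_t_max_s": self.sem_t_max_s,
        }


def _sem(x: np.ndarray) -> float:
    if len(x) < 2:
        warnings.warn("single participant: SEM reported as 0")
        return 0.0
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def group_iaf_summary(series: List[IAFSeries]) -> GroupIAFSummary:
    """Median and SEM of the fastest alpha and its timing across participants,
    plus the grand-averaged IAF time course."""
    if not series:
        raise ValueError("no participants")
    max_iafs = np.array([s.max_iaf_hz for s in series])
    t_maxes = np.array([s.t_max_s for s in series])
    stacked = pd.concat([s.to_frame() for s in series])
    grand = (
        stacked.groupby("window_center_s")["iaf_hz"].mean().rename("mean_iaf_hz").reset_index()
    )
    return GroupIAFSummary(
        n_participants=len(series),
        median_max_iaf_hz=float(np.median(max_iafs)),
        sem_max_iaf_hz=_sem(max_iafs),
        median_t_max_s=float(np.median(t_maxes)),
        mean_t_max_s=float(np.mean(t_maxes)),
        sem_t_max_s=_sem(t_maxes),
        grand_average=grand,
    )
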