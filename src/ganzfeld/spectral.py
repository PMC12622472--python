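"""EEG preprocessing, epoch-normalised power spectra and band-power models.

Power is estimated from a single discrete Fourier transform over each
continuous epoch (rectangular window, no segment averaging) so that the
temporal specificity of brief, self-reported perceptual states is
preserved.  The spectrum is amplitude-normalised: the one-sided amplitude
at bin k is ``a_k = 2 |X_k| / N`` (DC and Nyquist not doubled) and power is
``p_k = a_k^2 / 2`` (microvolts squared).  This normalisation makes the
peak-bin power of a stationary sinusoid independent of epoch length, which
is the point of dividing by the number of time points: epochs of 4 and 10
seconds become directly comparable.  A raw ``|X|^2 / N`` periodogram variant
remains available through ``AnalysisConfig.spectral_norm = "raw"``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from .config import AnalysisConfig
from .datatypes import EEGRecording

__all__ = [
    "PowerSpectrum",
    "preprocess_eeg",
    "epoch_power_spectrum",
    "band_power",
    "band_power_table",
    "baseline_subtracted_table",
    "fit_power_lmm",
    "PowerLMMResult",
]

log = logging.getLogger(__name__)


@dataclass
class PowerSpectrum:
    """One-sided, epoch-length-normalised power per channel per bin."""

    freqs_hz: np.ndarray          # bin centres, 0 .. fs/2
    power: np.ndarray             # (n_channels, n_bins), microvolts^2

    def channel_mean(self) -> np.ndarray:
        return self.power.mean(axis=0)


# ----------------------------------------------------------------------
# preprocessing
# ----------------------------------------------------------------------

def preprocess_eeg(raw: EEGRecording, config: Optional[AnalysisConfig] = None) -> EEGRecording:
    """High-pass, notch filters and common average reference.

    Zero-phase second-order-section Butterworth filters: a 0.5 Hz high-pass,
    then band-stop filters over 49-51 Hz (line noise) and 62-63 Hz
    (impedance-measurement tone).  Finally each sample is re-referenced to
    the cross-channel average; flat (zero-variance) channels are excluded
    from the reference with a warning but kept in the output.
    """
    config = config or AnalysisConfig()
    fs = raw.fs_hz
    data = raw.data.astype(float, copy=True)

    sos_hp = signal.butter(2, config.eeg_highpass_hz, btype="high", fs=fs, output="sos")
    data = signal.sosfiltfilt(sos_hp, data, axis=1)
    for lo, hi in config.notch_bands_hz:
        sos_bs = signal.butter(2, [lo, hi], btype="bandstop", fs=fs, output="sos")
        data = signal.sosfiltfilt(sos_bs, data, axis=1)

    variances = data.var(axis=1)
    usable = variances > 0
    if not usable.all():
        flat = [raw.channel_names[i] for i in np.flatnonzero(~usable)]
        warnings.warn(f"flat channels excluded from average reference: {flat}")
    if not usable.any():
        raise ValueError("all channels flat; cannot re-reference")
    reference = data[usable].mean(axis=0)
    data = data - reference
    return EEGRecording(list(raw.channel_names), fs, data, raw.t0_s)


# ----------------------------------------------------------------------
# spectra and band power
# ----------------------------------------------------------------------

def epoch_power_spectrum(
    segment: np.ndarray, fs: float, norm: str = "amplitude"
) -> PowerSpectrum:
    """Single-FFT power spectrum of one continuous epoch.

    ``segment`` is (n_channels, n_samples) or (n_samples,).  With the default
    amplitude normalisation a sinusoid of amplitude A at an exact bin
    frequency contributes ``A^2 / 2`` at that bin regardless of N, and the
    two-sided power sums to the mean square of the signal (Parseval).
    """
    x = np.atleast_2d(np.asarray(segment, dtype=float))
    n = x.shape[1]
    if n < fs:
        raise ValueError("epoch shorter than one second")
    if not np.isfinite(x).all():
        raise ValueError("epoch contains non-finite samples; reject artifacts upstream")

    X = np.fft.rfft(x, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    if norm == "amplitude":
        amp = np.abs(X) / n
        # double all bins except DC (and Nyquist for even N)
        scale = np.full(len(freqs), 2.0)
        scale[0] = 1.0
        if n % 2 == 0:
            scale[-1] = 1.0
        amp = amp * scale
        power = amp**2 / 2.0
        # undo the halving at the non-doubled bins so Parseval holds exactly
        power[:, 0] = np.abs(X[:, 0] / n) ** 2
        if n % 2 == 0:
            power[:, -1] = np.abs(X[:, -1] / n) ** 2
    elif norm == "raw":
        power = np.abs(X) ** 2 / n
        power[:, 1 : len(freqs) - (1 if n % 2 == 0 else 0)] *= 2.0
    else:
        raise ValueError("norm must be 'amplitude' or 'raw'")
    return PowerSpectrum(freqs_hz=freqs, power=power)


def band_power(spectrum: PowerSpectrum, band: Tuple[float, float]) -> float:
    """Channel-averaged mean power over bins with lo <= f < hi."""
    lo, hi = band
    sel = (spectrum.freqs_hz >= lo - 1e-9) & (spectrum.freqs_hz < hi - 1e-9)
    if not sel.any():
        raise ValueError(f"band {band} contains no frequency bins")
    return float(spectrum.power[:, sel].mean(axis=1).mean())


def band_power_table(
    eeg: EEGRecording,
    epochs: pd.DataFrame,
    config: Optional[AnalysisConfig] = None,
    participant: str = "p0",
) -> pd.DataFrame:
    """Alpha/theta band power per epoch (channel-averaged, microvolts^2).

    Epochs whose samples exceed ``artifact_reject_uv`` (when configured) are
    dropped with a log message.
    """
    config = config or AnalysisConfig()
    bands = {"alpha": config.alpha_band_hz, "theta": config.theta_band_hz}
    rows = []
    for _, ep in epochs.iterrows():
        seg = eeg.segment(ep.t_start_s, ep.t_end_s)
        if config.artifact_reject_uv is not None and np.abs(seg).max() > config.artifact_reject_uv:
            log.info("epoch %s rejected (amplitude artifact)", ep.epoch_id)
            continue
        spec = epoch_power_spectrum(seg, eeg.fs_hz, norm=config.spectral_norm)
        for band_name, band in bands.items():
            rows.append(
                {
                    "participant": participant,
                    "epoch_id": ep.epoch_id,
                    "epoch_type": ep.epoch_type,
                    "band": band_name,
                    "power_uv2": band_power(spec, band),
                }
            )
    return pd.DataFrame(
        rows, columns=["participant", "epoch_id", "epoch_type", "band", "power_uv2"]
    )


def baseline_subtracted_table(bands: pd.DataFrame) -> pd.DataFrame:
    """Subtract each participant's mean baseline power, per band.

    Returns one row per decay/hallucination epoch with the power difference
    from that participant's average baseline.  Participants without a
    baseline epoch are excluded (logged).
    """
    out = []
    for (participant, band), grp in bands.groupby(["participant", "band"]):
        base = grp.loc[grp.epoch_type == "baseline", "power_uv2"]
        if base.empty:
            log.info("participant %s has no baseline epochs for %s band; excluded", participant, band)
            continue
        base_mean = float(base.mean())
        for _, row in grp[grp.epoch_type.isin(["decay", "hallucination"])].iterrows():
            out.append(
                {
                    "participant": participant,
                    "epoch_id": row.epoch_id,
                    "epoch_type": row.epoch_type,
                    "band": band,
                    "diff_uv2": row.power_uv2 - base_mean,
                }
            )
    return pd.DataFrame(
        out, columns=["participant", "epoch_id", "epoch_type", "band", "diff_uv2"]
    )


# ----------------------------------------------------------------------
# mixed model on baseline-subtracted power
# ----------------------------------------------------------------------

@dataclass
class PowerLMMResult:
    """Random-intercept model of baseline-subtracted band power.

    ``effects`` has one row per epoch type (mean difference from baseline
    with SE, approximate df, t, p and 95 % CI); ``contrast`` is the
    decay-vs-hallucination comparison.
    """

    effects: pd.DataFrame
    contrast: Dict[str, float]
    converged: bool


def _df_between_within(n_obs: int, n_groups: int, n_fixed: int) -> float:
    """Residual-based degrees of freedom for mixed-model t statistics."""
    return max(float(n_obs - n_groups - n_fixed + 1), 1.0)


def fit_power_lmm(differences: pd.DataFrame) -> PowerLMMResult:
    """Fit ``diff ~ 0 + epoch_type`` with a participant random intercept.

    The fixed effects are the mean baseline-subtracted power per epoch type;
    the contrast is decay minus hallucination.  A singular random-effects
    fit falls back to a pooled OLS fit with a warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from scipy import stats

    df = differences.copy()
    if df.participant.nunique() < 2:
        raise ValueError("need at least 2 participants for the mixed model")
    types = sorted(df.epoch_type.unique())
    if not {"decay", "hallucination"} <= set(types):
        raise ValueError("both decay and hallucination epochs are required")

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm("diff_uv2 ~ 0 + C(epoch_type)", df, groups=df["participant"])
            fit = model.fit(reml=True, method="lbfgs")
            if not fit.converged or not np.isfinite(fit.bse.iloc[:2]).all():
                raise np.linalg.LinAlgError("singular mixed fit")
            params = fit.params
            cov = fit.cov_params()
        except (np.linalg.LinAlgError, ValueError):
            warnings.warn("singular mixed-model fit; falling back to pooled OLS")
            converged = False
            ols = smf.ols("diff_uv2 ~ 0 + C(epoch_type)", df).fit()
            params, cov = ols.params, ols.cov_params()

    dof = _df_between_within(len(df), df.participant.nunique(), len(types))
    rows = []
    names = {f"C(epoch_type)[{t}]": t for t in types}
    for pname, etype in names.items():
        est = float(params[pname])
        se = float(np.sqrt(cov.loc[pname, pname]))
        tval = est / se if se > 0 else np.nan
        p = 2 * stats.t.sf(abs(tval), dof) if np.isfinite(tval) else np.nan
        ci = stats.t.ppf(0.975, dof) * se
        rows.append(
            {
                "epoch_type": etype,
                "M": est,
                "SE": se,
                "df": dof,
                "t": tval,
                "p": p,
                "ci_lo": est - ci,
                "ci_hi": est + ci,
            }
        )
    effects = pd.DataFrame(rows)

    cvec = pd.Series(0.0, index=params.index)
    cvec["C(epoch_type)[decay]"] = 1.0
    cvec["C(epoch_type)[hallucination]"] = -1.0
    b = float(cvec @ params)
    se_c = float(np.sqrt(cvec @ cov.values @ cvec))
    t_c = b / se_c if se_c > 0 else np.nan
    p_c = 2 * stats.t.sf(abs(t_c), dof) if np.isfinite(t_c) else np.nan
    contrast = {"b": b, "SE": se_c, "df": dof, "t": t_c, "p": p_c}
    return PowerLMMResult(effects=effects, contrast=contrast, converged=converged)
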