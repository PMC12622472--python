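"""End-to-end pipeline over a set of session directories.

Stages: gaze preprocessing (with participant exclusion) -> dial epoching ->
per-epoch gaze dispersion -> EEG preprocessing and band power ->
baseline-subtracted power mixed models -> IAF time course -> group
summaries.  All result tables can be written as delimited text alongside a
machine-readable run log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import io as gio
from .config import AnalysisConfig
from .datatypes import Session
from .epochs import dial_to_events, make_eeg_epochs, make_eye_epochs
from .gaze import epoch_dispersion, preprocess_gaze
from .iaf import GroupIAFSummary, IAFSeries, group_iaf_summary, iaf_timecourse
from .spectral import (
    PowerLMMResult,
    band_power_table,
    baseline_subtracted_table,
    fit_power_lmm,
    preprocess_eeg,
)
from .stats import DispersionLMMResult, dispersion_lmm_tukey

__all__ = ["ResultBundle", "analyze_session", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class SessionResult:
    participant_id: str
    excluded: bool
    fraction_masked: float
    dispersion: pd.DataFrame
    band_power: pd.DataFrame
    iaf_series: Optional[IAFSeries]


@dataclass
class ResultBundle:
    dispersion: pd.DataFrame
    dispersion_models: Dict[str, DispersionLMMResult]
    band_power: pd.DataFrame
    power_differences: pd.DataFrame
    power_models: Dict[str, PowerLMMResult]
    iaf_series: List[IAFSeries]
    iaf_summary: Optional[GroupIAFSummary]
    exclusions: pd.DataFrame
    run_log: dict = field(default_factory=dict)


def analyze_session(session: Session, config: AnalysisConfig) -> SessionResult:
    """Run every per-participant stage on one session."""
    pid = session.participant_id
    prep = preprocess_gaze(session.gaze, session.gyro, config)
    if prep.exclusion.excluded:
        return SessionResult(
            participant_id=pid,
            excluded=True,
            fraction_masked=prep.exclusion.fraction_masked,
            dispersion=pd.DataFrame(),
            band_power=pd.DataFrame(),
            iaf_series=None,
        )

    schedule, baselines = dial_to_events(session.dial, config)
    eye_epochs = make_eye_epochs(schedule, baselines, config)
    dispersion = epoch_dispersion(prep.gaze, prep.mask, eye_epochs, participant=pid)

    eeg = preprocess_eeg(session.eeg, config)
    span = (eeg.t0_s, eeg.t0_s + eeg.duration_s)
    spec_epochs = make_eeg_epochs(schedule, baselines, "spectral", config, recording_span=span)
    bands = band_power_table(eeg, spec_epochs, config, participant=pid)

    iaf_epochs = make_eeg_epochs(schedule, baselines, "iaf", config, recording_span=span)
    series: Optional[IAFSeries] = None
    if len(iaf_epochs):
        segments = [eeg.segment(r.t_start_s, r.t_end_s) for _, r in iaf_epochs.iterrows()]
        series = iaf_timecourse(segments, eeg.fs_hz, config, participant=pid)
    else:
        log.warning("participant %s: no complete pre-hallucination epochs; omitted from IAF", pid)
    return SessionResult(
        participant_id=pid,
        excluded=False,
        fraction_masked=prep.exclusion.fraction_masked,
        dispersion=dispersion,
        band_power=bands,
        iaf_series=series,
    )


def run_pipeline(
    session_dirs: List,
    config: Optional[AnalysisConfig] = None,
    out_dir=None,
    seed: Optional[int] = None,
) -> ResultBundle:
    """Analyze a cohort of session directories and fit the group models."""
    config = config or AnalysisConfig()
    if not session_dirs:
        raise ValueError("need at least one session directory")

    results: List[SessionResult] = []
    for d in session_dirs:
        session = gio.load_session(d, config)
        results.append(analyze_session(session, config))

    kept = [r for r in results if not r.excluded]
    if not kept:
        raise ValueError("no analyzable participants (all excluded by the masking rule)")
    exclusions = pd.DataFrame(
        [
            {
                "participant": r.participant_id,
                "fraction_masked": r.fraction_masked,
                "excluded": r.excluded,
            }
            for r in results
        ]
    )

    dispersion = pd.concat([r.dispersion for r in kept], ignore_index=True)
    band_power = pd.concat([r.band_power for r in kept], ignore_index=True)
    differences = baseline_subtracted_table(band_power)

    dispersion_models: Dict[str, DispersionLMMResult] = {}
    if dispersion.participant.nunique() >= 2:
        for eye in ("left", "right"):
            for axis in ("x", "y"):
                try:
                    dispersion_models[f"{eye}_{axis}"] = dispersion_lmm_tukey(
                        dispersion, eye=eye, axis=axis
                    )
                except ValueError as exc:
                    log.warning("dispersion model %s_%s skipped: %s", eye, axis, exc)

    power_models: Dict[str, PowerLMMResult] = {}
    for band in ("alpha", "theta"):
        sub = differences[differences.band == band]
        try:
            power_models[band] = fit_power_lmm(sub)
        except ValueError as exc:
            log.warning("power model for %s band skipped: %s", band, exc)

    iaf_series = [r.iaf_series for r in kept if r.iaf_series is not None]
    iaf_summary = group_iaf_summary(iaf_series) if iaf_series else None

    run_log = {
        "config_hash": config.content_hash(),
        "seed": seed,
        "n_sessions": len(results),
        "n_excluded": int(exclusions.excluded.sum()),
        "excluded_participants": exclusions.loc[exclusions.excluded, "participant"].tolist(),
        "n_dispersion_records": int(len(dispersion)),
        "n_band_power_epochs": int(band_power.epoch_id.nunique()) if len(band_power) else 0,
        "n_iaf_participants": len(iaf_series),
    }
    bundle = ResultBundle(
        dispersion=dispersion,
        dispersion_models=dispersion_models,
        band_power=band_power,
        power_differences=differences,
        power_models=power_models,
        iaf_series=iaf_series,
        iaf_summary=iaf_summary,
        exclusions=exclusions,
        run_log=run_log,
    )
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _model_tables(bundle: ResultBundle) -> pd.DataFrame:
    rows = []
    for key, m in bundle.dispersion_models.items():
        for _, r in m.pairwise.iterrows():
            rows.append({"model": f"dispersion_{key}", **r.to_dict()})
    for band, m in bundle.power_models.items():
        for _, r in m.effects.iterrows():
            rows.append(
                {
                    "model": f"power_{band}",
                    "contrast": f"{r.epoch_type} - baseline",
                    "estimate": r.M,
                    "SE": r.SE,
                    "df": r.df,
                    "t": r.t,
                    "p_raw": r.p,
                    "p_tukey": np.nan,
                }
            )
        c = m.contrast
        rows.append(
            {
                "model": f"power_{band}",
                "contrast": "decay - hallucination",
                "estimate": c["b"],
                "SE": c["SE"],
                "df": c["df"],
                "t": c["t"],
                "p_raw": c["p"],
                "p_tukey": np.nan,
            }
        )
    return pd.DataFrame(rows)


def _write_bundle(bundle: ResultBundle, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    gio.save_tables(bundle.exclusions, out / "exclusions.tsv")
    if len(bundle.dispersion):
        gio.save_tables(bundle.dispersion, out / "dispersion.tsv")
    if len(bundle.band_power):
        gio.save_tables(bundle.band_power, out / "band_power.tsv")
    if len(bundle.power_differences):
        gio.save_tables(bundle.power_differences, out / "power_differences.tsv")
    models = _model_tables(bundle)
    if len(models):
        gio.save_tables(models, out / "model_contrasts.tsv")
    if bundle.iaf_series:
        gio.save_tables(
            pd.concat([s.to_frame() for s in bundle.iaf_series], ignore_index=True),
            out / "iaf_series.tsv",
        )
    if bundle.iaf_summary is not None:
        gio.save_tables(bundle.iaf_summary.grand_average, out / "iaf_grand_average.tsv")
        bundle.run_log["iaf_summary"] = bundle.iaf_summary.to_dict()
    (out / "run_log.json").write_text(json.dumps(bundle.run_log, indent=2, sort_keys=True))
    log.info("results written to %s", out)
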