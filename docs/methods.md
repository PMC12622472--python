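# Methods

This note documents the models, conventions and numerical choices behind
the `ganzfeld` package, and what the synthetic-data tests do and do not
establish about real recordings.

## Streams, clock and units

All streams of a session (gaze, gyroscope, dial, EEG) live on one
session-relative clock: t = 0 at the first sample of the earliest stream,
seconds as floats.  Gaze direction is expressed per eye as the angle of the
x (horizontal) and y (vertical) direction components against the forward z
axis, `atan(component / z)` in degrees; angular velocity is in deg/s about
pitch/yaw/roll; EEG is in microvolts at 250 Hz over a 24-channel 10–20
montage.  Missing gaze samples are NaN with a false validity flag.

## Gaze pipeline

The pipeline quantifies the *amount* of eye movement from raw samples; it
deliberately performs no fixation/saccade classification, which is
ill-posed for low-amplitude drift and glissade-like movements in a field
without fixation targets.  The order of operations is fixed:

1. **Filtering.** Zero-phase (forward–backward) 2nd-order Butterworth
   low-pass filters: 35 Hz on each eye-direction coordinate, 4 Hz on pupil
   area, 10 Hz on the gyroscope after resampling.  Forward–backward
   filtering squares the magnitude response (gain 1/2 at the nominal
   cutoff) and introduces no phase lag, which matters because epochs are
   time-locked to dial events.  NaN runs are bridged by linear
   interpolation before filtering and restored to NaN afterwards; an IIR
   filter cannot run across gaps, and bridging confines the error to the
   (re-masked) gap neighbourhood.
2. **Blink masking.** A 100 ms window moving in 50 ms steps over each of
   the four eye-direction coordinates; a window is flagged when ≥ 70 % of a
   coordinate's samples are missing, or when the maximum within-window
   per-sample pupil-area change exceeds k·MAD (k = 5) of all per-sample
   changes of that eye's recording.  "Unrealistically high pupil change"
   has no published magnitude; the MAD criterion is robust, unit-free and
   adapts to each recording.  Flagged windows are merged and padded by
   100 ms on each side (blink-adjacent samples carry pupil-size-driven
   direction errors).  Windows start at the recording's first timestamp; a
   trailing window covering less than half its width is dropped; interval
   membership is half-open with a 1 ns boundary tolerance.  The window
   verdict is OR-ed across the four coordinates and the two pupil signals.
3. **Centring.** Each eye/axis is centred on its median over all blink-free
   valid samples of the entire recording (medians are logged).
4. **Head-movement masking.** The gyroscope is aligned to the gaze clock
   with a shape-preserving monotone cubic (PCHIP) interpolant — it passes
   through the knots and cannot overshoot, so spurious super-threshold
   velocities are never invented between samples — then smoothed at 10 Hz.
   A sample is gyro-flagged when |ω| > 4°/s on at least one axis
   (`per_axis`, default) or when Σ|ω| > 4°/s (`summed`; both procedures
   are implemented).  For every 200 ms window (100 ms step) containing a
   gyro-flagged sample, the range (max − min) of each of the four gaze
   coordinates is computed; only if the maximum range exceeds 8° is the
   whole window masked.  The veto intentionally retains minimal head
   movements.
5. **Exclusion.** A recording with strictly more than 60 % of samples
   masked (blink ∨ head movement ∨ invalid) is excluded from all analyses.
6. **Dispersion.** Per epoch × eye × axis, the sample SD (denominator
   n − 1) of retained centred samples; epochs with fewer than two retained
   samples on a coordinate yield no record.  SD is translation-invariant,
   so centring does not bias it; it scales linearly with signal gain.

## Dial epoching

Events are maximal dial excursions beyond a hysteresis band (default 0.2
dial units against event amplitudes of ~5), debounced at 1 s minimum
duration; onsets/offsets sit at the first/last crossing sample (intervals
half-open, offset extended by one sample interval).  Baselines are maximal
neutral runs of ≥ 6 s, so every baseline admits one 6 s EEG window.  The
hysteresis and debounce values are conservative defaults exposed in the
config, not published constants.  Pre-decay epochs are the 2 s before a
decay onset and are dropped when they would leave the session or overlap a
preceding event.

EEG windows are anchored strictly before onsets — hallucination
[−20, −10] s, decay [−5, −1] s, IAF [−25, −5] s, baseline [0, 6] s from the
baseline start — because (i) a report can only begin once the experience is
under way and (ii) turning the dial produces motor artifacts.  One window
per baseline interval ("starting at the onset of a baseline").  Overlap
handling is automated with a strict rule replacing manual visual
inspection: a window is dropped if it leaves the recording, intersects any
reported event interval, or intersects an earlier-kept window of a
different source event.

## Spectral analysis

Each epoch is transformed with a single DFT (rectangular window, no
Welch-style segment averaging) to preserve the temporal specificity of
brief states.  The spectrum is amplitude-normalised: one-sided amplitude
`a_k = 2|X_k|/N` (DC/Nyquist not doubled), power `p_k = a_k²/2`.  Dividing
by the number of time points admits two readings (`|X|²/N` vs `|X/N|²`);
the amplitude reading is implemented because it is the one that actually
makes peak power epoch-length invariant — the stated purpose of the
normalisation, given 4 s decay vs 10 s hallucination epochs.  The raw
`|X|²/N` periodogram remains available via `spectral_norm="raw"`.  Parseval
holds to 1e-6 on white noise (verified in tests).  Band power is the mean
over bins in [8, 12) Hz (α) and [3, 8) Hz (θ) — the shared 8 Hz bin belongs
to alpha only, avoiding double counting — then the mean over channels.  No
1/f detrending is applied to band power: short, variable-length epochs make
aperiodic fits unreliable, and the aperiodic component may itself differ
between states.

Preprocessing: zero-phase 2nd-order Butterworth 0.5 Hz high-pass,
band-stops over 49–51 Hz (line) and 62–63 Hz (impedance-measurement tone at
62.5 Hz), then common average reference; flat channels are excluded from
the reference with a warning.  ICA-based artifact removal and spherical
channel interpolation are out of scope: they have no meaningful analogue on
synthetic dipole-free data, so an optional amplitude-threshold epoch
rejection (`artifact_reject_uv`) stands in; real recordings should be
cleaned externally first.

Baseline subtraction uses the participant's *mean* baseline power per band
(the pairing of epochs to nearest-in-time baselines being the unchosen
alternative).  The mixed model is `diff ~ 0 + epoch_type` with a
participant random intercept, fitted by REML (statsmodels `MixedLM`);
reported are the per-epoch-type mean differences with SE/CI/t and the
decay − hallucination contrast.  Degrees of freedom use a between-within
residual approximation (n_obs − n_participants − n_fixed + 1) rather than
Satterthwaite/Kenward–Roger, which statsmodels does not provide; at the
cohort sizes involved the difference is negligible for the sign/threshold
decisions the package reports.  A singular random-effects fit falls back to
pooled OLS with a warning.

## IAF time course

Each complete [−25, −5] s pre-hallucination epoch is cut into 2 s windows
with 1 s steps — exactly 19 positions with centres −24 … −6 s.  Per window
position, spectra (0.5 Hz resolution) are averaged over all epochs and all
channels of the participant (an occipital-subset average would be a
one-line change; channel-agnostic averaging matches the reporting style of
the analysis this follows).  The aperiodic background is removed by
subtracting a least-squares line fit to log10 power vs log10 frequency over
0.5–5.5 Hz, extrapolated across all positive frequencies; a pure power law
detrends to exactly zero on the fit band, and any monotone background
removal leaves the within-band argmax unchanged.  The detrended log-power
is smoothed with a 7-point centred moving average (edges shrink
symmetrically), spanning 3.0 Hz at native 0.5 Hz resolution; a span of
"≈ 3.4 Hz" would imply ~0.485 Hz bins (zero padding), which is not used —
the discrepancy is accepted and documented.  The IAF per window is the
frequency of maximum smoothed power within the closed band [7, 13] Hz,
ties breaking toward the lower frequency.  Per participant, the *fastest
alpha* is the maximum IAF over windows and its time is the centre of the
first window attaining it; group summaries give median and SEM (sample
SD/√n; 0 with a warning for n = 1) of both metrics plus the grand-averaged
time course.  With 0.5 Hz bins and 3 Hz smoothing the estimator is
inherently accurate to about one bin; single-bin line spectra (noise-free
sinusoids) are a degenerate input for which the smoothed argmax is
ill-conditioned — real and simulated alpha peaks have finite bandwidth.

## Group statistics

Gaze dispersion: one model per eye × axis, `sd ~ epoch_type` with baseline
as reference level and a participant random intercept; all pairwise epoch
contrasts are tested with familywise Tukey correction via the studentized
range distribution (p = P(q_{k,df} > |t|·√2)), guaranteed ≥ the raw p.
One-sample tests against the zero anchor of the altered-states rating scale
use `p_adj = min(1, m·p_raw)` (Bonferroni).  Percentage tables divide
category counts by the interviewed sample sizes (27/41/66 per experiment —
inferred from the printed per-experiment percentages, and differing from
the enrolled 28/45/67); pooled percentages divide summed counts by summed
denominators over the experiments present in the row, hence always lie
between the per-experiment extremes.  One bundled category row ("Loss of
depth perception") prints a pooled percentage consistent with a different
denominator in its source; the package computes from counts and
denominators and does not silently reconcile such rows.

## Synthetic sessions

The generator emulates the study conditions: 25-minute sessions at 100 Hz
gaze/gyro, 50 Hz dial, 250 Hz × 24-channel EEG, with short (2–6 minute)
schedules for desk-scale tests.  Event schedules alternate hallucinations
and decays with event-free gaps of ≥ 27 s before hallucination onsets and
≥ 12 s before decay onsets so the fixed pre-onset windows are realisable —
mirroring sessions with well-separated reports; hallucinations last
~15–22 s and decays ~8–14 s.

* **Dial**: zero outside events; inside, the intensity with a fast ramp and
  small jitter, so thresholding recovers onsets/offsets within one sample.
* **Gaze**: per-coordinate Gaussian noise low-passed at 15 Hz and rescaled
  to unit SD, multiplied by an epoch-type SD envelope (defaults: baseline
  1.0°, hallucination 0.9°, decay and pre-decay 0.5° — the published
  evidence for reduced movement is directional, via violin plots, so the
  magnitudes are free generator parameters chosen as plausible fixational
  jitter).  Blinks blank the gaze and imprint a sharp dip-and-recover pupil
  transient (~80 % area drop), exercising both detector criteria; blinks
  run at ~12/min for 150–300 ms, head movements at ~2/min for 0.6–1.2 s,
  masking ~20 % of samples overall.  Artifact intervals are drawn per
  participant — blinks are not synchronised across people.
* **Head movements**: brisk out-and-back rotations at constant angular
  speed (60°/s): square-wave gyro velocity and a matched triangular gaze
  excursion whose amplitude scales with duration.  The constant slope
  matters: the 8° range veto inspects 200 ms windows, and any smooth
  excursion profile has a low-range plateau at its apex that the veto
  leaves unmasked at full amplitude, contaminating dispersion estimates; a
  triangular profile keeps every window's range at slope × 0.2 s ≈ 12°, so
  injected movements are recoverable (interval F1 ≥ 0.9) and leakage is
  confined to sub-window edges.
* **EEG**: per channel, spectrally-shaped 1/f noise (random phases, unit SD
  scaled to 1.5 µV) + an alpha oscillation whose amplitude follows the
  epoch-type envelope over the EEG analysis windows (defaults 2.0 µV
  baseline, 2.6 decay, 1.5 hallucination) and whose instantaneous frequency
  is the baseline IAF (10 Hz) plus a Gaussian bump (+1.5 Hz, σ = 1.3 s ≈
  3 s FWHM) centred 13 s before each hallucination onset + a 5.5 Hz theta
  oscillation (1.5/1.9/1.1 µV) + common 50 Hz line and 62.5 Hz impedance
  tones.  Channels carry random gains, phases and a small alpha-frequency
  offset (σ = 0.3 Hz) so oscillations survive average-referencing and the
  channel-averaged alpha peak has a realistic finite bandwidth.
* **Cohorts** share one session design (schedule); participant parameters
  are perturbed around the template (lognormal ×e^{N(0,0.1)} on SDs and
  amplitudes, additive N(0, 0.4 Hz) on IAF, N(0, 1 s) on bump time).

What the passing tests show: the implementation recovers what the
generator injects — event boundaries, artifact intervals, SD ratios,
band-power directions, bump timing — under stationary Gaussian/sinusoidal
signal models.  What they do not show: robustness to real-world
non-stationarities (slow drift, saccadic intrusions, EMG/ocular EEG
artifacts, aperiodic-slope changes between states), for which the ICA-based
cleaning of real pipelines exists.

## Problem sizes

Desk-scale runs use 2–6 minute sessions: the effect-recovery studies run
20 replicates of 20-participant cohorts (3 hallucinations + 3–5 decays per
session) for the test suite, and 10 replicates of 12 participants in the
acceptance script; bump-timing recovery uses 6-hallucination sessions over
20 (tests) or 10 (script) seeds.  All randomness flows from explicit seeds
through `numpy.random.SeedSequence`; identical inputs, config and seed give
byte-identical result tables.

## Known limitations

* Random-effects structure is intercept-only (no random slopes), matching
  the reference analysis but potentially anti-conservative under strong
  participant-by-epoch interactions.
* df approximation is between-within, not Kenward–Roger/Satterthwaite.
* The dial-event extraction algorithm of the original acquisition system is
  published separately; the hysteresis segmentation here is a conservative
  stand-in whose thresholds are package defaults, not published values.
* EDF/vendor-specific readers are not included; sessions are plain
  delimited text plus a JSON sidecar.
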