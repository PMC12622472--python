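# ganzfeld

Analysis pipeline for co-registered eye-tracking + EEG recordings of
**Ganzfeld** sessions — immersion in an unstructured, homogeneous visual
field during which observers report two kinds of perceptual episodes with a
continuous dial: *hallucinations* (emergent percepts, dial above the neutral
point) and *decays* (fading of the field's colour/brightness, dial below
neutral).

The package is for researchers studying perceptual fading and
Ganzfeld-induced altered states who need a reproducible, scriptable version
of the standard analysis chain:

1. **Gaze preprocessing** — per-eye x/y direction angles
   (`atan(component/z)` in degrees), zero-phase 2nd-order Butterworth
   low-pass filters (35 Hz gaze, 4 Hz pupil, 10 Hz gyroscope), blink
   detection by a 100 ms moving window (50 ms step; flagged at ≥ 70 %
   missing samples or an unrealistic pupil-area change, padded ± 100 ms),
   median centring over blink-free samples, head-movement masking
   (gyroscope |ω| > 4°/s with an 8° eye-direction-range veto over 200 ms
   windows), and exclusion of recordings with > 60 % masked samples.
2. **Epoching** — the dial trace is segmented by hysteresis thresholding
   into hallucination/decay events and baselines; eye-tracking epochs cover
   the events plus a 2 s *pre-decay* window; EEG epochs are fixed windows
   strictly before each onset (hallucination [−20, −10] s, decay [−5, −1] s,
   baseline [0, 6] s from baseline start, IAF [−25, −5] s) so dial-turning
   motor artifacts never enter the spectra.
3. **Spectral analysis** — 0.5 Hz high-pass, 49–51 / 62–63 Hz notches,
   common average reference; per-epoch single-FFT spectra normalised by the
   number of time points (peak power of a sinusoid of amplitude A is A²/2
   regardless of epoch length); α = [8, 12) Hz and θ = [3, 8) Hz band power,
   channel-averaged; baseline-subtracted random-intercept mixed models with
   the decay-vs-hallucination contrast.
4. **Individual alpha frequency (IAF)** — 2 s sliding windows (1 s step, 19
   positions per epoch), 1/f background removed by a log–log line fit over
   0.5–5.5 Hz, 7-bin moving-average smoothing, peak frequency in 7–13 Hz;
   per-participant *fastest alpha* and its timing, summarised by group
   median and SEM.
5. **Group statistics** — gaze-dispersion mixed models with Tukey-corrected
   pairwise epoch contrasts, one-sample tests of questionnaire scores
   against the zero anchor with Bonferroni correction, and interview
   category count → percentage tables.

Because no public recording of this kind exists, the package ships a
**synthetic-session generator** (`ganzfeld.simulate`) producing
co-registered gaze/gyro/dial/EEG streams with known ground truth — epoch-
dependent gaze jitter, blinks with pupil transients, head rotations, and
EEG as 1/f noise plus epoch-modulated alpha/theta oscillations with a
pre-hallucination alpha-frequency bump — so every stage is testable end to
end.

## Worked example

```python
from ganzfeld import AnalysisConfig, default_ground_truth, run_pipeline, simulate_cohort

template = default_ground_truth(seed=0, n_hallucinations=3, n_decays=3)
dirs = simulate_cohort(5, "scratch_cohort", truth_template=template, seed=0)
bundle = run_pipeline(dirs, AnalysisConfig(), out_dir="scratch_results", seed=0)
```

Inspecting the bundle prints (exact output of the snippet above):

```
baseline - decay gaze SD contrast: +0.473 deg, Tukey p = 0.0000
alpha decay - baseline: M = +0.154 uV^2, SE = 0.008, t(24) = +19.63, p = 2.73e-16
alpha hallucination - baseline: M = -0.048 uV^2, SE = 0.008, t(24) = -6.09, p = 2.71e-06
alpha decay vs hallucination: b = +0.202, t = +18.19, p = 1.52e-15
IAF: median fastest alpha 11.00 Hz, mean time of fastest alpha -14.0 s (n = 5)
```

Reading: gaze dispersion during decays is ~0.47° lower than during baseline
(the generator injected a 1.0° → 0.5° reduction); alpha band power rises in
the window preceding decay reports and falls before hallucination reports,
relative to baseline, and the decay-vs-hallucination contrast is positive; the alpha
peak frequency reaches its maximum on average ~14 s before hallucination
onset (the generator's bump peaks at −13 s).  The same numbers land in
`scratch_results/` as TSV tables plus a JSON run log (config hash, seed,
exclusions).

The default `AnalysisConfig()` *is* the reference analysis: every
threshold above is a named field, and a flat YAML config overrides any of
them.  A `ganzfeld` command-line tool wraps the stages
(`simulate`, `preprocess-gaze`, `epoch`, `dispersion`, `psd`, `iaf`,
`qual-summary`, `run-all`).

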