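# oculomet

Oculomotor parameter extraction and clinical-association analysis for
multiple-sclerosis cohorts assessed with low-rate (60 Hz) tablet eye
tracking.

Eye movements are controlled by a wide cortical–subcortical network and
degrade in measurable ways in MS: fixation becomes unstable, saccades
slow and start later, anti-saccade errors increase, pursuit gain drops.
`oculomet` implements the full analysis chain from raw gaze traces of
four visual tasks (fixation, pro-saccade, anti-saccade, step–ramp
pursuit) to:

1. **20 named oculomotor parameters** per participant — fixation
   stability as the 95% bivariate contour ellipse area
   (BCEA95 = 2π·k·σxσy·√(1−ρ²), k = −ln 0.05), saccadic-intrusion rate
   and amplitude; pro-saccade latency, time-to-target, peak velocity and
   amplitude gain per eccentricity class; anti-saccade error/correction
   rates, latencies and time-to-correct; pursuit velocity gain, lag,
   proportion of time in pursuit and catch-up saccade count.
2. **Composite clinical scores** — BICAMS = mean z(SDMT, RAVLT, BVMT-R)
   and a modified MSFC = mean z(SDMT, −T25FW, 1/9HPT).
3. **Association statistics** — Spearman ρ between every parameter and
   EDSS/SDMT/BICAMS/MSFC with Benjamini–Hochberg FDR control, and a
   low-vs-high EDSS (≤ 4 vs ≥ 4.5) Mann–Whitney contrast of z-scored
   parameters.
4. **PLS regression** estimates of each clinical scale from the
   parameters (+ age), with 5-fold-CV latent-variable selection,
   subset search over parameter combinations, standardized coefficients
   and normalized contribution weights.

Saccades are detected with an adaptive velocity threshold (a robust
multiple of the non-saccadic speed spread, tuned for 60 Hz data) and
each event is fitted with a parametric waveform whose peak velocity
obeys the saccadic main sequence `Vp = η(1 − e^(−A/c))`.

Since no patient recordings are distributed, the package ships a
first-class synthetic cohort generator: gaze traces with planted
latencies, main-sequence parameters, fixational scatter, square-wave
intrusions, pursuit gain and blinks, plus clinical scores coupled to a
latent severity.  Everything downstream is validated by recovering what
was planted.  See `docs/methods.md` for the model details and what the
synthetic cohort does and does not emulate.

## Worked example

The numbered scripts under `analysis/` run the whole study on a
simulated cohort of 60 (deterministic; results land in `results/`):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_extract_profiles.py
python analysis/03_associations.py
python analysis/04_pls_models.py
```

Step 02 prints the end-to-end check — extracted cohort means against
the planted generative values:

```
extracted 60 profiles x 21 parameters (30 structurally missing cells)
cohort-mean recovery (planted -> extracted):
  pro-saccade latency (ms)      242.025 ->  243.781
  amplitude gain                  0.937 ->    0.942
  pursuit gain                    0.841 ->    0.834
  intrusion rate (/s)             0.588 ->    0.571
  anti-saccade error rate         0.333 ->    0.319
```

i.e. the detector + waveform fit + metrics chain reproduces the planted
latency to ~2 ms, gains to < 0.01 and rates within sampling error.
Step 04 then reports, per outcome:

```
  edss    R2=0.93 adjR2=0.92 cvR2=0.89 n=57 components=7 features=7 top=ps_time_to_target_short
  sdmt    R2=0.63 adjR2=0.59 cvR2=0.58 n=57 components=1 features=5 top=ps_time_to_target_short
```

— the fraction of each clinical scale's variance explained by the
selected oculomotor parameters (high here by construction: one latent
severity drives the whole synthetic cohort), the complete-case count,
and the parameter contributing the largest normalized |standardized
coefficient|.

The same stages are available as a CLI (`oculomet simulate / extract /
associate / model / all`) and as library functions
(`oculomet.simulate_cohort`, `extract_profile`, `compute_composites`,
`spearman_with_fdr`, `exhaustive_feature_selection`, ...).

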