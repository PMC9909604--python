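# sumus-metrics

Movement metrics from wrist-worn smartwatch inertial sensors, validated
against metabolic-chamber energy expenditure.

Slowly progressive neuromuscular diseases need outcome measures that capture
everyday upper-limb activity, not just clinic-based functional tests. This
package implements the analysis layer for that problem: it turns 20 Hz
smartwatch IMU exports (user acceleration, rotation rate, attitude, …)
recorded during standardized low-intensity arm exercises into scalar
movement metrics and epoch-based activity counts, pairs them with
indirect-calorimetry energy expenditure from a whole-room metabolic chamber,
and runs the statistics that relate the two. A fully seeded synthetic-data
generator reproduces the study conditions with known ground truth, so the
entire chain is testable without any human data.

## Method

For each subject × exercise:

1. **Magnitudes.** The gravity-removed user acceleration **a** = (aₓ, a_y,
   a_z) and rotation rate **ω** are reduced to orientation-independent
   magnitudes ‖**a**‖ (m/s²) and ‖**ω**‖ (rad/s) per 20 Hz sample.
2. **Uniform window.** The onset of rhythmic movement is detected (centered
   moving RMS exceeding k = 3 × a baseline noise floor, sustained ≥ 2 s) and
   both series are cut to a uniform 500-s window (10,000 samples), so every
   subject contributes the same number of data points.
3. **Summaries.** Mean, sample SD, CV = SD/mean, max, min per window;
   cohort tables report the *average of the per-subject statistics*.
4. **Activity counts.** The acceleration magnitude is reduced to one value
   per 1-s epoch (per-epoch peak). With threshold T, *total* counts are
   epochs > T, *medium* > 2T, *low* in (T, 2T], so total = medium + low.
   Free arm exercises (metronome-paced at 15 movements/min) use a variable
   per-subject threshold T = mean + 2·SD of the window; the continuous
   hand-ergometer exercise (40–45 rpm) uses a fixed T = 0.05 m/s².
5. **Energy expenditure.** A chamber session is 30 min equilibration,
   30 min rest, then 4 × (10 min exercise + 10 min pause) in randomized
   order — 140 min at the chamber's 10-min block resolution. VO₂ converts
   as EE [kcal/min] = VO₂ [mL/min] / 1000 × 4.867, reported in kJ/min
   (× 4.184). ΔEEₖ = EE(exercise k) − EE(preceding rest/pause block).
6. **Statistics.** Spearman rank correlation and OLS regression of ΔEE on
   acceleration mean, rotation mean and total counts, per exercise;
   two-sided t-tests (unpaired for fasted vs non-fasted) at α = 0.05.

## Worked example

```bash
sumus generate --out fixture --seed 2024 --subjects 14
sumus analyze --in fixture --out out
python analysis/01_simulate_cohort.py   # same, as a scripted narrative
python analysis/02_movement_metrics.py
```

`02_movement_metrics.py` prints, for the seed-2024 cohort:

```
cohort acceleration (average of per-subject statistics):
 exercise_id  avg_of_means  avg_of_sds  avg_of_cvs  avg_of_max
           1          1.81        3.09        1.70       17.01
           2          1.71        2.86        1.66       15.70
           3          1.99        3.53        1.77       19.21
           4          3.34        0.15        0.05        3.57
```

Free arm exercises 1–3 average ≈ 1.7–2.0 m/s² with high within-window
variability (bursty movement every 4 s); the guided ergometer exercise 4 is
stronger on average (≈ 3.3 m/s²) but nearly constant (CV ≈ 0.05), which is
why it gets the fixed rather than the variable threshold.
`04_associations.py` then recovers the generator's movement→energy coupling:

```
pooled counts→ΔEE regression: slope 0.00377 kJ/min per count (r² 0.668, p 1.6e-14, n 56)
generator truth 0.004 -> relative error 5.7%
```

i.e. with only 14 subjects the pooled regression estimates the true coupling
slope within ~6%, while the per-exercise associations at n = 14 are mostly
non-significant — the small-sample behaviour such validation studies report.

## Layout

- `src/sumus/` — library: `io` (CSV dialects), `kinematics` (magnitudes,
  onset, window), `counts` (thresholds, epochs, tiers), `calorimetry`
  (protocol, ΔEE), `stats`, `synthetic` (generators), `pipeline`,
  `calibration`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property (hypothesis) and end-to-end validation suite.
- `docs/methods.md` — modelling assumptions, parameter defaults, numerical
  choices and limitations.
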