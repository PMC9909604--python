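# Methods

## Signal model and movement metrics

The watch reports gravity-removed *user acceleration* (m/s²) and *rotation
rate* (rad/s) on three device axes at a nominal 20 Hz. Movement intensity is
defined as the per-sample Euclidean norm of each triaxial channel. The norm
(rather than a dominant axis or gravity-inclusive acceleration) is chosen
because it is invariant under re-orientation of the watch on the wrist — a
property the test suite asserts against randomized rotations — and because
it yields a single scalar per instant, which is what the downstream
summaries and counts need. Samples with NaN components in a channel are
excluded from that channel's magnitude series with a log entry.

All summaries use the sample SD (n − 1 denominator) and CV = SD/mean; a CV
with mean ≤ 1e-12 is reported as NaN with a warning. Cohort tables are
*averages of the per-subject statistics* (mean of means, mean of CVs, …),
never statistics of pooled samples — the two differ whenever subjects have
unequal variability.

## Onset detection and the uniform window

Recording starts before movement does, so every series is cut to a uniform
500-s analysis window (10,000 samples at 20 Hz) starting at the detected
onset of rhythmic movement. The detector compares a centered moving RMS
(window = `sustain`, default 2 s) against `k` (default 3) times a baseline
noise level, and takes the earliest time where the RMS exceeds that
threshold and stays above it for at least `sustain` seconds.

The baseline level is the 20th percentile of the moving RMS within the first
`baseline_window` (default 5 s). A low quantile rather than the plain RMS of
the opening seconds is a deliberate design choice: it is a noise-floor
estimate. On a quiet baseline the two coincide, but when movement is already
under way at t = 0 the plain RMS is contaminated by the movement itself and
the criterion can never fire, whereas the inter-burst quantile still
reflects the noise floor and the detector correctly returns 0. Detection
failure raises an error rather than guessing; a manual onset can be supplied
per subject × exercise through the run configuration, and in a cohort run a
failed trace is skipped and enumerated in the report instead of aborting the
cohort. A centered RMS necessarily fires up to half a window before the
first movement sample; windows therefore start marginally early, never late,
which only adds a fraction of a second of noise floor to a 500-s window.

## Activity counts

The acceleration magnitude is reduced to one value per non-overlapping 1-s
epoch. The default reducer is the per-epoch **peak**: with one movement
burst every 4 s, a burst registers at its full amplitude in whichever epoch
it falls, whereas a per-epoch mean would dilute a 1-s burst by the quiet
remainder of its epoch. The mean reducer remains selectable in the
configuration.

Thresholding is strict (value > T), so a constant series produces zero
counts under its own variable threshold (mean + 2·SD of a constant equals
the constant). The tiers are implemented as a partition — low ∈ (T, 2T],
medium ∈ (2T, ∞) — so that total = medium + low holds identically; this is
also the reading under which the published cohort count tables are
internally additive. The variable threshold (mean + 2·SD) is always computed
on the same trimmed 500-s window that is being counted, per subject ×
exercise. The fixed 0.05 m/s² threshold is used for the ergometer exercise,
whose continuous signal has no inter-movement noise floor for a variable
threshold to separate.

## Calorimetry

A chamber session is modelled at the instrument's 10-min block resolution
with the fixed template 3 × equilibration + 3 × rest + 4 × (exercise +
pause) = 14 blocks = 140 min; no sub-block interpolation is attempted.
VO₂ (mL/min) is converted to energy as (VO₂ / 1000) × 4.867 kcal/min — the
mL→L step is a division; a multiplication would be dimensionally inverted —
and kcal→kJ uses the thermochemical factor 4.184.

ΔEE pairing is genuinely ambiguous: "resting EE" can mean the block
immediately preceding each exercise or the initial 30-min resting phase.
Both are implemented (`preceding_rest`, the default, and `session_rest`);
the pairing used is recorded in the report and neither is claimed to be
canonical. ΔEE may be negative — a low-intensity exercise block can fall
below a noisy resting reference, as the published minima do.

## Synthetic data generator

The generator emulates the validation-study conditions and is the ground
truth for every end-to-end test:

* **Free arm exercises (1–3):** raised-cosine acceleration bursts of width
  ~1 s, one per 4 s (metronome at 15 movements/min), each along a random
  unit direction with per-burst amplitude jitter (±50% uniform by default),
  over i.i.d. Gaussian axis noise. Default peak amplitudes (11, 10.5,
  12.5 m/s² for exercises 1–3, subject-scattered ±15%) and noise SDs
  (0.2–0.4 m/s²) were chosen once so the cohort-average window means land
  in the 1.5–3.5 m/s² range typical of slow arm movement, and are not
  revisited.
* **Ergometer (4):** circular crank motion — an acceleration vector of
  near-constant magnitude (3.2 m/s² ± drift) rotating at the cadence
  (drawn uniformly from 40–45 rpm) — so the magnitude series has a low CV
  by construction while individual axes peak spectrally at cadence/60 Hz.
* **Chamber:** the 140-min template with per-block i.i.d. Gaussian noise
  (default SD 0.15 kJ/min) around resting EE ~ N(5.0, 0.6) kJ/min.
* **Coupling:** each subject's per-exercise ΔEE truth is
  `delta_base + slope × counts + N(0, delta_sd)` with defaults 0.1 kJ/min,
  0.004 kJ/min per count and 0.3 kJ/min. `counts` are the total activity
  counts *measured on that subject's generated trace through the standard
  analysis path*. Coupling to realized rather than idealized movement makes
  the recovery invariant exact in the noise-free limit: regressing
  pipeline ΔEE on pipeline counts is then free of errors-in-variables
  attenuation, so estimated slope → true slope as chamber noise → 0.
* Cohort traces are 540 s: a 10-s quiet lead-in (the app is started before
  movement begins), 500 s of analyzable movement, and slack for onsets that
  are detected late on noisy subjects. Stand-alone generator calls default
  to 500 s with no lead-in, which gives exactly 125 bursts at 15/min.
* Anthropometrics are drawn around the reference cohort (age 34.6 ± 9.2 y,
  height 171 ± 10.5 cm, weight 72 ± 12 kg); one third of subjects are
  flagged as overnight-fasted. Fasting has no effect on generated ΔEE,
  matching the absence of a detectable fasted/non-fasted difference.

What the generator does **not** model: autocorrelated or heteroscedastic
sensor noise, biomechanically realistic multi-joint arm kinematics,
within-session fatigue drift, postprandial thermogenesis dynamics, or
disease-specific movement patterns. Passing tests therefore demonstrate the
correctness and calibration of the analysis chain under the stated signal
model, not the clinical validity of the metrics on patient data.

## Statistical choices

* Spearman's rho uses average ranks for ties; its p-value uses the
  large-sample t approximation, with exact permutation enumeration
  available for n ≤ 10.
* OLS simple regression reports slope, intercept, Pearson r, r² (= r²) and
  the two-sided slope p-value.
* t-tests are two-sided, Student's (equal-variance) for independent groups,
  paired within subject; zero paired differences return t = 0, p = 1.
* A flat α = 0.05 is applied with no multiple-testing correction; reports
  state the number of tests run so readers can judge the multiplicity.
* Calibration is verified by simulation: type-I error of the t-test over
  2,000 null replicates must lie in [3.5%, 6.5%], power at a 2·SD shift
  (n = 20) above 80%, and the pooled counts→ΔEE regression under zero
  coupling must reject at ≈ 5% over 500 cohort replicates of 14 subjects.
  Problem sizes (2,000 / 500 replicates, 100-subject recovery cohorts) are
  the package's chosen compromise between Monte-Carlo error and runtime on
  a single CPU.

## Numerical and serialization choices

* IMU CSVs are written with 17-significant-digit floats and parsed with
  round-trip float precision, so write→read→write is byte-idempotent and
  read∘write is the identity on the in-memory trace.
* Report CSVs round to 6 significant digits for stable diffs; report.json
  keeps full precision.
* Timestamps (epoch or elapsed) are always re-based to elapsed seconds;
  a trace is flagged when its median sampling interval deviates more than
  20% from nominal, and gaps (> 2 sampling periods) are enumerated.
* Trailing partial epochs and partial final samples of a window are
  dropped, never padded.
* All generators run on `numpy.random.default_rng` with explicit seeds;
  cohort generation derives per-subject child seeds from the master seed,
  so every artifact is reproducible bit-for-bit given the seed.

## Known limitations

* The onset detector is a single-scale RMS rule; movements that ramp up
  gradually over tens of seconds would be detected late (manual onsets
  exist for that case).
* Activity counts are acceleration-only (rotation rate is summarized but
  not counted), and no proprietary actigraphy count algorithm is
  reproduced.
* The chamber model's 10-min resolution forbids within-exercise dynamics;
  multilevel/repeated-measures correlation models are out of scope at that
  resolution.
* Cohort tables at n = 14 carry the expected small-sample volatility; the
  per-exercise association tables are reported with raw p-values and no
  shrinkage.
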