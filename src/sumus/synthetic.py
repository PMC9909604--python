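"""Seeded generators for IMU traces, chamber sessions and whole cohorts.

Three archetypes reproduce the study conditions:

* ``rhythmic_burst`` — free arm exercises paced by a metronome at
  15 movements/min: raised-cosine acceleration bursts (~1 s wide) every
  60/rate s, each along a random unit direction with per-burst amplitude
  jitter, over a Gaussian noise floor on all three axes.
* ``continuous_ergometer`` — hand biking at 40–45 rpm: a rotating
  acceleration vector of near-constant magnitude (circular motion), so the
  magnitude series has a low coefficient of variation by construction while
  individual axes oscillate at the cadence frequency.
* chamber sessions — the 140-min protocol (30 min equilibration, 30 min
  rest, 4 × [10 min exercise + 10 min pause]) with per-block Gaussian noise.

``gen_cohort`` draws per-subject movement and metabolic parameters, couples
each subject's per-exercise ΔEE to the activity counts actually measured on
their generated trace (ΔEE = base + slope · counts + noise), and stores all
ground truth, so every downstream estimate has a known expectation.
Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calorimetry import ChamberSeries, ProtocolTemplate, segment_timeline
from .counts import count_activity, epoch_reduce, fixed_threshold, variable_threshold
from .io import ImuTrace, SubjectRecord, write_subjects_csv, write_sumus_csv
from .kinematics import detect_onset, trim_window, vector_magnitude

#: Metronome pace for the free arm exercises, movements per minute.
RHYTHMIC_RATE_PER_MIN = 15.0
#: Ergometer cadence band, rounds per minute.
ERGOMETER_RPM = (40.0, 45.0)


@dataclass
class GeneratorConfig:
    """Parameters of one synthetic IMU trace.

    ``movement_rate`` is movements/min for ``rhythmic_burst`` and rounds/min
    (cadence) for ``continuous_ergometer``. ``burst_amplitude`` is the peak
    acceleration of a movement (m/s²); ``rotation_amplitude`` the analogous
    rotation-rate peak (rad/s). ``amplitude_jitter`` is the relative
    half-width of the per-burst uniform amplitude scatter. ``lead_in_s``
    seconds of noise-only signal precede the first movement.
    """

    seed: int = 0
    rate: float = 20.0
    duration: float = 500.0
    archetype: str = "rhythmic_burst"
    movement_rate: float = RHYTHMIC_RATE_PER_MIN
    burst_amplitude: float = 11.0
    noise_sd: float = 0.3
    rotation_amplitude: float = 12.0
    rotation_noise_sd: float = 0.3
    amplitude_jitter: float = 0.5
    burst_width_s: float = 1.0
    lead_in_s: float = 0.0

    def __post_init__(self) -> None:
        if self.archetype not in ("rhythmic_burst", "continuous_ergometer"):
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if min(self.burst_amplitude, self.noise_sd, self.rotation_amplitude) < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.movement_rate <= 0:
            raise ValueError("movement_rate must be positive")


@dataclass
class SyntheticCohort:
    """A generated cohort with full ground truth.

    ``traces`` maps (subject_id, exercise_id) to the IMU trace, ``chamber``
    maps subject_id to the raw (unlabeled) chamber series, ``orders`` holds
    each subject's randomized exercise order, and ``truth`` records every
    generating parameter (resting EE, per-exercise ΔEE, measured counts,
    coupling slope).
    """

    subjects: list
    traces: dict
    chamber: dict
    orders: dict
    truth: dict


def expected_burst_count(config: GeneratorConfig) -> int:
    """Number of movement bursts whose centers fall inside the trace."""
    period = 60.0 / config.movement_rate
    first_center = config.lead_in_s + period / 2.0
    if first_center >= config.duration:
        return 0
    return int(math.floor((config.duration - first_center) / period)) + 1


def _unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _burst_channel(
    t: np.ndarray,
    rng: np.random.Generator,
    amplitude: float,
    noise_sd: float,
    jitter: float,
    period: float,
    width: float,
    lead_in: float,
    duration: float,
) -> np.ndarray:
    """Raised-cosine bursts along random per-burst directions plus noise."""
    n_bursts = expected_burst_count(
        GeneratorConfig(duration=duration, movement_rate=60.0 / period,
                        lead_in_s=lead_in)
    )
    phase = t - lead_in
    idx = np.floor(phase / period).astype(int)
    idx = np.clip(idx, 0, max(n_bursts - 1, 0))
    centers = lead_in + (idx + 0.5) * period
    u = (t - centers) / width
    env = np.where((np.abs(u) <= 0.5) & (phase >= 0) & (centers < duration),
                   0.5 * (1.0 + np.cos(2.0 * np.pi * u)), 0.0)
    amps = amplitude * (1.0 + jitter * rng.uniform(-1.0, 1.0, size=max(n_bursts, 1)))
    dirs = _unit_vectors(rng, max(n_bursts, 1))
    signal = env[:, None] * amps[idx, None] * dirs[idx]
    return signal + rng.normal(0.0, noise_sd, size=(len(t), 3))


def gen_rhythmic_trace(config: GeneratorConfig, subject_id: str = "S00",
                       exercise_id: int = 1) -> ImuTrace:
    """Metronome-paced burst trace (free arm exercises).

    At the default 15 movements/min a 500-s trace carries 125 bursts, one
    every 4 s, centered at lead_in + (b + ½)·period.
    """
    if config.archetype != "rhythmic_burst":
        raise ValueError("config archetype must be rhythmic_burst")
    period = 60.0 / config.movement_rate
    if config.duration - config.lead_in_s < period:
        raise ValueError("duration too short for a single movement period")
    rng = np.random.default_rng(config.seed)
    n = int(round(config.rate * config.duration))
    t = np.arange(n) / config.rate

    ua = _burst_channel(t, rng, config.burst_amplitude, config.noise_sd,
                        config.amplitude_jitter, period, config.burst_width_s,
                        config.lead_in_s, config.duration)
    rot = _burst_channel(t, rng, config.rotation_amplitude,
                         config.rotation_noise_sd, config.amplitude_jitter,
                         period, config.burst_width_s, config.lead_in_s,
                         config.duration)
    return _assemble_trace(subject_id, exercise_id, t, ua, rot, config.rate)


def gen_continuous_trace(config: GeneratorConfig, subject_id: str = "S00",
                         exercise_id: int = 4) -> ImuTrace:
    """Hand-ergometer trace: rotating acceleration vector at the cadence.

    Circular hand-crank motion produces a centripetal acceleration vector
    that rotates at cadence/60 Hz with near-constant magnitude, so the
    magnitude series is homogeneous (low CV) while each axis shows a clean
    spectral peak at the cadence frequency.
    """
    if config.archetype != "continuous_ergometer":
        raise ValueError("config archetype must be continuous_ergometer")
    rng = np.random.default_rng(config.seed)
    n = int(round(config.rate * config.duration))
    t = np.arange(n) / config.rate
    f = config.movement_rate / 60.0  # Hz
    if config.duration - config.lead_in_s < 1.0 / f:
        raise ValueError("duration too short for a single crank revolution")

    def channel(amplitude: float, noise_sd: float) -> np.ndarray:
        phi0 = rng.uniform(0.0, 2.0 * np.pi)
        # slow multiplicative amplitude drift (effort wobble)
        drift = 1.0 + config.amplitude_jitter * np.interp(
            t, np.linspace(0, config.duration, 20),
            rng.uniform(-1.0, 1.0, size=20),
        )
        phase = 2.0 * np.pi * f * t + phi0
        planar = amplitude * drift[:, None] * np.column_stack(
            [np.cos(phase), np.sin(phase), np.zeros_like(phase)]
        )
        basis = _random_rotation(rng)
        sig = planar @ basis.T
        sig[t < config.lead_in_s] = 0.0
        return sig + rng.normal(0.0, noise_sd, size=(n, 3))

    ua = channel(config.burst_amplitude, config.noise_sd)
    rot = channel(config.rotation_amplitude, config.rotation_noise_sd)
    return _assemble_trace(subject_id, exercise_id, t, ua, rot, config.rate)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3×3 rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _assemble_trace(subject_id: str, exercise_id: int, t: np.ndarray,
                    ua: np.ndarray, rot: np.ndarray, rate: float) -> ImuTrace:
    n = len(t)
    quat = np.tile([0.0, 0.0, 0.0, 1.0], (n, 1))
    gravity = np.tile([0.0, 0.0, -1.0], (n, 1))
    return ImuTrace(
        subject_id=subject_id,
        exercise_id=exercise_id,
        t=t,
        user_acc=ua,
        rotation_rate=rot,
        gravity=gravity,
        attitude_quat=quat,
        nominal_rate=rate,
    )


def gen_chamber_series(
    resting_ee: float,
    delta_truth: Sequence[float],
    noise_sd: float,
    order: Sequence[int],
    seed: int = 0,
    subject_id: str = "S00",
) -> ChamberSeries:
    """140-min chamber session with known per-exercise EE increments.

    ``delta_truth[k-1]`` is the EE increment of exercise k (kJ/min).
    Equilibration, rest and pause blocks sit at ``resting_ee``; exercise
    blocks at ``resting_ee + delta_truth``; every 10-min block gets
    independent Gaussian noise.
    """
    delta_truth = np.asarray(delta_truth, dtype=float)
    if delta_truth.shape != (4,):
        raise ValueError("delta_truth must have one increment per exercise (4)")
    template = ProtocolTemplate(order=list(order))
    labels = template.phases()
    rng = np.random.default_rng(seed)
    ee = np.full(len(labels), float(resting_ee))
    for i, lab in enumerate(labels):
        if lab.startswith("exercise_"):
            k = int(lab.split("_")[1])
            ee[i] += delta_truth[k - 1]
    ee = ee + rng.normal(0.0, noise_sd, size=len(labels))
    t = np.arange(len(labels)) * 10.0
    return ChamberSeries(t=t, ee=ee, phase=None, subject_id=subject_id)


# --- cohort-level defaults: the emulated study conditions ------------------

#: Per-exercise peak burst amplitudes (m/s²) for the free arm exercises.
COHORT_BURST_AMPLITUDE = {1: 11.0, 2: 10.5, 3: 12.5}
#: Per-exercise peak rotation-rate amplitudes (rad/s).
COHORT_ROTATION_AMPLITUDE = {1: 12.8, 2: 7.2, 3: 16.0, 4: 1.2}
#: Ergometer centripetal acceleration magnitude (m/s²).
COHORT_ERGOMETER_AMPLITUDE = 3.2
#: Resting energy expenditure distribution, kJ/min (adult seated rest).
COHORT_RESTING_EE = (5.0, 0.6)
#: Default ΔEE coupling: kJ/min per activity count, plus base and scatter.
DEFAULT_COUPLING_SLOPE = 0.004
DEFAULT_DELTA_BASE = 0.1
DEFAULT_DELTA_SD = 0.3
DEFAULT_CHAMBER_NOISE_SD = 0.15
#: Trace length: 10-s quiet lead-in plus 500 s of movement and slack for
#: late-detected onsets.
COHORT_TRACE_DURATION = 540.0
COHORT_LEAD_IN = 10.0


def _measure_total_counts(trace: ImuTrace, exercise_id: int,
                          true_onset: float = COHORT_LEAD_IN) -> int:
    """Total activity counts through the standard analysis path.

    When onset detection fails (or fires too late to leave a full window) the
    generator falls back to the onset it knows to be true, so every subject
    always has a ground-truth count.
    """
    from .kinematics import OnsetNotFoundError

    acc = vector_magnitude(trace, "user_acc")
    try:
        onset = detect_onset(acc)
        window = trim_window(acc, None, onset)
    except (OnsetNotFoundError, ValueError):
        window = trim_window(acc, None, true_onset)
    epochs = epoch_reduce(window.acc)
    if exercise_id == 4:
        thr = fixed_threshold()
    else:
        thr = variable_threshold(window.acc)
    return count_activity(epochs, thr).total


def gen_cohort(
    n: int,
    coupling_slope: float = DEFAULT_COUPLING_SLOPE,
    seed: int = 0,
    fasted_fraction: float = 1.0 / 3.0,
    delta_base: float = DEFAULT_DELTA_BASE,
    delta_sd: float = DEFAULT_DELTA_SD,
    chamber_noise_sd: float = DEFAULT_CHAMBER_NOISE_SD,
) -> SyntheticCohort:
    """Generate a full cohort: subjects, 4 traces each, chamber sessions.

    Each subject's ΔEE truth is ``delta_base + coupling_slope × counts +
    N(0, delta_sd)`` where counts are the total activity counts measured on
    that subject's own generated trace through the standard pipeline path —
    the coupling is between energy cost and realized movement, so a
    regression of estimated ΔEE on estimated counts recovers the slope
    without errors-in-variables attenuation as noise → 0.
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    subjects: list[SubjectRecord] = []
    traces: dict = {}
    chamber: dict = {}
    orders: dict = {}
    truth: dict = {
        "coupling_slope": coupling_slope,
        "delta_base": delta_base,
        "delta_sd": delta_sd,
        "chamber_noise_sd": chamber_noise_sd,
        "subjects": {},
    }

    n_fasted = int(round(n * fasted_fraction))
    fasted_flags = np.zeros(n, dtype=bool)
    fasted_flags[rng.permutation(n)[:n_fasted]] = True

    for i in range(n):
        sid = f"S{i:02d}"
        height = float(rng.normal(171.0, 10.5))
        weight = float(np.clip(rng.normal(72.0, 12.0), 45.0, 120.0))
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                age=float(np.clip(rng.normal(34.6, 9.2), 20.0, 55.0)),
                sex=str(rng.choice(["F", "M"])),
                height_cm=height,
                weight_kg=weight,
                fasted=bool(fasted_flags[i]),
            )
        )
        noise_sd = float(rng.uniform(0.2, 0.4))
        subject_truth: dict = {"noise_sd": noise_sd, "counts": {},
                               "delta_truth": {}, "amplitude": {}}

        for k in (1, 2, 3):
            amp = float(max(2.0, rng.normal(COHORT_BURST_AMPLITUDE[k],
                                            0.15 * COHORT_BURST_AMPLITUDE[k])))
            cfg = GeneratorConfig(
                seed=int(rng.integers(0, 2**31 - 1)),
                duration=COHORT_TRACE_DURATION,
                lead_in_s=COHORT_LEAD_IN,
                archetype="rhythmic_burst",
                movement_rate=RHYTHMIC_RATE_PER_MIN,
                burst_amplitude=amp,
                noise_sd=noise_sd,
                rotation_amplitude=COHORT_ROTATION_AMPLITUDE[k],
                rotation_noise_sd=noise_sd,
            )
            traces[(sid, k)] = gen_rhythmic_trace(cfg, sid, k)
            subject_truth["amplitude"][k] = amp
        amp4 = float(max(1.0, rng.normal(COHORT_ERGOMETER_AMPLITUDE, 0.3)))
        cfg4 = GeneratorConfig(
            seed=int(rng.integers(0, 2**31 - 1)),
            duration=COHORT_TRACE_DURATION,
            lead_in_s=COHORT_LEAD_IN,
            archetype="continuous_ergometer",
            movement_rate=float(rng.uniform(*ERGOMETER_RPM)),
            burst_amplitude=amp4,
            noise_sd=0.05,
            rotation_amplitude=COHORT_ROTATION_AMPLITUDE[4],
            rotation_noise_sd=0.05,
            amplitude_jitter=0.02,
        )
        traces[(sid, 4)] = gen_continuous_trace(cfg4, sid, 4)
        subject_truth["amplitude"][4] = amp4

        resting = float(rng.normal(*COHORT_RESTING_EE))
        delta_truth = np.empty(4)
        for k in (1, 2, 3, 4):
            counts = _measure_total_counts(traces[(sid, k)], k)
            subject_truth["counts"][k] = counts
            delta_truth[k - 1] = (delta_base + coupling_slope * counts
                                  + rng.normal(0.0, delta_sd))
            subject_truth["delta_truth"][k] = float(delta_truth[k - 1])
        subject_truth["resting_ee"] = resting

        order = [int(x) for x in rng.permutation([1, 2, 3, 4])]
        orders[sid] = order
        chamber[sid] = gen_chamber_series(
            resting, delta_truth, chamber_noise_sd, order,
            seed=int(rng.integers(0, 2**31 - 1)), subject_id=sid,
        )
        truth["subjects"][sid] = subject_truth

    return SyntheticCohort(subjects=subjects, traces=traces, chamber=chamber,
                           orders=orders, truth=truth)


def write_cohort_fixture(cohort: SyntheticCohort, out_dir: str) -> None:
    """Write a complete fixture directory: per-subject IMU and chamber CSVs,
    subjects.csv, sessions.json (exercise order + fasted flag) and
    truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (sid, k), trace in cohort.traces.items():
        write_sumus_csv(trace, str(out / f"imu_{sid}_ex{k}.csv"))
    for sid, series in cohort.chamber.items():
        pd.DataFrame(
            {"t_min": series.t, "value": series.ee,
             "value_kind": "ee_kj_min"}
        ).to_csv(out / f"chamber_{sid}.csv", index=False)
    write_subjects_csv(cohort.subjects, str(out / "subjects.csv"))
    sessions = {
        sid: {"order": cohort.orders[sid],
              "fasted": bool(next(s.fasted for s in cohort.subjects
                                  if s.subject_id == sid))}
        for sid in cohort.orders
    }
    (out / "sessions.json").write_text(json.dumps(sessions, indent=2,
                                                  sort_keys=True))
    (out / "truth.json").write_text(json.dumps(cohort.truth, indent=2,
                                               sort_keys=True))
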