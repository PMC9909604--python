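"""Scalar magnitude extraction, movement-onset detection and window trimming.

Movement intensity is summarized as the Euclidean norm of the gravity-removed
triaxial user acceleration (m/s²) and of the triaxial rotation rate (rad/s).
Using the norm rather than a single axis makes the metric independent of how
the watch is oriented on the wrist. Every exercise is trimmed to a uniform
500-s analysis window starting at the detected onset of rhythmic movement,
so that all subjects contribute the same number of data points.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import uniform_filter1d

from .io import ImuTrace

logger = logging.getLogger(__name__)

#: Uniform analysis-window length, seconds (8 min 20 s).
WINDOW_DURATION_S = 500.0

CV_UNDEFINED = float("nan")


class OnsetNotFoundError(RuntimeError):
    """The onset criterion was never met; a manual onset may be supplied."""


@dataclass
class ScalarSeries:
    """A scalar magnitude series sampled at a (nominally) uniform rate."""

    t: np.ndarray
    values: np.ndarray
    units: str  # "m/s^2" or "rad/s"
    rate: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.shape != self.values.shape:
            raise ValueError("t and values must have the same length")
        if np.any(self.values[np.isfinite(self.values)] < 0):
            raise ValueError("magnitude values must be non-negative")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) + 1.0 / self.rate if len(self) else 0.0


@dataclass
class ExerciseWindow:
    """Acceleration and rotation magnitudes trimmed to the uniform window."""

    subject_id: str
    exercise_id: int
    acc: ScalarSeries
    rot: Optional[ScalarSeries]
    duration: float = WINDOW_DURATION_S

    def __post_init__(self) -> None:
        if self.rot is not None and not np.array_equal(self.acc.t, self.rot.t):
            raise ValueError("acc and rot must share the same time base")


@dataclass
class SeriesSummary:
    """Mean, sample SD, CV (= SD/mean), max and min of one scalar series."""

    mean: float
    sd: float
    cv: float
    max: float
    min: float


def vector_magnitude(trace: ImuTrace, channel: str = "user_acc") -> ScalarSeries:
    """Euclidean norm of a triaxial channel, per sample.

    ``channel`` is ``"user_acc"`` (→ m/s²) or ``"rotation_rate"`` (→ rad/s).
    Samples with NaN components are dropped from the output with a log entry.
    """
    units = {"user_acc": "m/s^2", "rotation_rate": "rad/s"}
    if channel not in units:
        raise ValueError(f"unknown channel {channel!r}")
    block = getattr(trace, channel)
    if block is None:
        raise ValueError(f"trace has no {channel} channel")
    valid = ~np.isnan(block).any(axis=1)
    if not np.all(valid):
        logger.warning(
            "%s/%d: skipping %d invalid %s samples",
            trace.subject_id, trace.exercise_id, int((~valid).sum()), channel,
        )
    mags = np.linalg.norm(block[valid], axis=1)
    return ScalarSeries(t=trace.t[valid], values=mags, units=units[channel],
                        rate=trace.nominal_rate)


def moving_rms(values: np.ndarray, window_samples: int) -> np.ndarray:
    """Centered root-mean-square over a sliding window (edges use the nearest
    valid window)."""
    window_samples = max(1, int(window_samples))
    sq = np.asarray(values, dtype=float) ** 2
    return np.sqrt(uniform_filter1d(sq, size=window_samples, mode="nearest"))


def detect_onset(
    series: ScalarSeries,
    baseline_window: float = 5.0,
    k: float = 3.0,
    sustain: float = 2.0,
) -> float:
    """Locate the start of sustained rhythmic movement.

    A centered moving RMS with window ``sustain`` is compared against
    ``k`` times the baseline noise level, estimated as a low quantile (20th
    percentile) of the moving RMS within the first ``baseline_window``
    seconds. The low quantile is a noise-floor estimate: on a quiet baseline
    it coincides with the plain baseline RMS, while on a recording where
    movement is already under way at t = 0 it still reflects the inter-burst
    noise, so the detector correctly returns 0 instead of failing. The onset
    is the earliest time where the moving RMS exceeds the threshold and stays
    above it for at least ``sustain`` seconds.

    Raises :class:`OnsetNotFoundError` when the criterion is never met; the
    caller may then supply a manual onset to :func:`trim_window`.
    """
    if series.duration <= baseline_window + sustain:
        raise ValueError("series shorter than baseline_window + sustain")
    win = max(1, int(round(sustain * series.rate)))
    rms = moving_rms(series.values, win)

    base_mask = series.t < series.t[0] + baseline_window
    noise_level = float(np.quantile(rms[base_mask], 0.20))
    threshold = k * max(noise_level, np.finfo(float).tiny)

    above = rms > threshold
    # run-length encode: find starts of runs of True lasting >= win samples
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    for s, e in zip(starts, ends):
        if e - s >= win:
            return float(series.t[s])
    raise OnsetNotFoundError(
        f"moving RMS never exceeded {k} x baseline for {sustain} s"
    )


def trim_window(
    acc: ScalarSeries,
    rot: Optional[ScalarSeries],
    onset: float,
    duration: float = WINDOW_DURATION_S,
    subject_id: str = "",
    exercise_id: int = 0,
) -> ExerciseWindow:
    """Cut both magnitude series to [onset, onset + duration).

    The window holds exactly ``round(duration * rate)`` samples (10,000 at
    20 Hz for the default 500 s); a partial final sample is dropped. Raises
    ``ValueError`` when less than ``duration`` of signal remains after onset.
    """
    n = int(round(duration * acc.rate))
    start = int(np.searchsorted(acc.t, onset))
    available = (len(acc) - start) / acc.rate
    if start + n > len(acc):
        raise ValueError(
            f"only {available:.1f} s available after onset {onset:.2f} s; "
            f"{duration:.0f} s required"
        )
    sl = slice(start, start + n)
    acc_w = ScalarSeries(acc.t[sl], acc.values[sl], acc.units, acc.rate)
    rot_w = None
    if rot is not None:
        if len(rot) != len(acc):
            raise ValueError("acc and rot series must be aligned")
        rot_w = ScalarSeries(rot.t[sl], rot.values[sl], rot.units, rot.rate)
    return ExerciseWindow(subject_id=subject_id, exercise_id=exercise_id,
                          acc=acc_w, rot=rot_w, duration=duration)


def summarize_series(series: ScalarSeries) -> SeriesSummary:
    """Mean, sample SD (n−1 denominator), CV = SD/mean, max and min.

    When the mean is ≤ 1e-12 the CV is undefined and reported as NaN with a
    warning.
    """
    if len(series) == 0:
        raise ValueError("cannot summarize an empty series")
    v = series.values
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    if mean > 1e-12:
        cv = sd / mean
    else:
        warnings.warn("series mean is ~0; CV undefined", RuntimeWarning,
                      stacklevel=2)
        cv = CV_UNDEFINED
    return SeriesSummary(mean=mean, sd=sd, cv=cv,
                         max=float(np.max(v)), min=float(np.min(v)))
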