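"""Epoch-based activity counts from an acceleration magnitude series.

The magnitude series is reduced to one value per non-overlapping 1-s epoch
(per-epoch peak by default) and compared against a threshold T:

* total counts  — epochs with value strictly above T
* medium counts — epochs strictly above 2·T
* low counts    — epochs in (T, 2·T], so that total = medium + low

Free rhythmic exercises use a per-subject, per-exercise *variable* threshold
at mean + 2·SD of the trimmed window (robust to inter-subject noise
differences); the continuous ergometer exercise uses a *fixed* 0.05 m/s²
threshold because its signal has no inter-movement silence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import ScalarSeries

#: Fixed threshold for continuous (ergometer) movement, m/s².
FIXED_THRESHOLD_MS2 = 0.05


class CountsDataError(ValueError):
    """Epoch values violate a data invariant (negative magnitudes)."""


@dataclass(frozen=True)
class ThresholdSpec:
    kind: str  # "variable" | "fixed"
    value: float  # m/s²
    provenance: str

    def __post_init__(self) -> None:
        if self.kind not in ("variable", "fixed"):
            raise ValueError(f"unknown threshold kind {self.kind!r}")
        if self.value < 0:
            raise ValueError("threshold must be non-negative")


@dataclass(frozen=True)
class ActivityCounts:
    total: int
    medium: int
    low: int
    n_epochs: int
    threshold: ThresholdSpec
    epoch_s: float = 1.0

    def __post_init__(self) -> None:
        if self.total != self.medium + self.low:
            raise ValueError("tier counts must partition: total = medium + low")
        if not (0 <= self.total <= self.n_epochs):
            raise ValueError("total counts must lie in [0, n_epochs]")
        if min(self.total, self.medium, self.low) < 0:
            raise ValueError("counts must be non-negative")


def variable_threshold(window_acc: ScalarSeries) -> ThresholdSpec:
    """Per-window threshold at mean + 2 × sample SD of the acceleration."""
    if len(window_acc) == 0:
        raise ValueError("cannot compute a threshold from an empty window")
    v = window_acc.values
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    return ThresholdSpec(
        kind="variable",
        value=mean + 2.0 * sd,
        provenance=(
            f"mean + 2*SD of {len(v)}-sample window "
            f"[{window_acc.t[0]:.2f}, {window_acc.t[-1]:.2f}] s"
        ),
    )


def fixed_threshold(value: float = FIXED_THRESHOLD_MS2) -> ThresholdSpec:
    """Fixed threshold, 0.05 m/s² by default, identical for every subject."""
    return ThresholdSpec(kind="fixed", value=value,
                         provenance=f"fixed {value} m/s^2")


def epoch_reduce(series: ScalarSeries, epoch_s: float = 1.0,
                 reducer: str = "peak") -> np.ndarray:
    """Reduce the series to one value per complete, non-overlapping epoch.

    ``reducer`` is ``"peak"`` (per-epoch maximum, the default — a burst
    anywhere inside the epoch registers at its full amplitude) or ``"mean"``.
    A trailing partial epoch is dropped.
    """
    if series.rate < 1.0 / epoch_s:
        raise ValueError("sampling rate below one sample per epoch")
    spp = int(round(epoch_s * series.rate))
    n_epochs = len(series) // spp
    if n_epochs == 0:
        raise ValueError("series shorter than one epoch")
    block = series.values[: n_epochs * spp].reshape(n_epochs, spp)
    if reducer == "peak":
        return block.max(axis=1)
    if reducer == "mean":
        return block.mean(axis=1)
    raise ValueError(f"unknown reducer {reducer!r}")


def count_activity(epoch_values: np.ndarray,
                   threshold: ThresholdSpec,
                   epoch_s: float = 1.0) -> ActivityCounts:
    """Tiered counts of epochs exceeding the threshold (strict inequality).

    Strict comparison means a constant series yields zero counts under its
    own variable threshold (mean + 2·SD of a constant equals the constant).
    """
    v = np.asarray(epoch_values, dtype=float)
    if np.any(v < 0):
        raise CountsDataError("epoch values are magnitudes and cannot be negative")
    T = threshold.value
    total = int(np.sum(v > T))
    medium = int(np.sum(v > 2.0 * T))
    return ActivityCounts(total=total, medium=medium, low=total - medium,
                          n_epochs=len(v), threshold=threshold, epoch_s=epoch_s)
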