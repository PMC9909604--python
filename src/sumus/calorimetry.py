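"""Metabolic-chamber session timeline and exercise-vs-rest ΔEE.

A whole-room indirect calorimeter measures energy expenditure with an
effective temporal resolution of one value per 10-min block. A session
follows a fixed template: 30 min air equilibration, 30 min resting EE, then
four 10-min exercises in randomized order, each followed by a 10-min
complete rest — 140 min and 14 blocks in total.

ΔEE for exercise k is the exercise-block EE minus a resting reference, which
is either the block immediately preceding the exercise (default) or the mean
of the initial 30-min resting phase. Oxygen consumption is converted with a
caloric equivalent of 4.867 kcal per litre O₂; energies are reported in
kJ/min (1 kcal = 4.184 kJ, thermochemical).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

#: Caloric equivalent of oxygen, kcal per litre O₂.
KCAL_PER_L_O2 = 4.867
#: Thermochemical calorie, kJ per kcal.
KJ_PER_KCAL = 4.184
#: Chamber temporal resolution, minutes per block.
BLOCK_MIN = 10.0


class ConfigurationError(ValueError):
    """The session configuration is missing or inconsistent."""


@dataclass
class ProtocolTemplate:
    """Session layout: equilibration, rest, then 4 × (exercise + pause)."""

    order: Optional[Sequence[int]] = None  # permutation of exercise ids 1..4
    equilibration_min: float = 30.0
    rest_min: float = 30.0
    exercise_min: float = 10.0
    pause_min: float = 10.0

    @property
    def total_min(self) -> float:
        return (self.equilibration_min + self.rest_min
                + 4 * (self.exercise_min + self.pause_min))

    def phases(self) -> list[str]:
        """Per-block phase labels for the whole session."""
        if self.order is None:
            raise ConfigurationError("exercise order permutation not configured")
        if sorted(self.order) != [1, 2, 3, 4]:
            raise ConfigurationError(
                f"order must be a permutation of 1..4, got {list(self.order)}"
            )
        labels = []
        labels += ["equilibration"] * int(round(self.equilibration_min / BLOCK_MIN))
        labels += ["rest"] * int(round(self.rest_min / BLOCK_MIN))
        for k in self.order:
            labels += [f"exercise_{k}"] * int(round(self.exercise_min / BLOCK_MIN))
            labels += [f"pause_{k}"] * int(round(self.pause_min / BLOCK_MIN))
        return labels


@dataclass
class ChamberSeries:
    """Phase-labeled energy-expenditure timeline at 10-min block resolution.

    ``t`` holds block start times in minutes since session start; ``ee`` one
    kJ/min value per block. ``phase`` is None until :func:`segment_timeline`
    assigns labels.
    """

    t: np.ndarray  # minutes, block starts
    ee: np.ndarray  # kJ/min per block
    phase: Optional[list[str]] = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ee = np.asarray(self.ee, dtype=float)
        if self.t.shape != self.ee.shape:
            raise ValueError("t and ee must have the same length")
        if len(self.t) > 1 and not np.allclose(np.diff(self.t), BLOCK_MIN):
            raise ValueError("blocks must be contiguous 10-min intervals")
        if self.phase is not None and len(self.phase) != len(self.t):
            raise ValueError("one phase label per block required")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration_min(self) -> float:
        return len(self.t) * BLOCK_MIN


@dataclass
class EnergyResult:
    """Resting EE, per-exercise EE and ΔEE (kJ/min), keyed by exercise id."""

    resting_ee: float
    exercise_ee: dict = field(default_factory=dict)
    delta_ee: dict = field(default_factory=dict)
    pairing: str = "preceding_rest"


def ee_from_vo2(vo2_ml_min: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    """Convert oxygen consumption (mL O₂/min) to kcal/min.

    VO₂ in mL/min is divided by 1,000 to obtain L/min and multiplied by the
    caloric equivalent 4.867 kcal/L: 1,000 mL/min → 4.867 kcal/min.
    """
    vo2 = np.asarray(vo2_ml_min, dtype=float)
    if np.any(vo2 < 0):
        raise ValueError("VO2 cannot be negative")
    out = (vo2 / 1000.0) * KCAL_PER_L_O2
    return float(out) if np.isscalar(vo2_ml_min) else out


def kcal_to_kj(x: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    """kcal/min → kJ/min (thermochemical calorie, × 4.184)."""
    return x * KJ_PER_KCAL


def kj_to_kcal(x: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    return x / KJ_PER_KCAL


def segment_timeline(series: ChamberSeries,
                     protocol: ProtocolTemplate) -> ChamberSeries:
    """Assign one protocol phase to every 10-min block.

    The series must cover at least the protocol duration; blocks beyond the
    template are not labeled (the labeled series is truncated to the
    template).
    """
    labels = protocol.phases()
    if series.duration_min < protocol.total_min:
        raise ValueError(
            f"series covers {series.duration_min:.0f} min; protocol requires "
            f"{protocol.total_min:.0f} min"
        )
    n = len(labels)
    return ChamberSeries(t=series.t[:n], ee=series.ee[:n], phase=labels,
                         subject_id=series.subject_id)


def delta_ee(series: ChamberSeries,
             pairing: str = "preceding_rest") -> EnergyResult:
    """Per-exercise ΔEE against a resting reference.

    ``pairing="preceding_rest"`` (default) subtracts the block immediately
    preceding each exercise block (the last rest block for the first
    exercise, the previous pause for the others); ``pairing="session_rest"``
    subtracts the mean of the initial 30-min resting phase. Negative ΔEE is
    allowed — low-intensity arm exercise can fall below a noisy resting
    reference.
    """
    if series.phase is None:
        raise ValueError("series must be segmented before computing delta EE")
    if pairing not in ("preceding_rest", "session_rest"):
        raise ConfigurationError(f"unknown pairing {pairing!r}")
    phases = series.phase
    rest_blocks = [i for i, p in enumerate(phases) if p == "rest"]
    if not rest_blocks:
        raise ValueError("no resting blocks in the labeled series")
    resting = float(np.mean(series.ee[rest_blocks]))

    result = EnergyResult(resting_ee=resting, pairing=pairing)
    for k in (1, 2, 3, 4):
        idx = [i for i, p in enumerate(phases) if p == f"exercise_{k}"]
        if not idx:
            raise ValueError(f"exercise_{k} block missing from the series")
        ex_ee = float(np.mean(series.ee[idx]))
        if pairing == "preceding_rest":
            ref = float(series.ee[idx[0] - 1]) if idx[0] > 0 else resting
        else:
            ref = resting
        result.exercise_ee[k] = ex_ee
        result.delta_ee[k] = ex_ee - ref
    return result
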