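"""Reading, validating and writing smartwatch IMU CSV exports.

The export dialect is a comma-separated UTF-8 table with one header row and
a fixed column order (see :data:`IMU_COLUMNS`): elapsed or epoch timestamp,
gravity-removed user acceleration (m/s²), rotation rate (rad/s), gravity
(g-units), attitude quaternion (x, y, z, w), magnetic field plus calibration
code, and heading (degrees). Only the timestamp and the three user
acceleration columns are mandatory; optional channels may be entirely empty.
Timestamps are always re-based to seconds elapsed since the first sample.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Column order of the CSV export dialect.
IMU_COLUMNS = [
    "t",
    "ua_x", "ua_y", "ua_z",
    "rr_x", "rr_y", "rr_z",
    "g_x", "g_y", "g_z",
    "q_x", "q_y", "q_z", "q_w",
    "m_x", "m_y", "m_z", "m_c",
    "heading",
]

MANDATORY_COLUMNS = ["t", "ua_x", "ua_y", "ua_z"]

SUBJECT_COLUMNS = ["subject_id", "age", "sex", "height_cm", "weight_kg", "bmi", "fasted"]


class FormatError(ValueError):
    """The input stream is not a well-formed export (bad header, empty file)."""


class DataError(ValueError):
    """The input parses but violates a data invariant (e.g. non-monotone time)."""


@dataclass
class ImuTrace:
    """A timestamped multi-channel inertial record for one subject × exercise.

    ``t`` holds seconds since recording start; ``user_acc`` and
    ``rotation_rate`` are (N, 3) arrays in m/s² and rad/s.  ``gravity``
    (N, 3, g-units), ``attitude_quat`` (N, 4, x-y-z-w order), ``magnetic``
    (N, 4, three components plus calibration-accuracy code) and ``heading``
    (N, degrees) are optional and may be ``None``.
    """

    subject_id: str
    exercise_id: int
    t: np.ndarray
    user_acc: np.ndarray
    rotation_rate: Optional[np.ndarray] = None
    gravity: Optional[np.ndarray] = None
    attitude_quat: Optional[np.ndarray] = None
    magnetic: Optional[np.ndarray] = None
    heading: Optional[np.ndarray] = None
    nominal_rate: float = 20.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.user_acc = np.asarray(self.user_acc, dtype=float)
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise DataError("sample times must be strictly increasing")
        if len(self.t) and (not np.all(np.isfinite(self.t)) or self.t[0] < 0):
            raise DataError("sample times must be finite and non-negative")
        if self.user_acc.shape != (len(self.t), 3):
            raise DataError(
                f"user_acc must be (n, 3); got {self.user_acc.shape} for n={len(self.t)}"
            )
        if self.attitude_quat is not None:
            q = np.asarray(self.attitude_quat, dtype=float)
            norms = np.linalg.norm(q, axis=1)
            ok = np.isnan(norms) | (np.abs(norms - 1.0) <= 1e-3)
            if not np.all(ok):
                raise DataError("attitude quaternions must have unit norm (tol 1e-3)")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) > 1 else 0.0

    @property
    def rate_flagged(self) -> bool:
        """True when the median sampling interval deviates > 20% from nominal."""
        if len(self.t) < 2:
            return True
        med = float(np.median(np.diff(self.t)))
        return abs(med - 1.0 / self.nominal_rate) > 0.2 / self.nominal_rate


@dataclass
class SubjectRecord:
    """Anthropometrics and fasting status for one study participant."""

    subject_id: str
    age: float
    sex: str
    height_cm: float
    weight_kg: float
    bmi: float = np.nan
    fasted: bool = False

    def __post_init__(self) -> None:
        derived = self.weight_kg / (self.height_cm / 100.0) ** 2
        if np.isnan(self.bmi):
            self.bmi = derived
        elif abs(self.bmi - derived) > 0.01 * derived:
            raise DataError(
                f"subject {self.subject_id}: BMI {self.bmi:.2f} inconsistent with "
                f"weight/height² = {derived:.2f}"
            )


@dataclass
class ValidationReport:
    """Summary produced by :func:`validate_trace`."""

    subject_id: str
    exercise_id: int
    n_samples: int
    duration_s: float
    estimated_rate_hz: float
    gaps: list = field(default_factory=list)  # (t_before, interval_s) pairs
    nan_counts: dict = field(default_factory=dict)
    flagged: bool = False

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "exercise_id": self.exercise_id,
            "n_samples": self.n_samples,
            "duration_s": self.duration_s,
            "estimated_rate_hz": self.estimated_rate_hz,
            "n_gaps": len(self.gaps),
            "nan_counts": dict(self.nan_counts),
            "flagged": self.flagged,
        }


def _opt_block(df: pd.DataFrame, cols: Sequence[str]) -> Optional[np.ndarray]:
    """Extract an optional channel block; None when absent or all-NaN."""
    if not all(c in df.columns for c in cols):
        return None
    block = df[list(cols)].to_numpy(dtype=float)
    if np.all(np.isnan(block)):
        return None
    return block


def read_sumus_csv(
    source: Union[str, IO], subject_id: str, exercise_id: int
) -> ImuTrace:
    """Parse an IMU CSV export into an :class:`ImuTrace`.

    ``source`` may be a path or an open text/byte stream. Timestamps are
    re-based to elapsed seconds (epoch-second exports are handled by the same
    subtraction). Unrecognized columns are ignored.
    """
    try:
        df = pd.read_csv(source, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError("empty file: no header row found") from None
    if df.empty:
        raise FormatError("file contains a header but no samples")
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r}")

    t = df["t"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise DataError("timestamps are not strictly increasing")
    t = t - t[0]

    ua = df[["ua_x", "ua_y", "ua_z"]].to_numpy(dtype=float)
    heading = None
    if "heading" in df.columns and not df["heading"].isna().all():
        heading = df["heading"].to_numpy(dtype=float)

    return ImuTrace(
        subject_id=subject_id,
        exercise_id=int(exercise_id),
        t=t,
        user_acc=ua,
        rotation_rate=_opt_block(df, ["rr_x", "rr_y", "rr_z"]),
        gravity=_opt_block(df, ["g_x", "g_y", "g_z"]),
        attitude_quat=_opt_block(df, ["q_x", "q_y", "q_z", "q_w"]),
        magnetic=_opt_block(df, ["m_x", "m_y", "m_z", "m_c"]),
        heading=heading,
    )


def write_sumus_csv(trace: ImuTrace, dest: Union[str, IO, None] = None) -> Optional[str]:
    """Serialize a trace in the documented column order.

    Optional channels that are absent are emitted as empty fields so that the
    header is stable across traces. Floats are written at 17 significant
    digits, which round-trips float64 exactly and makes write→read→write
    byte-idempotent. When ``dest`` is None the CSV text is returned as a
    string.
    """
    if len(trace) == 0:
        raise ValueError("cannot serialize an empty trace")
    n = len(trace)
    data: dict = {"t": trace.t}
    blocks = {
        ("ua_x", "ua_y", "ua_z"): trace.user_acc,
        ("rr_x", "rr_y", "rr_z"): trace.rotation_rate,
        ("g_x", "g_y", "g_z"): trace.gravity,
        ("q_x", "q_y", "q_z", "q_w"): trace.attitude_quat,
        ("m_x", "m_y", "m_z", "m_c"): trace.magnetic,
    }
    for cols, block in blocks.items():
        for j, c in enumerate(cols):
            data[c] = block[:, j] if block is not None else np.full(n, np.nan)
    data["heading"] = trace.heading if trace.heading is not None else np.full(n, np.nan)

    df = pd.DataFrame(data, columns=IMU_COLUMNS)
    # %.17g guarantees bit-exact float64 round trips (with round_trip parsing)
    if dest is None:
        return df.to_csv(index=False, float_format="%.17g")
    df.to_csv(dest, index=False, float_format="%.17g")
    return None


def validate_trace(trace: ImuTrace) -> ValidationReport:
    """Report sample count, duration, estimated rate, gaps and NaN counts.

    A gap is an inter-sample interval longer than twice the nominal sampling
    period. The trace is flagged when empty or when the median interval
    deviates more than 20% from the nominal rate.
    """
    n = len(trace)
    if n == 0:
        return ValidationReport(trace.subject_id, trace.exercise_id, 0, 0.0,
                                0.0, [], {}, flagged=True)
    nan_counts = {"user_acc": int(np.isnan(trace.user_acc).any(axis=1).sum())}
    for name in ("rotation_rate", "gravity", "attitude_quat", "magnetic"):
        block = getattr(trace, name)
        if block is not None:
            nan_counts[name] = int(np.isnan(block).any(axis=1).sum())
    if trace.heading is not None:
        nan_counts["heading"] = int(np.isnan(trace.heading).sum())

    if n == 1:
        return ValidationReport(trace.subject_id, trace.exercise_id, 1, 0.0,
                                0.0, [], nan_counts, flagged=True)
    dt = np.diff(trace.t)
    gap_idx = np.flatnonzero(dt > 2.0 / trace.nominal_rate)
    gaps = [(float(trace.t[i]), float(dt[i])) for i in gap_idx]
    est_rate = 1.0 / float(np.median(dt))
    return ValidationReport(
        subject_id=trace.subject_id,
        exercise_id=trace.exercise_id,
        n_samples=n,
        duration_s=trace.duration,
        estimated_rate_hz=est_rate,
        gaps=gaps,
        nan_counts=nan_counts,
        flagged=trace.rate_flagged,
    )


def read_subjects_csv(source: Union[str, IO]) -> list[SubjectRecord]:
    """Read the subject-metadata table (subject_id, age, sex, height_cm,
    weight_kg, bmi, fasted)."""
    try:
        df = pd.read_csv(source)
    except pd.errors.EmptyDataError:
        raise FormatError("empty subjects file") from None
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"subjects table missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                age=float(row.age),
                sex=str(row.sex),
                height_cm=float(row.height_cm),
                weight_kg=float(row.weight_kg),
                bmi=float(row.bmi) if not pd.isna(row.bmi) else np.nan,
                fasted=bool(row.fasted),
            )
        )
    return records


def write_subjects_csv(records: Iterable[SubjectRecord],
                       dest: Union[str, IO, None] = None) -> Optional[str]:
    df = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "age": r.age,
                "sex": r.sex,
                "height_cm": r.height_cm,
                "weight_kg": r.weight_kg,
                "bmi": r.bmi,
                "fasted": r.fasted,
            }
            for r in records
        ],
        columns=SUBJECT_COLUMNS,
    )
    if dest is None:
        return df.to_csv(index=False)
    df.to_csv(dest, index=False)
    return None
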