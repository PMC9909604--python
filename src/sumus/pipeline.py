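"""End-to-end analysis: traces → metrics → counts → ΔEE → cohort statistics.

For every subject × exercise the pipeline reads the IMU export, extracts
acceleration and rotation magnitudes, detects the movement onset, trims the
uniform 500-s window, summarizes the series, reduces to 1-s epochs and
counts activity under the configured threshold (variable mean + 2·SD for
exercises 1–3, fixed 0.05 m/s² for exercise 4). With chamber data present it
segments each session and computes per-exercise ΔEE, then builds cohort
tables (averages of the per-subject statistics), the movement-vs-ΔEE
association table (Spearman and OLS side by side) and the fasted vs
non-fasted contrast. A subject failing onset detection is skipped and
enumerated in the report; the run aborts only when every subject fails.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .calorimetry import ChamberSeries, ProtocolTemplate, delta_ee, segment_timeline
from .counts import count_activity, epoch_reduce, fixed_threshold, variable_threshold
from .io import ImuTrace, SubjectRecord, read_subjects_csv, read_sumus_csv, validate_trace
from .kinematics import (
    OnsetNotFoundError,
    detect_onset,
    summarize_series,
    trim_window,
    vector_magnitude,
)
from .stats import cohort_summary, linear_fit, spearman_corr, two_sample_ttest

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_MODE = {1: "variable", 2: "variable", 3: "variable", 4: "fixed"}


@dataclass
class RunConfig:
    """Every configurable analysis decision, with its default."""

    onset_baseline_window: float = 5.0
    onset_k: float = 3.0
    onset_sustain: float = 2.0
    manual_onsets: dict = field(default_factory=dict)  # (subject, exercise) -> s
    window_duration: float = 500.0
    epoch_s: float = 1.0
    reducer: str = "peak"
    threshold_mode: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLD_MODE))
    fixed_threshold_value: float = 0.05
    pairing: str = "preceding_rest"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if key == "threshold_mode":
                value = {int(k): v for k, v in value.items()}
            if key == "manual_onsets":
                value = {(str(k).split(":")[0], int(str(k).split(":")[1])): v
                         for k, v in value.items()}
            setattr(cfg, key, value)
        return cfg

    def as_dict(self) -> dict:
        d = asdict(self)
        d["manual_onsets"] = {f"{s}:{e}": v for (s, e), v in self.manual_onsets.items()}
        return d


@dataclass
class RunReport:
    """All pipeline outputs plus provenance; serializable to CSV/JSON."""

    per_subject: pd.DataFrame
    cohort_tables: pd.DataFrame
    associations: Optional[pd.DataFrame]
    fasted_contrast: Optional[pd.DataFrame]
    failures: list
    config: dict
    validation: list = field(default_factory=list)
    n_statistical_tests: int = 0

    def write(self, out_dir: str) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_subject.to_csv(out / "report.csv", index=False,
                                float_format="%.6g")
        self.cohort_tables.to_csv(out / "cohort_tables.csv", index=False,
                                  float_format="%.6g")
        if self.associations is not None:
            self.associations.to_csv(out / "associations.csv", index=False,
                                     float_format="%.6g")
        payload = {
            "config": self.config,
            "failures": self.failures,
            "validation": self.validation,
            "n_statistical_tests": self.n_statistical_tests,
            "per_subject": self.per_subject.to_dict(orient="records"),
            "cohort_tables": self.cohort_tables.to_dict(orient="records"),
            "associations": (self.associations.to_dict(orient="records")
                             if self.associations is not None else None),
            "fasted_contrast": (self.fasted_contrast.to_dict(orient="records")
                                if self.fasted_contrast is not None else None),
        }
        (out / "report.json").write_text(json.dumps(payload, indent=2,
                                                    sort_keys=True,
                                                    default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def analyze_trace(trace: ImuTrace, config: RunConfig) -> dict:
    """Single subject × exercise: magnitudes, onset, window, summary, counts."""
    acc = vector_magnitude(trace, "user_acc")
    rot = (vector_magnitude(trace, "rotation_rate")
           if trace.rotation_rate is not None else None)
    key = (trace.subject_id, trace.exercise_id)
    if key in config.manual_onsets:
        onset = float(config.manual_onsets[key])
    else:
        onset = detect_onset(acc, config.onset_baseline_window,
                             config.onset_k, config.onset_sustain)
    window = trim_window(acc, rot, onset, config.window_duration,
                         subject_id=trace.subject_id,
                         exercise_id=trace.exercise_id)
    acc_sum = summarize_series(window.acc)
    rot_sum = summarize_series(window.rot) if window.rot is not None else None

    epochs = epoch_reduce(window.acc, config.epoch_s, config.reducer)
    mode = config.threshold_mode.get(trace.exercise_id, "variable")
    thr = (fixed_threshold(config.fixed_threshold_value) if mode == "fixed"
           else variable_threshold(window.acc))
    counts = count_activity(epochs, thr, config.epoch_s)

    rec = {
        "subject_id": trace.subject_id,
        "exercise_id": trace.exercise_id,
        "onset_s": onset,
        "acc_mean": acc_sum.mean, "acc_sd": acc_sum.sd, "acc_cv": acc_sum.cv,
        "acc_max": acc_sum.max, "acc_min": acc_sum.min,
        "threshold_kind": thr.kind, "threshold_value": thr.value,
        "n_epochs": counts.n_epochs, "total_counts": counts.total,
        "medium_counts": counts.medium, "low_counts": counts.low,
    }
    if rot_sum is not None:
        rec.update({"rot_mean": rot_sum.mean, "rot_sd": rot_sum.sd,
                    "rot_cv": rot_sum.cv, "rot_max": rot_sum.max,
                    "rot_min": rot_sum.min})
    return rec


def _scalar_cohort_stats(values: np.ndarray) -> dict:
    """Across-subject mean, SD, CV, max, min of one per-subject scalar."""
    values = np.asarray(values, dtype=float)
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return {
        "mean": mean,
        "sd": sd,
        "cv": sd / mean if mean > 1e-12 else float("nan"),
        "max": float(np.max(values)),
        "min": float(np.min(values)),
        "n": int(len(values)),
    }


def _cohort_tables(per_subject: pd.DataFrame) -> pd.DataFrame:
    """Cohort tables: averages of per-subject summary statistics (movement
    metrics) and across-subject statistics of per-subject scalars (counts,
    ΔEE)."""
    from .kinematics import SeriesSummary

    rows = []
    for ex, grp in per_subject.groupby("exercise_id"):
        for metric in ("acc", "rot"):
            if f"{metric}_mean" not in grp.columns or grp[f"{metric}_mean"].isna().all():
                continue
            summaries = [
                SeriesSummary(mean=r[f"{metric}_mean"], sd=r[f"{metric}_sd"],
                              cv=r[f"{metric}_cv"], max=r[f"{metric}_max"],
                              min=r[f"{metric}_min"])
                for _, r in grp.iterrows()
            ]
            cs = cohort_summary(summaries)
            rows.append({"exercise_id": ex, "metric": metric,
                         "avg_of_means": cs.avg_of_means,
                         "avg_of_sds": cs.avg_of_sds,
                         "avg_of_cvs": cs.avg_of_cvs,
                         "avg_of_max": cs.avg_of_max,
                         "avg_of_min": cs.avg_of_min,
                         "n_subjects": cs.n_subjects})
        for col in ("total_counts", "medium_counts", "low_counts", "delta_ee"):
            if col in grp.columns and not grp[col].isna().all():
                st = _scalar_cohort_stats(grp[col].dropna().to_numpy())
                rows.append({"exercise_id": ex, "metric": col,
                             "avg_of_means": st["mean"], "avg_of_sds": st["sd"],
                             "avg_of_cvs": st["cv"], "avg_of_max": st["max"],
                             "avg_of_min": st["min"], "n_subjects": st["n"]})
    return pd.DataFrame(rows)


def _associations(per_subject: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Spearman and OLS of ΔEE on each movement metric, per exercise."""
    rows = []
    n_tests = 0
    metrics = [m for m in ("acc_mean", "rot_mean", "total_counts")
               if m in per_subject.columns]
    for ex, grp in per_subject.groupby("exercise_id"):
        sub = grp.dropna(subset=["delta_ee"])
        if len(sub) < 3:
            continue
        y = sub["delta_ee"].to_numpy(dtype=float)
        for metric in metrics:
            x = sub[metric].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                continue
            sp = spearman_corr(x, y)
            ols = linear_fit(x, y)
            n_tests += 2
            rows.append({
                "exercise_id": ex, "metric": metric, "n": sp.n,
                "spearman_rho": sp.rho_or_r, "spearman_p": sp.p_value,
                "ols_r": ols.rho_or_r, "ols_r_squared": ols.r_squared,
                "ols_slope": ols.slope, "ols_intercept": ols.intercept,
                "ols_p": ols.p_value,
            })
    return pd.DataFrame(rows), n_tests


def _fasted_contrast(per_subject: pd.DataFrame,
                     subjects: list[SubjectRecord]) -> tuple[Optional[pd.DataFrame], int]:
    fasted_ids = {s.subject_id for s in subjects if s.fasted}
    rows = []
    n_tests = 0
    for ex, grp in per_subject.groupby("exercise_id"):
        sub = grp.dropna(subset=["delta_ee"])
        a = sub[sub["subject_id"].isin(fasted_ids)]["delta_ee"].to_numpy()
        b = sub[~sub["subject_id"].isin(fasted_ids)]["delta_ee"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            continue
        t, p = two_sample_ttest(a, b, paired=False)
        n_tests += 1
        rows.append({"exercise_id": ex, "n_fasted": len(a),
                     "n_nonfasted": len(b), "mean_fasted": float(np.mean(a)),
                     "mean_nonfasted": float(np.mean(b)), "t": t, "p": p})
    return (pd.DataFrame(rows) if rows else None), n_tests


def analyze_cohort(
    traces: dict,
    config: Optional[RunConfig] = None,
    chamber: Optional[dict] = None,
    orders: Optional[dict] = None,
    subjects: Optional[list] = None,
) -> RunReport:
    """Run the full analysis on in-memory objects.

    ``traces`` maps (subject_id, exercise_id) → ImuTrace; ``chamber`` maps
    subject_id → raw ChamberSeries with ``orders`` giving each subject's
    exercise order. Without chamber data the report is movement-only (ΔEE
    and associations absent).
    """
    config = config or RunConfig()
    records = []
    failures = []
    validation = []
    for key in sorted(traces):
        trace = traces[key]
        validation.append(validate_trace(trace).as_dict())
        try:
            records.append(analyze_trace(trace, config))
        except (OnsetNotFoundError, ValueError) as exc:
            logger.warning("skipping %s: %s", key, exc)
            failures.append({"subject_id": key[0], "exercise_id": key[1],
                             "error": str(exc)})
    if not records:
        raise RuntimeError("all traces failed analysis")
    per_subject = pd.DataFrame(records)

    if chamber:
        if orders is None:
            raise ValueError("chamber data requires per-subject exercise orders")
        delta_rows = {}
        for sid, series in chamber.items():
            template = ProtocolTemplate(order=orders[sid])
            labeled = segment_timeline(series, template)
            result = delta_ee(labeled, pairing=config.pairing)
            for k, v in result.delta_ee.items():
                delta_rows[(sid, k)] = (v, result.resting_ee, result.exercise_ee[k])
        per_subject["delta_ee"] = [
            delta_rows.get((r.subject_id, r.exercise_id), (np.nan,) * 3)[0]
            for r in per_subject.itertuples()
        ]
        per_subject["resting_ee"] = [
            delta_rows.get((r.subject_id, r.exercise_id), (np.nan,) * 3)[1]
            for r in per_subject.itertuples()
        ]
        per_subject["exercise_ee"] = [
            delta_rows.get((r.subject_id, r.exercise_id), (np.nan,) * 3)[2]
            for r in per_subject.itertuples()
        ]

    cohort_tables = _cohort_tables(per_subject)
    associations = None
    fasted = None
    n_tests = 0
    if "delta_ee" in per_subject.columns:
        associations, n_assoc = _associations(per_subject)
        n_tests += n_assoc
        if subjects:
            fasted, n_f = _fasted_contrast(per_subject, subjects)
            n_tests += n_f

    return RunReport(per_subject=per_subject, cohort_tables=cohort_tables,
                     associations=associations, fasted_contrast=fasted,
                     failures=failures, config=config.as_dict(),
                     validation=validation, n_statistical_tests=n_tests)


def _read_chamber_csv(path: Path, subject_id: str) -> ChamberSeries:
    df = pd.read_csv(path)
    for col in ("t_min", "value", "value_kind"):
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing column {col!r}")
    kinds = set(df["value_kind"].unique())
    if kinds == {"ee_kj_min"}:
        ee = df["value"].to_numpy(dtype=float)
    elif kinds == {"vo2_ml_min"}:
        from .calorimetry import ee_from_vo2, kcal_to_kj
        ee = kcal_to_kj(ee_from_vo2(df["value"].to_numpy(dtype=float)))
    else:
        raise ValueError(f"{path.name}: unsupported value_kind {kinds}")
    return ChamberSeries(t=df["t_min"].to_numpy(dtype=float), ee=ee,
                         subject_id=subject_id)


def run_analysis(input_dir: str, output_dir: str,
                 config: Optional[RunConfig] = None) -> RunReport:
    """File-based entry point over a fixture/export directory.

    Expects ``imu_<subject>_ex<k>.csv`` per subject × exercise, optional
    ``chamber_<subject>.csv`` plus ``sessions.json`` (exercise order, fasted
    flag) and optional ``subjects.csv``. Writes report.csv,
    cohort_tables.csv, associations.csv, report.json and run.log into
    ``output_dir``.
    """
    config = config or RunConfig()
    in_dir = Path(input_dir)
    out_dir = Path(output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("sumus")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    try:
        traces = {}
        for path in sorted(in_dir.glob("imu_*_ex*.csv")):
            stem = path.stem  # imu_<sid>_ex<k>
            sid = stem[len("imu_"):stem.rindex("_ex")]
            ex = int(stem[stem.rindex("_ex") + 3:])
            try:
                traces[(sid, ex)] = read_sumus_csv(str(path), sid, ex)
            except Exception as exc:  # per-file failure: log and skip
                logger.warning("could not read %s: %s", path.name, exc)
        if not traces:
            raise RuntimeError(f"no readable IMU traces in {input_dir}")

        chamber = {}
        orders = None
        sessions_path = in_dir / "sessions.json"
        if sessions_path.exists():
            sessions = json.loads(sessions_path.read_text())
            orders = {sid: [int(x) for x in rec["order"]]
                      for sid, rec in sessions.items()}
        for path in sorted(in_dir.glob("chamber_*.csv")):
            sid = path.stem[len("chamber_"):]
            try:
                chamber[sid] = _read_chamber_csv(path, sid)
            except Exception as exc:
                logger.warning("could not read %s: %s", path.name, exc)

        subjects = None
        if (in_dir / "subjects.csv").exists():
            subjects = read_subjects_csv(str(in_dir / "subjects.csv"))

        report = analyze_cohort(traces, config, chamber or None, orders, subjects)
        report.write(str(out_dir))
        logger.info("analyzed %d traces (%d failures)",
                    len(traces), len(report.failures))
        return report
    finally:
        root.removeHandler(handler)
        handler.close()
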