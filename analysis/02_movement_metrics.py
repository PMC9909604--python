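"""Run the full movement + energy analysis on the cohort fixture.

Reads the fixture written by 01_simulate_cohort.py, runs the end-to-end
pipeline (magnitudes → onset → 500-s window → summaries → 1-s epochs →
thresholds → counts → chamber segmentation → ΔEE) and writes the per-subject
report plus the cohort tables (average of the per-subject means, SDs, CVs
and extremes per exercise) under results/.
"""

from pathlib import Path

from sumus import RunConfig, run_analysis

FIXTURE_DIR = Path("scratch/cohort_fixture")
OUT_DIR = Path("results/analysis")


def main() -> None:
    if not FIXTURE_DIR.exists():
        raise SystemExit("fixture missing - run analysis/01_simulate_cohort.py first")
    report = run_analysis(str(FIXTURE_DIR), str(OUT_DIR), RunConfig())

    print(f"analyzed {len(report.per_subject)} subject-exercise records; "
          f"{len(report.failures)} failures")
    acc = report.cohort_tables.query("metric == 'acc'")
    print("\ncohort acceleration (average of per-subject statistics):")
    print(acc[["exercise_id", "avg_of_means", "avg_of_sds", "avg_of_cvs",
               "avg_of_max"]].round(2).to_string(index=False))
    counts = report.cohort_tables.query("metric == 'total_counts'")
    print("\ncohort total activity counts (across-subject statistics):")
    print(counts[["exercise_id", "avg_of_means", "avg_of_sds", "avg_of_cvs",
                  "avg_of_max"]].round(2).to_string(index=False))
    print(f"\nreports written to {OUT_DIR}")


if __name__ == "__main__":
    main()
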