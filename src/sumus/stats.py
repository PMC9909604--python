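"""Cohort summaries and the study's statistical comparisons.

Cohort tables report the *average of the per-subject statistics* (means,
SDs, CVs, extremes) — not statistics of pooled data. Associations between
movement metrics and ΔEE are assessed both with Spearman's rank correlation
and with ordinary least-squares regression (the two are reported side by
side). Group differences use two-sided t-tests (paired within subject,
unpaired for fasted vs non-fasted) at a flat α = 0.05 with no
multiple-testing correction; the number of tests run is reported alongside.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .kinematics import SeriesSummary

ALPHA = 0.05


@dataclass
class CohortSummary:
    """Across-subject averages of per-subject summary statistics."""

    avg_of_means: float
    avg_of_sds: float
    avg_of_cvs: float
    avg_of_max: float
    avg_of_min: float
    n_subjects: int


@dataclass
class AssociationResult:
    """Correlation or simple-regression result between two cohort variables."""

    rho_or_r: float
    p_value: float
    n: int
    method: str  # "spearman" | "ols"
    slope: Optional[float] = None
    intercept: Optional[float] = None
    r_squared: Optional[float] = None


def coefficient_of_variation(mean: float, sd: float) -> float:
    """CV = SD / mean; NaN (with a warning) when the mean is not positive."""
    if mean <= 0:
        warnings.warn("CV undefined for non-positive mean", RuntimeWarning,
                      stacklevel=2)
        return float("nan")
    return sd / mean


def cohort_summary(summaries: Sequence[SeriesSummary]) -> CohortSummary:
    """Arithmetic mean of each per-subject statistic across the cohort.

    NaN CVs (undefined for near-zero means) are excluded from the CV average.
    """
    if len(summaries) == 0:
        raise ValueError("empty cohort")
    cvs = np.array([s.cv for s in summaries], dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        avg_cv = float(np.nanmean(cvs))
    return CohortSummary(
        avg_of_means=float(np.mean([s.mean for s in summaries])),
        avg_of_sds=float(np.mean([s.sd for s in summaries])),
        avg_of_cvs=avg_cv,
        avg_of_max=float(np.mean([s.max for s in summaries])),
        avg_of_min=float(np.mean([s.min for s in summaries])),
        n_subjects=len(summaries),
    )


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (n ≤ 10).

    Enumerates all n! pairings of the rank vectors; ties are handled through
    average ranks exactly as in the observed statistic.
    """
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    n = len(rx)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        rho = float(np.mean(rx[list(perm)] * ry))
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman_corr(x: Sequence[float], y: Sequence[float],
                  exact: bool = False) -> AssociationResult:
    """Spearman rank correlation with a two-sided p-value.

    Ties receive average ranks. The p-value uses the large-sample t
    approximation by default; ``exact=True`` switches to full permutation
    enumeration (feasible for n ≤ 10).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman rho undefined", RuntimeWarning,
                      stacklevel=2)
        return AssociationResult(float("nan"), float("nan"), len(x), "spearman")
    rho, p = sps.spearmanr(x, y)
    if exact:
        if len(x) > 10:
            raise ValueError("exact permutation p-value limited to n <= 10")
        p = _exact_spearman_p(x, y, rho)
    return AssociationResult(float(rho), float(p), len(x), "spearman")


def linear_fit(x: Sequence[float], y: Sequence[float]) -> AssociationResult:
    """Ordinary least-squares simple regression of y on x.

    Returns slope, intercept, Pearson r, r² and the two-sided p-value for the
    slope. Raises ``ValueError`` for constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression undefined")
    res = sps.linregress(x, y)
    return AssociationResult(
        rho_or_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=len(x),
        method="ols",
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
    )


def two_sample_ttest(a: Sequence[float], b: Sequence[float],
                     paired: bool = False) -> tuple[float, float]:
    """Two-sided t-test: paired for within-subject exercise comparisons,
    unpaired (Student) for independent groups such as fasted vs non-fasted.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal-length groups")
        if np.all(a == b):
            return 0.0, 1.0  # zero differences: no evidence of any effect
        t, p = sps.ttest_rel(a, b)
    else:
        t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
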