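import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sumus import (
    cohort_summary,
    coefficient_of_variation,
    linear_fit,
    spearman_corr,
    two_sample_ttest,
)
from sumus.kinematics import SeriesSummary


def average_ranks(v):
    """Explicit average-rank computation (independent of scipy)."""
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v))
    i = 0
    sv = v[order]
    while i < len(v):
        j = i
        while j + 1 < len(v) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


class TestCV:
    def test_delta_ee_dispersion_values(self):
        """sd/mean for cohort ΔEE summaries lands on the expected 2-dp values."""
        means = [1.03, 0.86, 1.31, 1.25]
        sds = [0.72, 0.91, 1.07, 0.78]
        cvs = [round(coefficient_of_variation(m, s), 2) for m, s in zip(means, sds)]
        assert cvs == [0.70, 1.06, 0.82, 0.62]

    def test_zero_sd(self):
        assert coefficient_of_variation(2.0, 0.0) == 0.0

    def test_nonpositive_mean_warns_nan(self):
        with pytest.warns(RuntimeWarning):
            assert np.isnan(coefficient_of_variation(0.0, 1.0))


class TestCohortSummary:
    def _summary(self, mean, sd=0.5, cv=None, mx=None, mn=None):
        return SeriesSummary(mean=mean, sd=sd, cv=cv if cv is not None else sd / mean,
                             max=mx if mx is not None else mean + sd,
                             min=mn if mn is not None else mean - sd)

    def test_single_subject_equals_itself(self):
        s = self._summary(2.0)
        cs = cohort_summary([s])
        assert (cs.avg_of_means, cs.avg_of_sds, cs.avg_of_cvs) == (s.mean, s.sd, s.cv)
        assert cs.n_subjects == 1

    def test_two_subjects_average(self):
        cs = cohort_summary([self._summary(1.0), self._summary(3.0)])
        assert cs.avg_of_means == pytest.approx(2.0)

    def test_identical_subjects_collapse_to_single_summary(self):
        s = self._summary(1.7, 0.7)
        cs = cohort_summary([s] * 14)
        assert cs.avg_of_means == pytest.approx(s.mean)
        assert cs.avg_of_cvs == pytest.approx(s.cv)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(8)
        summaries = [self._summary(m, s) for m, s in
                     zip(rng.uniform(1, 4, 20), rng.uniform(0.1, 2, 20))]
        cs = cohort_summary(summaries)
        for attr, field in [("avg_of_means", "mean"), ("avg_of_sds", "sd"),
                            ("avg_of_cvs", "cv"), ("avg_of_max", "max"),
                            ("avg_of_min", "min")]:
            acc = 0.0
            for s in summaries:
                acc += getattr(s, field)
            assert getattr(cs, attr) == pytest.approx(acc / len(summaries), abs=1e-12)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary([])


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert spearman_corr(x, x**3 + 1).rho_or_r == pytest.approx(1.0)
        assert spearman_corr(x, -x).rho_or_r == pytest.approx(-1.0)

    def test_tied_data_matches_explicit_rank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 6.0, 7.0])
        rx, ry = average_ranks(x), average_ranks(y)
        rho_oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman_corr(x, y).rho_or_r == pytest.approx(rho_oracle, abs=1e-12)

    def test_exact_permutation_p_value(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([1.5, 2.0, 3.0, 2.5, 6.0, 8.0])
        res = spearman_corr(x, y, exact=True)
        assert 0.0 < res.p_value <= 1.0
        # perfectly monotone 6-point data: two-sided exact p = 2/6!
        perfect = spearman_corr(x, np.sort(y), exact=True)
        assert perfect.p_value == pytest.approx(2.0 / 720.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        base = spearman_corr(x, y).rho_or_r
        assert spearman_corr(np.exp(x), y).rho_or_r == pytest.approx(base)
        assert spearman_corr(x, 3.0 * y + 2.0).rho_or_r == pytest.approx(base)

    def test_constant_input_warns(self):
        with pytest.warns(RuntimeWarning):
            res = spearman_corr(np.ones(5), np.arange(5.0))
        assert np.isnan(res.rho_or_r)


class TestLinearFit:
    def test_exact_line(self):
        x = np.linspace(0, 10, 20)
        res = linear_fit(x, 2.0 * x + 1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(21)
        x = rng.uniform(0, 5, 40)
        y = 1.3 * x - 0.4 + rng.normal(0, 0.7, 40)
        res = linear_fit(x, y)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.intercept == pytest.approx(beta[0], abs=1e-9)
        assert res.slope == pytest.approx(beta[1], abs=1e-9)
        # r² equals squared Pearson correlation
        r = np.corrcoef(x, y)[0, 1]
        assert res.r_squared == pytest.approx(r**2, abs=1e-12)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            linear_fit(np.ones(5), np.arange(5.0))


class TestTTest:
    def test_identical_paired_groups_give_t0_p1(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = two_sample_ttest(a, a, paired=True)
        assert t == 0.0
        assert p == 1.0

    def test_obvious_shift_detected(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.0, 1.0, 20)
        b = rng.normal(5.0, 1.0, 20)
        t, p = two_sample_ttest(a, b)
        assert p < 1e-6

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            two_sample_ttest([1.0], [1.0, 2.0])
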