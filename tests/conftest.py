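import numpy as np
import pytest

from sumus import GeneratorConfig, gen_cohort, gen_rhythmic_trace
from sumus.kinematics import ScalarSeries

RATE = 20.0


def make_burst_series(start_s, duration_s=60.0, amp=2.0, noise_sd=0.05,
                      period_s=4.0, width_s=1.0, seed=1):
    """Magnitude series: |noise| floor with raised-cosine bursts whose leading
    edge is at ``start_s`` and every ``period_s`` thereafter."""
    rng = np.random.default_rng(seed)
    t = np.arange(int(duration_s * RATE)) / RATE
    v = np.abs(rng.normal(0.0, noise_sd, len(t)))
    center = start_s + width_s / 2.0
    while center < duration_s:
        u = (t - center) / width_s
        m = np.abs(u) <= 0.5
        v[m] = np.maximum(v[m], amp * 0.5 * (1.0 + np.cos(2.0 * np.pi * u[m])))
        center += period_s
    return ScalarSeries(t, v, "m/s^2", RATE)


@pytest.fixture
def rhythmic_trace():
    return gen_rhythmic_trace(GeneratorConfig(seed=7, duration=500.0))


@pytest.fixture(scope="session")
def small_cohort():
    """A 4-subject cohort with zero ΔEE scatter and zero chamber noise, so
    chamber-derived ΔEE equals the stored truth exactly."""
    return gen_cohort(n=4, coupling_slope=0.004, seed=11,
                      delta_sd=0.0, chamber_noise_sd=0.0)
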