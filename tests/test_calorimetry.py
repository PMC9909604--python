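import numpy as np
import pytest

from sumus import (
    ChamberSeries,
    ProtocolTemplate,
    delta_ee,
    ee_from_vo2,
    gen_chamber_series,
    kcal_to_kj,
    kj_to_kcal,
    segment_timeline,
)
from sumus.calorimetry import ConfigurationError


class TestVo2Conversion:
    def test_zero(self):
        assert ee_from_vo2(0.0) == 0.0

    def test_unit_definition_one_litre_per_min(self):
        # 1,000 mL/min = 1 L/min -> caloric equivalent 4.867 kcal/min
        assert ee_from_vo2(1000.0) == pytest.approx(4.867)

    def test_linearity(self):
        assert ee_from_vo2(250.0) == pytest.approx(1.21675)
        a, b = 137.0, 411.5
        assert ee_from_vo2(a + b) == pytest.approx(ee_from_vo2(a) + ee_from_vo2(b))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ee_from_vo2(-1.0)


class TestEnergyUnits:
    def test_kcal_to_kj(self):
        assert kcal_to_kj(0.0) == 0.0
        assert kcal_to_kj(1.0) == pytest.approx(4.184)

    def test_roundtrip_identity(self):
        x = 3.14159
        assert kj_to_kcal(kcal_to_kj(x)) == pytest.approx(x, abs=1e-12)


def _flat_series(n_blocks, level=5.0):
    return ChamberSeries(t=np.arange(n_blocks) * 10.0,
                         ee=np.full(n_blocks, level))


class TestSegmentTimeline:
    def test_full_protocol_is_140_min_with_4_exercise_4_pause(self):
        template = ProtocolTemplate(order=[2, 4, 1, 3])
        assert template.total_min == 140.0
        labeled = segment_timeline(_flat_series(14), template)
        phases = labeled.phase
        assert len(phases) == 14
        assert phases[:3] == ["equilibration"] * 3
        assert phases[3:6] == ["rest"] * 3
        assert sum(p.startswith("exercise_") for p in phases) == 4
        assert sum(p.startswith("pause_") for p in phases) == 4
        assert phases[6] == "exercise_2" and phases[7] == "pause_2"

    def test_exact_length_series_ends_with_last_pause(self):
        labeled = segment_timeline(_flat_series(14), ProtocolTemplate(order=[1, 2, 3, 4]))
        assert labeled.phase[-1] == "pause_4"

    def test_every_block_gets_exactly_one_phase(self):
        labeled = segment_timeline(_flat_series(16), ProtocolTemplate(order=[4, 3, 2, 1]))
        assert len(labeled.phase) == len(labeled.ee)
        assert all(isinstance(p, str) and p for p in labeled.phase)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="100"):
            segment_timeline(_flat_series(10), ProtocolTemplate(order=[1, 2, 3, 4]))

    def test_missing_order_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            segment_timeline(_flat_series(14), ProtocolTemplate())

    def test_bad_permutation_rejected(self):
        with pytest.raises(ConfigurationError):
            ProtocolTemplate(order=[1, 1, 2, 3]).phases()


class TestDeltaEE:
    def _labeled(self, ee):
        return ChamberSeries(t=np.arange(14) * 10.0, ee=np.asarray(ee, float),
                             phase=ProtocolTemplate(order=[1, 2, 3, 4]).phases())

    def test_simple_increment(self):
        ee = [1.0] * 6 + [2.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
        res = delta_ee(self._labeled(ee))
        assert res.delta_ee[1] == pytest.approx(1.0)
        assert res.delta_ee[2] == pytest.approx(0.0)

    def test_exercise_equal_to_rest_gives_zero(self):
        res = delta_ee(self._labeled([5.0] * 14))
        assert all(v == pytest.approx(0.0) for v in res.delta_ee.values())

    def test_negative_delta_is_allowed(self):
        ee = [1.0] * 6 + [0.8] + [1.0] * 7
        res = delta_ee(self._labeled(ee))
        assert res.delta_ee[1] == pytest.approx(-0.2)

    def test_session_rest_pairing_uses_initial_rest(self):
        ee = np.full(14, 1.0)
        ee[3:6] = 2.0  # resting phase higher than all pauses
        ee[6] = 3.0  # exercise 1
        res = delta_ee(self._labeled(ee), pairing="session_rest")
        assert res.resting_ee == pytest.approx(2.0)
        assert res.delta_ee[1] == pytest.approx(1.0)

    def test_unlabeled_series_rejected(self):
        with pytest.raises(ValueError):
            delta_ee(_flat_series(14))


class TestChamberGenerator:
    TRUTH = np.array([1.03, 0.86, 1.31, 1.25])

    def test_noise_free_recovery_is_exact_both_pairings(self):
        series = gen_chamber_series(5.0, self.TRUTH, 0.0, order=[3, 1, 4, 2], seed=0)
        labeled = segment_timeline(series, ProtocolTemplate(order=[3, 1, 4, 2]))
        for pairing in ("preceding_rest", "session_rest"):
            res = delta_ee(labeled, pairing=pairing)
            for k in (1, 2, 3, 4):
                assert res.delta_ee[k] == pytest.approx(self.TRUTH[k - 1], abs=1e-12)

    def test_noise_free_exercise_blocks_sit_at_resting_plus_truth(self):
        series = gen_chamber_series(5.0, self.TRUTH, 0.0, order=[1, 2, 3, 4], seed=0)
        labeled = segment_timeline(series, ProtocolTemplate(order=[1, 2, 3, 4]))
        for k, expected in zip((1, 2, 3, 4), (6.03, 5.86, 6.31, 6.25)):
            idx = labeled.phase.index(f"exercise_{k}")
            assert labeled.ee[idx] == pytest.approx(expected)

    def test_session_is_14_blocks_of_10_min(self):
        series = gen_chamber_series(5.0, self.TRUTH, 0.1, order=[1, 2, 3, 4], seed=1)
        assert len(series) == 14
        assert series.duration_min == 140.0

    def test_noisy_recovery_within_two_noise_sd(self):
        noise = 0.1
        rng_errors = []
        for seed in range(30):
            series = gen_chamber_series(5.0, self.TRUTH, noise,
                                        order=[1, 2, 3, 4], seed=seed)
            labeled = segment_timeline(series, ProtocolTemplate(order=[1, 2, 3, 4]))
            res = delta_ee(labeled)
            rng_errors.extend(res.delta_ee[k] - self.TRUTH[k - 1] for k in (1, 2, 3, 4))
        # each delta is a difference of two blocks with independent noise
        assert np.std(rng_errors) < 2.0 * noise * np.sqrt(2.0)
        assert abs(np.mean(rng_errors)) < 0.05
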