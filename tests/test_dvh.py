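"""DVH representation changes, metric extraction, constraints, envelopes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ntcpkit import (DVH, ConstraintSpec, MetricSpec, RangeError,
                     UndefinedValueError, ValidationError,
                     evaluate_constraints, worst_case_envelope)
from conftest import random_cumulative_dvh


class TestConversions:
    def test_step_function_differential(self, step_dvh):
        diff = step_dvh.to_differential()
        np.testing.assert_allclose(diff.volume_cc, [0, 100, 0])

    def test_successive_differences(self, ramp_dvh):
        np.testing.assert_allclose(ramp_dvh.to_differential().volume_cc,
                                   [40, 35, 25, 0])

    def test_suffix_sums(self):
        diff = DVH("o", "differential", [0, 20, 40, 60], [40, 35, 25, 0])
        np.testing.assert_allclose(diff.to_cumulative().volume_cc,
                                   [100, 60, 25, 0])

    def test_differential_sum_equals_total(self, ramp_dvh):
        diff = ramp_dvh.to_differential()
        assert diff.total_volume_cc == pytest.approx(
            ramp_dvh.total_volume_cc, rel=1e-12)

    def test_all_zero_degenerate(self):
        cum = DVH("o", "differential", [0, 1], [0, 0]).to_cumulative()
        assert cum.total_volume_cc == 0

    def test_non_monotone_cumulative_rejected(self):
        with pytest.raises(ValidationError, match="bin 1"):
            DVH("o", "cumulative", [0, 1, 2], [100, 50, 60])

    def test_negative_volume_rejected(self):
        with pytest.raises(ValidationError):
            DVH("o", "differential", [0, 1], [10, -1])

    @settings(deadline=None, max_examples=50)
    @given(seed=st.integers(0, 10_000))
    def test_round_trip_identity(self, seed):
        dvh = random_cumulative_dvh(np.random.default_rng(seed))
        back = dvh.to_differential().to_cumulative()
        np.testing.assert_allclose(back.volume_cc, dvh.volume_cc, atol=1e-9)


class TestVolumeAtDose:
    def test_uniform_plan(self):
        dvh = DVH.uniform(60.0, 100.0)
        assert dvh.volume_at_dose(50) == pytest.approx(100.0)
        assert dvh.volume_at_dose(50, "percent") == pytest.approx(100.0)

    def test_linear_midpoint(self, ramp_dvh):
        assert ramp_dvh.volume_at_dose(30) == pytest.approx(42.5)

    def test_beyond_max_dose_is_zero(self, ramp_dvh):
        assert ramp_dvh.volume_at_dose(65) == 0.0

    def test_percent_of_zero_volume_undefined(self):
        empty = DVH("o", "cumulative", [0, 1], [0, 0])
        with pytest.raises(UndefinedValueError):
            empty.volume_at_dose(0.5, "percent")

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_non_increasing_in_dose(self, seed):
        rng = np.random.default_rng(seed)
        dvh = random_cumulative_dvh(rng)
        doses = np.sort(rng.uniform(0, dvh.dose[-1] * 1.1, size=20))
        values = [dvh.volume_at_dose(d) for d in doses]
        assert all(x >= y - 1e-9 for x, y in zip(values, values[1:]))


class TestDoseAtVolume:
    def test_uniform_hot_spot(self):
        dvh = DVH.uniform(59.4, 300.0)
        assert dvh.dose_at_volume(0.1) == pytest.approx(59.4)

    def test_exact_grid_hit(self, ramp_dvh):
        assert ramp_dvh.dose_at_volume(25) == pytest.approx(40.0)

    def test_whole_organ(self, ramp_dvh):
        assert ramp_dvh.dose_at_volume(100) == pytest.approx(0.0)

    def test_volume_beyond_organ_rejected(self, ramp_dvh):
        with pytest.raises(RangeError):
            ramp_dvh.dose_at_volume(150)

    def test_inverse_of_volume_at_dose_on_grid(self, ramp_dvh):
        for d, v in zip(ramp_dvh.dose[1:], ramp_dvh.volume_cc[1:]):
            if v > 0:
                assert ramp_dvh.dose_at_volume(v) == pytest.approx(d)

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_non_increasing_in_volume(self, seed):
        dvh = random_cumulative_dvh(np.random.default_rng(seed))
        vols = np.linspace(0.05, 1.0, 15) * dvh.total_volume_cc
        doses = [dvh.dose_at_volume(v) for v in vols]
        assert all(x >= y - 1e-9 for x, y in zip(doses, doses[1:]))


class TestMeanDose:
    def test_uniform(self):
        assert DVH.uniform(30.0, 50.0).mean_dose() == pytest.approx(30.0)

    def test_symmetric_halves(self):
        dvh = DVH("o", "differential", [0, 60], [50, 50])
        assert dvh.mean_dose() == pytest.approx(30.0)

    def test_weighted_mean_by_hand(self):
        dvh = DVH("o", "differential", [10, 30, 50], [40, 35, 25])
        assert dvh.mean_dose() == pytest.approx(27.0)

    def test_zero_volume_undefined(self):
        with pytest.raises(UndefinedValueError):
            DVH("o", "cumulative", [0, 1], [0, 0]).mean_dose()

    def test_matches_analytic_mean_at_fine_bins(self):
        # linear cumulative curve V(D) = total * (1 - D/60): density uniform
        # on [0, 60], analytic mean 30 Gy; left-edge binning at 0.05 Gy must
        # agree to 0.1%
        grid = np.arange(0, 60.0001, 0.05)
        dvh = DVH("o", "cumulative", grid, 100 * (1 - grid / 60))
        assert dvh.mean_dose() == pytest.approx(30.0, rel=1e-3)


class TestConstraints:
    def test_stomach_volume_limit_passes(self):
        # ~9.8 cc of a 300 cc stomach at/above 50 Gy(RBE), limit 16 cc
        grid = np.array([0.0, 25.0, 50.0, 55.0])
        dvh = DVH("stomach", "cumulative", grid, [300, 40, 9.8, 0])
        spec = ConstraintSpec(MetricSpec("volume_at_dose", 50, "cc"),
                              "<=", 16.0, "V50GyE <= 16 cc")
        (res,) = evaluate_constraints(dvh, [spec])
        assert res.passed and res.achieved == pytest.approx(9.8)

    def test_duodenum_percent_limit_fails(self):
        grid = np.array([0.0, 25.0, 50.0])
        dvh = DVH("duodenum", "cumulative", grid, [70, 0.46 * 70, 0])
        spec = ConstraintSpec(MetricSpec("volume_at_dose", 25, "percent"),
                              "<=", 45.0, "V25GyE <= 45%")
        (res,) = evaluate_constraints(dvh, [spec])
        assert not res.passed and res.achieved == pytest.approx(46.0)

    def test_limit_tie_passes_le(self, ramp_dvh):
        spec = ConstraintSpec(MetricSpec("volume_at_dose", 40, "cc"), "<=", 25.0)
        assert evaluate_constraints(ramp_dvh, [spec])[0].passed

    def test_empty_constraint_list(self, ramp_dvh):
        assert evaluate_constraints(ramp_dvh, []) == []

    def test_metric_error_attached_not_raised(self):
        empty = DVH("o", "cumulative", [0, 1], [0, 0])
        spec = ConstraintSpec(MetricSpec("volume_at_dose", 0.5, "percent"),
                              "<=", 10.0)
        (res,) = evaluate_constraints(empty, [spec])
        assert res.passed is None and "zero-volume" in res.error


class TestWorstCaseEnvelope:
    def _scenarios(self, fracs):
        grid = np.array([0.0, 25.0, 50.0])
        return [DVH("duodenum", "cumulative", grid, [100, f, 0]) for f in fracs]

    def test_max_over_scenarios(self):
        metric = MetricSpec("volume_at_dose", 25, "percent")
        value, idx = worst_case_envelope(self._scenarios([40, 46, 43]), metric)
        assert (value, idx) == (pytest.approx(46.0), 1)

    def test_single_scenario_identity(self):
        metric = MetricSpec("volume_at_dose", 25, "percent")
        value, idx = worst_case_envelope(self._scenarios([40]), metric)
        assert (value, idx) == (pytest.approx(40.0), 0)

    def test_dose_metric_against_limit(self):
        grid = np.array([0.0, 40.0, 49.5, 55.9, 60.0])
        s1 = DVH("duodenum", "cumulative", grid, [70, 10, 1.0, 0, 0])
        s2 = DVH("duodenum", "cumulative", grid, [70, 10, 2.0, 1.0, 0])
        value, idx = worst_case_envelope(
            [s1, s2], MetricSpec("dose_at_volume", 1.0, "GyE"))
        assert idx == 1 and value == pytest.approx(55.9)
        assert value > 55.0  # worst scenario violates the 55 Gy(RBE) limit

    def test_min_direction_for_target_coverage(self):
        grid = np.array([0.0, 56.0, 60.0])
        scenarios = [DVH("CTV", "cumulative", grid, [80, v, 0])
                     for v in (79, 75, 78)]
        metric = MetricSpec("volume_at_dose", 56, "percent", direction="min")
        value, idx = worst_case_envelope(scenarios, metric)
        assert idx == 1 and value == pytest.approx(75 / 80 * 100)

    def test_envelope_bounds_every_scenario(self):
        metric = MetricSpec("volume_at_dose", 25, "percent")
        scenarios = self._scenarios([40, 46, 43, 12, 30])
        worst, _ = worst_case_envelope(scenarios, metric)
        assert all(worst >= metric.evaluate(s) for s in scenarios)

    def test_empty_and_mixed_labels_rejected(self):
        metric = MetricSpec("volume_at_dose", 25, "percent")
        with pytest.raises(RangeError):
            worst_case_envelope([], metric)
        mixed = self._scenarios([40]) + [DVH.uniform(10, 50, "stomach")]
        with pytest.raises(ValidationError):
            worst_case_envelope(mixed, metric)
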