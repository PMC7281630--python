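"""Per-sample aggregation, normality testing and Tukey outlier screening."""

import math

import numpy as np
import pytest

import spherefall as sf
from spherefall.cohort import METRICS, SampleMeasurement
from spherefall.errors import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidParameterError,
)
from spherefall.track import RepetitionResult


def rep(sid, idx, vt, r_max, accepted=True, r2=1.0):
    return RepetitionResult(sid, idx, vt, 0.0, r2 if accepted else 0.99, 12,
                            max_radius_um=r_max, accepted=accepted)


class TestAggregateSample:
    def test_below_five_of_nine_gate_is_invalid(self, medium):
        reps = [rep("a", i, 200.0, 50.0, accepted=i < 4) for i in range(9)]
        m = sf.aggregate_sample(reps, medium)
        assert not m.valid
        assert m.n_repetitions_accepted == 4
        assert "4" in (m.invalid_reason or "")

    def test_identical_noiseless_repetitions_zero_sd(self, medium, constants):
        truth = sf.SpherePhysical(47.5, 1024.0)
        vt = sf.terminal_velocity(truth, medium, constants)
        reps = [rep("a", i, vt, 47.5) for i in range(7)]
        m = sf.aggregate_sample(reps, medium, constants)
        assert m.valid
        assert m.vt_sd_um_s == 0.0 and m.density_sd_fg_um3 == 0.0 and m.weight_sd_ng == 0.0
        assert m.density_mean_fg_um3 == pytest.approx(1024.0, rel=1e-12)
        assert m.weight_mean_ng == pytest.approx(truth.weight_ng, rel=1e-12)
        assert m.diameter_um == pytest.approx(95.0)

    def test_parameter_recovery_on_noisy_sample(self, medium):
        """Mean density over 9 noisy reps lies within 3 SE of the truth."""
        cfg = sf.SimConfig(true_density_fg_um3=1032.0, radius_um=60.0, seed=11)
        reps = [
            sf.fit_terminal_velocity(sf.simulate_track(cfg, k, "x")) for k in range(9)
        ]
        m = sf.aggregate_sample(reps, medium)
        assert m.valid
        se = m.density_sd_fg_um3 / math.sqrt(m.n_repetitions_accepted)
        assert abs(m.density_mean_fg_um3 - 1032.0) < 3 * se + 1e-9

    def test_sd_shrinks_with_repetition_count(self, medium):
        """Across many simulated samples the SE of the density mean scales
        like 1/√n_repetitions (checked at n = 5, 9, 20 within 20%)."""
        scatter = {}
        for n_reps in (5, 9, 20):
            means = []
            for s in range(120):
                cfg = sf.SimConfig(
                    true_density_fg_um3=1030.0, radius_um=50.0, seed=1000 * n_reps + s
                )
                reps = [
                    sf.fit_terminal_velocity(sf.simulate_track(cfg, k, "x"),
                                             r2_threshold=1e-9)
                    for k in range(n_reps)
                ]
                means.append(sf.aggregate_sample(reps, medium, min_accepted=1).density_mean_fg_um3)
            scatter[n_reps] = np.std(means, ddof=1)
        assert scatter[5] / scatter[20] == pytest.approx(math.sqrt(20 / 5), rel=0.2)
        assert scatter[5] / scatter[9] == pytest.approx(math.sqrt(9 / 5), rel=0.2)

    def test_zero_accepted_reports_reason(self, medium):
        reps = [rep("a", i, 100.0, 40.0, accepted=False) for i in range(9)]
        m = sf.aggregate_sample(reps, medium)
        assert not m.valid and m.invalid_reason == "no accepted repetitions"

    def test_mixed_sample_ids_raise(self, medium):
        with pytest.raises(InvalidParameterError):
            sf.aggregate_sample([rep("a", 0, 1, 1), rep("b", 1, 1, 1)], medium)


class TestShapiroWilk:
    def test_type_one_error_calibrated(self, rng):
        """On standard-normal draws (n=72) the normal verdict rate over
        1000 replicates sits at the nominal 95% (±3σ binomial band)."""
        hits = sum(sf.shapiro_wilk(rng.normal(size=72)).normal for _ in range(1000))
        assert 0.93 <= hits / 1000 <= 0.97

    def test_power_against_heavy_contamination(self, rng):
        rejections = 0
        for _ in range(200):
            values = np.concatenate([rng.normal(size=66), rng.normal(8.0, 1.0, 6)])
            rejections += not sf.shapiro_wilk(values).normal
        assert rejections / 200 >= 0.95

    def test_w_statistic_in_unit_interval(self, rng):
        report = sf.shapiro_wilk(rng.normal(size=30), metric="density")
        assert 0 < report.statistic_w <= 1
        assert 0 < report.p_value <= 1
        assert report.metric == "density"

    def test_too_few_values_raise(self):
        with pytest.raises(InsufficientDataError):
            sf.shapiro_wilk([1.0, 2.0])

    def test_constant_values_degenerate(self):
        with pytest.raises(DegenerateDataError):
            sf.shapiro_wilk([3.0] * 10)


def brute_force_tukey(values, k=1.5):
    """Independent oracle: fences from manually interpolated quartiles."""
    v = sorted(values)
    n = len(v)

    def quantile(p):
        h = (n - 1) * p
        lo = int(math.floor(h))
        if lo == n - 1:
            return v[-1]
        return v[lo] + (h - lo) * (v[lo + 1] - v[lo])

    q1, q3 = quantile(0.25), quantile(0.75)
    iqr = q3 - q1
    return [x < q1 - k * iqr or x > q3 + k * iqr for x in values]


class TestTukeyOutliers:
    def test_uniform_spread_no_flags(self):
        assert not sf.tukey_outliers(range(1, 10)).any()

    def test_single_gross_outlier_flagged(self):
        flags = sf.tukey_outliers(list(range(1, 10)) + [100])
        assert flags.tolist() == [False] * 9 + [True]

    def test_all_equal_no_flags(self):
        assert not sf.tukey_outliers([5.0] * 8).any()

    def test_agrees_with_brute_force_battery(self, rng):
        """Random lists of every length 4–12 against the brute-force oracle."""
        for _ in range(300):
            n = int(rng.integers(4, 13))
            values = rng.normal(0, 1, n) * 10.0 ** float(rng.integers(-2, 3))
            if rng.random() < 0.3:  # occasionally inject a gross outlier
                values[rng.integers(n)] *= 50
            flags = sf.tukey_outliers(values)
            assert flags.tolist() == brute_force_tukey(values.tolist())

    def test_too_few_raise(self):
        with pytest.raises(InsufficientDataError):
            sf.tukey_outliers([1.0, 2.0, 3.0])


def make_measurement(sid, vt=300.0, rho=1035.0, d=140.0, w=1500.0):
    return SampleMeasurement(
        sample_id=sid,
        final_radius_um=d / 2,
        radius_sd_um=1.0,
        vt_mean_um_s=vt,
        vt_sd_um_s=5.0,
        density_mean_fg_um3=rho,
        density_sd_fg_um3=2.0,
        weight_mean_ng=w,
        weight_sd_ng=20.0,
        n_repetitions_total=9,
        n_repetitions_accepted=9,
        valid=True,
    )


class TestScreenCohort:
    def _cohort(self, rng, n=30):
        # normally distributed metrics, tight enough for normal verdicts
        return [
            make_measurement(
                f"s{i}",
                vt=300 + rng.normal(0, 10),
                rho=1035 + rng.normal(0, 2),
                d=140 + rng.normal(0, 4),
                w=1500 + rng.normal(0, 30),
            )
            for i in range(n)
        ]

    def _bounded_cohort(self, rng, n=30):
        # uniform (bounded) metrics can never exceed their own Tukey fences,
        # so any flag is attributable to the perturbation under test
        return [
            make_measurement(
                f"s{i}",
                vt=300 + rng.uniform(-20, 20),
                rho=1035 + rng.uniform(-4, 4),
                d=140 + rng.uniform(-8, 8),
                w=1500 + rng.uniform(-60, 60),
            )
            for i in range(n)
        ]

    def test_single_weight_outlier_removed_by_any_category_rule(self, rng):
        cohort = self._bounded_cohort(rng)
        cohort[7] = make_measurement("s7", w=9000.0)  # outlying only in weight
        table = sf.screen_cohort(cohort, tukey_on="all")
        assert table.removed_ids == ["s7"]
        assert table.removal_reasons()["s7"] == ["weight"]
        assert len(table.retained_ids) == 29

    def test_normal_verdicts_mean_no_tukey_no_removals(self, rng):
        cohort = self._cohort(rng)
        table = sf.screen_cohort(cohort)
        for metric in METRICS:
            assert table.normality_before[metric].normal
        assert table.removed_ids == []
        assert table.outlier_flags == {}

    def test_screen_is_deterministic(self, rng):
        cohort = self._bounded_cohort(rng)
        cohort[3] = make_measurement("s3", rho=1100.0)
        t1 = sf.screen_cohort(cohort, tukey_on="all")
        t2 = sf.screen_cohort(cohort, tukey_on="all")
        assert t1.removed_ids == t2.removed_ids == ["s3"]

    def test_invalid_samples_excluded_from_screen(self, rng):
        cohort = self._cohort(rng)
        gated = SampleMeasurement(sample_id="gated", valid=False,
                                  invalid_reason="only 3 accepted repetitions < 5")
        table = sf.screen_cohort(cohort + [gated])
        assert "gated" not in table.retained_ids
        assert "gated" not in table.removed_ids

    def test_normality_retested_after_removal(self, rng):
        cohort = self._cohort(rng, n=40)
        cohort[0] = make_measurement("s0", rho=1200.0)  # breaks density normality
        table = sf.screen_cohort(cohort)
        assert not table.normality_before["mass_density"].normal
        assert table.removed_ids == ["s0"]
        after = table.normality_after["mass_density"]
        assert after is not None and after.normal

    def test_too_few_valid_samples_raise(self, rng):
        with pytest.raises(InsufficientDataError):
            sf.screen_cohort(self._cohort(rng, n=3))


class TestSummarizeCohort:
    def test_single_sample_min_equals_max(self):
        table = sf.CohortTable(samples=[make_measurement("only")])
        table.retained_ids = ["only"]
        s = sf.summarize_cohort(table)
        for metric in METRICS:
            assert s[metric]["min"]["sample_id"] == "only"
            assert s[metric]["max"]["sample_id"] == "only"

    def test_density_range_tracks_generator_bounds(self, medium):
        """With densities drawn in [1024, 1046] the summarized extremes sit
        near those bounds."""
        samples = sf.simulate_cohort(60, n_repetitions=9, seed=7)
        measured = []
        for s in samples:
            reps = [sf.fit_terminal_velocity(t) for t in s.tracks]
            measured.append(sf.aggregate_sample(reps, medium))
        table = sf.screen_cohort(measured)
        summary = sf.summarize_cohort(table)
        lo = summary["mass_density"]["min"]["mean"]
        hi = summary["mass_density"]["max"]["mean"]
        assert 1023.0 < lo < 1028.0
        assert 1042.0 < hi < 1047.0

    def test_empty_retained_raises(self):
        table = sf.CohortTable(samples=[make_measurement("a")])
        with pytest.raises(InsufficientDataError):
            sf.summarize_cohort(table)
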