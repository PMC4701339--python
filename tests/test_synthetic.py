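"""Synthetic cohort generator tests: MIX process, calibration, cohorts."""

import numpy as np
import pytest

from fallgrf.data import FEATURE_NAMES, GROUP_FALLER, GROUP_NONFALLER
from fallgrf.entropy import sample_entropy, standardize
from fallgrf.exceptions import CalibrationError, ParameterError
from fallgrf.features import channel_entropy
from fallgrf.synthetic import (
    CohortSpec,
    MixProcessParams,
    calibrate_irregularity,
    generate_cohort,
    generate_mix_series,
    make_planted_targets,
    mix_entropy_curve,
)


class TestMixProcess:
    def test_p_zero_is_pure_sinusoid(self):
        params = MixProcessParams(p=0.0, period=8.0)
        s = generate_mix_series(params, 200, seed=42)
        t = np.arange(200)
        np.testing.assert_allclose(s, np.sin(2 * np.pi * t / 8.0))

    def test_pure_noise_has_higher_entropy_than_sinusoid(self):
        noisy = generate_mix_series(MixProcessParams(p=1.0), 1000, seed=1)
        clean = generate_mix_series(MixProcessParams(p=0.0), 1000, seed=1)
        assert sample_entropy(standardize(noisy)) > sample_entropy(
            standardize(clean))

    def test_deterministic_for_fixed_seed(self):
        params = MixProcessParams(p=0.3)
        a = generate_mix_series(params, 500, seed=9)
        b = generate_mix_series(params, 500, seed=9)
        np.testing.assert_array_equal(a, b)
        c = generate_mix_series(params, 500, seed=10)
        assert not np.array_equal(a, c)

    def test_entropy_stable_across_seeds(self):
        """Two seeds at the same p give entropies within the replicate spread."""
        params = MixProcessParams(p=0.3)
        ents = np.array([
            sample_entropy(standardize(generate_mix_series(params, 1000, s)))
            for s in range(50)
        ])
        e1, e2 = ents[0], ents[1]
        assert abs(e1 - e2) <= 3 * ents.std() * np.sqrt(2)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            MixProcessParams(p=1.5)
        with pytest.raises(ParameterError):
            generate_mix_series(MixProcessParams(p=0.5), 5, seed=0)

    def test_mean_entropy_monotone_in_p(self):
        """Mean SampEn over replicates is non-decreasing along the p grid."""
        p_grid = np.linspace(0, 1, 11)
        means = []
        for p in p_grid:
            params = MixProcessParams(p=float(p))
            vals = [
                sample_entropy(standardize(generate_mix_series(params, 600, s)))
                for s in range(30)
            ]
            means.append(np.nanmean(vals))
        diffs = np.diff(means)
        assert np.all(diffs >= -0.01)  # tiny Monte-Carlo wiggle allowed
        assert means[-1] > means[0] + 1.0


class TestCalibration:
    def test_target_at_floor_returns_p_zero(self):
        floor = float(np.mean([
            sample_entropy(standardize(
                generate_mix_series(MixProcessParams(0.0), 1000, s)))
            for s in range(5)
        ]))
        params = calibrate_irregularity(max(floor, 1e-6) + 1e-6, length=1000,
                                        seed=2)
        assert params.p == 0.0

    @pytest.mark.parametrize("target", [0.26, 0.111])
    def test_group_mean_targets_hit_within_tolerance(self, target):
        params = calibrate_irregularity(target, length=1000, seed=2)
        realized = np.mean([
            sample_entropy(standardize(
                generate_mix_series(params, 1000, 1000 + s)))
            for s in range(25)
        ])
        assert realized == pytest.approx(target, abs=0.05)

    def test_unachievable_target_names_interval(self):
        with pytest.raises(CalibrationError, match="achievable"):
            calibrate_irregularity(5.0, length=300, seed=0)

    def test_curve_inversion_round_trip(self):
        curve = mix_entropy_curve(600, seed=7)
        lo, hi = curve.achievable_range
        for target in np.linspace(lo + 0.05, hi - 0.05, 5):
            p = curve.p_for_entropy(float(target))
            assert 0.0 <= p <= 1.0
        with pytest.raises(CalibrationError):
            curve.p_for_entropy(hi + 1.0)


class TestGenerateCohort:
    def test_cohort_counts_and_labels(self, small_cohort):
        assert len(small_cohort) == 8
        fallers = [s for s in small_cohort if s.group == GROUP_FALLER]
        assert len(fallers) == 4
        for s in small_cohort:
            assert len(s.recordings) == 8
            assert 40.0 <= s.weight_kg <= 90.0

    def test_minimal_cohort_two_subjects_sixteen_recordings(self):
        spec = CohortSpec(n_fallers=1, n_nonfallers=1, seed=1,
                          series_length=300)
        cohort = generate_cohort(spec)
        assert len(cohort) == 2
        assert sum(len(s.recordings) for s in cohort) == 16

    def test_reference_cohort_shape(self):
        spec = CohortSpec(n_fallers=23, n_nonfallers=15, seed=7,
                          series_length=200)
        cohort = generate_cohort(spec)
        assert len(cohort) == 38
        assert sum(s.group == GROUP_FALLER for s in cohort) == 23

    def test_bit_identical_for_identical_spec(self):
        spec = CohortSpec(n_fallers=2, n_nonfallers=2, seed=13,
                          series_length=300)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        for sa, sb in zip(a, b):
            assert sa.subject_id == sb.subject_id
            assert sa.weight_kg == sb.weight_kg
            for ra, rb in zip(sa.recordings, sb.recordings):
                np.testing.assert_array_equal(ra.series, rb.series)

    def test_faller_sts_entropy_lower_across_replicates(self):
        """Group ordering on the most separated channel (R_V_F), checked on
        realized entropies over seeded replicates at n=30 per group."""
        correct = 0
        n_rep = 10
        for seed in range(n_rep):
            spec = CohortSpec(n_fallers=30, n_nonfallers=30, seed=900 + seed)
            cohort = generate_cohort(spec)
            faller = np.mean([channel_entropy(s, "R_V_F")
                              for s in cohort if s.group == GROUP_FALLER])
            nonfaller = np.mean([channel_entropy(s, "R_V_F")
                                 for s in cohort if s.group == GROUP_NONFALLER])
            correct += faller < nonfaller
        assert correct >= n_rep - 1

    def test_invalid_specs_rejected(self):
        with pytest.raises(ParameterError):
            CohortSpec(n_fallers=0, n_nonfallers=3)
        with pytest.raises(ParameterError):
            CohortSpec(n_fallers=2, n_nonfallers=2, series_length=50)

    def test_infeasible_targets_raise_calibration_error(self):
        targets = make_planted_targets(())
        targets[GROUP_FALLER]["L_ML_F"] = (9.0, 0.01)
        with pytest.raises(CalibrationError):
            generate_cohort(CohortSpec(2, 2, seed=0, series_length=300,
                                       entropy_targets=targets))

    def test_planted_targets_layout(self):
        targets = make_planted_targets(("L_V_F",), gap_sd=2.0,
                                       baseline_mean=0.4, sd=0.05)
        assert targets[GROUP_FALLER]["L_V_F"] == (0.4 - 0.1, 0.05)
        assert targets[GROUP_FALLER]["L_ML_F"] == (0.4, 0.05)
        assert all(v == (0.4, 0.05)
                   for v in targets[GROUP_NONFALLER].values())
        with pytest.raises(ParameterError):
            make_planted_targets(("NOT_A_CHANNEL",))
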