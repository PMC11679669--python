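import json

import numpy as np
import pytest

from imep import io_formats
from imep.marker_motion import exercise_movement
from imep.marker_motion import test_total_movement as total_movement_of_test
from imep.plate_features import cop_path, segment_window
from imep.scoring import raw_score_static
from imep.synthetic import (
    GeneratorConfig,
    SwayConfig,
    generate_cohort,
    generate_protocol,
    generate_static_trial,
    generate_ybt_scores,
    emit_fixture_set,
)


class TestGenerateCohort:
    def test_mean_age_matches_population_within_monte_carlo_bound(self, default_cohort):
        ages = [p.age for p in default_cohort]
        assert abs(np.mean(ages) - 7.27) <= 3 * 0.74 / np.sqrt(75)

    def test_ages_respect_inclusion_window(self, default_cohort):
        assert all(6.0 <= p.age <= 9.0 for p in default_cohort)

    def test_same_seed_reproduces_cohort(self, default_cohort):
        again = generate_cohort(GeneratorConfig(n=75, seed=1))
        assert again == default_cohort

    def test_zero_n_gives_empty_list(self):
        assert generate_cohort(GeneratorConfig(n=0, seed=1)) == []

    def test_sex_proportion_near_configured(self, default_cohort):
        frac = np.mean([p.sex == "female" for p in default_cohort])
        p = 44 / 75
        assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / 75)


class TestGenerateStaticTrial:
    def test_eyes_closed_increases_movement_on_paired_draws(self, default_cohort):
        profile = default_cohort[0]
        diffs = []
        for k in range(100):
            totals = {}
            for eyes in ("open", "closed"):
                _, tracks = generate_static_trial(profile, "SLB", eyes, seed=1000 + k)
                movement = exercise_movement(tracks, 1)
                totals[eyes] = movement.mvt
            diffs.append(totals["closed"] - totals["open"])
        assert np.mean(diffs) > 0

    def test_cop_pipeline_inverts_simulated_path(self, default_cohort):
        profile = default_cohort[0]
        trial, _ = generate_static_trial(profile, "SLB", "open", seed=3)
        window = segment_window("SLB", 16.0, trial.sampling_rate, trial.n_samples)
        cop_x, cop_y, dropped = cop_path(trial, window)
        assert dropped == 0
        # reconstruct the simulated path from the stored moments analytically
        start, stop = window
        sim_x = -trial.my[start:stop] / trial.fz[start:stop] * 100
        np.testing.assert_allclose(cop_x, sim_x, atol=1e-6)

    def test_zero_sway_means_zero_movement_and_raw_equals_cte(self, default_cohort):
        profile = default_cohort[0]
        quiet = SwayConfig(base_amplitude_cm=0.0)
        _, tracks = generate_static_trial(profile, "SLB", "open", seed=4, sway=quiet)
        exercises = [exercise_movement(tracks, i + 1) for i in range(4)]
        total = total_movement_of_test("SLB", exercises).total
        assert total == 0.0
        assert raw_score_static(total, 350.0) == 350.0

    def test_trial_is_deterministic_in_seed(self, default_cohort):
        profile = default_cohort[0]
        a, _ = generate_static_trial(profile, "TBT", "closed", seed=9)
        b, _ = generate_static_trial(profile, "TBT", "closed", seed=9)
        np.testing.assert_array_equal(a.fz, b.fz)
        np.testing.assert_array_equal(a.mx, b.mx)

    def test_older_children_sway_less_in_expectation(self, default_cohort):
        base = default_cohort[0]
        young = type(base)(nickname="y", sex=base.sex, age=6.2,
                           foot_size=base.foot_size, leg_length=base.leg_length,
                           weight=base.weight)
        old = type(base)(nickname="o", sex=base.sex, age=8.8,
                         foot_size=base.foot_size, leg_length=base.leg_length,
                         weight=base.weight)
        def mean_mvt(profile):
            vals = []
            for k in range(40):
                _, tracks = generate_static_trial(profile, "SLB", "open", seed=500 + k)
                vals.append(exercise_movement(tracks, 1).mvt)
            return np.mean(vals)
        assert mean_mvt(old) < mean_mvt(young)


class TestGenerateYbtScores:
    def test_direction_means_calibrated(self, default_cohort):
        anterior, posterolateral = [], []
        for i, profile in enumerate(default_cohort):
            for attempt in generate_ybt_scores(profile, seed=2000 + i):
                if attempt.direction == "anterior":
                    anterior.append(attempt.normalized_score)
                elif attempt.direction == "posterolateral":
                    posterolateral.append(attempt.normalized_score)
        se = 2.0 / np.sqrt(150)
        assert abs(np.mean(anterior) - 18.57) <= 3 * se
        assert abs(np.mean(posterolateral) - 16.30) <= 3 * se

    def test_direction_ordering_in_expectation(self, default_cohort):
        sums = {"anterior": 0.0, "posteromedial": 0.0, "posterolateral": 0.0}
        for i, profile in enumerate(default_cohort):
            for attempt in generate_ybt_scores(profile, seed=3000 + i):
                sums[attempt.direction] += attempt.normalized_score
        assert sums["anterior"] > sums["posteromedial"] > sums["posterolateral"]

    def test_reach_consistent_with_normalized_score(self, default_cohort):
        profile = default_cohort[0]
        for attempt in generate_ybt_scores(profile, seed=5):
            assert attempt.reach == pytest.approx(
                attempt.normalized_score * profile.leg_length / 10.0
            )

    def test_same_seed_reproduces_attempts(self, default_cohort):
        profile = default_cohort[0]
        assert generate_ybt_scores(profile, seed=6) == generate_ybt_scores(profile, seed=6)


class TestProtocolAndFixtures:
    def test_protocol_has_fourteen_slots(self, default_cohort):
        protocol = generate_protocol(default_cohort[0], seed=1)
        assert len(protocol) == 14
        tests = [meta["test_type"] for meta, _, _ in protocol]
        assert tests.count("SLB") == 4
        assert tests.count("TBT") == 4
        assert tests.count("YBT") == 6

    def test_fixture_set_counts_and_round_trip(self, tmp_path):
        config = GeneratorConfig(n=2, seed=7)
        manifest = emit_fixture_set(config, tmp_path)
        assert len(manifest["plate_files"]) == 28
        assert len(manifest["marker_files"]) == 28 * 3
        # re-read one plate file and its markers through the io layer
        trial = io_formats.read_plate_export(tmp_path / manifest["plate_files"][0])
        assert trial.n_samples == int(16 * config.sway.sampling_rate)
        track = io_formats.read_marker_track(
            tmp_path / manifest["marker_files"][0], "acromion"
        )
        assert len(track) == trial.n_samples
        profiles = io_formats.read_cohort_table(tmp_path / "cohort.csv")
        assert len(profiles) == 2

    def test_ground_truth_records_generator_parameters(self, tmp_path):
        config = GeneratorConfig(n=1, seed=8)
        emit_fixture_set(config, tmp_path)
        truth = json.loads((tmp_path / "ground_truth.json").read_text())
        assert truth["seed"] == 8
        assert truth["demographics"]["age_mean"] == 7.27
        assert truth["ybt"]["anterior_mean"] == 18.57
        assert truth["sway"]["base_amplitude_cm"] == 1.0
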