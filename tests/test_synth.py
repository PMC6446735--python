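"""Synthetic-cohort generator: schedules, signal model, artifacts, outcomes."""

import numpy as np
import pandas as pd
import pytest

from cuelpp.config import BLOCK_COMPOSITION, CATEGORIES, DEFAULT_CONFIG, POSSIBLE_TRIALS
from cuelpp.data_model import ValidationError, default_montage
from cuelpp.erp import average_by_category, extract_lpp
from cuelpp.preprocess import average_reference, baseline_correct
from cuelpp.qc import RULE_FLATLINE, flag_sensor_artifacts
from cuelpp.synth import (
    DEFAULT_AMPLITUDE_MAP,
    CohortSpec,
    build_task_schedule,
    cohort_ground_truth,
    expected_lpp,
    generate_cohort,
    inject_artifacts,
    lpp_trial_noise_sd,
    max_run_length,
    pink_noise,
    simulate_epochs,
    simulate_lpp_cohort,
    simulate_outcomes,
)


class TestTaskSchedule:
    def test_composition_exact(self):
        sched = build_task_schedule(3, "sweet")
        assert len(sched) == 330
        df = sched.table
        for block in range(1, 7):
            counts = df[df["block"] == block]["category"].value_counts().to_dict()
            assert counts == BLOCK_COMPOSITION
        total = df["category"].value_counts().to_dict()
        assert total == POSSIBLE_TRIALS

    def test_run_length_at_most_two(self):
        for seed in range(20):
            sched = build_task_schedule(seed)
            assert max_run_length(list(sched.categories)) <= 2

    def test_deterministic(self):
        a = build_task_schedule(42, "savory").table
        b = build_task_schedule(42, "savory").table
        pd.testing.assert_frame_equal(a, b)

    def test_onsets_spacing(self):
        # gap >= duration + minimum ITI; paired trials are longer
        sched = build_task_schedule(5).table
        gaps = np.diff(sched["onset_sample"].to_numpy())
        cats = sched["category"].to_numpy()[:-1]
        min_unpaired = (2200 + 500) * 0.25 / 1000 * 1000   # samples at 250 Hz
        assert np.all(gaps[cats != "food_paired"] >= 675)
        assert np.all(gaps[cats != "food_paired"] <= 1050 + 1)
        assert np.all(gaps[cats == "food_paired"] >= 675 + 250)

    def test_bad_paired_content(self):
        with pytest.raises(ValidationError):
            build_task_schedule(1, "salty")


class TestSignalModel:
    def test_noise_free_lpp_closed_form(self, small_montage):
        sched = build_task_schedule(1, "sweet")
        epochs = simulate_epochs(
            sched, "PC", DEFAULT_AMPLITUDE_MAP, 0.0, small_montage, 0
        )
        epochs = baseline_correct(average_reference(epochs))
        averages = average_by_category(epochs)
        exp = expected_lpp(DEFAULT_AMPLITUDE_MAP["PC"])
        for cat in CATEGORIES:
            got = extract_lpp(averages[cat], small_montage, epochs.time_axis)
            assert got == pytest.approx(exp[cat], abs=1e-9)

    def test_expected_ordering_arousal_gradient(self):
        # within both profiles: erotica & mutilation > romantic & violence
        # > neutral & pollution; paired > unpaired
        for prof in ("CP", "PC"):
            e = expected_lpp(DEFAULT_AMPLITUDE_MAP[prof])
            assert min(e["erotica"], e["mutilation"]) > max(e["romantic"], e["violence"])
            assert min(e["romantic"], e["violence"]) > max(e["neutral"], e["pollution"])
            assert e["food_paired"] > e["food_unpaired"]
        assert expected_lpp(DEFAULT_AMPLITUDE_MAP["CP"])["food_paired"] > \
            expected_lpp(DEFAULT_AMPLITUDE_MAP["CP"])["erotica"]
        assert expected_lpp(DEFAULT_AMPLITUDE_MAP["PC"])["food_paired"] < \
            expected_lpp(DEFAULT_AMPLITUDE_MAP["PC"])["erotica"]

    def test_baseline_has_zero_expected_mean(self, small_montage):
        sched = build_task_schedule(2)
        epochs = simulate_epochs(sched, "CP", DEFAULT_AMPLITUDE_MAP, 0.0,
                                 small_montage, 0)
        base = epochs.data[:, :, epochs.time_axis < 0]
        assert np.abs(base).max() == 0.0

    def test_pink_noise_sd_and_analytic_lpp_sd(self):
        rng = np.random.default_rng(0)
        y = pink_noise(rng, (3000,), 300, 250.0, 8.0)
        assert y.std() == pytest.approx(8.0, rel=0.05)
        # Monte-Carlo check of the analytic single-trial LPP noise SD
        cfg = DEFAULT_CONFIG
        sl, bl = cfg.window_slice(cfg.lpp_window_ms), cfg.window_slice(cfg.baseline_ms)
        y = pink_noise(rng, (3000, 10), 300, 250.0, 8.0)
        est = (y[:, :, sl].mean(axis=2) - y[:, :, bl].mean(axis=2)).mean(axis=1)
        assert lpp_trial_noise_sd(8.0) == pytest.approx(est.std(), rel=0.1)

    def test_unknown_profile_rejected(self, small_montage):
        sched = build_task_schedule(1)
        with pytest.raises(ValidationError):
            simulate_epochs(sched, "XX", DEFAULT_AMPLITUDE_MAP, 1.0, small_montage, 0)


class TestArtifacts:
    def _clean_epochs(self, montage, seed=4):
        sched = build_task_schedule(seed)
        return simulate_epochs(sched, "CP", DEFAULT_AMPLITUDE_MAP, 0.0, montage, seed)

    def test_zero_rates_identity(self, small_montage):
        epochs = self._clean_epochs(small_montage)
        out, log = inject_artifacts(epochs, {k: 0.0 for k in ("excursion", "jump")}, 1)
        np.testing.assert_array_equal(out.data, epochs.data)
        assert len(log) == 0

    def test_every_injected_artifact_is_flagged(self, small_montage):
        epochs = self._clean_epochs(small_montage)
        rates = {"excursion": 0.05, "jump": 0.05, "range": 0.05, "flatline": 0.05}
        out, log = inject_artifacts(epochs, rates, 2)
        assert len(log) > 50
        flags, bits = flag_sensor_artifacts(out.data)
        for row in log.itertuples():
            assert flags[row.trial, row.sensor], (row.trial, row.sensor, row.kind)

    def test_flatline_caught_by_rule_4_only(self, small_montage):
        epochs = self._clean_epochs(small_montage)
        out, log = inject_artifacts(epochs, {"flatline": 0.05}, 3)
        _, bits = flag_sensor_artifacts(out.data)
        assert len(log) > 10
        for row in log.itertuples():
            assert bits[row.trial, row.sensor] == 1 << (RULE_FLATLINE - 1)

    def test_false_flag_rate_without_injection_at_default_noise(self, small_montage):
        from cuelpp.pipeline import preprocess_epochs

        sched = build_task_schedule(9)
        epochs = simulate_epochs(sched, "CP", DEFAULT_AMPLITUDE_MAP, 8.0,
                                 small_montage, 9)
        raw_rate = flag_sensor_artifacts(epochs.data)[0].mean()
        # QC runs on filtered epochs; the 30 Hz low-pass removes nearly all
        # step-rule false positives of the raw 1/f noise
        filtered_rate = flag_sensor_artifacts(preprocess_epochs(epochs).data)[0].mean()
        assert filtered_rate < 0.005
        assert filtered_rate <= raw_rate

    def test_rates_sum_validation(self, small_montage):
        epochs = self._clean_epochs(small_montage)
        with pytest.raises(ValidationError):
            inject_artifacts(epochs, {"excursion": 0.7, "jump": 0.7}, 0)


class TestOutcomes:
    def test_dispersion_one_is_poisson(self):
        spec = CohortSpec(n_cp=8000, n_pc=0, outcome_means={"CP": 8.0, "PC": 8.0},
                          outcome_dispersion=1.0, seed=1)
        truth = cohort_ground_truth(spec)
        outcomes = simulate_outcomes(truth, dispersion=1.0, seed=2)
        candies = outcomes.table["candies"].to_numpy()
        assert candies.var() / candies.mean() == pytest.approx(1.0, abs=0.05)

    def test_dispersion_moments(self):
        spec = CohortSpec(n_cp=8000, n_pc=0, outcome_dispersion=1.5, seed=1)
        truth = cohort_ground_truth(spec)
        outcomes = simulate_outcomes(truth, seed=3)
        candies = outcomes.table["candies"].to_numpy()
        assert candies.mean() == pytest.approx(20.0, rel=0.03)
        assert candies.var() / candies.mean() == pytest.approx(1.5, abs=0.1)

    def test_underdispersion_rejected(self):
        spec = CohortSpec(seed=1)
        truth = cohort_ground_truth(spec)
        with pytest.raises(ValidationError):
            simulate_outcomes(truth, dispersion=0.8, seed=0)

    def test_same_seed_identical(self):
        truth = cohort_ground_truth(CohortSpec(seed=5))
        a = simulate_outcomes(truth, seed=9).table
        b = simulate_outcomes(truth, seed=9).table
        pd.testing.assert_frame_equal(a, b)


class TestCohortAssembly:
    def test_default_cohort_has_49_participants(self):
        spec = CohortSpec()
        truth = cohort_ground_truth(spec)
        assert len(truth.frame) == 49
        assert (truth.frame["profile"] == "CP").sum() == 20
        assert (truth.frame["profile"] == "PC").sum() == 29

    def test_paired_content_counterbalanced(self):
        truth = cohort_ground_truth(CohortSpec())
        paired = truth.frame["paired_content"].value_counts()
        assert abs(paired["sweet"] - paired["savory"]) <= 1

    def test_two_participant_cohort(self):
        spec = CohortSpec(n_cp=1, n_pc=1, n_sensors=16, n_roi=4)
        cohort = generate_cohort(spec)
        assert set(cohort.truth.frame["profile"]) == {"CP", "PC"}
        sets = list(cohort.epoch_sets())
        assert len(sets) == 2

    def test_cohort_determinism(self):
        spec = CohortSpec(n_cp=1, n_pc=1, n_sensors=16, n_roi=4, seed=13)
        a, b = generate_cohort(spec), generate_cohort(spec)
        pd.testing.assert_frame_equal(a.truth.frame, b.truth.frame)
        pd.testing.assert_frame_equal(a.outcomes.table, b.outcomes.table)
        (ea, sa, la), (eb, sb, lb) = next(a.epoch_sets()), next(b.epoch_sets())
        np.testing.assert_array_equal(ea.data, eb.data)
        pd.testing.assert_frame_equal(sa.table, sb.table)

    def test_lpp_cohort_matches_closed_form_in_expectation(self):
        # with jitter/noise off, the LPP-level generator reproduces the
        # closed-form expectations exactly (up to per-subject gain/offset)
        spec = CohortSpec(n_cp=2, n_pc=2, noise_sd=0.0, subject_gain_log_sd=0.0,
                          subject_amp_jitter_sd=0.0, subject_offset_sd=0.0, seed=3)
        lpp_df, truth = simulate_lpp_cohort(spec)
        for pid in truth.participants:
            exp = expected_lpp(DEFAULT_AMPLITUDE_MAP[truth.profile_of(pid)])
            for cat in CATEGORIES:
                assert lpp_df.loc[pid, f"lpp_{cat}"] == pytest.approx(exp[cat], abs=1e-9)
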