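import math

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from eegworkload import spectral, synth, tasks
from eegworkload.synth import (
    BehaviorConfigError,
    BehaviorModel,
    EEGGenParams,
    RTParams,
    StudyConfig,
    amplitudes_for_target,
    simulate_behavior,
    simulate_cohort_scores,
    simulate_eeg,
    simulate_session,
    simulate_study,
    trial_results_from_frame,
    trial_results_to_frame,
)
from eegworkload.tasks import Task, build_stroop_design

from conftest import perfect_behavior_model


class TestSimulateBehavior:
    def test_zero_rates_all_correct(self):
        design = build_stroop_design(1, "congruent")
        results = simulate_behavior(design, perfect_behavior_model(), 2)
        assert len(results) == design.n_trials
        assert all(r.correct for r in results)
        assert all(r.response == t.correct_response
                   for r, t in zip(results, design.trials))

    def test_determinism(self):
        design = build_stroop_design(1, "congruent")
        model = BehaviorModel()
        a = trial_results_to_frame(simulate_behavior(design, model, 5))
        b = trial_results_to_frame(simulate_behavior(design, model, 5))
        pd.testing.assert_frame_equal(a, b)

    def test_missing_condition_named(self):
        design = build_stroop_design(1, "congruent")
        model = BehaviorModel({(Task.STROOP, "congruent"): RTParams(0.9, 0.1)})
        with pytest.raises(BehaviorConfigError, match="incongruent"):
            simulate_behavior(design, model, 1)

    def test_rt_truncated_at_deadline(self):
        design = build_stroop_design(4, "congruent")
        model = BehaviorModel(
            {
                (Task.STROOP, c): RTParams(2.0, 2.0, error_prob=0.0, omission_prob=0.0)
                for c in ("congruent", "incongruent")
            }
        )
        results = simulate_behavior(design, model, 3)
        assert all(r.rt < 3.0 for r in results)

    def test_onsets_strictly_increasing(self):
        design = build_stroop_design(2, "incongruent")
        results = simulate_behavior(design, BehaviorModel(), 9)
        onsets = [r.onset for r in results]
        assert all(b > a for a, b in zip(onsets, onsets[1:]))

    def test_omissions_counted_as_errors(self):
        design = build_stroop_design(2, "congruent")
        model = BehaviorModel(
            {
                (Task.STROOP, c): RTParams(0.9, 0.1, error_prob=0.0, omission_prob=1.0)
                for c in ("congruent", "incongruent")
            }
        )
        results = simulate_behavior(design, model, 1)
        assert all(r.response is None and not r.correct for r in results)
        assert all(math.isnan(r.rt) for r in results)

    def test_monte_carlo_rt_means(self):
        # ~10k trials per condition: sample means within 2 SE of configured
        model = perfect_behavior_model()
        rts = {"congruent": [], "incongruent": []}
        for seed in range(70):
            design = build_stroop_design(seed, "congruent")
            for r in simulate_behavior(design, model, 1000 + seed):
                rts[r.condition].append(r.rt)
        for cond, mean, sd in (("congruent", 0.905, 0.130),
                               ("incongruent", 1.078, 0.200)):
            xs = np.array(rts[cond])
            assert len(xs) >= 10000
            se = sd / np.sqrt(len(xs))
            assert abs(xs.mean() - mean) < 2 * se + 0.005

    def test_roundtrip_frame(self, tmp_path):
        design = build_stroop_design(3, "congruent")
        results = simulate_behavior(design, BehaviorModel(), 7)
        path = tmp_path / "trials.csv"
        trial_results_to_frame(results).to_csv(path, index=False)
        back = trial_results_from_frame(pd.read_csv(path))
        assert len(back) == len(results)
        for x, y in zip(back, results):
            assert (x.trial_id, x.condition, x.response, x.correct) == (
                y.trial_id, y.condition, y.response, y.correct
            )
            assert x.rt == pytest.approx(y.rt, nan_ok=True)


def welch_band_power(x, rate, band):
    """Independent oracle: Welch band power in µV²."""
    f, pxx = sps.welch(x, fs=rate, nperseg=2048)
    mask = (f >= band[0]) & (f < band[1])
    return np.trapezoid(pxx[mask], f[mask])


class TestSimulateEEG:
    def test_symmetric_amplitudes_tar_one(self, short_trials, compact_params):
        rec = simulate_eeg(short_trials, compact_params, 3)
        eps = spectral.extract_epochs(rec, short_trials)
        assert spectral.compute_tar(eps).tar == pytest.approx(1.0, rel=0.05)

    def test_double_theta_power_welch_oracle(self, short_trials):
        params = EEGGenParams(
            channel_labels=tuple(synth.compact_montage()),
            noise_amplitude=0.0,
            artifact_prob=0.0,
            theta_amp_fz=10.0 * np.sqrt(2),
            alpha_amp_pz=10.0,
        )
        rec = simulate_eeg(short_trials, params, 3)
        theta = welch_band_power(rec.channel("Fz"), rec.sampling_rate, (4, 8))
        alpha = welch_band_power(rec.channel("Pz"), rec.sampling_rate, (8, 12))
        assert theta / alpha == pytest.approx(2.0, rel=0.05)
        eps = spectral.extract_epochs(rec, short_trials)
        assert spectral.compute_tar(eps).tar == pytest.approx(2.0, rel=0.05)

    def test_all_artifacts_zero_retention(self, short_trials):
        params = EEGGenParams(
            channel_labels=tuple(synth.compact_montage()),
            noise_amplitude=0.0,
            artifact_prob=1.0,
        )
        rec = simulate_eeg(short_trials, params, 4)
        eps = spectral.extract_epochs(rec, short_trials)
        assert len(eps) == 0
        with pytest.raises(spectral.InsufficientDataError):
            spectral.compute_tar(eps)

    def test_markers_at_onsets(self, short_trials, short_recording):
        assert len(short_recording.events) == len(short_trials)
        for ev, t in zip(short_recording.events, short_trials):
            assert ev.sample == int(round(t.onset * 500.0))
            assert ev.trial_id == t.trial_id

    def test_low_rate_rejected(self, short_trials):
        with pytest.raises(ValueError):
            EEGGenParams(
                sampling_rate=50.0, channel_labels=tuple(synth.compact_montage())
            )

    def test_determinism(self, short_trials, compact_params):
        a = simulate_eeg(short_trials, compact_params, 8)
        b = simulate_eeg(short_trials, compact_params, 8)
        np.testing.assert_array_equal(a.data, b.data)

    def test_montage_requires_fz_pz(self):
        with pytest.raises(ValueError, match="Fz"):
            EEGGenParams(channel_labels=("Cz", "Pz"))

    def test_default_montage_64_plus_eyes(self):
        labels = synth.standard_montage()
        assert len(labels) == 66
        assert "Fz" in labels and "Pz" in labels
        assert labels[-2:] == ["HEOG", "VEOG"]
        assert len(set(labels)) == 66


class TestAmplitudes:
    def test_infeasible_target(self):
        with pytest.raises(ValueError, match="infeasible"):
            amplitudes_for_target(-0.5, 10.0)

    def test_target_scaling(self):
        theta, alpha = amplitudes_for_target(4.0, 10.0)
        assert alpha == 10.0
        assert theta == pytest.approx(20.0)  # power ratio 4 => amp ratio 2


class TestCohortScores:
    def test_sizes(self):
        cfg = StudyConfig(group_sizes={"A": 30, "B": 23, "C": 23}, master_seed=1)
        scores = simulate_cohort_scores(cfg)
        assert scores["subject"].nunique() == 76
        assert len(scores) == 76 * 3  # per subject x task
        assert scores.groupby("group")["subject"].nunique().to_dict() == {
            "A": 30, "B": 23, "C": 23
        }

    def test_reproducible(self):
        cfg = StudyConfig(group_sizes={"A": 4, "B": 4, "C": 4}, master_seed=7)
        pd.testing.assert_frame_equal(
            simulate_cohort_scores(cfg), simulate_cohort_scores(cfg)
        )

    def test_subject_independence(self):
        # growing group C must not perturb earlier subjects' draws
        small = StudyConfig(group_sizes={"A": 3, "B": 3, "C": 3}, master_seed=5)
        big = StudyConfig(group_sizes={"A": 3, "B": 3, "C": 6}, master_seed=5)
        a = simulate_cohort_scores(small)
        b = simulate_cohort_scores(big)
        common = a["subject"].unique()
        pd.testing.assert_frame_equal(
            a[a["subject"].isin(common)].reset_index(drop=True),
            b[b["subject"].isin(common)].reset_index(drop=True),
        )

    def test_latent_correlation_approaches_r(self):
        cfg = StudyConfig(
            group_sizes={"A": 400, "B": 2, "C": 2},
            tasks=(Task.STROOP,),
            pre_post_r=0.7,
            master_seed=11,
        )
        scores = simulate_cohort_scores(cfg)
        sub = scores[scores["group"] == "A"]
        r_emp = np.corrcoef(sub["tar_pre"], sub["tar_post"])[0, 1]
        assert r_emp == pytest.approx(0.7, abs=0.08)

    def test_configured_simulator_stroop_drop(self):
        # mean pre-post TAR drop for group A, Stroop ~ 2.06 - 1.34 = 0.72
        cfg = StudyConfig(
            group_sizes={"A": 500, "B": 2, "C": 2},
            tasks=(Task.STROOP,),
            master_seed=3,
        )
        scores = simulate_cohort_scores(cfg)
        sub = scores[scores["group"] == "A"]
        drop = (sub["tar_pre"] - sub["tar_post"]).mean()
        assert drop == pytest.approx(0.72, abs=0.12)

    def test_invalid_config(self):
        with pytest.raises(ValueError, match="at least 2"):
            StudyConfig(group_sizes={"A": 1, "B": 4, "C": 4})
        with pytest.raises(ValueError, match="-1, 1"):
            StudyConfig(pre_post_r=1.0)


@pytest.mark.slow
class TestSimulateStudy:
    def test_latent_target_recovery_noise_free(self, compact_params):
        cfg = StudyConfig(
            group_sizes={"A": 2, "B": 2, "C": 2},
            tasks=(Task.STROOP,),
            eeg=EEGGenParams(
                channel_labels=tuple(synth.compact_montage()),
                noise_amplitude=0.0,
                artifact_prob=0.0,
            ),
            master_seed=21,
        )
        for target in (0.8, 1.7, 3.2):
            trials, rec = simulate_session(
                Task.STROOP, "pre", target, cfg, seed=100 + int(target * 10)
            )
            rec = spectral.bandpass_filter(rec)
            eps = spectral.extract_epochs(rec, trials)
            assert spectral.compute_tar(eps).tar == pytest.approx(target, rel=0.05)

    def test_cohort_tree_written(self, tmp_path):
        cfg = StudyConfig(
            group_sizes={"A": 2, "B": 2, "C": 2},
            tasks=(Task.STROOP,),
            eeg=EEGGenParams(
                sampling_rate=250.0,
                channel_labels=tuple(synth.compact_montage()),
            ),
            master_seed=2,
        )
        manifest = simulate_study(cfg, tmp_path / "cohort")
        assert len(manifest["subjects"]) == 6
        # 6 subjects x 2 phases x 1 task
        sessions = [
            s for subj in manifest["subjects"] for s in subj["sessions"]
        ]
        assert len(sessions) == 12
        for subj in manifest["subjects"]:
            for sess in subj["sessions"]:
                d = tmp_path / "cohort" / sess["path"]
                assert (d / "trials.csv").exists()
                assert (d / "eeg.dat").exists()
                assert (d / "eeg.json").exists()
                assert sess["tar_target"] > 0
        assert (tmp_path / "cohort" / "manifest.json").exists()
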