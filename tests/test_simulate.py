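"""Simulator contracts: determinism, label structure, signal structure, IO."""

import numpy as np
import pytest

import ovinesense as ov
from ovinesense.features import compute_spectrum, dominant_and_harmonic_frequencies
from ovinesense.simulate import ACTIVITIES, generate_recording


def flock_equal(a, b):
    return all(
        ra.sheep_id == rb.sheep_id
        and np.array_equal(ra.accel, rb.accel)
        and np.array_equal(ra.gyro, rb.gyro)
        and ra.annotations == rb.annotations
        for ra, rb in zip(a, b)
    )


class TestGenerateFlock:
    def test_fixed_seed_reproduces_bit_identical_flock(self):
        cfg = ov.SimulationConfig(recording_duration=120, n_lame=2, n_nonlame=2, rng_seed=7)
        assert flock_equal(ov.generate_flock(cfg), ov.generate_flock(cfg))

    def test_sample_count_is_rate_times_duration(self):
        cfg = ov.SimulationConfig(recording_duration=3600, n_lame=1, n_nonlame=0, rng_seed=0)
        rec = ov.generate_flock(cfg)[0]
        assert len(rec.timestamps) == 57_600
        assert rec.accel.shape == (57_600, 3)

    def test_default_flock_matches_deployment_composition(self):
        cfg = ov.SimulationConfig(recording_duration=60)
        profiles = ov.default_profiles(cfg)
        assert sum(p.lameness_score >= 2 for p in profiles) == 13
        assert sum(p.lameness_score <= 1 for p in profiles) == 10

    def test_empty_profiles_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ov.generate_flock(ov.SimulationConfig(recording_duration=60), [])

    def test_non_positive_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            ov.SimulationConfig(recording_duration=0.0)

    def test_activity_shares_track_budget_for_long_recordings(self):
        cfg = ov.SimulationConfig(recording_duration=1800, n_lame=0, n_nonlame=1, rng_seed=11)
        profile = ov.SheepProfile("s0", 0)
        rec = ov.generate_flock(cfg, [profile])[0]
        spent = dict.fromkeys(ACTIVITIES, 0.0)
        for start, end, activity, _ in rec.annotations:
            spent[activity] += end - start
        total = sum(spent.values())
        for activity in ACTIVITIES:
            assert spent[activity] / total == pytest.approx(
                profile.activity_budget[activity], abs=0.05
            )


class TestGenerateActivityBout:
    def test_zero_effect_size_makes_lame_generator_identical(self, rng):
        """With effect_size=0 the lame and non-lame code paths coincide:
        the same RNG state produces bit-identical segments."""
        cfg = ov.SimulationConfig()
        sound = ov.SheepProfile("a", lameness_score=0, effect_size=0.0)
        lame = ov.SheepProfile("b", lameness_score=3, effect_size=0.0)
        for activity in ACTIVITIES:
            a0, g0 = ov.generate_activity_bout(activity, sound, 20, np.random.default_rng(9))
            a1, g1 = ov.generate_activity_bout(activity, lame, 20, np.random.default_rng(9))
            assert np.array_equal(a0, a1) and np.array_equal(g0, g1)

    def test_walking_dominant_frequency_is_gait_frequency(self):
        """Low-noise walking: the accel-magnitude-difference spectrum peaks
        at the gait frequency to within one DFT bin of a 7 s window."""
        profile = ov.SheepProfile("s", 0, gait_frequency=1.5)
        cfg = ov.SimulationConfig(noise_sd_accel=1e-12, noise_sd_gyro=1e-12)
        bin_width = 16.0 / 112
        for seed in range(10):
            accel, _ = ov.generate_activity_bout(
                "walking", profile, 7.0625, np.random.default_rng(seed), cfg
            )
            accel[:, 0] += 1.0  # gravity on the main axis
            diff = np.diff(np.linalg.norm(accel, axis=1))
            dom = dominant_and_harmonic_frequencies(compute_spectrum(diff[:112], 16.0))[0]
            assert abs(dom - 1.5) <= bin_width + 1e-9

    def test_activity_intensity_ordering(self, rng):
        """Mean |accel magnitude difference| orders lying < standing < walking."""
        profile = ov.SheepProfile("s", 0)
        cfg = ov.SimulationConfig()
        means = {}
        for activity in ACTIVITIES:
            vals = []
            for _ in range(100):
                accel, _ = ov.generate_activity_bout(activity, profile, 10, rng, cfg)
                accel[:, 0] += 1.0
                vals.append(np.mean(np.abs(np.diff(np.linalg.norm(accel, axis=1)))))
            means[activity] = np.mean(vals)
        assert means["lying"] < means["standing"] < means["walking"]

    def test_lame_walking_shifts_frequency_and_adds_nod(self, rng):
        profile = ov.SheepProfile("s", 3, gait_frequency=1.9, effect_size=2.0)
        cfg = ov.SimulationConfig(noise_sd_accel=1e-6, noise_sd_gyro=1e-6)
        accel, _ = ov.generate_activity_bout("walking", profile, 14, rng, cfg)
        accel[:, 0] += 1.0
        diff = np.diff(np.linalg.norm(accel, axis=1))
        dom = dominant_and_harmonic_frequencies(compute_spectrum(diff[:112], 16.0))[0]
        expected = 1.9 - 2.0 * cfg.lame_frequency_shift
        assert abs(dom - expected) <= 2 * 16.0 / 112

    def test_unknown_activity_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown activity"):
            ov.generate_activity_bout("grazing", ov.SheepProfile("s", 0), 10, rng)

    def test_walking_shorter_than_ethogram_minimum_rejected(self, rng):
        with pytest.raises(ValueError, match="2"):
            ov.generate_activity_bout("walking", ov.SheepProfile("s", 0), 1.0, rng)


class TestProfileValidation:
    def test_budget_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ov.SheepProfile("s", 0, activity_budget={"walking": 0.5, "standing": 0.5, "lying": 0.5})

    def test_score_bounds(self):
        with pytest.raises(ValueError, match="lameness_score"):
            ov.SheepProfile("s", 7)

    def test_binary_class_threshold(self):
        assert not ov.SheepProfile("s", 1).is_lame
        assert ov.SheepProfile("s", 2).is_lame


class TestRecordingIO:
    def test_round_trip_is_exact(self, small_recording, tmp_path):
        ov.write_recording(small_recording, tmp_path / "s.csv", tmp_path / "a.csv")
        back = ov.read_recording(tmp_path / "s.csv", tmp_path / "a.csv")
        assert back.sheep_id == small_recording.sheep_id
        assert np.array_equal(back.timestamps, small_recording.timestamps)
        assert np.array_equal(back.accel, small_recording.accel)
        assert np.array_equal(back.gyro, small_recording.gyro)
        assert back.annotations == small_recording.annotations

    def test_out_of_order_annotations_sorted_on_read(self, small_recording, tmp_path):
        ov.write_recording(small_recording, tmp_path / "s.csv", tmp_path / "a.csv")
        lines = (tmp_path / "a.csv").read_text().splitlines()
        shuffled = [lines[0]] + lines[1:][::-1]
        (tmp_path / "a.csv").write_text("\n".join(shuffled) + "\n")
        back = ov.read_recording(tmp_path / "s.csv", tmp_path / "a.csv")
        assert back.annotations == small_recording.annotations

    def test_annotation_end_before_start_names_row(self, small_recording, tmp_path):
        ov.write_recording(small_recording, tmp_path / "s.csv", tmp_path / "a.csv")
        lines = (tmp_path / "a.csv").read_text().splitlines()
        sheep, start, end, act, score = lines[1].split(",")
        lines[1] = ",".join([sheep, end, start, act, score])
        (tmp_path / "a.csv").write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="row 0"):
            ov.read_recording(tmp_path / "s.csv", tmp_path / "a.csv")

    def test_non_monotone_timestamps_rejected(self, small_recording, tmp_path):
        ov.write_recording(small_recording, tmp_path / "s.csv", tmp_path / "a.csv")
        lines = (tmp_path / "s.csv").read_text().splitlines()
        lines[2], lines[3] = lines[3], lines[2]
        (tmp_path / "s.csv").write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="non-monotone"):
            ov.read_recording(tmp_path / "s.csv", tmp_path / "a.csv")


def test_recording_generation_is_deterministic_per_stream():
    cfg = ov.SimulationConfig(recording_duration=100)
    profile = ov.SheepProfile("s", 2, effect_size=1.0)
    r1 = generate_recording(profile, cfg, np.random.default_rng(4))
    r2 = generate_recording(profile, cfg, np.random.default_rng(4))
    assert np.array_equal(r1.accel, r2.accel) and r1.annotations == r2.annotations


def test_cv_accuracy_is_monotone_in_effect_size():
    """Downstream classification accuracy is non-decreasing in the
    generator's effect size across {0, 0.5, 1, 2} (2-point tolerance
    between adjacent levels).  Folds are grouped by sheep so the curve
    measures the injected signal."""
    from conftest import build_feature_table
    from ovinesense.classify import ClassifierSpec, grouped_kfold, run_cv

    accuracies = []
    for effect in (0.0, 0.5, 1.0, 2.0):
        table = build_feature_table(
            effect_size=effect, seed=11, n_lame=4, n_nonlame=4, duration=450
        )
        per_activity = []
        for activity in ACTIVITIES:
            sub = table[table["activity"] == activity].reset_index(drop=True)
            folds = grouped_kfold(sub["lame"], sub["sheep_id"], k=4, seed=0)
            result = run_cv(
                sub, None, ClassifierSpec("RF", seed=0), n_features=32, fold_assignment=folds
            )
            per_activity.append(result.mean_accuracy)
        accuracies.append(float(np.mean(per_activity)))
    for lower, higher in zip(accuracies, accuracies[1:]):
        assert higher >= lower - 0.02, accuracies
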