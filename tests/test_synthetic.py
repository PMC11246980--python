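"""Seeded EMG and task-kinematics generators."""
import numpy as np
import pytest
from scipy import signal as scipy_signal
from scipy import stats

from myocomp.kinematics import trunk_angle_series
from myocomp.synthetic import (
    DEFAULT_CLASS_PROFILES,
    EmgSimParams,
    LabelSchedule,
    TaskSimParams,
    available_presets,
    make_benchmark_scenario,
    simulate_emg,
    simulate_task_landmarks,
)


def _profiles(**overrides):
    profs = {k: dict(v) for k, v in DEFAULT_CLASS_PROFILES.items()}
    for lab, p in overrides.items():
        profs[lab].update(p)
    return profs


class TestSimulateEmg:
    def test_pure_noise_rms(self):
        params = EmgSimParams(
            class_profiles=_profiles(
                **{lab: {"gains": (0, 0, 0)} for lab in DEFAULT_CLASS_PROFILES}
            ),
            noise_sigma=0.2,
            line_amplitude=0.0,
            seed=3,
        )
        stream = simulate_emg(params, LabelSchedule(), duration=10.0)
        rms = np.sqrt(np.mean(stream.samples**2, axis=1))
        assert np.all(np.abs(rms - 0.2) <= 0.05 * 0.2)

    def test_segment_rms_ratio_tracks_gain_ratio(self):
        # grip gain on CH3 is 5x the rest gain; noise kept small
        params = EmgSimParams(
            class_profiles=_profiles(
                rest={"gains": (0.2, 0.2, 0.2)}, grip={"gains": (0.2, 0.2, 1.0)}
            ),
            noise_sigma=0.005,
            line_amplitude=0.0,
            crosstalk=0.0,
            seed=5,
        )
        schedule = LabelSchedule(((0, 4, "rest"), (4, 8, "grip"), (8, 12, "rest"), (12, 16, "grip")))
        stream = simulate_emg(params, schedule, duration=16.0)
        ch3 = stream.samples[2]
        rms_grip = np.sqrt(np.mean(ch3[stream.labels == "grip"] ** 2))
        rms_rest = np.sqrt(np.mean(ch3[stream.labels == "rest"] ** 2))
        assert 4.5 <= rms_grip / rms_rest <= 5.5

    def test_seeded_determinism(self):
        params = EmgSimParams(seed=11)
        schedule = LabelSchedule(((0, 2, "grip"),))
        a = simulate_emg(params, schedule, 3.0)
        b = simulate_emg(params, schedule, 3.0)
        assert a.samples.tobytes() == b.samples.tobytes()
        assert list(a.labels) == list(b.labels)

    def test_label_track_matches_schedule(self):
        schedule = LabelSchedule(((0.5, 1.0, "grip"), (1.5, 2.0, "open")))
        stream = simulate_emg(EmgSimParams(seed=1), schedule, 2.5)
        for i, t in enumerate(stream.times):
            assert stream.labels[i] == schedule.label_at(t)

    def test_schedule_longer_than_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            simulate_emg(EmgSimParams(), LabelSchedule(((0, 5, "grip"),)), duration=2.0)

    def test_activation_spectrum_confined_below_400hz(self):
        params = EmgSimParams(noise_sigma=0.0, line_amplitude=0.0, seed=2)
        stream = simulate_emg(params, LabelSchedule(((0, 20, "grip"),)), duration=20.0)
        f, pxx = scipy_signal.welch(stream.samples[1], fs=params.sample_rate, nperseg=4096)
        assert pxx[f < 400].sum() >= 0.95 * pxx.sum()

    @pytest.mark.parametrize(
        "kwargs",
        [{"crosstalk": 1.0}, {"noise_sigma": -1.0}, {"sample_rate": float("nan")}, {"n_channels": 0}],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EmgSimParams(**kwargs)


class TestLabelSchedule:
    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            LabelSchedule(((0, 2, "grip"), (1, 3, "open")))

    def test_reversed_segment_rejected(self):
        with pytest.raises(ValueError):
            LabelSchedule(((2, 1, "grip"),))


class TestSimulateTask:
    def test_zero_tilt_gives_zero_trunk_angle(self):
        params = TaskSimParams(
            tilt_amplitude_mean=0.0, tilt_amplitude_sd=0.0, landmark_noise_sd=0.0, seed=4
        )
        for tr in simulate_task_landmarks(params):
            np.testing.assert_allclose(trunk_angle_series(tr.landmarks), 0.0, atol=1e-12)

    def test_monte_carlo_grasp_height_mean(self):
        params = TaskSimParams(
            base_height_mean=45.1, base_height_sd=1.38, n_trials=200, seed=6
        )
        trials = simulate_task_landmarks(params)
        heights = np.array(
            [tr.landmarks.landmark("right_elbow")[tr.grasp_frame, 1] for tr in trials]
        )
        sd = np.sqrt(1.38**2 + params.landmark_noise_sd**2)
        assert abs(heights.mean() - 45.1) <= 3 * sd / np.sqrt(200)

    def test_exact_frame_timestamps_without_jitter(self):
        trials = simulate_task_landmarks(TaskSimParams(seed=8, timestamp_jitter=False))
        for tr in trials:
            k = np.arange(len(tr.landmarks.timestamps))
            np.testing.assert_array_equal(tr.landmarks.timestamps, 0.11 * k)

    def test_jitter_stays_within_one_percent(self):
        trials = simulate_task_landmarks(TaskSimParams(seed=8, timestamp_jitter=True))
        for tr in trials:
            dt = np.diff(tr.landmarks.timestamps)
            assert np.all(np.abs(dt - 0.11) <= 0.011 + 1e-12)

    def test_seeded_determinism(self):
        a = simulate_task_landmarks(TaskSimParams(seed=9))
        b = simulate_task_landmarks(TaskSimParams(seed=9))
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.landmarks.positions, tb.landmarks.positions)

    def test_condition_contrast_in_grasp_heights(self):
        """Conventional presets sit strictly above separate presets (alpha = 0.01)."""
        scenario = make_benchmark_scenario("table1_C", seed=10, n_trials=50)
        heights = {}
        for cond, params in scenario.task_params.items():
            trials = simulate_task_landmarks(params)
            heights[cond] = [
                tr.landmarks.landmark("right_elbow")[tr.grasp_frame, 1] for tr in trials
            ]
        res = stats.ttest_ind(heights["conventional"], heights["separate"], alternative="greater")
        assert res.pvalue < 0.01

    def test_grasp_before_release(self):
        for tr in simulate_task_landmarks(TaskSimParams(seed=2, n_trials=5)):
            assert tr.grasp_frame < tr.release_frame

    def test_left_side_mirrors_x(self):
        right = simulate_task_landmarks(TaskSimParams(seed=3, landmark_noise_sd=0.0))[0].landmarks
        left = simulate_task_landmarks(
            TaskSimParams(seed=3, side="left", landmark_noise_sd=0.0)
        )[0].landmarks
        # shoulders mirror in place; the task path moves to the left elbow
        np.testing.assert_allclose(left.positions[:, :2, 0], -right.positions[:, :2, 0])
        np.testing.assert_allclose(left.positions[:, :2, 1], right.positions[:, :2, 1])
        np.testing.assert_allclose(
            left.landmark("left_elbow") * np.array([-1.0, 1.0]),
            right.landmark("right_elbow"),
        )

    @pytest.mark.parametrize("kwargs", [{"trial_duration_mean": -1.0}, {"frame_interval": 0.0}])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TaskSimParams(**kwargs)


class TestPresets:
    def test_table1_c_preset_heights(self):
        scenario = make_benchmark_scenario("table1_C", seed=0)
        conv = scenario.task_params["conventional"]
        sep = scenario.task_params["separate"]
        assert conv.base_height_mean == 45.1 and conv.end_height_mean == 27.6
        assert sep.base_height_mean == 22.2 and sep.end_height_mean == 10.0

    def test_default_trial_count_is_ten(self):
        for name in available_presets():
            scenario = make_benchmark_scenario(name, seed=0)
            assert all(p.n_trials == 10 for p in scenario.task_params.values())

    def test_unknown_preset_lists_available_names(self):
        with pytest.raises(ValueError, match="table1_C"):
            make_benchmark_scenario("nope", seed=0)
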