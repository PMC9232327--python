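"""Synthetic cohort generator: movement model, scripts, EMG model, determinism."""

import numpy as np
import pytest

from armbiomech import emg as emg_mod
from armbiomech import kinematics as kin
from armbiomech import synthetic as syn
from armbiomech.errors import ConfigurationError, InvalidArgumentError


class TestMinJerkSegment:
    def test_degenerate_segment_is_constant(self):
        pts = syn.min_jerk_segment([1, 2, 3], [1, 2, 3], duration=0.7, rate=30)
        np.testing.assert_array_equal(pts, np.tile([1, 2, 3], (len(pts), 1)))

    def test_quintic_symmetry_at_midpoint(self):
        pts = syn.min_jerk_segment([0, 0, 0], [1, 0, 0], duration=1.0, rate=100)
        mid = len(pts) // 2
        assert pts[mid, 0] == pytest.approx(0.5, abs=1e-12)

    def test_peak_speed_matches_analytic_maximum(self):
        d, T, rate = 1.0, 0.5, 1000.0
        pts = syn.min_jerk_segment([0, 0, 0], [d, 0, 0], T, rate)
        speed = np.linalg.norm(np.gradient(pts, 1 / rate, axis=0), axis=1)
        assert speed.max() == pytest.approx(15 * d / (8 * T), rel=5e-3)

    def test_starts_and_ends_at_rest(self):
        pts = syn.min_jerk_segment([0, 0, 0], [1, 1, 0], 0.5, 1000.0)
        speed = np.linalg.norm(np.gradient(pts, 1e-3, axis=0), axis=1)
        peak = speed.max()
        assert speed[0] < 1e-3 * peak and speed[-1] < 1e-3 * peak

    @pytest.mark.parametrize("duration, rate", [(0.0, 30), (-1.0, 30), (1.0, 0)])
    def test_nonpositive_arguments_rejected(self, duration, rate):
        with pytest.raises(InvalidArgumentError):
            syn.min_jerk_segment([0, 0, 0], [1, 0, 0], duration, rate)

    def test_warp_delays_speed_peak(self):
        rate = 1000.0
        plain = syn.min_jerk_segment([0, 0, 0], [1, 0, 0], 0.5, rate, warp=1.0)
        warped = syn.min_jerk_segment([0, 0, 0], [1, 0, 0], 0.5, rate, warp=1.4)
        t_peak = lambda pts: np.argmax(
            np.linalg.norm(np.gradient(pts, 1 / rate, axis=0), axis=1)
        )
        assert t_peak(warped) > t_peak(plain)


class TestCombinationScripts:
    def test_combo1_eight_beat_symmetric_pattern(self):
        script = syn.build_combination_script(1)
        assert script.n_beats == 8
        names = [b.action_name for b in script.beats]
        assert names[0] == names[6] == "front_lift"
        assert names[1] == names[5] == "up_lift"
        assert names[2] == names[4] == "side_lift"
        assert names[3] == names[7] == "down_lift"

    def test_combo2_chest_cross_on_beats_1_and_3(self):
        script = syn.build_combination_script(2)
        assert script.n_beats == 4
        names = [b.action_name for b in script.beats]
        assert names[0] == names[2] == "chest_cross"
        assert set(names[1::2]) == {"side_up_lift", "side_down_lift"}

    @pytest.mark.parametrize("combo", [1, 2])
    def test_beats_chain_per_hand(self, combo):
        script = syn.build_combination_script(combo)
        for prev, nxt in zip(script.beats[:-1], script.beats[1:]):
            np.testing.assert_array_equal(prev.left_end, nxt.left_start)
            np.testing.assert_array_equal(prev.right_end, nxt.right_start)

    def test_unknown_combo_rejected(self):
        with pytest.raises(InvalidArgumentError):
            syn.build_combination_script(3)

    def test_plane_dominance_matches_study_structure(self, noiseless_config, subject_b):
        """Combination 1 moves most in the sagittal plane, combination 2 in the
        horizontal plane (group-independent geometric property)."""
        dominant = {}
        for combo in (1, 2):
            script = syn.build_combination_script(combo)
            trial = syn.generate_motion_trial(
                subject_b, script, noiseless_config, np.random.default_rng(0)
            )
            lengths = {
                p: kin.plane_track_length(trial.right, p) for p in kin.PlaneCode
            }
            dominant[combo] = max(lengths, key=lengths.get)
        assert dominant[1] == kin.PlaneCode.YZ  # sagittal
        assert dominant[2] == kin.PlaneCode.XY  # horizontal


class TestMotionTrial:
    def test_beat_accounting_at_120bpm_30hz(self, default_config, subject_a):
        script = syn.build_combination_script(1, tempo=120.0)
        trial = syn.generate_motion_trial(
            subject_a, script, default_config, np.random.default_rng(0)
        )
        assert trial.duration == pytest.approx(4.0)
        assert trial.boundaries.tolist() == list(range(0, 121, 15))
        assert len(trial.left) == 121

    def test_path_length_linear_in_amplitude_scale(self, subject_a, subject_b):
        base = syn.CohortConfig(
            amplitude_scale={"A": 1.1, "B": 1.0},
            coord_noise_sd=0.0,
            subject_amplitude_sd=0.0,
        )
        script = syn.build_combination_script(1)
        t_a = syn.generate_motion_trial(subject_a, script, base, np.random.default_rng(3))
        t_b = syn.generate_motion_trial(subject_b, script, base, np.random.default_rng(3))
        ratio = kin.track_length(t_a.right) / kin.track_length(t_b.right)
        assert ratio == pytest.approx(1.1, rel=1e-12)

    def test_determinism_bit_identical(self, default_config, subject_a):
        script = syn.build_combination_script(2)
        t1 = syn.generate_motion_trial(
            subject_a, script, default_config, np.random.default_rng(99)
        )
        t2 = syn.generate_motion_trial(
            subject_a, script, default_config, np.random.default_rng(99)
        )
        np.testing.assert_array_equal(t1.left.positions, t2.left.positions)
        np.testing.assert_array_equal(t1.right.positions, t2.right.positions)

    def test_frame_rate_too_low_rejected(self, subject_a):
        cfg = syn.CohortConfig(frame_rate=2.0)  # 1 frame per 0.5 s beat
        script = syn.build_combination_script(1)
        with pytest.raises(ConfigurationError):
            syn.generate_motion_trial(subject_a, script, cfg, np.random.default_rng(0))


class TestEMGTrial:
    def _trial(self, config, profile, seed=0):
        script = syn.build_combination_script(1)
        motion = syn.generate_motion_trial(
            profile, script, config, np.random.default_rng(seed)
        )
        return syn.generate_emg_trial(
            motion, profile, config, np.random.default_rng(seed + 1)
        )

    def test_zero_weights_give_silent_channels(self, subject_a):
        cfg = syn.CohortConfig(
            muscle_weights={
                "A": {m: 0.0 for m in syn.MUSCLES},
                "B": {m: 1.0 for m in syn.MUSCLES},
            },
            emg_noise_sd=0.0,
        )
        trial = self._trial(cfg, subject_a)
        for v in trial.channels.values():
            assert emg_mod.rms(v) == 0.0

    def test_doubling_weight_doubles_rms(self, subject_a):
        weights = {m: 0.5 for m in syn.MUSCLES}
        doubled = dict(weights, latissimus_dorsi=1.0)
        base_cfg = syn.CohortConfig(
            muscle_weights={"A": weights, "B": weights}, emg_noise_sd=0.0
        )
        doub_cfg = syn.CohortConfig(
            muscle_weights={"A": doubled, "B": weights}, emg_noise_sd=0.0
        )
        r1 = emg_mod.rms(self._trial(base_cfg, subject_a).channels["right_latissimus_dorsi"])
        r2 = emg_mod.rms(self._trial(doub_cfg, subject_a).channels["right_latissimus_dorsi"])
        assert r2 == pytest.approx(2 * r1, rel=1e-12)

    def test_group_a_dominant_channel_is_latissimus(self, default_config, subject_a):
        trial = self._trial(default_config, subject_a)
        mvic = syn.generate_mvic(subject_a, default_config, np.random.default_rng(5))
        std = {
            name: emg_mod.standardize(emg_mod.rms(v), mvic.reference_rms[name])
            for name, v in trial.channels.items()
        }
        assert max(std, key=std.get).endswith("latissimus_dorsi")

    def test_missing_channel_weight_rejected(self, subject_a):
        cfg = syn.CohortConfig(
            muscle_weights={"A": {"latissimus_dorsi": 1.0}, "B": {m: 1.0 for m in syn.MUSCLES}}
        )
        with pytest.raises(ConfigurationError):
            self._trial(cfg, subject_a)

    def test_channel_layout(self, default_config, subject_a):
        trial = self._trial(default_config, subject_a)
        assert set(trial.channels) == set(syn.CHANNELS)
        assert len(trial.channels) == 8
        lengths = {len(v) for v in trial.channels.values()}
        assert lengths == {int(round(4.0 * default_config.emg_rate))}


class TestMVIC:
    def test_reference_rms_tracks_constant_envelope(self, subject_a):
        cfg = syn.CohortConfig(emg_noise_sd=0.0)
        mvic = syn.generate_mvic(subject_a, cfg, np.random.default_rng(11))
        expected = cfg.emg_gain_mv * cfg.mvic_drive
        for ref in mvic.reference_rms.values():
            assert ref == pytest.approx(expected, rel=0.05)

    def test_standardizing_reference_against_itself_is_100(self, subject_a, default_config):
        mvic = syn.generate_mvic(subject_a, default_config, np.random.default_rng(2))
        name = "right_latissimus_dorsi"
        assert emg_mod.standardize(
            mvic.reference_rms[name], mvic.reference_rms[name]
        ) == pytest.approx(100.0)

    def test_different_streams_give_different_references(self, subject_a, default_config):
        m1 = syn.generate_mvic(subject_a, default_config, np.random.default_rng(1))
        m2 = syn.generate_mvic(subject_a, default_config, np.random.default_rng(2))
        assert m1.reference_rms != m2.reference_rms

    def test_reference_exceeds_task_rms(self, default_config, subject_a):
        """Standardized task values stay bounded: reference > task RMS."""
        script = syn.build_combination_script(1)
        motion = syn.generate_motion_trial(
            subject_a, script, default_config, np.random.default_rng(0)
        )
        trial = syn.generate_emg_trial(
            motion, subject_a, default_config, np.random.default_rng(1)
        )
        mvic = syn.generate_mvic(subject_a, default_config, np.random.default_rng(2))
        for name, v in trial.channels.items():
            assert emg_mod.rms(v) < mvic.reference_rms[name]


class TestCohort:
    def test_cohort_counts(self):
        cfg = syn.CohortConfig(n_group_a=4, n_group_b=11, seed=7)
        bundle = syn.generate_cohort(cfg)
        assert len(bundle.profiles) == 15
        assert len(bundle.motion) == 30
        assert len(bundle.emg) == 30
        assert len(bundle.mvic) == 15
        assert sum(p.group == "A" for p in bundle.profiles) == 4

    def test_identical_configs_identical_bundles(self):
        cfg = syn.CohortConfig(n_group_a=2, n_group_b=3, seed=21)
        b1 = syn.generate_cohort(cfg)
        b2 = syn.generate_cohort(cfg)
        for key in b1.motion:
            np.testing.assert_array_equal(
                b1.motion[key].left.positions, b2.motion[key].left.positions
            )
        for key in b1.emg:
            for name in syn.CHANNELS:
                np.testing.assert_array_equal(
                    b1.emg[key].channels[name], b2.emg[key].channels[name]
                )
        assert b1.mvic.keys() == b2.mvic.keys()
        for sid in b1.mvic:
            assert b1.mvic[sid].reference_rms == b2.mvic[sid].reference_rms

    def test_skipping_emg_leaves_motion_unchanged(self):
        cfg = syn.CohortConfig(n_group_a=2, n_group_b=2, seed=5)
        full = syn.generate_cohort(cfg, include_emg=True)
        lean = syn.generate_cohort(cfg, include_emg=False)
        assert len(lean.emg) == 0
        for key in full.motion:
            np.testing.assert_array_equal(
                full.motion[key].right.positions, lean.motion[key].right.positions
            )

    def test_height_sampling_distribution(self):
        """Monte-Carlo check: heights ~ Normal(1.77, 0.09^2) truncated positive."""
        rng = np.random.default_rng(0)
        heights = [syn._draw_height(rng, 1.77, 0.09) for _ in range(1000)]
        assert np.mean(heights) == pytest.approx(1.77, abs=0.02)
        assert min(heights) > 0

    def test_nonpositive_group_sizes_rejected(self):
        with pytest.raises(ConfigurationError):
            syn.CohortConfig(n_group_a=0, n_group_b=5)
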