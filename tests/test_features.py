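"""Angle folding, speech ratio, bimanual descriptors, timing bins."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from naturalreach.events import MovementEvent
from naturalreach.features import (AudioTrack, bimanual_features, compute_feature_table,
                                   estimate_noise_profile, speech_ratio, stft_power_ratio,
                                   timing_features, transform_angle)
from naturalreach.hsmm import StateSequence, WristTrajectory
from naturalreach.synthetic import generate_audio


class TestTransformAngle:
    @pytest.mark.parametrize("raw,expected", [
        (90.0, 90.0),
        (270.0, -90.0),
        (135.0, 45.0),
        (0.0, 0.0),
        (180.0, 0.0),
        (315.0, -45.0),
    ])
    def test_examples(self, raw, expected):
        assert transform_angle(raw) == pytest.approx(expected)

    @given(st.floats(min_value=0.0, max_value=359.999))
    @settings(max_examples=200, deadline=None)
    def test_range_and_idempotence(self, raw):
        a = transform_angle(raw)
        assert -90.0 <= a <= 90.0
        # idempotent on its range (folding a folded angle changes nothing)
        assert transform_angle(a % 360.0) == pytest.approx(a, abs=1e-9)

    @given(st.floats(min_value=0.0, max_value=359.999))
    @settings(max_examples=200, deadline=None)
    def test_vertical_symmetry(self, raw):
        mirrored = (180.0 - raw) % 360.0
        assert transform_angle(raw) == pytest.approx(transform_angle(mirrored), abs=1e-9)

    def test_vectorized(self):
        out = transform_angle(np.array([90.0, 270.0, 135.0]))
        np.testing.assert_allclose(out, [90.0, -90.0, 45.0])


class TestSpeechRatio:
    def test_tone_in_band_near_one(self):
        fs = 2000.0
        t = np.arange(int(30 * fs)) / fs
        audio = AudioTrack(sample_rate=fs, samples=np.sin(2 * np.pi * 500.0 * t))
        r = speech_ratio(audio, 15.0, smooth=False)
        assert r > 0.95

    def test_broadband_noise_band_fraction(self, rng):
        fs = 2000.0
        audio = AudioTrack(sample_rate=fs, samples=rng.normal(0, 1, int(60 * fs)))
        r = speech_ratio(audio, 30.0, smooth=False)
        # flat spectrum: expect roughly (900-370)/1000 of total power
        assert r == pytest.approx(530.0 / 1000.0, abs=0.05)

    def test_gain_invariance(self, rng):
        fs = 2000.0
        x = rng.normal(0, 0.3, int(30 * fs))
        a1 = AudioTrack(sample_rate=fs, samples=x)
        a2 = AudioTrack(sample_rate=fs, samples=2.0 * x)
        assert speech_ratio(a1, 15.0) == pytest.approx(speech_ratio(a2, 15.0), abs=1e-12)

    def test_window_outside_track_raises(self, rng):
        audio = AudioTrack(sample_rate=2000.0, samples=rng.normal(0, 1, 4000))
        with pytest.raises(ValueError, match="outside"):
            speech_ratio(audio, 1.8)

    def test_speech_event_beats_silent_event(self):
        audio = generate_audio([(9.0, 11.0)], duration_s=40.0, seed=0)
        with_speech = speech_ratio(audio, 10.0, smooth=False)
        without = speech_ratio(audio, 30.0, smooth=False)
        assert with_speech > without

    def test_no_intervals_near_noise_floor(self, rng):
        audio = generate_audio([], duration_s=30.0, seed=1)
        r = speech_ratio(audio, 15.0, smooth=False)
        assert r == pytest.approx(530.0 / 1000.0, abs=0.1)  # flat-floor fraction

    def test_noise_gate_suppresses_floor(self):
        audio = generate_audio([(20.0, 22.0)], duration_s=40.0, seed=2)
        profile = estimate_noise_profile(audio, (2.0, 10.0))
        _, gated = stft_power_ratio(audio, noise_profile=profile)
        times, ungated = stft_power_ratio(audio)
        sel = (times >= 20.0) & (times <= 22.0)
        assert gated[sel].mean() >= ungated[sel].mean()


def _states(labels):
    return StateSequence(labels=np.asarray(labels, dtype=int), frame_rate=30.0)


def _traj(positions):
    pos = np.asarray(positions, dtype=float)
    return WristTrajectory(frame_rate=30.0, positions=pos, confidence=np.ones(len(pos)))


class TestBimanual:
    def _setup(self, ipsi_positions, ipsi_labels, n=90):
        u = np.linspace(0, 1, 30)
        radial = 60 * 4 * u * (1 - u)
        contra_pos = np.zeros((n, 2))
        contra_pos[30:60, 0] = radial
        contra = _traj(contra_pos)
        contra_states = _states([0] * 30 + [1] * 30 + [0] * 30)
        ev = MovementEvent(onset_frame=30, onset_time=1.0, move_dwell=(30, 60))
        return contra, _traj(ipsi_positions), contra_states, _states(ipsi_labels), ev

    def test_stationary_ipsilateral(self):
        contra, ipsi, cs, is_, ev = self._setup(np.zeros((90, 2)), [0] * 90)
        ratio, overlap, cls = bimanual_features(contra, ipsi, cs, is_, ev)
        assert (ratio, overlap, cls) == (0.0, 0.0, 0)

    def test_identical_mirrored_movement(self):
        u = np.linspace(0, 1, 30)
        radial = 60 * 4 * u * (1 - u)
        ipsi_pos = np.zeros((90, 2))
        ipsi_pos[30:60, 0] = -radial  # mirrored
        contra, ipsi, cs, is_, ev = self._setup(ipsi_pos, [0] * 30 + [1] * 30 + [0] * 30)
        ratio, overlap, cls = bimanual_features(contra, ipsi, cs, is_, ev)
        assert ratio == pytest.approx(0.5, abs=1e-9)
        assert overlap == pytest.approx(1.0)
        assert cls == 1

    def test_three_frame_flicker_is_unimanual(self):
        labels = [0] * 90
        labels[40:43] = [1, 1, 1]  # only 3 consecutive move frames
        contra, ipsi, cs, is_, ev = self._setup(np.zeros((90, 2)), labels)
        _, _, cls = bimanual_features(contra, ipsi, cs, is_, ev)
        assert cls == 0

    def test_run_starting_before_lookback_ignored(self):
        # ipsilateral run already in progress when the 1 s lookback opens:
        # it did not *begin* in the window, so the event stays unimanual
        n = 150
        contra_pos = np.zeros((n, 2))
        u = np.linspace(0, 1, 30)
        contra_pos[60:90, 0] = 60 * 4 * u * (1 - u)
        contra = _traj(contra_pos)
        cs = _states([0] * 60 + [1] * 30 + [0] * 60)
        ev = MovementEvent(onset_frame=60, onset_time=2.0, move_dwell=(60, 90))
        ipsi_labels = [1] * 35 + [0] * (n - 35)  # run starts at 0, ends inside window
        ipsi = _traj(np.zeros((n, 2)))
        _, _, cls = bimanual_features(contra, ipsi, cs, _states(ipsi_labels), ev)
        assert cls == 0

    def test_run_in_lookback_counts(self):
        labels = [0] * 90
        labels[20:26] = [1] * 6  # starts 10 frames (0.33 s) before onset
        contra, ipsi, cs, is_, ev = self._setup(np.zeros((90, 2)), labels)
        _, _, cls = bimanual_features(contra, ipsi, cs, is_, ev)
        assert cls == 1

    def test_zero_magnitudes_warns(self):
        contra_pos = np.zeros((90, 2))
        contra = _traj(contra_pos)
        ipsi = _traj(np.zeros((90, 2)))
        cs = _states([0] * 30 + [1] * 30 + [0] * 30)
        is_ = _states([0] * 90)
        ev = MovementEvent(onset_frame=30, onset_time=1.0, move_dwell=(30, 60))
        with pytest.warns(UserWarning, match="zero"):
            ratio, _, _ = bimanual_features(contra, ipsi, cs, is_, ev)
        assert ratio == 0.0


class TestTiming:
    @pytest.mark.parametrize("clock,expected_bin", [
        (7 * 3600 + 59 * 60 + 59, 1),
        (8 * 3600, 2),
        (23 * 3600 + 1800, 3),
        (0.0, 1),
        (16 * 3600, 3),
    ])
    def test_bins(self, clock, expected_bin):
        ev = MovementEvent(onset_frame=0, onset_time=0.0, day=4, clock_time=clock)
        day, b = timing_features(ev)
        assert (day, b) == (4, expected_bin)


class TestFeatureTable:
    def test_complete_on_synthetic_session(self, small_study):
        sess = small_study.sessions[0]
        kept = [e for e in sess.events]
        for e in kept:
            e.kept = True
        table = compute_feature_table(
            kept, sess.contra_traj, sess.ipsi_traj,
            sess.contra_states, sess.ipsi_states, audio=sess.audio,
        )
        assert len(table) == len(kept)
        assert not table.isna().any().any()
        assert table["angle"].between(-90, 90).all()
        assert table["speech_ratio"].between(0, 1).all()
        assert table["bimanual_ratio"].between(0, 1).all()
        assert set(table["bimanual_class"]) <= {0, 1}
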