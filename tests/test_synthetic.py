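"""Generator contracts: determinism, dwell statistics, injected effects, round trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from naturalreach import io
from naturalreach.events import MovementEvent
from naturalreach.features import speech_ratio
from naturalreach.hsmm import MOVE, REST, decode_states
from naturalreach.preprocess import preprocess, remove_dc
from naturalreach.spectral import compute_band_powers, extract_segments
from naturalreach.synthetic import (DwellConfig, InvalidConfigError, SyntheticConfig,
                                    _generate_session_behavior, event_deltas,
                                    generate_audio, generate_layout, generate_neural,
                                    generate_study, generate_trajectory, true_hsmm_params)

BAND_FREQS = np.concatenate([np.arange(8.0, 33.0, 2.0), np.arange(76.0, 101.0, 2.0)])


class TestConfigValidation:
    def test_nonpositive_dwell_raises(self):
        with pytest.raises(InvalidConfigError):
            SyntheticConfig(duration_params=DwellConfig(rest_mean=-5.0))

    def test_empty_days_raises(self):
        with pytest.raises(InvalidConfigError):
            SyntheticConfig(days=())

    def test_negative_noise_raises(self):
        with pytest.raises(InvalidConfigError):
            SyntheticConfig(noise_sd=-1.0)


class TestGenerateTrajectory:
    def test_deterministic(self):
        cfg = SyntheticConfig(events_per_day=10, seed=3)
        t1, s1 = generate_trajectory(cfg, 0, 1, seed=55)
        t2, s2 = generate_trajectory(cfg, 0, 1, seed=55)
        np.testing.assert_array_equal(t1.positions, t2.positions)
        np.testing.assert_array_equal(t1.confidence, t2.confidence)
        np.testing.assert_array_equal(s1.labels, s2.labels)

    def test_states_match_trajectory_length(self):
        cfg = SyntheticConfig(events_per_day=5)
        traj, states = generate_trajectory(cfg, 0, 1, seed=1)
        assert len(states.labels) == traj.n_frames

    def test_single_event_noiseless_decode(self):
        cfg = SyntheticConfig(events_per_day=1, seed=0, rest_jitter_px=0.05,
                              move_noise_px=0.3)
        traj, states = generate_trajectory(cfg, 0, 1, seed=10)
        transitions = np.flatnonzero((states.labels[1:] == MOVE) & (states.labels[:-1] == REST))
        assert len(transitions) == 1
        dec = decode_states(true_hsmm_params(cfg), traj)
        assert (dec.labels == states.labels).mean() > 0.99

    def test_dwell_means_match_configured(self):
        cfg = SyntheticConfig(events_per_day=120, seed=9)  # ~12000 frames
        _, states, *_ = _generate_session_behavior(cfg, 77)
        labels = states.labels
        pad = int(cfg.pad_s * cfg.frame_rate)
        labels = labels[pad:-pad]
        change = np.flatnonzero(np.diff(labels)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(labels)]))
        seg_states = labels[starts]
        lens = ends - starts
        for state, mean, r in ((REST, 60.0, 5.0), (MOVE, 45.0, 5.0)):
            d = lens[seg_states == state][1:-1]  # interior dwells only
            mu = mean - 1.0
            var = mu + mu**2 / r  # negative binomial variance (shifted)
            se = np.sqrt(var / len(d))
            assert abs(d.mean() - mean) < 3 * se + 1.0  # +1 frame truncation allowance

    def test_confidence_dips_present(self):
        cfg = SyntheticConfig(events_per_day=40, seed=2)
        traj, _ = generate_trajectory(cfg, 0, 1, seed=3)
        assert (traj.confidence < 0.4).any()
        assert traj.confidence.min() >= 0.0 and traj.confidence.max() <= 1.0


def _fixed_events(n_ev, spacing=12.0, start=10.0):
    return [MovementEvent(onset_frame=i, onset_time=start + i * spacing) for i in range(n_ev)]


class TestGenerateNeural:
    def _measure(self, deltas, n_ev=40, seed=0, layout_seed=1):
        events = _fixed_events(n_ev)
        dur = 10.0 + n_ev * 12.0 + 10.0
        layout = generate_layout(SyntheticConfig(n_channels=8), 0, layout_seed)
        rec = generate_neural(events, deltas, layout, dur, 1000.0, seed)
        clean = preprocess(rec)
        segs, _ = extract_segments(clean, events)
        return compute_band_powers(segs, freqs=BAND_FREQS), layout

    def test_null_betas_measure_near_zero(self):
        n_ev = 40
        deltas = pd.DataFrame({"LFB": np.zeros(n_ev), "HFB": np.zeros(n_ev)})
        bp, _ = self._measure(deltas, n_ev=n_ev)
        for band in ("LFB", "HFB"):
            vals = bp[bp.band == band].groupby("channel").value.mean()
            # per-event band power fluctuates ~1.5-3 dB; at 40 events the
            # per-channel mean has SE ~0.4 dB, the grand mean ~0.15 dB
            assert np.abs(vals).max() < 1.2
            assert abs(vals.mean()) < 0.4

    def test_angle_sign_contrast(self):
        # negative LFB beta: +90° events show lower LFB power than -90° events
        n_ev = 60
        angles = np.array([90.0, -90.0] * (n_ev // 2))
        feats = pd.DataFrame({
            "day": 1, "time_of_day": 1, "duration": 1.0, "magnitude": 70.0,
            "angle": angles, "onset_speed": 100.0, "speech_ratio": 0.0,
            "bimanual_ratio": 0.0, "bimanual_overlap": 0.0, "bimanual_class": 0,
        })
        deltas = event_deltas(feats, {"angle": (-2.0, 0.0)}, (0.0, 0.0), 0.0,
                              np.random.default_rng(0))
        bp, _ = self._measure(deltas, n_ev=n_ev)
        lfb = bp[(bp.band == "LFB") & bp.channel.str.startswith("MOT")]
        up = lfb[np.isin(lfb.event, np.flatnonzero(angles > 0))].value.mean()
        down = lfb[np.isin(lfb.event, np.flatnonzero(angles < 0))].value.mean()
        assert up < down - 1.0

    def test_motor_only_injection(self):
        n_ev = 40
        deltas = pd.DataFrame({"LFB": np.full(n_ev, -4.0), "HFB": np.full(n_ev, 3.0)})
        bp, layout = self._measure(deltas, n_ev=n_ev)
        motor = bp[bp.channel.str.startswith("MOT")]
        other = bp[bp.channel.str.startswith("TMP")]
        assert motor[motor.band == "LFB"].value.mean() < -2.0
        assert motor[motor.band == "HFB"].value.mean() > 1.5
        assert np.abs(other.groupby("band").value.mean()).max() < 0.5

    def test_event_out_of_bounds_raises(self):
        events = [MovementEvent(onset_frame=0, onset_time=99.9)]
        deltas = pd.DataFrame({"LFB": [0.0], "HFB": [0.0]})
        layout = generate_layout(SyntheticConfig(n_channels=8), 0, 1)
        with pytest.raises(ValueError, match="exceeds recording bounds"):
            generate_neural(events, deltas, layout, 100.0, 1000.0, 0)

    def test_unsorted_events_raise(self):
        events = [MovementEvent(onset_frame=0, onset_time=50.0),
                  MovementEvent(onset_frame=1, onset_time=20.0)]
        deltas = pd.DataFrame({"LFB": [0.0, 0.0], "HFB": [0.0, 0.0]})
        layout = generate_layout(SyntheticConfig(n_channels=8), 0, 1)
        with pytest.raises(ValueError, match="sorted"):
            generate_neural(events, deltas, layout, 100.0, 1000.0, 0)

    def test_baseline_psd_above_zero_db(self, rng):
        # segments from pure background must not trip the < 0 dB rejection
        from naturalreach.spectral import _segment_psd_db

        events = _fixed_events(3)
        deltas = pd.DataFrame({"LFB": np.zeros(3), "HFB": np.zeros(3)})
        layout = generate_layout(SyntheticConfig(n_channels=8), 0, 2)
        rec = preprocess(generate_neural(events, deltas, layout, 60.0, 1000.0, 4))
        segs, _ = extract_segments(rec, events)
        for seg in segs:
            _, psd_db = _segment_psd_db(seg)
            assert psd_db.mean() > 0.0


class TestGenerateAudio:
    def test_tone_ratio_near_one_inside_interval(self):
        audio = generate_audio([(10.0, 14.0)], duration_s=30.0, seed=0)
        assert speech_ratio(audio, 12.0, smooth=False) > 0.8

    def test_malformed_interval_raises(self):
        with pytest.raises(ValueError, match="malformed"):
            generate_audio([(5.0, 2.0)], duration_s=30.0)
        with pytest.raises(ValueError, match="malformed"):
            generate_audio([(25.0, 35.0)], duration_s=30.0)

    def test_overlapping_intervals_raise(self):
        with pytest.raises(ValueError, match="overlap"):
            generate_audio([(5.0, 10.0), (8.0, 12.0)], duration_s=30.0)


class TestGenerateStudy:
    def test_reproducible_under_fixed_seed(self, small_study):
        cfg = small_study.config
        again = generate_study(cfg)
        for a, b in zip(small_study.sessions, again.sessions):
            np.testing.assert_array_equal(a.contra_traj.positions, b.contra_traj.positions)
            np.testing.assert_array_equal(a.recording.voltages, b.recording.voltages)
            np.testing.assert_array_equal(a.audio.samples, b.audio.samples)
            pd.testing.assert_frame_equal(a.features, b.features)

    def test_true_event_counts_match_config(self, small_study):
        for sess in small_study.sessions:
            assert len(sess.events) == small_study.config.events_per_day

    def test_events_inside_recording(self, small_study):
        for sess in small_study.sessions:
            for ev in sess.events:
                assert 0 <= ev.onset_time <= sess.recording.duration

    def test_labels_match_trajectory_lengths(self, small_study):
        for sess in small_study.sessions:
            assert len(sess.contra_states.labels) == sess.contra_traj.n_frames
            assert len(sess.ipsi_states.labels) == sess.ipsi_traj.n_frames

    def test_hemispheres_alternate(self, small_study):
        hems = {s: small_study.layouts[s].hemisphere for s in small_study.layouts}
        assert hems[0] == "left" and hems[1] == "right"


class TestRoundTrips:
    def test_trajectory(self, tmp_path, small_study):
        sess = small_study.sessions[0]
        path = tmp_path / "traj.csv"
        io.save_trajectory(path, sess.contra_traj)
        back = io.load_trajectory(path)
        np.testing.assert_allclose(back.positions, sess.contra_traj.positions)
        np.testing.assert_allclose(back.confidence, sess.contra_traj.confidence)
        assert back.frame_rate == sess.contra_traj.frame_rate
        assert back.wrist_side == "contralateral"

    def test_states(self, tmp_path, small_study):
        sess = small_study.sessions[0]
        path = tmp_path / "states.csv"
        io.save_states(path, sess.contra_states)
        back = io.load_states(path)
        np.testing.assert_array_equal(back.labels, sess.contra_states.labels)
        assert back.source == "ground-truth"

    def test_events(self, tmp_path, small_study):
        sess = small_study.sessions[0]
        path = tmp_path / "events.csv"
        io.save_events(path, sess.events)
        back = io.load_events(path)
        assert len(back) == len(sess.events)
        for a, b in zip(back, sess.events):
            assert a.onset_frame == b.onset_frame
            assert a.reach_angle == pytest.approx(b.reach_angle)
            assert a.move_dwell == b.move_dwell

    def test_recording(self, tmp_path, small_study):
        sess = small_study.sessions[0]
        prefix = tmp_path / "rec"
        rec = remove_dc(sess.recording)
        rec.zeroed_mask[100:200] = True
        io.save_recording(prefix, rec)
        back = io.load_recording(prefix)
        np.testing.assert_array_equal(back.voltages, rec.voltages)
        np.testing.assert_array_equal(back.zeroed_mask, rec.zeroed_mask)
        assert back.group == rec.group
        assert back.hemisphere == rec.hemisphere

    def test_audio(self, tmp_path, small_study):
        sess = small_study.sessions[0]
        path = tmp_path / "a.wav"
        io.save_audio(path, sess.audio)
        back = io.load_audio(path)
        assert back.sample_rate == sess.audio.sample_rate
        np.testing.assert_allclose(back.samples, sess.audio.samples, atol=1e-6)

    def test_atlas(self, tmp_path, small_study):
        path = tmp_path / "atlas.csv"
        io.save_atlas(path, small_study.atlas)
        back = io.load_atlas(path)
        assert sorted(back.names) == sorted(small_study.atlas.names)
        for name in back.names:
            np.testing.assert_allclose(back.regions[name], small_study.atlas.regions[name])
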