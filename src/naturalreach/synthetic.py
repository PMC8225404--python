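"""Synthetic multi-subject studies with known ground truth.

Generates, per subject-day: contralateral and ipsilateral wrist trajectories
driven by a semi-Markov move/rest process with state-conditional dynamics
(rest: low-noise jitter; move: parabolic radial excursions), a multichannel
neural recording with pink-noise background and event-locked band-power
changes that follow a linear model in the behavioral features, a mono audio
track with speech-band energy during designated intervals, an electrode
layout, and a point-cloud atlas.  Every quantity needed to validate the
downstream pipeline (state labels, event onsets, feature values, injected
betas) is recorded as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .events import MovementEvent
from .features import AudioTrack
from .hsmm import MOVE, REST, HSMMParams, StateSequence, WristTrajectory
from .preprocess import NeuralRecording
from .roi import AtlasRegions
from .spectral import BANDS

PIXELS_PER_CM = 3.0  # scale metadata: 3 pixels ~ 1 cm

# Dilution of an injected band-power step as seen by the Morlet band average
# ([0, 0.5] s window, closed band bins) after full preprocessing: wavelet
# temporal smoothing, band-edge leakage, and common-median rereferencing all
# shrink the measured dB change by a near-constant slope.  Calibrated once on
# fixed-delta injections with the default 8-channel layout (4-channel groups)
# and pinned; requested deltas are divided by these factors so the measured
# band average moves by the requested amount per unit.
INJECTION_CALIBRATION = {"LFB": 0.632, "HFB": 0.749}


class InvalidConfigError(ValueError):
    pass


@dataclass
class DwellConfig:
    """Shifted negative-binomial dwell distributions (frames) for rest/move."""

    rest_mean: float = 60.0
    move_mean: float = 45.0
    rest_r: float = 5.0
    move_r: float = 5.0
    min_rest: int = 16  # guarantees the 0.5 s pre-onset rest window at 30 fps
    min_move: int = 15
    max_move: int = 119  # keeps durations inside [0.5, 4] s at 30 fps

    def validate(self) -> None:
        if min(self.rest_mean, self.move_mean, self.rest_r, self.move_r) <= 0:
            raise InvalidConfigError("dwell parameters must be positive")
        if self.rest_mean <= self.min_rest or self.move_mean <= self.min_move:
            raise InvalidConfigError("dwell means must exceed their minimum supports")

    def nbinom_params(self, state: int) -> tuple[float, float]:
        """(r, p) of the negative binomial on dwell-1 for REST/MOVE."""
        mean, r = (self.rest_mean, self.rest_r) if state == REST else (self.move_mean, self.move_r)
        mu = mean - 1.0
        p = r / (r + mu)
        return r, p


@dataclass
class SyntheticConfig:
    n_subjects: int = 2
    days: tuple[int, ...] = (1, 2, 3)
    frame_rate: float = 30.0
    neural_rate: float = 1000.0
    n_channels: int = 8
    events_per_day: int = 50
    true_betas: dict[str, tuple[float, float]] = field(default_factory=dict)
    beta0: tuple[float, float] = (-2.0, 1.0)  # (LFB, HFB) dB at feature means
    noise_sd: float = 0.5  # dB, per event/channel/band
    duration_params: DwellConfig = field(default_factory=DwellConfig)
    seed: int = 0
    # trajectory noise and pruning-exercise fractions
    rest_jitter_px: float = 0.1
    move_noise_px: float = 0.5
    quad_fraction: float = 1.0  # fraction of moves with parabolic radial traces
    bad_confidence_fraction: float = 0.0
    coupled_fraction: float = 0.4  # fraction of events with ipsilateral co-movement
    speech_fraction: float = 0.35
    pad_s: float = 6.0  # rest padding at day edges so no event is near a boundary
    pink_rms_uv: float = 60.0
    audio_rate: float = 2000.0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0 or self.neural_rate <= 0:
            raise InvalidConfigError("rates must be positive")
        if not self.days:
            raise InvalidConfigError("days must be nonempty")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")
        if self.n_subjects < 1 or self.n_channels < 1 or self.events_per_day < 1:
            raise InvalidConfigError("counts must be positive")
        self.duration_params.validate()


@dataclass
class ElectrodeLayout:
    names: list[str]
    positions: np.ndarray  # (n, 3) mm
    groups: list[str]
    hemisphere: str
    is_motor: np.ndarray  # bool per channel


@dataclass
class SubjectDay:
    subject: int
    day: int
    contra_traj: WristTrajectory
    ipsi_traj: WristTrajectory
    contra_states: StateSequence
    ipsi_states: StateSequence
    events: list[MovementEvent]  # ground-truth onsets with true annotations
    features: pd.DataFrame  # true feature values, one row per event
    recording: NeuralRecording
    audio: AudioTrack
    speech_intervals: list[tuple[float, float]]
    day_start_clock: float


@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    layouts: dict[int, ElectrodeLayout]
    atlas: AtlasRegions
    sessions: list[SubjectDay]

    def sessions_for(self, subject: int) -> list[SubjectDay]:
        return [s for s in self.sessions if s.subject == subject]


def _draw_dwell(rng: np.random.Generator, cfg: DwellConfig, state: int) -> int:
    r, p = cfg.nbinom_params(state)
    lo = cfg.min_rest if state == REST else cfg.min_move
    hi = 10**9 if state == REST else cfg.max_move
    for _ in range(1000):
        d = 1 + int(rng.negative_binomial(r, p))
        if lo <= d <= hi:
            return d
    return int(np.clip(round(cfg.rest_mean if state == REST else cfg.move_mean), lo, hi))


def true_hsmm_params(config: SyntheticConfig) -> HSMMParams:
    """HSMM parameters matching the generator, for decode-only tests."""
    dc = config.duration_params
    rr, rp = dc.nbinom_params(REST)
    mr, mp = dc.nbinom_params(MOVE)
    rest_var = max(config.rest_jitter_px, 0.05) ** 2
    # effective move innovation: reach slope variability dominates
    move_var = max(config.move_noise_px, 0.05) ** 2 + 9.0
    return HSMMParams(
        ar=np.zeros((2, 2, 2)),
        innovation_cov=np.array([rest_var * np.eye(2), move_var * np.eye(2)]),
        dwell_r=np.array([rr, mr]),
        dwell_p=np.array([rp, mp]),
        max_dwell=300,
    )


def _plan_day(config: SyntheticConfig, rng: np.random.Generator) -> list[dict]:
    """Per-event plan: dwell lengths and true feature values."""
    dc = config.duration_params
    plan = []
    for _ in range(config.events_per_day):
        rest_len = _draw_dwell(rng, dc, REST)
        move_len = _draw_dwell(rng, dc, MOVE)
        u = rng.random()
        if u < 0.45:
            raw_angle = (90.0 + rng.normal(0, 10.0)) % 360.0
        elif u < 0.90:
            raw_angle = (270.0 + rng.normal(0, 10.0)) % 360.0
        else:
            raw_angle = rng.uniform(0.0, 360.0)
        plan.append(
            {
                "rest_len": rest_len,
                "move_len": move_len,
                "raw_angle": raw_angle,
                "magnitude": float(np.exp(rng.normal(np.log(70.0), 0.3))),
                "parabolic": bool(rng.random() < config.quad_fraction),
                "bad_confidence": bool(rng.random() < config.bad_confidence_fraction),
                "coupled": bool(rng.random() < config.coupled_fraction),
                "coupled_scale": float(rng.uniform(0.3, 0.8)),
                "speech": bool(rng.random() < config.speech_fraction),
            }
        )
    return plan


def _radial_trace(move_len: int, magnitude: float, parabolic: bool, rng: np.random.Generator) -> np.ndarray:
    u = np.linspace(0.0, 1.0, move_len)
    if parabolic:
        return magnitude * 4.0 * u * (1.0 - u)
    # complex multi-lobed trace that defeats the quadratic fit
    return magnitude * np.abs(np.sin(3.0 * np.pi * u)) * (0.7 + 0.3 * rng.random(move_len))


def generate_trajectory(
    config: SyntheticConfig, subject: int, day: int, seed: int
) -> tuple[WristTrajectory, StateSequence]:
    """Forward-simulate one contralateral wrist trajectory and its true states."""
    traj, states, *_ = _generate_session_behavior(config, seed)
    return traj, states


def _generate_session_behavior(config: SyntheticConfig, seed: int):
    rng = np.random.default_rng(seed)
    plan = _plan_day(config, rng)
    fps = config.frame_rate
    pad = int(round(config.pad_s * fps))

    labels = [np.zeros(pad, dtype=int)]
    for ev in plan:
        labels.append(np.zeros(ev["rest_len"], dtype=int))
        labels.append(np.ones(ev["move_len"], dtype=int))
    labels.append(np.zeros(pad, dtype=int))
    labels = np.concatenate(labels)
    n = len(labels)

    rest_sd = max(config.rest_jitter_px, 1e-6)
    pos = np.zeros((n, 2))
    conf = np.clip(0.95 - 0.1 * rng.random(n), 0.0, 1.0)
    # occasional single-frame confidence dips to exercise pruning paths
    dips = rng.random(n) < 0.01
    conf[dips] = rng.uniform(0.05, 0.35, dips.sum())

    ipsi_pos = np.zeros((n, 2))
    ipsi_labels = np.zeros(n, dtype=int)
    ipsi_rest_steps = rng.normal(0.0, rest_sd, size=(n, 2))

    cursor = pad
    base = np.array([320.0, 240.0])
    # rest jitter filled globally, overwritten inside move dwells
    steps = rng.normal(0.0, rest_sd, size=(n, 2))
    steps[0] = 0.0
    ipsi_rest_steps[0] = 0.0
    pos[:] = base + np.cumsum(steps, axis=0)
    ipsi_pos[:] = (base + np.array([120.0, 0.0])) + np.cumsum(ipsi_rest_steps, axis=0)

    for ev in plan:
        cursor += ev["rest_len"]
        onset = cursor
        L = ev["move_len"]
        theta = np.radians(ev["raw_angle"])
        direction = np.array([np.cos(theta), -np.sin(theta)])  # y-down pixels
        radial = _radial_trace(L, ev["magnitude"], ev["parabolic"], rng)
        noise = rng.normal(0.0, config.move_noise_px, size=(L, 2))
        start = pos[onset - 1]
        seg = start[None, :] + direction[None, :] * radial[:, None] + noise
        # reconnect the subsequent rest walk to the dwell's end point
        if onset + L < n:
            pos[onset + L :] += seg[-1] - pos[onset + L - 1]
        pos[onset : onset + L] = seg
        if ev["bad_confidence"]:
            conf[onset : onset + L] = rng.uniform(0.05, 0.3, L)
        if ev["coupled"]:
            iradial = radial * ev["coupled_scale"]
            inoise = rng.normal(0.0, config.move_noise_px, size=(L, 2))
            istart = ipsi_pos[onset - 1]
            iseg = istart[None, :] + direction[None, :] * iradial[:, None] + inoise
            if onset + L < n:
                ipsi_pos[onset + L :] += iseg[-1] - ipsi_pos[onset + L - 1]
            ipsi_pos[onset : onset + L] = iseg
            ipsi_labels[onset : onset + L] = MOVE
        ev["onset_frame"] = onset
        cursor += L

    traj = WristTrajectory(frame_rate=fps, positions=pos, confidence=conf, wrist_side="contralateral")
    states = StateSequence(labels=labels, frame_rate=fps, source="ground-truth")
    ipsi_conf = np.clip(0.95 - 0.1 * rng.random(n), 0.0, 1.0)
    ipsi_traj = WristTrajectory(frame_rate=fps, positions=ipsi_pos, confidence=ipsi_conf,
                                wrist_side="ipsilateral")
    ipsi_states = StateSequence(labels=ipsi_labels, frame_rate=fps, source="ground-truth")
    return traj, states, ipsi_traj, ipsi_states, plan


def generate_layout(config: SyntheticConfig, subject: int, seed: int) -> ElectrodeLayout:
    """Half the channels cluster over a 'motor' site, half over a 'temporal' site.

    Rereferencing groups are chunks of (at most) 4 channels so the
    common-median dilution absorbed into INJECTION_CALIBRATION is the same
    for any channel count.
    """
    rng = np.random.default_rng(seed)
    n = config.n_channels
    n_motor = max(1, n // 2)
    hemisphere = "left" if subject % 2 == 0 else "right"
    sign = -1.0 if hemisphere == "left" else 1.0
    motor_center = np.array([sign * 40.0, -20.0, 50.0])
    temporal_center = np.array([sign * 60.0, -40.0, -10.0])
    pos = np.vstack(
        [
            motor_center + rng.normal(0.0, 5.0, size=(n_motor, 3)),
            temporal_center + rng.normal(0.0, 5.0, size=(n - n_motor, 3)),
        ]
    )
    names = [f"MOT{i}" for i in range(n_motor)] + [f"TMP{i}" for i in range(n - n_motor)]
    groups = [f"grid{i // 4}" for i in range(n_motor)]
    groups += [f"strip{i // 4}" for i in range(n - n_motor)]
    is_motor = np.array([True] * n_motor + [False] * (n - n_motor))
    return ElectrodeLayout(names=names, positions=pos, groups=groups,
                           hemisphere=hemisphere, is_motor=is_motor)


def generate_atlas(seed: int = 0, left_sign: int = -1) -> AtlasRegions:
    """Three point-cloud regions: one over the motor site, two elsewhere."""
    rng = np.random.default_rng(seed)
    centers = {
        "motor": np.array([-40.0, -20.0, 50.0]),
        "temporal": np.array([-60.0, -40.0, -10.0]),
        "occipital": np.array([-20.0, -90.0, 10.0]),
    }
    regions = {
        name: c + rng.normal(0.0, 6.0, size=(40, 3)) for name, c in centers.items()
    }
    return AtlasRegions(regions=regions, left_sign=left_sign)


def _pink_noise(rng: np.random.Generator, n: int, rms: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, d=1.0)
    amp = np.zeros(len(freqs))
    amp[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = amp * (rng.normal(size=len(freqs)) + 1j * rng.normal(size=len(freqs)))
    x = np.fft.irfft(spec, n=n)
    return x * (rms / x.std())


def _standardize_features(features: pd.DataFrame) -> pd.DataFrame:
    """Z-score the continuous columns over the whole study population."""
    from .regression import CONTINUOUS_FEATURES, LOG_FEATURES

    out = features.copy()
    for col in CONTINUOUS_FEATURES:
        x = out[col].to_numpy(dtype=float)
        if col in LOG_FEATURES:
            x = np.log(x)
        s = x.std()
        out[col] = (x - x.mean()) / s if s > 1e-12 else 0.0
    return out


def event_deltas(
    features: pd.DataFrame,
    true_betas: dict[str, tuple[float, float]],
    beta0: tuple[float, float],
    noise_sd: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Target (LFB, HFB) dB change per event under the linear forward model.

    Continuous feature names in ``true_betas`` act on study-standardized
    values; keys like ``"day=2"`` or ``"time_of_day=3"`` act as one-hot
    indicators.
    """
    z = _standardize_features(features)
    n = len(features)
    out = {}
    for bi, band in enumerate(("LFB", "HFB")):
        delta = np.full(n, beta0[bi], dtype=float)
        for key, betas in true_betas.items():
            if "=" in key:
                col, lv = key.split("=", 1)
                x = (features[col].astype(str) == lv).to_numpy(dtype=float)
            else:
                x = z[key].to_numpy(dtype=float)
            delta += betas[bi] * x
        delta += rng.normal(0.0, noise_sd, size=n)
        out[band] = delta
    return pd.DataFrame(out, index=features.index)


def generate_neural(
    events: list[MovementEvent],
    deltas: pd.DataFrame,
    layout: ElectrodeLayout,
    duration_s: float,
    neural_rate: float,
    seed: int,
    pink_rms_uv: float = 60.0,
) -> NeuralRecording:
    """Pink-noise recording with event-locked band-power changes on motor channels.

    For each event and band, the band-limited component of each motor
    channel's background is rescaled during [onset, onset + 0.5] s (with
    short cosine ramps) so the Morlet band average changes by the event's
    target delta; the requested change is divided by the pinned calibration
    factor to pre-compensate wavelet dilution.  Non-motor channels receive no
    injected effect.
    """
    if sorted(ev.onset_time for ev in events) != [ev.onset_time for ev in events]:
        raise ValueError("events must be sorted by onset time")
    fs = neural_rate
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    n_ch = len(layout.names)
    v = np.empty((n_ch, n))
    for c in range(n_ch):
        v[c] = _pink_noise(rng, n, pink_rms_uv)

    ramp = int(round(0.05 * fs))
    hold = int(round(0.5 * fs))
    win = np.concatenate([
        0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp)),
        np.ones(hold),
        0.5 * (1 + np.cos(np.pi * np.arange(ramp) / ramp)),
    ])
    nyq = fs / 2.0
    band_signals = {}
    motor_idx = np.flatnonzero(layout.is_motor)
    for band, (lo, hi) in BANDS.items():
        sos = signal.butter(4, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
        band_signals[band] = signal.sosfiltfilt(sos, v[motor_idx], axis=1)

    for j, ev in enumerate(events):
        i0 = int(round(ev.onset_time * fs))
        if i0 < 0 or i0 + len(win) > n:
            raise ValueError(f"event at t={ev.onset_time:.2f}s exceeds recording bounds")
        for band in BANDS:
            target = float(deltas[band].iloc[j])
            g = 10.0 ** (target / (20.0 * INJECTION_CALIBRATION[band]))
            sl = slice(i0, i0 + len(win))
            v[motor_idx, sl] += (g - 1.0) * win[None, :] * band_signals[band][:, sl]

    return NeuralRecording(
        sample_rate=fs,
        voltages=v,
        channel_names=list(layout.names),
        positions=layout.positions.copy(),
        group=list(layout.groups),
        hemisphere=layout.hemisphere,
    )


def generate_audio(
    speech_intervals: list[tuple[float, float]],
    duration_s: float,
    sample_rate: float = 2000.0,
    seed: int = 0,
    floor_rms: float = 0.01,
    speech_rms: float = 0.3,
) -> AudioTrack:
    """Broadband noise floor plus 370–900 Hz band-limited energy in speech intervals."""
    ivals = sorted(speech_intervals)
    for (a, b) in ivals:
        if not (0.0 <= a < b <= duration_s):
            raise ValueError(f"malformed speech interval ({a}, {b})")
    for (a1, b1), (a2, b2) in zip(ivals, ivals[1:]):
        if a2 < b1:
            raise ValueError("overlapping speech intervals")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    x = rng.normal(0.0, floor_rms, n)
    nyq = sample_rate / 2.0
    sos = signal.butter(6, [370.0 / nyq, 900.0 / nyq], btype="bandpass", output="sos")
    speech = signal.sosfiltfilt(sos, rng.normal(0.0, 1.0, n))
    speech *= speech_rms / speech.std()
    for (a, b) in ivals:
        ia, ib = int(round(a * sample_rate)), int(round(b * sample_rate))
        x[ia:ib] += speech[ia:ib]
    return AudioTrack(sample_rate=sample_rate, samples=x)


def _true_events_and_features(
    config: SyntheticConfig,
    plan: list[dict],
    traj: WristTrajectory,
    ipsi_states: StateSequence,
    day: int,
    day_start_clock: float,
) -> tuple[list[MovementEvent], pd.DataFrame]:
    from .features import transform_angle

    fps = config.frame_rate
    events, rows = [], []
    for ev in plan:
        onset = ev["onset_frame"]
        L = ev["move_len"]
        me = MovementEvent(
            onset_frame=onset,
            onset_time=onset / fps,
            day=day,
            clock_time=day_start_clock + onset / fps,
            duration=L / fps,
            reach_magnitude=ev["magnitude"],
            reach_angle_raw=ev["raw_angle"],
            reach_angle=transform_angle(ev["raw_angle"]),
            onset_speed=ev["magnitude"] * 4.0 / (L / fps) * 0.5,
            mean_confidence=1.0,
            quad_r2=1.0 if ev["parabolic"] else 0.0,
            move_dwell=(onset, onset + L),
        )
        events.append(me)
        hours = (me.clock_time / 3600.0) % 24.0
        rows.append(
            {
                "event": onset,
                "day": day,
                "time_of_day": 1 if hours < 8 else (2 if hours < 16 else 3),
                "duration": L / fps,
                "magnitude": ev["magnitude"],
                "angle": transform_angle(ev["raw_angle"]),
                "onset_speed": ev["magnitude"] * 4.0 / (L / fps) * 0.5,  # mean slope, first half
                "speech_ratio": 1.0 if ev["speech"] else 0.0,
                "bimanual_ratio": ev["coupled_scale"] / (1.0 + ev["coupled_scale"]) if ev["coupled"] else 0.0,
                "bimanual_overlap": 1.0 if ev["coupled"] else 0.0,
                "bimanual_class": 1 if ev["coupled"] else 0,
            }
        )
    return events, pd.DataFrame(rows)


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Compose trajectories, neural recordings, audio, layouts, and atlas.

    All randomness derives from ``config.seed`` through a spawned seed tree,
    so a fixed config reproduces the study bit for bit.
    """
    root = np.random.SeedSequence(config.seed)
    atlas = generate_atlas(seed=int(root.spawn(1)[0].generate_state(1)[0]) % (2**31))
    layouts = {}
    sessions: list[SubjectDay] = []
    subj_seeds = root.spawn(config.n_subjects)
    for s in range(config.n_subjects):
        layout_seed, *day_seeds = subj_seeds[s].spawn(1 + len(config.days))
        layouts[s] = generate_layout(config, s, int(layout_seed.generate_state(1)[0]) % (2**31))
        # first pass: behavior and true features for every day of this subject
        per_day = []
        for d_i, day in enumerate(config.days):
            ds = day_seeds[d_i]
            beh_s, neu_s, aud_s, clk_s = [int(x.generate_state(1)[0]) % (2**31) for x in ds.spawn(4)]
            traj, states, ipsi_traj, ipsi_states, plan = _generate_session_behavior(config, beh_s)
            clock_rng = np.random.default_rng(clk_s)
            day_start_clock = float(clock_rng.uniform(7.0, 15.0) * 3600.0)
            events, features = _true_events_and_features(
                config, plan, traj, ipsi_states, day, day_start_clock
            )
            per_day.append(dict(
                day=day, traj=traj, states=states, ipsi_traj=ipsi_traj,
                ipsi_states=ipsi_states, plan=plan, events=events, features=features,
                neu_s=neu_s, aud_s=aud_s, clk_s=clk_s, day_start_clock=day_start_clock,
            ))
        # second pass: deltas standardized over the subject's whole event
        # population, then the per-day recordings and audio
        all_features = pd.concat([d["features"] for d in per_day], ignore_index=True)
        delta_rng = np.random.default_rng(per_day[0]["clk_s"] + 1)
        all_deltas = event_deltas(all_features, config.true_betas, config.beta0,
                                  config.noise_sd, delta_rng)
        offset = 0
        for d in per_day:
            n_ev = len(d["features"])
            deltas = all_deltas.iloc[offset : offset + n_ev].reset_index(drop=True)
            offset += n_ev
            duration_s = d["traj"].n_frames / config.frame_rate
            recording = generate_neural(
                d["events"], deltas, layouts[s], duration_s, config.neural_rate,
                d["neu_s"], pink_rms_uv=config.pink_rms_uv,
            )
            raw_intervals = [
                (max(0.0, ev.onset_time - 1.0), min(duration_s, ev.onset_time + 1.0))
                for ev, p in zip(d["events"], d["plan"]) if p["speech"]
            ]
            speech_intervals: list[tuple[float, float]] = []
            for a, b in sorted(raw_intervals):  # merge overlaps from nearby events
                if speech_intervals and a <= speech_intervals[-1][1]:
                    speech_intervals[-1] = (speech_intervals[-1][0], max(b, speech_intervals[-1][1]))
                else:
                    speech_intervals.append((a, b))
            audio = generate_audio(speech_intervals, duration_s, config.audio_rate, d["aud_s"])
            sessions.append(
                SubjectDay(
                    subject=s, day=d["day"],
                    contra_traj=d["traj"], ipsi_traj=d["ipsi_traj"],
                    contra_states=d["states"], ipsi_states=d["ipsi_states"],
                    events=d["events"], features=d["features"],
                    recording=recording, audio=audio,
                    speech_intervals=speech_intervals,
                    day_start_clock=d["day_start_clock"],
                )
            )
    return SyntheticStudy(config=config, layouts=layouts, atlas=atlas, sessions=sessions)
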