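"""Per-event behavioral and environmental metadata features.

Ten features per kept movement event: day of recording and time-of-day bin
(timing), reach duration, magnitude, vertical-sensitive angle, and onset
speed (kinematics), a 370–900 Hz speech-band audio power ratio
(environment), and three bimanual descriptors (ratio, overlap, class).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .events import MovementEvent
from .hsmm import MOVE, StateSequence, WristTrajectory

SPEECH_BAND = (370.0, 900.0)
SPEECH_SMOOTH_CUTOFF_HZ = 4.2e-3
SPEECH_WINDOW = (-1.0, 1.0)
STFT_WINDOW_S = 1.0
STFT_HOP_S = 0.5
GATE_REDUCTION_DB = 40.0
BIMANUAL_MIN_RUN = 4
BIMANUAL_LOOKBACK_S = 1.0
TIME_BIN_EDGES_H = (0.0, 8.0, 16.0, 24.0)

FEATURE_COLUMNS = [
    "day", "time_of_day", "duration", "magnitude", "angle", "onset_speed",
    "speech_ratio", "bimanual_ratio", "bimanual_overlap", "bimanual_class",
]


@dataclass
class AudioTrack:
    """Mono audio waveform."""

    sample_rate: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("audio must be mono (1-D)")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


def transform_angle(raw_angle_deg: float | np.ndarray):
    """Fold a raw 2D angle onto [-90, 90] so it is sensitive to vertical reach.

    Raw angles are degrees in [0, 360), counter-clockwise from screen-right
    with up = 90.  Angles between 90 and 270 are reflected so the output
    ranges from 90 (upward) to -90 (downward); the map is idempotent on its
    range and symmetric about the vertical axis.
    """
    raw = np.asarray(raw_angle_deg, dtype=float)
    a = ((raw + 180.0) % 360.0) - 180.0  # (-180, 180]
    a = np.where(a > 90.0, 180.0 - a, a)
    a = np.where(a < -90.0, -180.0 - a, a)
    return float(a) if np.ndim(raw_angle_deg) == 0 else a


def stft_power_ratio(
    audio: AudioTrack,
    band: tuple[float, float] = SPEECH_BAND,
    noise_profile: Optional[np.ndarray] = None,
    gate_margin: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Short-time band-to-total power ratio of an audio track.

    Returns (frame_times, ratio).  Frames use a 1 s window with a 0.5 s hop.
    If ``noise_profile`` (per-bin magnitude from a rest period) is given,
    spectral components with magnitude below ``gate_margin`` times the
    profile are attenuated by 40 dB before power is computed.
    """
    fs = audio.sample_rate
    nper = int(round(STFT_WINDOW_S * fs))
    hop = int(round(STFT_HOP_S * fs))
    freqs, times, Z = signal.stft(
        audio.samples, fs=fs, nperseg=nper, noverlap=nper - hop, boundary=None, padded=False
    )
    mag = np.abs(Z)
    if noise_profile is not None:
        if len(noise_profile) != len(freqs):
            raise ValueError("noise profile length must match the STFT bin count")
        gated = mag < gate_margin * noise_profile[:, None]
        mag = np.where(gated, mag * 10.0 ** (-GATE_REDUCTION_DB / 20.0), mag)
    power = mag**2
    total = power.sum(axis=0)
    insel = (freqs >= band[0]) & (freqs <= band[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, power[insel].sum(axis=0) / total, 0.0)
    return times, ratio


def estimate_noise_profile(audio: AudioTrack, interval: tuple[float, float]) -> np.ndarray:
    """Median short-time magnitude spectrum over a rest (noise-only) interval."""
    fs = audio.sample_rate
    a, b = int(interval[0] * fs), int(interval[1] * fs)
    clip = AudioTrack(sample_rate=fs, samples=audio.samples[a:b])
    nper = int(round(STFT_WINDOW_S * fs))
    hop = int(round(STFT_HOP_S * fs))
    _, _, Z = signal.stft(clip.samples, fs=fs, nperseg=nper, noverlap=nper - hop,
                          boundary=None, padded=False)
    return np.median(np.abs(Z), axis=1)


def _one_pole_lowpass(x: np.ndarray, cutoff_hz: float, rate_hz: float) -> np.ndarray:
    """First-order low-pass, state initialised at the first sample."""
    rc = 1.0 / (2.0 * np.pi * cutoff_hz)
    dt = 1.0 / rate_hz
    alpha = dt / (rc + dt)
    b, a = [alpha], [1.0, -(1.0 - alpha)]
    zi = signal.lfiltic(b, a, y=[x[0]], x=[x[0]])
    y, _ = signal.lfilter(b, a, x, zi=zi)
    return y


def speech_ratio(
    audio: AudioTrack,
    event_time: float,
    band: tuple[float, float] = SPEECH_BAND,
    cutoff_hz: float = SPEECH_SMOOTH_CUTOFF_HZ,
    window: tuple[float, float] = SPEECH_WINDOW,
    noise_profile: Optional[np.ndarray] = None,
    smooth: bool = True,
) -> float:
    """Speech-band power fraction around one event, in [0, 1].

    The short-time band-to-total ratio is optionally noise-gated, smoothed by
    a first-order low-pass at ``cutoff_hz`` (default 4.2 mHz), and averaged
    over ``window`` seconds around ``event_time``.
    """
    lo, hi = event_time + window[0], event_time + window[1]
    if lo < 0 or hi > audio.duration:
        raise ValueError("event window extends outside the audio track")
    times, ratio = stft_power_ratio(audio, band=band, noise_profile=noise_profile)
    if smooth:
        ratio = _one_pole_lowpass(ratio, cutoff_hz, 1.0 / STFT_HOP_S)
    sel = (times >= lo) & (times <= hi)
    if not sel.any():
        sel = np.argmin(np.abs(times - event_time))  # degenerate short track
        val = float(ratio[sel])
    else:
        val = float(ratio[sel].mean())
    return float(np.clip(val, 0.0, 1.0))


def _has_run(mask: np.ndarray, min_run: int) -> bool:
    """True if ``mask`` contains a run of >= min_run consecutive True values
    that *begins* inside the mask span (run start within the window)."""
    count = 0
    for i, m in enumerate(mask):
        count = count + 1 if m else 0
        if count >= min_run:
            return True
    return False


def bimanual_features(
    contra_traj: WristTrajectory,
    ipsi_traj: WristTrajectory,
    contra_states: StateSequence,
    ipsi_states: StateSequence,
    event: MovementEvent,
) -> tuple[float, float, int]:
    """(bimanual ratio, overlap, class) for one contralateral event.

    ratio: ipsilateral reach magnitude over the contralateral move dwell,
    divided by the sum of both magnitudes.  overlap: fraction of contralateral
    move-dwell frames in which the ipsilateral wrist is also in a move state.
    class: 1 (bimanual) iff a run of >= 4 consecutive ipsilateral move frames
    begins between 1 s before onset and the end of the contralateral dwell.
    """
    start, end = event.move_dwell
    fps = contra_traj.frame_rate
    contra_pos = contra_traj.positions[start:end]
    contra_mag = float(np.max(np.linalg.norm(contra_pos - contra_pos[0], axis=1)))
    ipsi_pos = ipsi_traj.positions[start:end]
    ipsi_mag = float(np.max(np.linalg.norm(ipsi_pos - ipsi_pos[0], axis=1)))
    if contra_mag + ipsi_mag <= 0:
        warnings.warn("both reach magnitudes are zero; bimanual ratio set to 0", stacklevel=2)
        ratio = 0.0
    else:
        ratio = ipsi_mag / (ipsi_mag + contra_mag)

    ipsi_move = ipsi_states.labels == MOVE
    overlap = float(np.mean(ipsi_move[start:end]))

    look = int(round(BIMANUAL_LOOKBACK_S * fps))
    w0 = max(0, start - look)
    window = ipsi_move[w0:end].copy()
    if w0 > 0 and ipsi_move[w0 - 1]:
        # a run already in progress before the window did not *begin* in it;
        # strip its continuation at the window head
        i = 0
        while i < len(window) and window[i]:
            window[i] = False
            i += 1
    # a qualifying run must start in-window but may extend past the dwell end
    tail = ipsi_move[end : end + BIMANUAL_MIN_RUN - 1]
    padded = np.concatenate([window, tail])
    bimanual = int(_has_run(padded, BIMANUAL_MIN_RUN))
    return ratio, overlap, bimanual


def timing_features(event: MovementEvent) -> tuple[int, int]:
    """(day index, time-of-day bin) with half-open 8 h bins [0-8), [8-16), [16-24)."""
    hours = (event.clock_time / 3600.0) % 24.0
    if hours < TIME_BIN_EDGES_H[1]:
        bin_ = 1
    elif hours < TIME_BIN_EDGES_H[2]:
        bin_ = 2
    else:
        bin_ = 3
    return event.day, bin_


def compute_feature_table(
    events: Sequence[MovementEvent],
    contra_traj: WristTrajectory,
    ipsi_traj: WristTrajectory,
    contra_states: StateSequence,
    ipsi_states: StateSequence,
    audio: Optional[AudioTrack] = None,
    noise_profile: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """All 10 features for every kept event of one subject-day, as a tidy table."""
    rows = []
    for ev in events:
        if not ev.kept:
            continue
        day, tod = timing_features(ev)
        ratio, overlap, biclass = bimanual_features(
            contra_traj, ipsi_traj, contra_states, ipsi_states, ev
        )
        if audio is not None:
            sr = speech_ratio(audio, ev.onset_time, noise_profile=noise_profile)
        else:
            sr = 0.0
        rows.append(
            {
                "event": ev.onset_frame,
                "day": day,
                "time_of_day": tod,
                "duration": ev.duration,
                "magnitude": ev.reach_magnitude,
                "angle": ev.reach_angle,
                "onset_speed": ev.onset_speed,
                "speech_ratio": sr,
                "bimanual_ratio": ratio,
                "bimanual_overlap": overlap,
                "bimanual_class": biclass,
            }
        )
    df = pd.DataFrame(rows, columns=["event"] + FEATURE_COLUMNS)
    if df[FEATURE_COLUMNS].isna().any().any():
        raise ValueError("feature table contains missing values")
    return df
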