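"""Event-aligned segmentation and Morlet time–frequency log power.

Segments are 10 s of 500 Hz voltage centred on each movement onset.  Power is
computed by convolution with complex Morlet wavelets (unit L2 norm, n_cycles
= f/2 with a floor of 3), expressed in dB (10·log10), baseline-subtracted
against the [-1.5, -1] s pre-onset window, and averaged over the LFB
(8–32 Hz) and HFB (76–100 Hz) bands in the first 0.5 s after onset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .events import MovementEvent
from .preprocess import NeuralRecording

SEGMENT_HALF_S = 5.0
BASELINE_WINDOW = (-1.5, -1.0)
RESPONSE_WINDOW = (0.0, 0.5)
BANDS = {"LFB": (8.0, 32.0), "HFB": (76.0, 100.0)}
DEFAULT_FREQS = np.arange(4.0, 126.0, 2.0)  # 4–124 Hz in 2 Hz steps
EDGE_S = 1.0  # leading/trailing second of each spectrogram is edge-contaminated
_TINY = 1e-300


@dataclass
class EventSegment:
    event_id: int
    data: np.ndarray  # (n_channels, n_samples) µV at `sample_rate`
    sample_rate: float
    channel_names: list[str]
    onset_index: int  # sample index of the movement onset (window centre)
    zeroed_count: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        expected = int(round(2 * SEGMENT_HALF_S * self.sample_rate))
        if self.data.shape[1] != expected:
            raise ValueError(f"segment must span 10 s ({expected} samples), got {self.data.shape[1]}")
        if self.onset_index != expected // 2:
            raise ValueError("onset must sit at the window centre")


@dataclass
class Spectrogram:
    freqs: np.ndarray  # Hz, strictly increasing
    times: np.ndarray  # s relative to onset, strictly increasing
    power_db: np.ndarray  # (n_freqs, n_times)
    baseline_subtracted: bool = False
    baseline_window: tuple[float, float] = BASELINE_WINDOW
    channel: str = ""
    event_id: int = -1

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.power_db = np.asarray(self.power_db, dtype=float)
        if np.any(np.diff(self.freqs) <= 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("frequency and time grids must be strictly increasing")
        if self.power_db.shape != (len(self.freqs), len(self.times)):
            raise ValueError("power_db shape must be (n_freqs, n_times)")


def extract_segments(
    recording: NeuralRecording, events: Sequence[MovementEvent]
) -> tuple[list[EventSegment], list[tuple[MovementEvent, str]]]:
    """Cut a 10 s window centred on each event onset; bad channels are dropped.

    Returns (segments, dropped) where ``dropped`` pairs each skipped event
    with a reason (currently only proximity to the recording edge).
    """
    fs = recording.sample_rate
    half = int(round(SEGMENT_HALF_S * fs))
    good = ~recording.bad_channels
    names = [n for n, g in zip(recording.channel_names, good) if g]
    segments: list[EventSegment] = []
    dropped: list[tuple[MovementEvent, str]] = []
    for ev in events:
        i0 = int(round(ev.onset_time * fs))
        lo, hi = i0 - half, i0 + half
        if lo < 0 or hi > recording.n_samples:
            dropped.append((ev, "too close to recording edge"))
            continue
        seg = EventSegment(
            event_id=ev.onset_frame,
            data=recording.voltages[good, lo:hi].copy(),
            sample_rate=fs,
            channel_names=names,
            onset_index=half,
            zeroed_count=int(recording.zeroed_mask[lo:hi].sum()),
        )
        segments.append(seg)
    return segments, dropped


def _segment_psd_db(segment: EventSegment) -> tuple[np.ndarray, np.ndarray]:
    """Channel-averaged Welch PSD of one segment, in dB (freqs, psd_db)."""
    freqs, psd = signal.welch(segment.data, fs=segment.sample_rate, nperseg=1024, axis=1)
    mean_psd = psd.mean(axis=0)
    return freqs, 10.0 * np.log10(mean_psd + _TINY)


def reject_bad_segments(
    segments: Sequence[EventSegment], sd_k: float = 3.0
) -> tuple[list[EventSegment], list[tuple[EventSegment, str]]]:
    """Drop segments with missing data or line-noise-like artifacts.

    A segment is discarded if its mean log spectral density is below 0 dB
    (proxy for zeroed/missing data) or if its 115–125 Hz power exceeds the
    across-segment mean by more than ``sd_k`` standard deviations.
    """
    if len(segments) < 2:
        raise ValueError("need at least 2 segments for the SD criterion")
    mean_db = np.empty(len(segments))
    line_db = np.empty(len(segments))
    for i, seg in enumerate(segments):
        f, psd_db = _segment_psd_db(seg)
        mean_db[i] = psd_db.mean()
        band = (f >= 115.0) & (f <= 125.0)
        line_db[i] = psd_db[band].mean()
    keep: list[EventSegment] = []
    rejected: list[tuple[EventSegment, str]] = []
    line_thresh = line_db.mean() + sd_k * line_db.std()
    for i, seg in enumerate(segments):
        if mean_db[i] < 0.0:
            rejected.append((seg, "power below 0 dB"))
        elif line_db[i] > line_thresh:
            rejected.append((seg, "115-125 Hz power outlier"))
        else:
            keep.append(seg)
    if not keep:
        raise ValueError("all segments rejected")
    return keep, rejected


def morlet_wavelet(freq: float, sample_rate: float, n_cycles: float) -> np.ndarray:
    """Complex Morlet wavelet with unit L2 norm, truncated at ±5 sigma_t."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(5.0 * sigma_t * sample_rate))
    t = np.arange(-half, half + 1) / sample_rate
    w = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2.0 * sigma_t**2))
    return w / np.linalg.norm(w)


def default_n_cycles(freq: np.ndarray) -> np.ndarray:
    return np.maximum(3.0, np.asarray(freq, dtype=float) / 2.0)


def morlet_power(
    segment: EventSegment,
    freqs: Optional[np.ndarray] = None,
    decim: int = 10,
) -> list[Spectrogram]:
    """Log-power (dB) Morlet spectrogram for each channel of a segment.

    Time is decimated by ``decim`` after power computation.  The first and
    last ``EDGE_S`` seconds suffer wavelet edge effects and should not be
    interpreted; both lie well outside the baseline and response windows.
    """
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, dtype=float)
    fs = segment.sample_rate
    n = segment.data.shape[1]
    cycles = default_n_cycles(freqs)
    power = np.empty((segment.data.shape[0], len(freqs), int(np.ceil(n / decim))))
    for i, (f0, nc) in enumerate(zip(freqs, cycles)):
        w = morlet_wavelet(f0, fs, nc)
        conv = signal.fftconvolve(segment.data, w[None, :], mode="same", axes=1)
        power[:, i, :] = np.abs(conv[:, ::decim]) ** 2
    times = (np.arange(n)[::decim] - segment.onset_index) / fs
    power_db = 10.0 * np.log10(power + _TINY)
    return [
        Spectrogram(freqs=freqs, times=times, power_db=power_db[c],
                    channel=segment.channel_names[c], event_id=segment.event_id)
        for c in range(segment.data.shape[0])
    ]


def baseline_subtract(spec: Spectrogram) -> Spectrogram:
    """Subtract the per-frequency mean over the pre-onset baseline window."""
    if spec.baseline_subtracted:
        raise ValueError("spectrogram already baseline-subtracted")
    lo, hi = spec.baseline_window
    sel = (spec.times >= lo) & (spec.times <= hi)
    if not sel.any():
        raise ValueError("baseline window absent from time grid")
    base = spec.power_db[:, sel].mean(axis=1, keepdims=True)
    return Spectrogram(
        freqs=spec.freqs.copy(),
        times=spec.times.copy(),
        power_db=spec.power_db - base,
        baseline_subtracted=True,
        baseline_window=spec.baseline_window,
        channel=spec.channel,
        event_id=spec.event_id,
    )


def band_average(
    spec: Spectrogram,
    band: str | tuple[float, float],
    window: tuple[float, float] = RESPONSE_WINDOW,
) -> float:
    """Mean baseline-subtracted log power over a band and post-onset window.

    Band membership is a closed interval on frequency-bin centres; the time
    window is closed as well.
    """
    if not spec.baseline_subtracted:
        raise ValueError("band_average requires a baseline-subtracted spectrogram")
    lo, hi = BANDS[band] if isinstance(band, str) else band
    fsel = (spec.freqs >= lo) & (spec.freqs <= hi)
    if not fsel.any():
        raise ValueError(f"band [{lo}, {hi}] Hz outside the frequency grid")
    tsel = (spec.times >= window[0]) & (spec.times <= window[1])
    if not tsel.any():
        raise ValueError("time window outside the spectrogram")
    return float(spec.power_db[np.ix_(fsel, tsel)].mean())


def compute_band_powers(
    segments: Sequence[EventSegment],
    freqs: Optional[np.ndarray] = None,
    decim: int = 10,
    bands: Sequence[str] = ("LFB", "HFB"),
) -> pd.DataFrame:
    """Per-event, per-channel band powers as a tidy table (event, channel, band, value)."""
    rows = []
    for seg in segments:
        for spec in morlet_power(seg, freqs=freqs, decim=decim):
            sub = baseline_subtract(spec)
            for band in bands:
                rows.append(
                    {"event": seg.event_id, "channel": spec.channel, "band": band,
                     "value": band_average(sub, band)}
                )
    return pd.DataFrame(rows, columns=["event", "channel", "band", "value"])
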