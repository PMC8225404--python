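"""Cleaning of multichannel neural voltage recordings.

Fixed stage order: DC removal → artifact zeroing → band-pass/notch filtering
with resampling to 500 Hz → common-median rereferencing per electrode group →
bad-channel flagging.  All "IQR, > k" rules are one-sided high: a value is
abnormal when it exceeds median + k·IQR of the relevant distribution.
Medians over an even number of values use the lower of the two central order
statistics, for exact reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field


import numpy as np
from scipy import signal, stats

TARGET_RATE = 500.0
BANDPASS = (1.0, 200.0)
NOTCH_FREQS = (60.0, 120.0, 180.0)
ARTIFACT_K = 50.0
ARTIFACT_PAD_S = 2.0
BAD_SD_K = 5.0
BAD_KURT_K = 10.0


class RecordingUnusableError(ValueError):
    """Raised when artifact rejection would zero the entire recording."""


@dataclass
class NeuralRecording:
    """Multichannel voltage array with electrode metadata.

    positions are (x, y, z) in mm, MNI-like, with signed x encoding hemisphere
    (left x <= 0 by convention).  ``group`` carries the grid/strip/depth group
    id used for common-median rereferencing.  ``zeroed_mask`` marks samples
    blanked by artifact rejection (shared across channels).
    """

    sample_rate: float
    voltages: np.ndarray  # (n_channels, n_samples) µV
    channel_names: list[str]
    positions: np.ndarray  # (n_channels, 3) mm
    group: list[str]
    hemisphere: str = "left"  # implanted hemisphere: "left" or "right"
    bad_channels: np.ndarray = field(default=None)  # bool (n_channels,)
    zeroed_mask: np.ndarray = field(default=None)  # bool (n_samples,)

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.voltages.ndim != 2:
            raise ValueError("voltages must be (n_channels, n_samples)")
        n_ch = self.voltages.shape[0]
        if len(self.channel_names) != n_ch or len(self.group) != n_ch or len(self.positions) != n_ch:
            raise ValueError("channel metadata length mismatch")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("electrode positions must be finite")
        if self.bad_channels is None:
            self.bad_channels = np.zeros(n_ch, dtype=bool)
        if self.zeroed_mask is None:
            self.zeroed_mask = np.zeros(self.voltages.shape[1], dtype=bool)
        if self.zeroed_mask.shape != (self.voltages.shape[1],):
            raise ValueError("zeroed_mask must match the sample axis")

    @property
    def n_channels(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def copy_with(self, **kw) -> "NeuralRecording":
        base = dict(
            sample_rate=self.sample_rate,
            voltages=self.voltages.copy(),
            channel_names=list(self.channel_names),
            positions=self.positions.copy(),
            group=list(self.group),
            hemisphere=self.hemisphere,
            bad_channels=self.bad_channels.copy(),
            zeroed_mask=self.zeroed_mask.copy(),
        )
        base.update(kw)
        return NeuralRecording(**base)


def low_median(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Median taking the lower of the two central order statistics when n is even."""
    x = np.asarray(x)
    n = x.shape[axis]
    k = (n - 1) // 2
    return np.take(np.sort(x, axis=axis), k, axis=axis)


def remove_dc(recording: NeuralRecording) -> NeuralRecording:
    """Subtract each channel's median voltage (idempotent up to float error)."""
    if recording.n_samples < 1:
        raise ValueError("empty recording")
    med = low_median(recording.voltages, axis=1)
    return recording.copy_with(voltages=recording.voltages - med[:, None])


def zero_artifacts(
    recording: NeuralRecording, k: float = ARTIFACT_K, pad_s: float = ARTIFACT_PAD_S
) -> NeuralRecording:
    """Blank widespread high-amplitude artifacts.

    Samples where the channel-averaged absolute voltage exceeds
    median + k·IQR (median/IQR over samples of that statistic) are set to 0
    on all channels, together with ±``pad_s`` seconds.  The zeroed-sample
    mask records what was blanked.
    """
    s = np.mean(np.abs(recording.voltages), axis=0)
    med = np.median(s)
    q75, q25 = np.percentile(s, [75, 25])
    thresh = med + k * (q75 - q25)
    flagged = s > thresh
    if not flagged.any():
        return recording.copy_with()
    pad = int(round(pad_s * recording.sample_rate))
    mask = np.zeros_like(flagged)
    idx = np.flatnonzero(flagged)
    for i in idx:
        mask[max(0, i - pad) : i + pad + 1] = True
    if mask.all():
        raise RecordingUnusableError("recording unusable: artifact rejection removed all samples")
    v = recording.voltages.copy()
    v[:, mask] = 0.0
    return recording.copy_with(voltages=v, zeroed_mask=recording.zeroed_mask | mask)


def filter_resample(recording: NeuralRecording, target_rate: float = TARGET_RATE) -> NeuralRecording:
    """1–200 Hz band-pass, 60/120/180 Hz notches, then resample to 500 Hz.

    Filtering is zero-phase (forward–backward) so event times are not
    shifted.  Requires the input rate to be at least the target rate.
    """
    fs = recording.sample_rate
    if fs < target_rate:
        raise ValueError(f"sample rate {fs} below target {target_rate}")
    nyq = fs / 2.0
    sos = signal.butter(4, [BANDPASS[0] / nyq, BANDPASS[1] / nyq], btype="bandpass", output="sos")
    v = signal.sosfiltfilt(sos, recording.voltages, axis=1)
    for f0 in NOTCH_FREQS:
        if f0 >= nyq:
            continue
        b, a = signal.iirnotch(f0, 30.0, fs=fs)
        v = signal.filtfilt(b, a, v, axis=1)
    # rational resampling
    from fractions import Fraction

    frac = Fraction(int(round(target_rate * 1000)), int(round(fs * 1000)))
    up, down = frac.numerator, frac.denominator
    v = signal.resample_poly(v, up, down, axis=1)
    # carry the zeroed mask onto the new time base
    n_new = v.shape[1]
    old_idx = np.minimum((np.arange(n_new) * down) // up, recording.n_samples - 1)
    mask = recording.zeroed_mask[old_idx]
    return recording.copy_with(sample_rate=float(target_rate), voltages=v, zeroed_mask=mask)


def rereference_common_median(recording: NeuralRecording) -> NeuralRecording:
    """Subtract, per sample, the median across channels within each electrode group."""
    v = recording.voltages.copy()
    for g in sorted(set(recording.group)):
        idx = [i for i, gi in enumerate(recording.group) if gi == g]
        if len(idx) == 1:
            warnings.warn(f"group {g!r} has a single channel; left unreferenced", stacklevel=2)
            continue
        ref = low_median(v[idx], axis=0)
        v[idx] -= ref[None, :]
    return recording.copy_with(voltages=v)


def flag_bad_channels(
    recording: NeuralRecording, k_sd: float = BAD_SD_K, k_kurt: float = BAD_KURT_K
) -> NeuralRecording:
    """Flag channels with abnormal SD or kurtosis relative to the channel median.

    A channel is bad if its SD exceeds median + k_sd·IQR or its kurtosis
    exceeds median + k_kurt·IQR, where medians and IQRs are taken across
    channels.  One-sided high rule; flags are order-invariant.
    """
    if recording.n_channels < 4:
        raise ValueError("need at least 4 channels for stable IQR-based flagging")
    sd = recording.voltages.std(axis=1)
    kurt = stats.kurtosis(recording.voltages, axis=1, fisher=False)

    def _thresh(x: np.ndarray, k: float) -> float:
        q75, q25 = np.percentile(x, [75, 25])
        return float(np.median(x) + k * (q75 - q25))

    bad = (sd > _thresh(sd, k_sd)) | (kurt > _thresh(kurt, k_kurt))
    return recording.copy_with(bad_channels=recording.bad_channels | bad)


def preprocess(recording: NeuralRecording) -> NeuralRecording:
    """Full pipeline: DC → artifacts → filter/resample → rereference → bad channels."""
    rec = remove_dc(recording)
    rec = zero_artifacts(rec)
    rec = filter_resample(rec)
    rec = rereference_common_median(rec)
    rec = flag_bad_channels(rec)
    return rec
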