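"""Readers and writers for the on-disk interchange formats.

Delimited text tables (CSV) for trajectories, states, events, features, band
powers, and atlases; a ``.npy`` array plus JSON sidecar for neural
recordings; RIFF WAV for audio.  Small metadata (frame rate, wrist side,
hemisphere, ...) lives in JSON sidecars named ``<stem>.meta.json``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .events import MovementEvent
from .features import AudioTrack
from .hsmm import StateSequence, WristTrajectory
from .preprocess import NeuralRecording
from .roi import AtlasRegions


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def save_trajectory(path: str | Path, traj: WristTrajectory) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "frame": np.arange(traj.n_frames),
            "x": traj.positions[:, 0],
            "y": traj.positions[:, 1],
            "confidence": traj.confidence,
        }
    )
    df.to_csv(path, index=False)
    _write_json(_sidecar(path), {"frame_rate": traj.frame_rate, "wrist_side": traj.wrist_side})


def load_trajectory(path: str | Path, frame_rate: float | None = None) -> WristTrajectory:
    path = Path(path)
    df = pd.read_csv(path)
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    fr = frame_rate if frame_rate is not None else meta.get("frame_rate")
    if fr is None:
        raise ValueError(f"frame rate unknown for {path}: pass frame_rate or provide a sidecar")
    return WristTrajectory(
        frame_rate=float(fr),
        positions=df[["x", "y"]].to_numpy(dtype=float),
        confidence=df["confidence"].to_numpy(dtype=float),
        wrist_side=meta.get("wrist_side", "contralateral"),
    )


def save_states(path: str | Path, states: StateSequence) -> None:
    path = Path(path)
    post = states.posterior if states.posterior is not None else np.full(len(states.labels), np.nan)
    df = pd.DataFrame(
        {"frame": np.arange(len(states.labels)), "label": states.labels, "posterior": post}
    )
    df.to_csv(path, index=False)
    _write_json(_sidecar(path), {"frame_rate": states.frame_rate, "source": states.source})


def load_states(path: str | Path, frame_rate: float | None = None) -> StateSequence:
    path = Path(path)
    df = pd.read_csv(path)
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    fr = frame_rate if frame_rate is not None else meta.get("frame_rate")
    post = df["posterior"].to_numpy(dtype=float)
    return StateSequence(
        labels=df["label"].to_numpy(dtype=int),
        frame_rate=float(fr),
        posterior=None if np.isnan(post).all() else post,
        source=meta.get("source", "fitted"),
    )


EVENT_COLUMNS = [
    "onset_frame", "onset_time", "day", "clock_time", "duration", "reach_magnitude",
    "reach_angle_raw", "reach_angle", "onset_speed", "mean_confidence", "quad_r2",
    "kept", "rejection_reason", "dwell_start", "dwell_end",
]


def events_to_frame(events: Sequence[MovementEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        d = dataclasses.asdict(ev)
        start, end = d.pop("move_dwell")
        d["dwell_start"], d["dwell_end"] = start, end
        rows.append(d)
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def frame_to_events(df: pd.DataFrame) -> list[MovementEvent]:
    events = []
    for _, row in df.iterrows():
        events.append(
            MovementEvent(
                onset_frame=int(row["onset_frame"]),
                onset_time=float(row["onset_time"]),
                day=int(row["day"]),
                clock_time=float(row["clock_time"]),
                duration=float(row["duration"]),
                reach_magnitude=float(row["reach_magnitude"]),
                reach_angle_raw=float(row["reach_angle_raw"]),
                reach_angle=float(row["reach_angle"]),
                onset_speed=float(row["onset_speed"]),
                mean_confidence=float(row["mean_confidence"]),
                quad_r2=float(row["quad_r2"]),
                kept=bool(row["kept"]),
                rejection_reason="" if pd.isna(row["rejection_reason"]) else str(row["rejection_reason"]),
                move_dwell=(int(row["dwell_start"]), int(row["dwell_end"])),
            )
        )
    return events


def save_events(path: str | Path, events: Sequence[MovementEvent]) -> None:
    events_to_frame(events).to_csv(Path(path), index=False)


def load_events(path: str | Path) -> list[MovementEvent]:
    return frame_to_events(pd.read_csv(path))


def save_recording(prefix: str | Path, rec: NeuralRecording) -> None:
    """Write voltages to ``<prefix>.npy`` and metadata to ``<prefix>.json``."""
    prefix = Path(prefix)
    np.save(prefix.with_suffix(".npy"), rec.voltages)
    _write_json(
        prefix.with_suffix(".json"),
        {
            "sample_rate": rec.sample_rate,
            "channel_names": rec.channel_names,
            "positions_mm": rec.positions.tolist(),
            "group": rec.group,
            "hemisphere": rec.hemisphere,
            "bad_channels": rec.bad_channels.astype(int).tolist(),
            "zeroed_mask_runs": _mask_to_runs(rec.zeroed_mask),
        },
    )


def _mask_to_runs(mask: np.ndarray) -> list[list[int]]:
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.astype(int), [0]])))
    return [[int(a), int(b)] for a, b in zip(idx[::2], idx[1::2])]


def _runs_to_mask(runs: list[list[int]], n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for a, b in runs:
        mask[a:b] = True
    return mask


def load_recording(prefix: str | Path) -> NeuralRecording:
    prefix = Path(prefix)
    v = np.load(prefix.with_suffix(".npy"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return NeuralRecording(
        sample_rate=float(meta["sample_rate"]),
        voltages=v,
        channel_names=list(meta["channel_names"]),
        positions=np.asarray(meta["positions_mm"], dtype=float),
        group=list(meta["group"]),
        hemisphere=meta["hemisphere"],
        bad_channels=np.asarray(meta["bad_channels"], dtype=bool),
        zeroed_mask=_runs_to_mask(meta["zeroed_mask_runs"], v.shape[1]),
    )


def save_audio(path: str | Path, audio: AudioTrack) -> None:
    wavfile.write(Path(path), int(round(audio.sample_rate)), audio.samples.astype(np.float32))


def load_audio(path: str | Path) -> AudioTrack:
    rate, data = wavfile.read(Path(path))
    return AudioTrack(sample_rate=float(rate), samples=np.asarray(data, dtype=float))


def save_atlas(path: str | Path, atlas: AtlasRegions) -> None:
    rows = []
    for name in atlas.names:
        for x, y, z in atlas.regions[name]:
            rows.append({"region": name, "x": x, "y": y, "z": z})
    pd.DataFrame(rows, columns=["region", "x", "y", "z"]).to_csv(Path(path), index=False)


def load_atlas(path: str | Path) -> AtlasRegions:
    df = pd.read_csv(Path(path))
    regions = {
        str(name): grp[["x", "y", "z"]].to_numpy(dtype=float)
        for name, grp in df.groupby("region", sort=True)
    }
    return AtlasRegions(regions=regions)
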