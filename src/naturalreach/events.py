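"""Movement-initiation event detection and pruning.

Onsets are rest-to-move transitions with at least 0.5 s of contiguous rest
before and at least 0.5 s of contiguous move after.  Detected events are
annotated with kinematics (reach magnitude, angle, onset speed), tracking
confidence, and the quadratic-fit R² of the radial trace, then pruned:
duration in [0.5, 4] s, mean confidence > 0.4, quadratic R² > 0.6, and at
most the 200 highest-onset-speed events per day (ties broken by earlier
onset).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .hsmm import MOVE, REST, StateSequence, WristTrajectory

ONSET_WINDOW_S = 0.5
DURATION_RANGE_S = (0.5, 4.0)  # closed interval
MIN_CONFIDENCE = 0.4
MIN_QUAD_R2 = 0.6
PER_DAY_CAP = 200


@dataclass
class MovementEvent:
    onset_frame: int
    onset_time: float  # s from start of the trajectory
    day: int = 0
    clock_time: float = 0.0  # s-of-day at onset
    duration: float = np.nan  # s, length of the move dwell
    reach_magnitude: float = np.nan  # pixels
    reach_angle_raw: float = np.nan  # degrees in [0, 360)
    reach_angle: float = np.nan  # degrees in [-90, 90]
    onset_speed: float = np.nan  # pixels / s
    mean_confidence: float = np.nan
    quad_r2: float = np.nan
    kept: bool = True
    rejection_reason: str = ""
    move_dwell: tuple[int, int] = field(default=(0, 0))  # [start, end) frames


def _dwell_bounds(labels: np.ndarray, onset: int) -> tuple[int, int]:
    """[start, end) of the move dwell containing ``onset``."""
    end = onset
    n = len(labels)
    while end < n and labels[end] == MOVE:
        end += 1
    return onset, end


def detect_onsets(states: StateSequence, frame_rate: Optional[float] = None) -> list[MovementEvent]:
    """Find movement-initiation events in a labelled state sequence.

    An onset is a rest→move transition preceded by >= 0.5 s of contiguous rest
    and followed by >= 0.5 s of contiguous move.  Event duration is the full
    length of the move dwell containing the onset.
    """
    fps = frame_rate if frame_rate is not None else states.frame_rate
    w = fps * ONSET_WINDOW_S
    if abs(w - round(w)) > 1e-9:
        raise ValueError(f"frame rate {fps} does not give an integral 0.5 s window")
    w = int(round(w))
    labels = states.labels
    n = len(labels)
    events: list[MovementEvent] = []
    transitions = np.flatnonzero((labels[1:] == MOVE) & (labels[:-1] == REST)) + 1
    for t in transitions:
        if t - w < 0 or t + w > n:
            continue
        if np.all(labels[t - w : t] == REST) and np.all(labels[t : t + w] == MOVE):
            start, end = _dwell_bounds(labels, t)
            events.append(
                MovementEvent(
                    onset_frame=int(t),
                    onset_time=t / fps,
                    duration=(end - start) / fps,
                    move_dwell=(start, end),
                )
            )
    return events


def quad_fit_r2(trajectory: WristTrajectory, event: MovementEvent) -> float:
    """R² of a degree-2 polynomial fit to radial displacement over the move dwell.

    Radial displacement is measured from the wrist position at onset.  A
    constant trace fits exactly (R² = 1 by convention for zero total variance
    with zero residual).
    """
    start, end = event.move_dwell
    if end - start < 3:
        raise ValueError("move dwell shorter than 3 frames: quadratic fit undefined")
    pos = trajectory.positions[start:end]
    radial = np.linalg.norm(pos - pos[0], axis=1)
    t = np.arange(end - start) / trajectory.frame_rate
    coef = np.polynomial.polynomial.polyfit(t, radial, 2)
    fit = np.polynomial.polynomial.polyval(t, coef)
    ss_res = float(np.sum((radial - fit) ** 2))
    ss_tot = float(np.sum((radial - radial.mean()) ** 2))
    if ss_tot < 1e-12:
        return 1.0 if ss_res < 1e-9 else 0.0
    return 1.0 - ss_res / ss_tot


def annotate_events(
    events: Sequence[MovementEvent],
    trajectory: WristTrajectory,
    day: int = 0,
    day_start_clock: float = 0.0,
) -> list[MovementEvent]:
    """Fill kinematic and context annotations on detected events, in place.

    reach_magnitude: maximum radial displacement from the onset position over
    the move dwell.  reach_angle_raw: direction (degrees CCW from screen
    right, up = +90 under the y-down pixel convention) of the displacement at
    maximum radial excursion.  onset_speed: mean radial speed over the first
    0.5 s of the move dwell.  mean_confidence: mean keypoint confidence over
    the move dwell.
    """
    fps = trajectory.frame_rate
    w = int(round(fps * ONSET_WINDOW_S))
    for ev in events:
        start, end = ev.move_dwell
        pos = trajectory.positions[start:end]
        rel = pos - pos[0]
        radial = np.linalg.norm(rel, axis=1)
        imax = int(np.argmax(radial))
        ev.reach_magnitude = float(radial[imax])
        dx, dy = rel[imax]
        ev.reach_angle_raw = float(np.degrees(np.arctan2(-dy, dx)) % 360.0)
        from .features import transform_angle  # local import avoids cycle

        ev.reach_angle = transform_angle(ev.reach_angle_raw)
        head = radial[: w + 1]
        if len(head) >= 2:
            ev.onset_speed = float(np.mean(np.abs(np.diff(head))) * fps)
        else:
            ev.onset_speed = 0.0
        ev.mean_confidence = float(np.mean(trajectory.confidence[start:end]))
        try:
            ev.quad_r2 = quad_fit_r2(trajectory, ev)
        except ValueError:
            ev.quad_r2 = np.nan
        ev.day = day
        ev.clock_time = day_start_clock + ev.onset_time
    return list(events)


def apply_exclusions(
    events: Sequence[MovementEvent], exclusion_intervals: Sequence[tuple[float, float]]
) -> list[MovementEvent]:
    """Mark events whose onset falls inside a user-supplied exclusion interval."""
    out = []
    for ev in events:
        for a, b in exclusion_intervals:
            if a <= ev.onset_time < b:
                ev.kept = False
                ev.rejection_reason = "excluded_interval"
                break
        out.append(ev)
    return out


def prune_events(
    events: Sequence[MovementEvent],
    per_day_cap: int = PER_DAY_CAP,
    duration_range: tuple[float, float] = DURATION_RANGE_S,
    min_confidence: float = MIN_CONFIDENCE,
    min_quad_r2: float = MIN_QUAD_R2,
) -> list[MovementEvent]:
    """Apply the rule-based filters, then the per-day onset-speed cap.

    Keeps an event iff duration in the closed interval ``duration_range`` AND
    mean confidence > ``min_confidence`` AND quadratic R² > ``min_quad_r2``;
    then within each day keeps at most ``per_day_cap`` events with the highest
    onset speeds (ties broken by earlier onset time).  Rejection reasons are
    recorded; the operation is idempotent.
    """
    lo, hi = duration_range
    out = list(events)
    for ev in out:
        if not ev.kept and ev.rejection_reason == "excluded_interval":
            continue
        ev.kept = True
        ev.rejection_reason = ""
        if not (lo <= ev.duration <= hi):
            ev.kept, ev.rejection_reason = False, "duration"
        elif not (np.isfinite(ev.mean_confidence) and ev.mean_confidence > min_confidence):
            ev.kept, ev.rejection_reason = False, "confidence"
        elif not (np.isfinite(ev.quad_r2) and ev.quad_r2 > min_quad_r2):
            ev.kept, ev.rejection_reason = False, "quad_r2"

    days = sorted({ev.day for ev in out})
    for day in days:
        day_events = [ev for ev in out if ev.day == day and ev.kept]
        if len(day_events) > per_day_cap:
            ranked = sorted(day_events, key=lambda e: (-e.onset_speed, e.onset_time))
            for ev in ranked[per_day_cap:]:
                ev.kept, ev.rejection_reason = False, "per_day_cap"
    return out
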