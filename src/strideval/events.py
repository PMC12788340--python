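"""Gait-event detection and stride spatiotemporal metrics.

Foot strike and toe-off are identified from vertical ground-reaction-force
traces using a force threshold (50 N by default, the standard choice for
instrumented runways), strides are segmented between consecutive ipsilateral
foot strikes, and stride length is measured as the horizontal-plane
displacement of a foot-mounted reference marker between those strikes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GaitEvent",
    "StrideMetrics",
    "ZoneEvents",
    "TrajectoryGapError",
    "detect_foot_contacts",
    "segment_strides",
    "stride_length",
    "stride_cadence",
    "stride_metrics_table",
    "zone_crossings",
]

FOOT_STRIKE = "foot_strike"
TOE_OFF = "toe_off"


class TrajectoryGapError(ValueError):
    """A marker trajectory is missing at a frame needed for a measurement."""


@dataclass(frozen=True)
class GaitEvent:
    """A timestamped foot-strike or toe-off on one foot."""

    time: float
    foot: str
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in (FOOT_STRIKE, TOE_OFF):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.foot not in ("left", "right"):
            raise ValueError(f"unknown foot {self.foot!r}")


@dataclass(frozen=True)
class StrideMetrics:
    """One stride: duration (s), length (m) and cadence (strides/min)."""

    foot: str
    start_time: float
    duration: float
    length: float
    cadence: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("stride duration must be positive")
        if self.length <= 0:
            raise ValueError("stride length must be positive")
        if abs(self.cadence * self.duration - 60.0) > 1e-9 * 60.0:
            raise ValueError("cadence inconsistent with duration")

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration


@dataclass(frozen=True)
class ZoneEvents:
    """Mocap frame indices at which the runner enters and exits the fly zone."""

    entry_frame: int
    exit_frame: int

    def __post_init__(self) -> None:
        if self.exit_frame <= self.entry_frame:
            raise ValueError("exit_frame must exceed entry_frame")


def _check_uniform(time: np.ndarray) -> float:
    dt = np.diff(time)
    if len(dt) == 0:
        raise ValueError("need at least two samples")
    if not np.all(dt > 0):
        raise ValueError("time must be strictly increasing")
    period = float(np.median(dt))
    if np.max(np.abs(dt - period)) > 1e-6 * period:
        raise ValueError("non-uniform sampling")
    return period


def detect_foot_contacts(
    time: np.ndarray,
    force: np.ndarray,
    foot: str,
    threshold: float = 50.0,
    min_contact: float = 0.02,
) -> list[GaitEvent]:
    """Detect foot-strike/toe-off events from one foot's vertical GRF trace.

    A foot strike is the first sample at or above ``threshold`` following a
    sustained (>= ``min_contact``) sub-threshold interval; the matching
    toe-off is the first subsequent sample below ``threshold`` that stays
    below it for at least ``min_contact``.  Shorter excursions on either side
    are treated as threshold chatter and merged into the surrounding state.
    """
    time = np.asarray(time, dtype=float)
    force = np.asarray(force, dtype=float)
    if time.shape != force.shape:
        raise ValueError("time and force must have equal length")
    dt = _check_uniform(time)
    debounce = max(1, int(round(min_contact / dt)))

    above = force >= threshold
    if not above.any():
        return []

    # Run-length encode, then merge runs shorter than the debounce window
    # into the preceding state (the first and last runs are kept whole).
    change = np.flatnonzero(np.diff(above.astype(np.int8))) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(above)]))
    runs: list[list[int]] = []  # [state, start, end]
    for s, e in zip(starts, ends):
        state = int(above[s])
        if runs and 0 < s and e - s < debounce and e != len(above):
            runs[-1][2] = e  # chatter: absorb into previous run
            continue
        if runs and runs[-1][0] == state:
            runs[-1][2] = e
        else:
            runs.append([state, s, e])
    # Merging may have created adjacent same-state runs; coalesce.
    merged: list[list[int]] = []
    for state, s, e in runs:
        if merged and merged[-1][0] == state:
            merged[-1][2] = e
        else:
            merged.append([state, s, e])

    events: list[GaitEvent] = []
    for state, s, e in merged:
        if state == 1 and s > 0:
            events.append(GaitEvent(float(time[s]), foot, FOOT_STRIKE))
        elif state == 0 and s > 0:
            events.append(GaitEvent(float(time[s]), foot, TOE_OFF))
    return events


def segment_strides(
    events: Sequence[GaitEvent], foot: str
) -> list[tuple[GaitEvent, GaitEvent]]:
    """Pair consecutive ipsilateral foot strikes into strides."""
    _check_alternation(events)
    strikes = [e for e in events if e.foot == foot and e.kind == FOOT_STRIKE]
    return [(a, b) for a, b in zip(strikes, strikes[1:])]


def _check_alternation(events: Sequence[GaitEvent]) -> None:
    for foot in ("left", "right"):
        kinds = [e.kind for e in sorted(events, key=lambda e: e.time) if e.foot == foot]
        for a, b in zip(kinds, kinds[1:]):
            if a == b:
                raise ValueError(f"events on {foot} foot do not alternate")


def stride_length(
    device_marker_traj: pd.DataFrame,
    stride: tuple[GaitEvent, GaitEvent],
    rate: float = 100.0,
) -> float:
    """Horizontal-plane displacement of the foot marker between the stride's
    two foot strikes.

    ``device_marker_traj`` needs columns ``frame``, ``x`` and ``y``; each
    event time is mapped to the nearest mocap frame.  Raises
    :class:`TrajectoryGapError` if the marker is missing at either frame.
    """
    start, end = stride
    frames = device_marker_traj["frame"].to_numpy()
    pos = device_marker_traj[["x", "y"]].to_numpy(dtype=float)
    out = []
    for ev in (start, end):
        idx = int(round(ev.time * rate))
        where = np.flatnonzero(frames == idx)
        if len(where) == 0:
            raise TrajectoryGapError(f"no frame {idx} in trajectory")
        p = pos[where[0]]
        if not np.all(np.isfinite(p)):
            raise TrajectoryGapError(f"marker missing at frame {idx}")
        out.append(p)
    return float(np.hypot(*(out[1] - out[0])))


def stride_cadence(duration: float) -> float:
    """Strides per minute for one stride of the given duration (s)."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return 60.0 / duration


def stride_metrics_table(
    events: Sequence[GaitEvent],
    marker_trajs: dict[str, pd.DataFrame],
    rate: float = 100.0,
) -> list[StrideMetrics]:
    """Build stride metrics for both feet from events and per-foot foot-marker
    trajectories; strides whose marker is missing at a strike frame are
    dropped."""
    out: list[StrideMetrics] = []
    for foot in ("left", "right"):
        for start, end in segment_strides(events, foot):
            dur = end.time - start.time
            try:
                length = stride_length(marker_trajs[foot], (start, end), rate)
            except TrajectoryGapError:
                continue
            if length <= 0:
                continue
            out.append(
                StrideMetrics(foot, start.time, dur, length, stride_cadence(dur))
            )
    return sorted(out, key=lambda s: s.start_time)


def zone_crossings(
    toe_marker_trajs: Sequence[np.ndarray],
    zone_start: float,
    zone_end: float,
) -> ZoneEvents:
    """Entry/exit frames of the capture zone.

    Entry is the first frame at which the leading (most forward) toe marker
    reaches ``zone_start``; exit is the first frame at which the trailing
    (least forward) toe marker reaches ``zone_end``.
    """
    xs = np.vstack([np.asarray(t, dtype=float) for t in toe_marker_trajs])
    leading = np.nanmax(xs, axis=0)
    trailing = np.nanmin(xs, axis=0)
    if leading[0] >= zone_end:
        raise ValueError("trajectories start beyond the zone")
    entry_candidates = np.flatnonzero(leading >= zone_start)
    exit_candidates = np.flatnonzero(trailing >= zone_end)
    if len(entry_candidates) == 0 or len(exit_candidates) == 0:
        raise ValueError("zone never fully traversed")
    entry = int(entry_candidates[0])
    exit_ = int(exit_candidates[0])
    if exit_ <= entry:
        raise ValueError("zone never fully traversed")
    return ZoneEvents(entry, exit_)
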