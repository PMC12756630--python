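"""Trajectory linking, intensity traces, and exocytosis event calling.

Detections are linked frame to frame by mutual-nearest-neighbor matching
within a distance gate — deliberately simple Lagrangian tracking, since the
vesicles of interest are docked and nearly stationary.  When no significant
motion is detected across the stack, positions from the first frame are used
for every frame (static mode) and intensities are read out at those fixed
anchors.

Each particle's fluorescence trace is the mean of the anchor pixel and its
four 4-connected neighbors.  An exocytosis event is the signature rise in
fluorescence followed by complete, abrupt signal loss: the trace exceeds
``rise_factor`` times its local baseline, then falls below ``loss_factor``
times baseline and stays there for at least ``persistence`` frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .preprocessing import ImageStack

__all__ = [
    "EventParams",
    "Trajectory",
    "IntensityTrace",
    "ExocytosisEvent",
    "link_trajectories",
    "decide_motion_mode",
    "trace_intensity",
    "detect_exocytosis",
    "summarize",
    "analyze_stack",
]


@dataclass(frozen=True)
class EventParams:
    """Thresholds parameterizing the qualitative exocytosis signature.

    Defaults assume ~20 fps acquisition: a 0.5 s baseline window, a 40%
    fluorescence rise, loss below 25% of baseline persisting for 0.25 s.
    """

    baseline_window: int = 10
    rise_factor: float = 1.4
    loss_factor: float = 0.25
    persistence: int = 5
    max_link_distance: float = 3.0
    motion_threshold: float = 1.0

    def __post_init__(self) -> None:
        if not (self.rise_factor > 1 > self.loss_factor > 0):
            raise ValueError("need rise_factor > 1 > loss_factor > 0")
        if self.persistence < 1:
            raise ValueError("persistence must be >= 1")
        if self.baseline_window < 1:
            raise ValueError("baseline_window must be >= 1")


@dataclass
class Trajectory:
    track_id: int
    frames: list[int] = field(default_factory=list)
    positions: list[tuple[int, int]] = field(default_factory=list)  # (y, x)

    def append(self, frame: int, y: int, x: int) -> None:
        if self.frames and frame <= self.frames[-1]:
            raise ValueError("frames must be strictly increasing in a track")
        self.frames.append(frame)
        self.positions.append((int(y), int(x)))

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class IntensityTrace:
    track_id: int
    start_frame: int
    values: np.ndarray
    policy: str = "tracked"  # or "static_first_frame"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1)


@dataclass(frozen=True)
class ExocytosisEvent:
    track_id: int
    onset_frame: int
    peak_frame: int
    loss_frame: int
    baseline: float
    peak_over_baseline: float


def link_trajectories(per_frame: list, params: EventParams | None = None
                      ) -> list[Trajectory]:
    """Greedy mutual-nearest-neighbor linking across consecutive frames.

    A detection in frame t+1 continues a track from frame t only when the
    two are each other's nearest candidate and lie within
    ``max_link_distance``; every unmatched detection starts a new track.
    Every detection ends up in exactly one track.
    """
    params = params or EventParams()
    tracks: list[Trajectory] = []
    open_tracks: dict[int, Trajectory] = {}  # index in prev frame -> track
    next_id = 0
    prev_pos: np.ndarray | None = None

    for ps in per_frame:
        pos = np.asarray(ps.positions, dtype=float).reshape(-1, 2)
        assigned: dict[int, Trajectory] = {}
        matched_curr: set[int] = set()
        if prev_pos is not None and len(prev_pos) and len(pos):
            d = cdist(prev_pos, pos)
            nearest_curr = d.argmin(axis=1)
            nearest_prev = d.argmin(axis=0)
            for i in range(len(prev_pos)):
                j = int(nearest_curr[i])
                if int(nearest_prev[j]) == i \
                        and d[i, j] <= params.max_link_distance \
                        and i in open_tracks:
                    tr = open_tracks[i]
                    tr.append(ps.frame_index, *ps.positions[j])
                    assigned[j] = tr
                    matched_curr.add(j)
        for j in range(len(pos)):
            if j not in matched_curr:
                tr = Trajectory(next_id)
                next_id += 1
                tr.append(ps.frame_index, *ps.positions[j])
                tracks.append(tr)
                assigned[j] = tr
        open_tracks = assigned
        prev_pos = pos
    return tracks


def decide_motion_mode(tracks: list[Trajectory],
                       motion_threshold: float = 1.0) -> str:
    """Pick ``static_first_frame`` when the median frame-to-frame
    displacement over all tracks is below ``motion_threshold`` pixels."""
    if not tracks:
        raise ValueError("no tracks to analyze")
    steps: list[float] = []
    for tr in tracks:
        p = np.asarray(tr.positions, dtype=float)
        if len(p) >= 2:
            steps.extend(np.hypot(*(np.diff(p, axis=0).T)))
    if not steps:
        return "static_first_frame"  # only singleton tracks: nothing moved
    return ("static_first_frame"
            if float(np.median(steps)) < motion_threshold else "tracked")


def _five_point_mean(frame: np.ndarray, y: int, x: int) -> float:
    h, w = frame.shape
    vals = [frame[y, x]]
    for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        ny, nx = y + dy, x + dx
        if 0 <= ny < h and 0 <= nx < w:
            vals.append(frame[ny, nx])
    return float(np.mean(vals))


def trace_intensity(
    stack: ImageStack | np.ndarray,
    anchor,
    policy: str = "static_first_frame",
    track_id: int = 0,
    start_frame: int = 0,
) -> IntensityTrace:
    """Five-point intensity trace at a fixed or per-frame anchor.

    ``trace[t]`` is the mean of the pixel at the anchor and its 4-connected
    neighbors.  ``anchor`` is a single ``(y, x)`` for the static policy, or
    a sequence of per-frame ``(y, x)`` for tracked anchors.  Anchors on the
    image border average over the in-bounds subset and are flagged with a
    warning.
    """
    if not isinstance(stack, ImageStack):
        stack = ImageStack(stack)
    data = stack.data[start_frame:] if policy == "static_first_frame" \
        else stack.data
    if policy == "static_first_frame":
        y, x = int(anchor[0]), int(anchor[1])
        anchors = [(y, x)] * len(data)
    else:
        anchors = [(int(a[0]), int(a[1])) for a in anchor]
        data = stack.data[start_frame:start_frame + len(anchors)]
        if len(anchors) != len(data):
            raise ValueError("per-frame anchors must cover the trace span")
    h, w = stack.frame_shape
    values = []
    for frame, (y, x) in zip(data, anchors):
        if not (0 <= y < h and 0 <= x < w):
            raise ValueError(f"anchor ({y}, {x}) outside frame {h}×{w}")
        if y in (0, h - 1) or x in (0, w - 1):
            warnings.warn(
                f"anchor ({y}, {x}) on the image border; averaging over the "
                "in-bounds neighbors only",
                stacklevel=2,
            )
        values.append(_five_point_mean(frame, y, x))
    return IntensityTrace(track_id, start_frame, np.array(values), policy)


def detect_exocytosis(trace: IntensityTrace,
                      params: EventParams | None = None
                      ) -> list[ExocytosisEvent]:
    """Call rise-then-abrupt-loss events on one intensity trace.

    Scanning left to right: at each frame the baseline is the median of the
    preceding ``baseline_window`` values (median, so an in-progress rise does
    not inflate it).  An onset is the first frame exceeding
    ``rise_factor * baseline``; the event is confirmed when the trace later
    drops below ``loss_factor * baseline`` and stays below for
    ``persistence`` consecutive frames.  A rise that never loses signal
    (a docked, non-fusing granule) is not an event.
    """
    params = params or EventParams()
    v = trace.values
    n = len(v)
    if n <= params.baseline_window + params.persistence:
        warnings.warn("trace shorter than baseline + persistence windows; "
                      "no events callable", stacklevel=2)
        return []
    events: list[ExocytosisEvent] = []
    t = params.baseline_window
    while t < n:
        baseline = float(np.median(v[t - params.baseline_window:t]))
        if baseline > 0 and v[t] > params.rise_factor * baseline:
            onset = t
            loss_level = params.loss_factor * baseline
            loss = None
            for u in range(onset + 1, n - params.persistence + 1):
                if np.all(v[u:u + params.persistence] < loss_level):
                    loss = u
                    break
            if loss is None:
                break  # rise without abrupt loss: not exocytosis
            peak = onset + int(np.argmax(v[onset:loss]))
            events.append(
                ExocytosisEvent(
                    track_id=trace.track_id,
                    onset_frame=trace.start_frame + onset,
                    peak_frame=trace.start_frame + peak,
                    loss_frame=trace.start_frame + loss,
                    baseline=baseline,
                    peak_over_baseline=float(v[peak] / baseline),
                )
            )
            t = loss + params.persistence
        else:
            t += 1
    return events


def summarize(values) -> tuple[float, float]:
    """Mean and standard error of the mean (sd/sqrt(n)); needs n >= 2."""
    values = np.asarray(values, dtype=float).reshape(-1)
    if len(values) < 2:
        raise ValueError("sem undefined for fewer than 2 values")
    return float(values.mean()), float(values.std(ddof=1) / np.sqrt(len(values)))


def analyze_stack(
    stack: ImageStack | np.ndarray,
    det=None,
    morph=None,
    grid=None,
    params: EventParams | None = None,
):
    """Detect, track, trace and call events for a whole stack.

    Returns a dict with per-frame ``particles``, ``tracks``, the chosen
    ``mode``, per-anchor ``traces`` and the called ``events``.  In static
    mode the anchors are the first frame's detections; in tracked mode each
    track is traced along its own positions.
    """
    from .detection import detect_particles  # local import avoids a cycle

    if not isinstance(stack, ImageStack):
        stack = ImageStack(stack)
    params = params or EventParams()
    particles = detect_particles(stack, det=det, morph=morph, grid=grid)
    tracks = link_trajectories(particles, params)
    mode = decide_motion_mode(tracks, params.motion_threshold) if tracks \
        else "static_first_frame"

    traces: list[IntensityTrace] = []
    if mode == "static_first_frame":
        first = particles[0]
        for i, (y, x) in enumerate(first.positions):
            traces.append(trace_intensity(stack, (y, x),
                                          policy="static_first_frame",
                                          track_id=i))
    else:
        for tr in tracks:
            traces.append(trace_intensity(stack, tr.positions,
                                          policy="tracked",
                                          track_id=tr.track_id,
                                          start_frame=tr.frames[0]))
    events = [e for trace in traces for e in detect_exocytosis(trace, params)]
    return {"particles": particles, "tracks": tracks, "mode": mode,
            "traces": traces, "events": events}
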