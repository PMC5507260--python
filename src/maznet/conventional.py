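"""Conventional spatial-learning metrics: errors, latency, travel distance,
per-hole dwell, and occupancy maps.

A hole "visit" is an entry event into the closed disk of radius
``hole_proximity_radius`` (default 40 px, about one mouse body length) around
a hole centroid: consecutive frames inside one disk count as a single visit.
Visits to non-target (dummy) holes are errors. Latency is the time from trial
start to the first entry into the target disk — a geometric proxy for
escape-box entry, which is not observable from positions alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from maznet.arena import ArenaSpec, hole_positions
from maznet.trajectory import Trajectory


@dataclass
class ConventionalFeatures:
    """Per-trial classical features.

    ``latency_s`` falls back to the trial duration with ``target_reached``
    False when the animal never enters the target disk.
    """

    n_errors: int
    latency_s: float
    target_reached: bool
    travel_distance_px: float
    time_near_hole: np.ndarray  # per-hole frame counts
    valid: bool = True


@dataclass
class OccupancyMap:
    """Spatial occupancy histogram over square blocks covering the arena.

    ``grid[iy, ix]`` is the fraction of frames falling in that block; frames
    outside the arena bounding box are excluded from the grid but still count
    in ``total_frames``, so rates sum to at most 1.
    """

    grid: np.ndarray
    block_px: float
    total_frames: int
    x_edges: np.ndarray = field(default=None)
    y_edges: np.ndarray = field(default=None)


def _inside_disks(traj: Trajectory, spec: ArenaSpec) -> np.ndarray:
    """(n_frames, n_holes) boolean: frame within the closed proximity disk of hole."""
    holes = hole_positions(spec)
    d = np.linalg.norm(traj.xy[:, None, :] - holes[None, :, :], axis=2)
    return d <= spec.hole_proximity_radius


def hole_visit_events(traj: Trajectory, spec: ArenaSpec) -> list[tuple[int, int, int]]:
    """Ordered list of hole visits as (hole index, enter frame, exit frame).

    A visit opens at the first frame inside a hole's proximity disk after
    being outside that disk, and closes at the last consecutive inside frame
    (``exit frame`` is the last frame still inside). With the default
    geometry the disks are disjoint, but overlapping disks are handled
    per-hole independently.
    """
    inside = _inside_disks(traj, spec)
    events: list[tuple[int, int, int]] = []
    for h in range(spec.n_holes):
        col = inside[:, h]
        # run-length encode entries
        prev = np.concatenate([[False], col[:-1]])
        enters = np.nonzero(col & ~prev)[0]
        nxt = np.concatenate([col[1:], [False]])
        exits = np.nonzero(col & ~nxt)[0]
        for e, x in zip(enters, exits):
            events.append((h, int(e), int(x)))
    events.sort(key=lambda ev: (ev[1], ev[0]))
    return events


def count_errors(traj: Trajectory, spec: ArenaSpec) -> int:
    """Number of visits to dummy (non-target) holes over the whole trial."""
    return sum(1 for h, _, _ in hole_visit_events(traj, spec) if h != spec.target_index)


def latency_to_target(traj: Trajectory, spec: ArenaSpec) -> tuple[float, bool]:
    """Time (s) from trial start to first entry into the target disk.

    Returns ``(latency, reached)``; when the target disk is never entered the
    latency is the trial duration and ``reached`` is False.
    """
    inside = _inside_disks(traj, spec)[:, spec.target_index]
    idx = np.nonzero(inside)[0]
    if len(idx) == 0:
        return traj.duration, False
    return float(traj.t[idx[0]] - traj.t[0]), True


def travel_distance(traj: Trajectory) -> float:
    """Total path length: sum of frame-to-frame displacement norms."""
    if len(traj) < 2:
        raise ValueError("travel_distance requires at least 2 frames")
    return float(np.linalg.norm(np.diff(traj.xy, axis=0), axis=1).sum())


def time_near_holes(traj: Trajectory, spec: ArenaSpec) -> np.ndarray:
    """Per-hole count of frames spent within the hole's proximity disk."""
    return _inside_disks(traj, spec).sum(axis=0).astype(int)


def occupancy_map(traj: Trajectory, spec: ArenaSpec, block_px: float = 20.0) -> OccupancyMap:
    """Occupancy rate per square block of the arena bounding box."""
    if block_px <= 0:
        raise ValueError("block_px must be positive")
    cx, cy = spec.center
    r = spec.arena_radius
    nb = int(np.ceil(2 * r / block_px))
    x_edges = cx - r + block_px * np.arange(nb + 1)
    y_edges = cy - r + block_px * np.arange(nb + 1)
    h, _, _ = np.histogram2d(traj.xy[:, 1], traj.xy[:, 0], bins=[y_edges, x_edges])
    return OccupancyMap(
        grid=h / len(traj), block_px=block_px, total_frames=len(traj),
        x_edges=x_edges, y_edges=y_edges,
    )


def conventional_features(traj: Trajectory, spec: ArenaSpec) -> ConventionalFeatures:
    """All classical features of one trial."""
    if len(traj) < 2 or not traj.valid:
        return ConventionalFeatures(
            n_errors=0, latency_s=0.0, target_reached=False,
            travel_distance_px=0.0,
            time_near_hole=np.zeros(spec.n_holes, dtype=int), valid=False,
        )
    latency, reached = latency_to_target(traj, spec)
    return ConventionalFeatures(
        n_errors=count_errors(traj, spec),
        latency_s=latency,
        target_reached=reached,
        travel_distance_px=travel_distance(traj),
        time_near_hole=time_near_holes(traj, spec),
    )


def daily_average(
    table: pd.DataFrame,
    feature_cols: list[str] | None = None,
    subject_col: str = "subject_id",
    day_col: str = "day",
) -> pd.DataFrame:
    """Arithmetic mean of each feature across a subject's trials within a day.

    Mirrors the standard per-day averaging of the three training trials.
    Returns one row per (subject, day) with an ``n_trials`` count column.
    """
    if table.empty:
        raise ValueError("empty feature table")
    if feature_cols is None:
        feature_cols = [c for c in table.columns
                        if c not in (subject_col, day_col)
                        and pd.api.types.is_numeric_dtype(table[c])]
    grouped = table.groupby([subject_col, day_col], sort=True)
    out = grouped[feature_cols].mean()
    out["n_trials"] = grouped.size()
    return out.reset_index()
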