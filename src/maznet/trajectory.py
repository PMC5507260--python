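"""Trajectory containers and plain-text I/O for per-trial point sequences.

A trial is an ordered sequence of timestamped 2-D positions plus metadata
(subject, day, trial number, entry type, phase). Files are CSV/TSV with columns
``frame,x,y`` or ``t,x,y``; a manifest CSV lists the trial files of a whole
experiment together with their metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from maznet.arena import ArenaSpec, radius_of

ENTRY_TYPES = ("MANUAL", "LIFT")
PHASES = ("habituation", "training", "probe")


@dataclass
class Trajectory:
    """One trial's position sequence.

    Attributes
    ----------
    t : ndarray of float
        Frame timestamps in seconds, strictly increasing.
    xy : ndarray, shape (n_frames, 2)
        Position per frame in image pixels.
    subject_id, day, trial, entry, phase
        Trial metadata. ``entry`` is MANUAL or LIFT; ``phase`` is habituation,
        training or probe.
    n_dropped : int
        Number of non-finite input rows dropped while reading.
    valid : bool
        False when preprocessing produced an unusable trajectory (e.g. a LIFT
        trial that never left the lift scaffold).
    """

    t: np.ndarray
    xy: np.ndarray
    subject_id: str = "s0"
    day: int = 0
    trial: int = 1
    entry: str = "MANUAL"
    phase: str = "training"
    n_dropped: int = 0
    valid: bool = True

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if len(self.t) != len(self.xy):
            raise ValueError("t and xy length mismatch")
        if self.valid and len(self.t) >= 2 and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.entry not in ENTRY_TYPES:
            raise ValueError(f"entry must be one of {ENTRY_TYPES}")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Trial duration in seconds (0 for < 2 frames)."""
        return float(self.t[-1] - self.t[0]) if len(self.t) >= 2 else 0.0

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.subject_id, self.day, self.trial)

    def with_xy(self, xy: np.ndarray) -> "Trajectory":
        return replace(self, xy=np.asarray(xy, dtype=float))

    def slice(self, start: int, stop: int | None = None) -> "Trajectory":
        return replace(self, t=self.t[start:stop], xy=self.xy[start:stop])


@dataclass
class TrialSet:
    """A collection of trials sharing one arena configuration."""

    trials: list[Trajectory]
    spec: ArenaSpec

    def __post_init__(self) -> None:
        keys = [tr.key for tr in self.trials]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (subject, day, trial) keys in TrialSet")

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trials)

    def __len__(self) -> int:
        return len(self.trials)

    def manifest(self) -> pd.DataFrame:
        """Trial metadata table: one row per trial."""
        return pd.DataFrame(
            {
                "subject_id": [tr.subject_id for tr in self.trials],
                "day": [tr.day for tr in self.trials],
                "trial": [tr.trial for tr in self.trials],
                "entry": [tr.entry for tr in self.trials],
                "phase": [tr.phase for tr in self.trials],
                "n_frames": [len(tr) for tr in self.trials],
            }
        )


def read_points(
    path,
    frame_rate: float = 5.0,
    subject_id: str = "s0",
    day: int = 0,
    trial: int = 1,
    entry: str = "MANUAL",
    phase: str = "training",
    column_map: dict[str, str] | None = None,
    skip_initial_frames: int = 0,
) -> Trajectory:
    """Read a point-sequence file into a Trajectory.

    The file is CSV or TSV (sniffed), with or without a header, holding either
    ``frame,x,y`` (timestamps derived as frame_index / frame_rate) or
    ``t,x,y``. ``column_map`` can rename arbitrary headers onto
    {"frame"|"t", "x", "y"}. Rows with non-finite coordinates are dropped and
    counted in ``n_dropped``. ``skip_initial_frames`` discards that many frames
    from the front (per-trial override for corrupted trial starts).
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    has_header = not _is_numeric_row(first, sep)
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
    if not has_header:
        if df.shape[1] < 3:
            raise ValueError(f"{path}: need at least 3 columns (frame-or-time, x, y)")
        df.columns = ["frame", "x", "y"] + [f"extra{i}" for i in range(df.shape[1] - 3)]
    if column_map:
        df = df.rename(columns=column_map)
    df.columns = [str(c).strip().lower() for c in df.columns]

    if "t" in df.columns:
        t = df["t"].to_numpy(dtype=float)
    elif "frame" in df.columns:
        t = df["frame"].to_numpy(dtype=float) / frame_rate
    else:
        raise ValueError(f"{path}: no 'frame' or 't' column found")
    if "x" not in df.columns or "y" not in df.columns:
        raise ValueError(f"{path}: missing x/y columns")
    xy = df[["x", "y"]].to_numpy(dtype=float)

    ok = np.isfinite(t) & np.all(np.isfinite(xy), axis=1)
    n_dropped = int(np.sum(~ok))
    t, xy = t[ok], xy[ok]
    if skip_initial_frames:
        t, xy = t[skip_initial_frames:], xy[skip_initial_frames:]
    if len(t) < 2:
        raise ValueError(f"{path}: fewer than 2 valid rows")
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: non-monotone timestamps")
    return Trajectory(
        t=t, xy=xy, subject_id=subject_id, day=day, trial=trial,
        entry=entry, phase=phase, n_dropped=n_dropped,
    )


def _is_numeric_row(line: str, sep: str) -> bool:
    parts = [p.strip() for p in line.strip().split(sep)]
    if len(parts) < 3:
        return False
    try:
        for p in parts[:3]:
            float(p)
        return True
    except ValueError:
        return False


def write_points(traj: Trajectory, path) -> None:
    """Write a trajectory as a ``t,x,y`` CSV (readable by :func:`read_points`)."""
    df = pd.DataFrame({"t": traj.t, "x": traj.xy[:, 0], "y": traj.xy[:, 1]})
    df.to_csv(path, index=False, float_format="%.6f")


def write_trialset(ts: TrialSet, out_dir) -> Path:
    """Write every trial as a CSV plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for tr in ts.trials:
        fname = f"{tr.subject_id}_d{tr.day}_t{tr.trial}.csv"
        write_points(tr, out_dir / fname)
        rows.append({
            "file": fname, "subject_id": tr.subject_id, "day": tr.day,
            "trial": tr.trial, "entry": tr.entry, "phase": tr.phase,
        })
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_trialset(manifest_path, spec: ArenaSpec) -> TrialSet:
    """Read a manifest CSV and all trial files it lists."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    trials = []
    for _, row in df.iterrows():
        trials.append(read_points(
            manifest_path.parent / row["file"],
            frame_rate=spec.frame_rate,
            subject_id=str(row["subject_id"]), day=int(row["day"]),
            trial=int(row["trial"]), entry=str(row["entry"]),
            phase=str(row.get("phase", "training")),
        ))
    return TrialSet(trials=trials, spec=spec)


DEFAULT_LIFT_TRIM_THRESHOLD = 38.0
"""Default start-trim radius (px) for LIFT trials.

The trim threshold is defined as the mean initial distance from the center in
MANUAL-entry trials; with the MANUAL start positions spread over a ~15.25 cm
diameter this is about 38 px at 5 px/cm. Compute it from your own MANUAL data
with :func:`manual_start_radius` when available.
"""


def manual_start_radius(trials: Iterable[Trajectory], spec: ArenaSpec) -> float:
    """Mean first-frame distance from center over MANUAL trials (the trim threshold)."""
    rs = [float(radius_of(tr.xy[:1], spec)[0]) for tr in trials if tr.entry == "MANUAL"]
    if not rs:
        raise ValueError("no MANUAL trials supplied")
    return float(np.mean(rs))


def trim_lift_start(
    traj: Trajectory,
    spec: ArenaSpec,
    distance_threshold: float = DEFAULT_LIFT_TRIM_THRESHOLD,
) -> Trajectory:
    """Discard all frames before a LIFT trial first leaves the lift scaffold.

    Returns the suffix of the trajectory starting at the first frame whose
    distance from the arena center exceeds ``distance_threshold``. This removes
    micromovements on the lift platform that would otherwise inflate the random
    strategy. If the threshold is never exceeded, an empty trajectory flagged
    invalid is returned. Applied to a MANUAL trial it is a no-op with a warning.
    """
    if traj.entry != "LIFT":
        warnings.warn("trim_lift_start applied to non-LIFT trial; returning unchanged",
                      stacklevel=2)
        return traj
    r = radius_of(traj.xy, spec)
    idx = np.nonzero(r > distance_threshold)[0]
    if len(idx) == 0:
        out = traj.slice(len(traj))
        out.valid = False
        return out
    return traj.slice(int(idx[0]))
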