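"""Circular arena geometry: hole ring, quadrants, and the canonical coordinate frame.

Every downstream stage (conventional metrics, strategy labels, networks) works in
a canonical frame in which the target hole sits at 45 degrees ("top right") from
the arena center. Coordinates follow the image convention of the acquisition
system: origin at the top-left of a nominally 500x500-pixel frame, x to the
right, y downward, 2 mm per pixel. Angles used here are measured in the
conventional mathematical sense (counterclockwise from the +x axis) *after*
flipping y, so that "counterclockwise" matches what an observer looking at the
arena from above would call counterclockwise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from maznet.trajectory import Trajectory

#: canonical angular position of the target hole, radians ("top right" diagonal)
TARGET_ANGLE = np.pi / 4.0


@dataclass(frozen=True)
class ArenaSpec:
    """Geometry, hole layout, thresholds and frame rate of one experiment.

    All lengths are in pixels (2 mm/pixel at the default scale); ``px_per_cm``
    is carried so reports can convert to centimetres.

    Parameters
    ----------
    center : tuple of float
        Arena center in image coordinates (pixels).
    arena_radius : float
        Radius of the circular table, default 245 px (~49 cm).
    n_holes : int
        Number of peripheral holes, default 12.
    hole_ring_radius : float
        Radius of the circle the hole centroids lie on, default 200 px (40 cm).
    hole_proximity_radius : float
        Radius of the disk around each hole centroid that counts as a visit
        (~one mouse body length), default 40 px.
    target_index : int
        Index of the hole with the escape box, 0..n_holes-1.
    px_per_cm : float
        Pixels per centimetre, default 5.
    frame_rate : float
        Acquisition rate in Hz, default 5.
    center_zone_radius : float
        Radius of the central zone used to detect quadrant crosses; defaults to
        0.25 * arena_radius when not given.
    stop_threshold : float
        Path length (px) below which a sliding window counts as stopping,
        default 20 px (~half a body length).
    stop_window : int
        Number of successive frames in the stop criterion window, default 5.
    cca_threshold : float
        Distance threshold (px) of the City Clustering Algorithm, default 20.
    """

    center: tuple[float, float] = (250.0, 250.0)
    arena_radius: float = 245.0
    n_holes: int = 12
    hole_ring_radius: float = 200.0
    hole_proximity_radius: float = 40.0
    target_index: int = 0
    px_per_cm: float = 5.0
    frame_rate: float = 5.0
    center_zone_radius: float | None = None
    stop_threshold: float = 20.0
    stop_window: int = 5
    cca_threshold: float = 20.0

    def __post_init__(self) -> None:
        if self.center_zone_radius is None:
            object.__setattr__(self, "center_zone_radius", 0.25 * self.arena_radius)
        if self.n_holes < 2:
            raise ValueError("n_holes must be >= 2")
        if not (0 <= self.target_index < self.n_holes):
            raise ValueError(f"target_index {self.target_index} out of range 0..{self.n_holes - 1}")
        for name in ("arena_radius", "hole_ring_radius", "hole_proximity_radius",
                     "center_zone_radius", "stop_threshold", "cca_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hole_ring_radius >= self.arena_radius:
            raise ValueError("hole_ring_radius must be smaller than arena_radius")
        if self.stop_window < 2:
            raise ValueError("stop_window must be >= 2 frames")

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_json(cls, path) -> "ArenaSpec":
        """Load an ArenaSpec from a JSON configuration file."""
        with open(path) as fh:
            data = json.load(fh)
        if "center" in data:
            data["center"] = tuple(data["center"])
        return cls(**data)

    def to_json(self, path) -> None:
        data = asdict(self)
        data["center"] = list(data["center"])
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2)

    def with_target(self, target_index: int) -> "ArenaSpec":
        return replace(self, target_index=target_index)


def _to_math(xy: np.ndarray, spec: ArenaSpec) -> np.ndarray:
    """Image coordinates -> center-origin coordinates with y up."""
    out = np.asarray(xy, dtype=float) - np.asarray(spec.center, dtype=float)
    out = np.atleast_2d(out).copy()
    out[:, 1] = -out[:, 1]
    return out


def _from_math(xy: np.ndarray, spec: ArenaSpec) -> np.ndarray:
    out = np.atleast_2d(np.asarray(xy, dtype=float)).copy()
    out[:, 1] = -out[:, 1]
    return out + np.asarray(spec.center, dtype=float)


def angle_of(points: np.ndarray, spec: ArenaSpec) -> np.ndarray:
    """Counterclockwise angle (radians, in [0, 2pi)) of points about the center."""
    p = _to_math(points, spec)
    return np.mod(np.arctan2(p[:, 1], p[:, 0]), 2 * np.pi)


def radius_of(points: np.ndarray, spec: ArenaSpec) -> np.ndarray:
    """Distance of points from the arena center."""
    p = _to_math(points, spec)
    return np.hypot(p[:, 0], p[:, 1])


def hole_positions(spec: ArenaSpec) -> np.ndarray:
    """Coordinates of the hole centroids in the canonical frame.

    Returns an ``(n_holes, 2)`` array in image coordinates. Hole 0 sits at the
    canonical target angle (45 degrees, top right); indices increase
    counterclockwise with equal angular spacing.
    """
    k = np.arange(spec.n_holes)
    theta = TARGET_ANGLE + 2 * np.pi * k / spec.n_holes
    pts = spec.hole_ring_radius * np.column_stack([np.cos(theta), np.sin(theta)])
    return _from_math(pts, spec)


def ring_point(spec: ArenaSpec, angle: float, radius: float) -> np.ndarray:
    """Image coordinates of the point at (angle, radius) about the center."""
    p = radius * np.array([[np.cos(angle), np.sin(angle)]])
    return _from_math(p, spec)[0]


def canonical_transform(traj: "Trajectory", spec: ArenaSpec) -> "Trajectory":
    """Rotate a trajectory about the arena center so its target hole lands at 45 deg.

    The recorded target hole (``spec.target_index`` on the physical layout,
    where hole 0 is at 45 degrees and indices increase counterclockwise) is
    mapped onto the canonical target position. A rigid rotation, so all
    distances from the center and all inter-frame distances are preserved.
    """
    if spec.target_index is None:
        raise ValueError("canonical_transform requires a target_index")
    # physical angle of the target hole; rotate it back to TARGET_ANGLE
    target_angle = TARGET_ANGLE + 2 * np.pi * spec.target_index / spec.n_holes
    rot = TARGET_ANGLE - target_angle
    c, s = np.cos(rot), np.sin(rot)
    R = np.array([[c, -s], [s, c]])
    xy = _to_math(traj.xy, spec)
    xy = xy @ R.T
    out = traj.with_xy(_from_math(xy, spec))
    return out


def canonicalize(traj: "Trajectory", spec: ArenaSpec) -> tuple["Trajectory", ArenaSpec]:
    """Rotate a trajectory into the canonical frame and re-index holes.

    Convenience wrapper around :func:`canonical_transform`: after the rotation
    the physical target hole occupies canonical hole slot 0 (at 45 degrees),
    so the returned spec carries ``target_index = 0``. Use the returned pair
    for all downstream analysis.
    """
    return canonical_transform(traj, spec), spec.with_target(0)


def quadrant_of(points: np.ndarray, spec: ArenaSpec, warn: bool = True) -> np.ndarray:
    """Quadrant id 0..3 of points in the canonical frame.

    Quadrant boundaries lie on the cardinal axes (0/90/180/270 degrees) so the
    canonical target at 45 degrees sits mid-quadrant in quadrant 0. A point
    exactly on a boundary is assigned to the counterclockwise quadrant, i.e.
    quadrant id = floor(angle / 90deg) mod 4. Points outside the arena are
    flagged with a warning and assigned by angle anyway.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    r = radius_of(pts, spec)
    if warn and np.any(r > spec.arena_radius):
        warnings.warn(
            f"{int(np.sum(r > spec.arena_radius))} point(s) outside arena; "
            "assigned to nearest quadrant by angle", stacklevel=2)
    theta = angle_of(pts, spec)
    q = np.floor(theta / (np.pi / 2)).astype(int) % 4
    return q if pts.shape[0] > 1 or np.ndim(points) > 1 else q
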