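"""Synthetic arena trajectories with controlled strategy archetype and stop structure.

The generator emulates a mouse exploring the circular arena at the nominal
5-Hz acquisition rate. Locomotion is a discrete-time correlated random walk:
each frame the animal takes a step of Gaussian-distributed length whose
heading blends the direction to the current waypoint with wrapped-normal
noise. Three waypoint policies realize the three strategy archetypes:

* ``spatial`` — straight from the arena center to the target hole;
* ``serial``  — out to a starting hole, then around the hole ring visiting
  ring-adjacent holes (clockwise or counterclockwise) until the target;
* ``random``  — a sequence of random waypoints, periodically routed through
  the arena center into a different quadrant so the trajectory accumulates
  center-zone quadrant crosses.

Stop episodes are realized as zero-mean positional jitter (sd =
stop_threshold / 8) around a fixed anchor for a geometric number of frames:
every trial begins with a brief start dwell, dwells at each visited hole, and
additional stops are injected along the way at ``stop_rate``. The arena edge
reflects; all points stay inside the arena.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from maznet.arena import ArenaSpec, hole_positions, radius_of
from maznet.trajectory import Trajectory, TrialSet

STRATEGY_TAGS = ("spatial", "serial", "random")


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulated trial.

    Speeds are in px/s (80 px/s = 16 cm/s, a typical exploring mouse);
    durations in frames at the arena frame rate; ``stop_rate`` in episodes/s.
    """

    strategy: str = "random"
    speed_mean: float = 80.0
    speed_sd: float = 20.0
    turn_sd: float = 0.25
    stop_rate: float = 0.08
    stop_duration: int = 8
    start_dwell: int = 6
    hole_dwell: int = 6
    serial_start_hole: int = 8
    serial_direction: str = "ccw"
    random_center_cross_rate: int = 4
    max_duration: float = 180.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGY_TAGS:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.speed_mean <= 0:
            raise ValueError("speed_mean must be positive")
        for name in ("speed_sd", "turn_sd", "stop_rate", "stop_duration",
                     "start_dwell", "hole_dwell", "max_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.serial_direction not in ("cw", "ccw"):
            raise ValueError("serial_direction must be 'cw' or 'ccw'")


class _Walker:
    """Stateful frame-by-frame walk generator on one arena."""

    def __init__(self, params: SimParams, spec: ArenaSpec, rng: np.random.Generator):
        self.p = params
        self.spec = spec
        self.rng = rng
        self.dt = 1.0 / spec.frame_rate
        self.pos = np.asarray(spec.center, dtype=float).copy()
        self.frames: list[np.ndarray] = [self.pos.copy()]
        self.max_frames = int(params.max_duration * spec.frame_rate)
        self.jitter_sd = spec.stop_threshold / 8.0

    @property
    def done(self) -> bool:
        return len(self.frames) >= self.max_frames

    def _push(self, pos: np.ndarray) -> None:
        # reflect at the arena edge, then clamp (large steps)
        c = np.asarray(self.spec.center)
        v = pos - c
        r = float(np.hypot(*v))
        R = self.spec.arena_radius
        if r > R:
            r_new = max(2 * R - r, 0.0)
            v = v * ((min(r_new, R) if r_new > 0 else 0.0) / r)
            pos = c + v
        self.pos = pos
        self.frames.append(pos.copy())

    def dwell(self, n_frames: int) -> None:
        """Jitter around the current position for n_frames."""
        anchor = self.pos.copy()
        for _ in range(n_frames):
            if self.done:
                return
            self._push(anchor + self.rng.normal(0.0, self.jitter_sd, size=2))

    def maybe_stop(self) -> None:
        if self.rng.random() < self.p.stop_rate * self.dt:
            n = 1 + self.rng.geometric(1.0 / max(self.p.stop_duration, 1))
            self.dwell(int(n))

    def walk_to(self, waypoint: np.ndarray, arrive_tol: float = 10.0,
                allow_stops: bool = True) -> bool:
        """Steer toward a waypoint; returns True when it was reached."""
        waypoint = np.asarray(waypoint, dtype=float)
        while not self.done:
            delta = waypoint - self.pos
            dist = float(np.hypot(*delta))
            if dist <= arrive_tol:
                return True
            heading = np.arctan2(delta[1], delta[0]) + self.rng.normal(0.0, self.p.turn_sd)
            step = max(self.rng.normal(self.p.speed_mean, self.p.speed_sd), 5.0) * self.dt
            step = min(step, dist)  # do not overshoot the waypoint
            self._push(self.pos + step * np.array([np.cos(heading), np.sin(heading)]))
            if allow_stops:
                self.maybe_stop()
        return False


def _hole_xy(spec: ArenaSpec, index: int) -> np.ndarray:
    return hole_positions(spec)[index % spec.n_holes]


def simulate_trial(params: SimParams, spec: ArenaSpec,
                   subject_id: str = "s0", day: int = 0, trial: int = 1,
                   entry: str = "LIFT", phase: str = "training") -> Trajectory:
    """Simulate one trial; identical seeds give identical frame sequences."""
    rng = np.random.default_rng(params.seed)
    w = _Walker(params, spec, rng)
    w.dwell(params.start_dwell)

    if params.strategy == "spatial":
        _simulate_spatial(w, params, spec)
    elif params.strategy == "serial":
        _simulate_serial(w, params, spec)
    else:
        _simulate_random(w, params, spec)

    xy = np.asarray(w.frames)
    t = np.arange(len(xy)) / spec.frame_rate
    return Trajectory(t=t, xy=xy, subject_id=subject_id, day=day, trial=trial,
                      entry=entry, phase=phase)


def _simulate_spatial(w: _Walker, p: SimParams, spec: ArenaSpec) -> None:
    # straight to the target, then dwell there (escape-box inspection)
    target = _hole_xy(spec, spec.target_index)
    w.walk_to(target, arrive_tol=spec.hole_proximity_radius / 2)
    w.dwell(p.hole_dwell)


def _simulate_serial(w: _Walker, p: SimParams, spec: ArenaSpec) -> None:
    step = 1 if p.serial_direction == "ccw" else -1
    h = p.serial_start_hole % spec.n_holes
    # out to the first hole, then ring-adjacent circuit until the target
    for _ in range(spec.n_holes + 1):
        w.walk_to(_hole_xy(spec, h), arrive_tol=spec.hole_proximity_radius / 2)
        w.dwell(p.hole_dwell)
        if h == spec.target_index or w.done:
            return
        h = (h + step) % spec.n_holes


def _simulate_random(w: _Walker, p: SimParams, spec: ArenaSpec) -> None:
    rng = w.rng
    c = np.asarray(spec.center, dtype=float)
    R = spec.arena_radius

    def random_point(quadrant: int | None = None) -> np.ndarray:
        # canonical quadrant q spans angles [q*90, (q+1)*90) degrees (y up)
        if quadrant is None:
            theta = rng.uniform(0, 2 * np.pi)
        else:
            theta = (quadrant + rng.uniform(0.05, 0.95)) * np.pi / 2
        r = rng.uniform(0.45, 0.9) * R
        return c + r * np.array([np.cos(theta), -np.sin(theta)])

    crossings = 0
    quad = int(rng.integers(4))
    while not w.done:
        if crossings < p.random_center_cross_rate:
            # guaranteed center traversal into a different quadrant
            w.walk_to(random_point(quad), arrive_tol=15.0)
            w.walk_to(c, arrive_tol=spec.center_zone_radius / 4)
            quad = int((quad + rng.integers(1, 4)) % 4)
            w.walk_to(random_point(quad), arrive_tol=15.0)
            crossings += 1
        else:
            w.walk_to(random_point(), arrive_tol=15.0)
        w.maybe_stop()


def default_learning_schedule() -> list[SimParams]:
    """A 6-day schedule emulating spatial learning across training.

    Early days are dominated by long random search, middle days by serial
    hole-ring sweeps that start closer to the target as days pass, and late
    days by direct spatial runs — the canonical random -> serial -> spatial
    progression of arena learning. One SimParams per day; per-trial seeds are
    filled in by :func:`simulate_cohort`.
    """
    return [
        SimParams(strategy="random", max_duration=180.0, random_center_cross_rate=6),
        SimParams(strategy="serial", serial_start_hole=6, stop_rate=0.15, hole_dwell=8),
        SimParams(strategy="serial", serial_start_hole=8),
        SimParams(strategy="serial", serial_start_hole=9, stop_rate=0.04),
        SimParams(strategy="spatial", speed_mean=60.0, turn_sd=0.35, stop_rate=0.5),
        SimParams(strategy="spatial", stop_rate=0.05),
    ]


def simulate_cohort(
    n_subjects: int,
    schedule: list[SimParams],
    spec: ArenaSpec,
    seed: int = 0,
    trials_per_day: int = 3,
    entry: str = "LIFT",
    subject_prefix: str = "m",
) -> TrialSet:
    """Simulate a cohort: ``n_subjects`` animals x days x ``trials_per_day`` trials.

    ``schedule`` holds one SimParams per day (its ``seed`` field is ignored);
    per-trial seeds are derived deterministically from the master seed, so a
    fixed master seed reproduces the cohort exactly.
    """
    if not schedule:
        raise ValueError("schedule must be non-empty")
    trials = []
    for s in range(n_subjects):
        sid = f"{subject_prefix}{s:02d}"
        for day, day_params in enumerate(schedule):
            for k in range(1, trials_per_day + 1):
                ss = np.random.SeedSequence(seed, spawn_key=(s, day, k))
                trial_seed = int(ss.generate_state(1)[0])
                params = replace(day_params, seed=trial_seed)
                trials.append(simulate_trial(
                    params, spec, subject_id=sid, day=day, trial=k, entry=entry,
                ))
    return TrialSet(trials=trials, spec=spec)
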