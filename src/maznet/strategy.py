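"""Rule-based search-strategy classification: spatial, serial, or random.

A trial is labeled *spatial* when the animal heads to the target without
crossing the arena center (0 quadrant crosses) and makes fewer than 3 errors;
*serial* when it sweeps neighboring holes in order (the visited-hole sequence
is ring-adjacent) with fewer than 3 quadrant crosses and is not spatial; and
*random* otherwise. A quadrant cross is a traversal of the central zone that
exits into a different quadrant than it entered from — perimeter runs cross
quadrant boundary rays constantly, so raw boundary crossings would not
separate serial from random search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from maznet.arena import ArenaSpec, quadrant_of, radius_of
from maznet.conventional import count_errors, hole_visit_events
from maznet.trajectory import Trajectory

STRATEGIES = ("spatial", "serial", "random")


@dataclass
class StrategyLabel:
    """A trial's strategy label plus the diagnostics that produced it."""

    label: str | None
    n_quadrant_crosses: int
    n_errors: int
    visit_sequence: list[int]
    sequential: bool
    valid: bool = True


def quadrant_cross_count(traj: Trajectory, spec: ArenaSpec) -> int:
    """Count center-zone traversals that exit into a different quadrant.

    The trajectory enters the central zone (disk of ``center_zone_radius``)
    from some quadrant and later exits into a quadrant; the excursion counts
    as a cross only when the two quadrants differ. A trajectory that starts
    inside the central zone has no entry quadrant, so its first exit never
    counts.
    """
    if len(traj) == 0:
        return 0
    r = radius_of(traj.xy, spec)
    in_center = r <= spec.center_zone_radius
    quad = quadrant_of(traj.xy, spec, warn=False)
    crosses = 0
    entry_quad: int | None = None  # quadrant we were in when we entered the center
    prev_in = in_center[0]
    for i in range(1, len(traj)):
        if in_center[i] and not prev_in:
            entry_quad = int(quad[i - 1])
        elif not in_center[i] and prev_in:
            if entry_quad is not None and int(quad[i]) != entry_quad:
                crosses += 1
            entry_quad = None
        prev_in = in_center[i]
    return crosses


def is_sequential(visit_sequence: list[int], n_holes: int, strict: bool = True) -> bool:
    """True when every consecutive pair of distinct visited holes is ring-adjacent.

    Consecutive duplicate visits are collapsed first. Adjacency is modular
    (hole n_holes-1 neighbors hole 0) and direction reversals are permitted.
    With ``strict=False`` a single skipped hole (difference of 2) is also
    tolerated. Sequences with fewer than 2 distinct consecutive visits are
    vacuously sequential.
    """
    seq = [h for i, h in enumerate(visit_sequence)
           if i == 0 or h != visit_sequence[i - 1]]
    max_gap = 1 if strict else 2
    for a, b in zip(seq[:-1], seq[1:]):
        d = abs(a - b) % n_holes
        d = min(d, n_holes - d)
        if d > max_gap:
            return False
    return True


def classify_trial(
    traj: Trajectory,
    spec: ArenaSpec,
    max_spatial_errors: int = 3,
    max_serial_crosses: int = 3,
    strict_sequential: bool = True,
) -> StrategyLabel:
    """Label one training trial spatial / serial / random.

    Decision rules, evaluated in order:

    * spatial — quadrant crosses == 0 and errors < ``max_spatial_errors``;
    * serial  — quadrant crosses < ``max_serial_crosses``, visited-hole
      sequence ring-adjacent, and not already spatial;
    * random  — everything else.

    Probe-phase trials and empty/invalid trajectories get ``label=None``.
    """
    if len(traj) == 0 or not traj.valid or traj.phase != "training":
        return StrategyLabel(None, 0, 0, [], False, valid=False)
    crosses = quadrant_cross_count(traj, spec)
    errors = count_errors(traj, spec)
    visits = [h for h, _, _ in hole_visit_events(traj, spec)]
    seq = is_sequential(visits, spec.n_holes, strict=strict_sequential)
    if crosses == 0 and errors < max_spatial_errors:
        label = "spatial"
    elif crosses < max_serial_crosses and seq:
        label = "serial"
    else:
        label = "random"
    return StrategyLabel(label, crosses, errors, visits, seq)


def daily_strategy_usage(
    labels: pd.DataFrame,
    subject_col: str = "subject_id",
    day_col: str = "day",
    label_col: str = "label",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate strategy usage per subject-day and group-level daily proportions.

    Parameters
    ----------
    labels : DataFrame
        One row per labeled trial with subject, day and label columns.

    Returns
    -------
    counts : DataFrame
        One row per (subject, day) with one count column per strategy.
    proportions : DataFrame
        One row per day; per-strategy fraction of that day's labeled trials
        (each day's proportions sum to 1).
    """
    df = labels.dropna(subset=[label_col])
    counts = (
        df.groupby([subject_col, day_col])[label_col]
        .value_counts().unstack(fill_value=0)
        .reindex(columns=list(STRATEGIES), fill_value=0)
        .reset_index()
    )
    day_tot = df.groupby(day_col)[label_col].value_counts().unstack(fill_value=0)
    day_tot = day_tot.reindex(columns=list(STRATEGIES), fill_value=0)
    proportions = day_tot.div(day_tot.sum(axis=1), axis=0).reset_index()
    return counts, proportions
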