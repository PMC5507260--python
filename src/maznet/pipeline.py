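"""End-to-end per-trial analysis: conventional metrics, strategy label, and
dynamic/static network features in one table.

This is the orchestration layer the CLI and batch scripts use: it applies the
canonical coordinate transform, the LIFT start-trim (strategy analysis only),
and produces one FeatureRecord row per trial plus the per-trial networks for
downstream global aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from maznet.arena import ArenaSpec, canonicalize
from maznet.conventional import conventional_features
from maznet.dynamic import build_local_network, detect_stops
from maznet.metrics import NetworkFeatures, feature_vector
from maznet.network import BehaviorNetwork
from maznet.static import StaticLayout, build_static_network, default_static_layout
from maznet.strategy import classify_trial
from maznet.trajectory import (
    DEFAULT_LIFT_TRIM_THRESHOLD,
    TrialSet,
    Trajectory,
    trim_lift_start,
)


@dataclass
class TrialResult:
    """Everything computed for one trial."""

    trajectory: Trajectory
    record: dict
    dynamic_net: BehaviorNetwork
    static_net: BehaviorNetwork


def analyze_trial(
    traj: Trajectory,
    spec: ArenaSpec,
    layout: StaticLayout | None = None,
    lift_trim_threshold: float = DEFAULT_LIFT_TRIM_THRESHOLD,
    canonical: bool = True,
) -> TrialResult:
    """Run the full per-trial analysis.

    The trajectory is rotated into the canonical frame (target at 45 degrees)
    unless ``canonical=False`` (for data already canonical). The LIFT
    start-trim is applied only for the strategy classification, mirroring its
    purpose of suppressing spurious random labels from lift-scaffold
    micromovements; conventional and network metrics use the full trajectory.
    """
    if canonical:
        traj, spec = canonicalize(traj, spec)
    if layout is None:
        layout = default_static_layout(spec)

    conv = conventional_features(traj, spec)

    strat_traj = traj
    if traj.entry == "LIFT":
        strat_traj = trim_lift_start(traj, spec, lift_trim_threshold)
    label = classify_trial(strat_traj, spec)

    stops = detect_stops(traj, spec)
    dyn_net = build_local_network(stops, spec)
    dyn_feats = feature_vector(dyn_net, n_stops=len(stops))

    stat_net = build_static_network(traj, layout)
    stat_feats = feature_vector(stat_net, n_stops=None)

    record = {
        "subject_id": traj.subject_id,
        "day": traj.day,
        "trial": traj.trial,
        "entry": traj.entry,
        "phase": traj.phase,
        "n_frames": len(traj),
        "n_errors": conv.n_errors,
        "latency_s": conv.latency_s,
        "target_reached": conv.target_reached,
        "travel_distance_px": conv.travel_distance_px,
        "time_near_target": int(conv.time_near_hole[spec.target_index]),
        "strategy": label.label,
        "n_quadrant_crosses": label.n_quadrant_crosses,
        "sequential": label.sequential,
    }
    for prefix, feats in (("dyn", dyn_feats), ("stat", stat_feats)):
        for name, value in feats.as_dict().items():
            record[f"{prefix}_{name}"] = value
    return TrialResult(trajectory=traj, record=record,
                       dynamic_net=dyn_net, static_net=stat_net)


def analyze_trialset(
    ts: TrialSet,
    layout: StaticLayout | None = None,
    lift_trim_threshold: float = DEFAULT_LIFT_TRIM_THRESHOLD,
    canonical: bool = True,
) -> tuple[pd.DataFrame, list[TrialResult]]:
    """Analyze every trial; returns (feature table, per-trial results)."""
    if layout is None:
        spec0 = ts.spec.with_target(0) if canonical else ts.spec
        layout = default_static_layout(spec0)
    results = [
        analyze_trial(tr, ts.spec, layout=layout,
                      lift_trim_threshold=lift_trim_threshold, canonical=canonical)
        for tr in ts.trials
    ]
    table = pd.DataFrame([r.record for r in results])
    return table, results
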