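"""Matplotlib renders: trajectories, occupancy maps, and network plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless batch rendering
import matplotlib.pyplot as plt
import numpy as np

from maznet.arena import ArenaSpec, hole_positions
from maznet.conventional import OccupancyMap
from maznet.globalnet import GlobalNetwork, polar_topology_layout
from maznet.network import BehaviorNetwork
from maznet.trajectory import Trajectory


def _draw_arena(ax, spec: ArenaSpec) -> None:
    ax.add_patch(plt.Circle(spec.center, spec.arena_radius, fill=False, color="k"))
    for i, (x, y) in enumerate(hole_positions(spec)):
        color = "tab:green" if i == spec.target_index else "0.6"
        ax.add_patch(plt.Circle((x, y), spec.hole_proximity_radius,
                                fill=False, color=color, lw=0.8))
    ax.set_aspect("equal")
    ax.invert_yaxis()  # image convention: y grows downward
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")


def plot_trajectory(traj: Trajectory, spec: ArenaSpec, ax=None):
    """Trajectory over the arena outline; target hole in green."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    _draw_arena(ax, spec)
    ax.plot(traj.xy[:, 0], traj.xy[:, 1], lw=0.7, color="tab:blue")
    ax.plot(*traj.xy[0], "o", color="tab:orange", ms=5, label="start")
    ax.legend(loc="upper left", fontsize=8)
    return ax


def plot_occupancy(occ: OccupancyMap, spec: ArenaSpec, ax=None):
    """Contour map of block occupancy rates."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    xc = 0.5 * (occ.x_edges[:-1] + occ.x_edges[1:])
    yc = 0.5 * (occ.y_edges[:-1] + occ.y_edges[1:])
    cs = ax.contourf(xc, yc, occ.grid, levels=10, cmap="viridis")
    plt.colorbar(cs, ax=ax, label="occupancy rate")
    _draw_arena(ax, spec)
    return ax


def plot_network(net: BehaviorNetwork, spec: ArenaSpec, ax=None,
                 node_size_scale: float = 30.0):
    """Spatial network plot: nodes at their arena coordinates, links weighted
    by transition multiplicity."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    _draw_arena(ax, spec)
    ii, jj = np.nonzero(np.triu(net.adjacency, 1))
    for i, j in zip(ii, jj):
        w = net.transition_counts[i, j]
        ax.plot(net.node_xy[[i, j], 0], net.node_xy[[i, j], 1],
                color="tab:red", lw=0.5 + 0.4 * w, alpha=0.7)
    sizes = node_size_scale * np.array([max(len(m), 1) for m in net.members])
    ax.scatter(net.node_xy[:, 0], net.node_xy[:, 1], s=sizes,
               color="tab:blue", zorder=3)
    return ax


def plot_global_spatial(gnet: GlobalNetwork, spec: ArenaSpec, ax=None,
                        min_size: float = 20.0):
    """Group-day global network over the arena; node area follows the
    log-scaled member magnitude (singletons kept visible at min_size)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    _draw_arena(ax, spec)
    net = gnet.network
    ii, jj = np.nonzero(np.triu(net.adjacency, 1))
    for i, j in zip(ii, jj):
        w = net.transition_counts[i, j]
        ax.plot(net.node_xy[[i, j], 0], net.node_xy[[i, j], 1],
                color="tab:red", lw=0.5 + 0.3 * w, alpha=0.7)
    sizes = min_size + 60.0 * gnet.magnitudes
    ax.scatter(net.node_xy[:, 0], net.node_xy[:, 1], s=sizes,
               color="tab:blue", zorder=3)
    ax.set_title(f"{gnet.group} day {gnet.day}")
    return ax


def plot_global_polar(gnet: GlobalNetwork, ax=None):
    """Degree-sorted polar topology plot: highest-degree node at 0 degrees,
    lowest at 360, colored by degree bin."""
    if ax is None:
        fig = plt.figure(figsize=(5, 5))
        ax = fig.add_subplot(projection="polar")
    layout = polar_topology_layout(gnet)
    pos = {e["node"]: np.deg2rad(e["angle_deg"]) for e in layout}
    net = gnet.network
    ii, jj = np.nonzero(np.triu(net.adjacency, 1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        ax.plot([pos[i], pos[j]], [1.0, 1.0], color="0.6", lw=0.6, alpha=0.7)
    for e in layout:
        ax.plot(np.deg2rad(e["angle_deg"]), 1.0, "o", ms=8,
                color=e["color"], mec="k")
    ax.set_rticks([])
    ax.set_theta_direction(-1)
    ax.set_theta_zero_location("N")
    return ax
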