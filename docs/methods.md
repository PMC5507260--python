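# Methods

This note documents the models and procedures implemented in `maznet`, the
choices made where the underlying definitions were genuinely open, and what
the synthetic-data validation does and does not establish.

## Coordinate frame and arena geometry

Positions arrive in image coordinates (origin top-left, x right, y down,
nominally 500×500 px at 2 mm/px, 5 Hz). All geometry is computed after
translating to the arena center; angles are counterclockwise as seen from
above (y flipped). The default arena has radius 245 px (≈49 cm), 12 holes
equally spaced on a 200-px ring, and a 40-px proximity disk per hole
(≈ one mouse body length).

Every trial is rotated rigidly about the center so its target hole lands at
45° ("top right"); the rotation is an isometry, so distances and all derived
metrics are unaffected. The exact canonical angle is a free convention; 45°
places the target on the symmetric diagonal. Quadrant boundaries sit on the
cardinal axes so the target is mid-quadrant — the source definitions never
locate the boundaries, and a mid-quadrant target avoids classifying noise at
a boundary ray as quadrant traffic. Boundary points belong to the
counterclockwise quadrant (deterministic tie-break).

## Conventional metrics

A **visit** is an entry event into the closed proximity disk of a hole:
consecutive inside frames count once. **Errors** are visits to non-target
holes over the whole recorded trial (recording conventionally stops at
escape, so "before escape" and "whole trial" coincide; for probe trials the
full trial counts). Repeat visits to the same dummy hole count repeatedly.
**Latency** is the time to the first entry into the target disk — a
geometric proxy for escape-box entry, which is not observable from point
sequences; trials that never enter the disk report the trial duration with a
`target_reached=False` flag. **Travel distance** is the summed frame-to-frame
displacement. **Occupancy maps** bin frames into square blocks (default
20 px ≈ 4 cm, a free choice) over the arena bounding box. Per-day values are
arithmetic means over a subject's trials within a day.

## Strategy classification

Rules are evaluated in order on training trials:

1. **spatial** — quadrant crosses = 0 and errors < 3;
2. **serial** — quadrant crosses < 3 and the visited-hole sequence is
   ring-adjacent (and not spatial);
3. **random** — everything else.

A **quadrant cross** is operationalized as a traversal of the central zone
(radius 0.25 × arena radius, configurable) that exits into a different
quadrant than it entered from. Raw boundary-ray crossings cannot be the
intended meaning: a serial perimeter sweep crosses quadrant rays constantly
yet is the canonical low-cross strategy, while random search is described by
its many *center* crossings. A trajectory starting inside the central zone
has no entry quadrant, so its first exit never counts.

**Sequential** means every consecutive pair of distinct visited holes
differs by ±1 mod 12 (wraparound counts, direction reversals allowed;
fewer than two distinct visits is vacuously sequential). A lenient mode
tolerating a single skipped hole is available but off by default. For LIFT
(center-lift) entries, frames before the animal first exceeds a start radius
(default 38 px ≈ the mean MANUAL-entry start distance, recomputable from a
MANUAL trial set via `manual_start_radius`) are discarded before
classification so micromovements on the lift scaffold cannot inflate the
random label. The trim applies to strategy classification only; conventional
and network metrics use the full trajectory.

## Stop detection and dynamic networks

A sliding window of 5 successive frames qualifies as stopping when its path
length is below 20 px (≈ half a body length at 5 Hz). All qualifying windows
that share frames are merged into one maximal episode summarized by the
centroid of its frames; episodes are therefore ordered and non-overlapping.
The per-window reading without merging would emit a near-duplicate stop
every frame of a long pause.

Stop centroids are clustered with the **City Clustering Algorithm**:
sweeping the points in chronological order, each point joins the nearest
current node if closer than 20 px, otherwise spawns a new node; after each
sweep node centroids are recomputed as member means and empty nodes dropped;
sweeps repeat until the assignment stabilizes (max 100 passes, convergence
failure warned). The convergence condition and pass order are not fixed by
the published description; chronological order with assignment-stability is
the documented choice. Exact order-independence cannot hold for arbitrary
point sets at a fixed threshold; it is asserted (and tested) only for
well-separated data, where each cluster's diameter is below the threshold.

Consecutive stops mapped to distinct nodes add an undirected link;
same-node transitions are ignored (no self-links). Adjacency is binary for
all feature computation; transition multiplicities are retained for
visualization. Trials with zero stops yield an empty network whose features
are flagged undefined rather than zero, so group statistics can exclude them.

## Static networks

25 static nodes tessellate the arena: 1 at the center, 8 at half the arena
radius, 16 at 0.85 × arena radius, the first node of each ring on the 45°
diagonal. The published node geometry is not available in text form; this
1+8+16 layout is uniform, resolves all 12 holes on the outer ring, and is
fully overridable via JSON. A point's zone is its nearest node (ties to the
lowest id); zone adjacency is derived from the Voronoi diagram clipped to
the arena disk (two zones are adjacent iff their Voronoi ridge intersects
the open disk). Consecutive distinct zones in the frame sequence add links;
a frame-to-frame jump across non-adjacent zones is decomposed by recursive
midpoint subdivision into the chain of zones the straight segment crosses,
preserving the planarity guarantee (every link joins boundary-sharing
zones) instead of dropping the transition.

## Network features

For binary symmetric adjacency A with zero diagonal: m = ½∑ᵢⱼAᵢⱼ;
**degree** is reported as m/n following the source definition (half the
conventional mean degree, which is also exported as `mean_degree`);
**density** ρ = 2m/(n(n−1)); **clustering** C_WS averages
Cᵢ = Rᵢ/(kᵢ−1) over nodes with kᵢ ≥ 2, where the redundancy Rᵢ is the
average number of links from a neighbor of i to other neighbors of i
(algebraically 2Tᵢ/kᵢ); **shortest path** l averages unweighted
shortest-path lengths over unordered reachable pairs, excluding and counting
unreachable pairs (disconnected handling is not specified upstream);
**betweenness** averages the unnormalized xᵢ = ∑_{s≠t≠i} σ_st(i)/g_st over
ordered pairs, using the standard fractional count of shortest paths through
i — an indicator variant (does i lie on *any* shortest path) is available
behind a flag, and the two coincide whenever shortest paths are unique;
**closeness** averages 1/∑ⱼdᵢⱼ over nodes that reach at least one other
node. Every feature carries a defined/undefined flag for degenerate
networks (n < 2, no qualifying node, no reachable pair).

## Global networks

All local-network nodes of a group-day are re-clustered with the same CCA
threshold; each local node belongs to exactly one global node. A global link
joins two global nodes when some local link joins their members; its weight
counts supporting local links. Node magnitude is ln(member count) — the log
base is a rendering choice; singleton nodes (ln 1 = 0) are drawn at a
minimum marker size. The polar topology layout sorts nodes by degree
descending (ties by id) at angles linearly spaced 0°→360°, colored white
(M ≥ 12), yellow (12 > M ≥ 9), orange (9 > M ≥ 6), red (6 > M ≥ 3), brown
(M < 3).

## Group statistics

Kruskal–Wallis between groups per day and Friedman across days within
groups, delegated to scipy; follow-up pairwise Mann–Whitney (between) and
exact sign tests (within) run only when the omnibus test is significant, at
Ryan's step-down level α′ = 2α/(k(m−1)) with m the rank span of the pair —
the procedure is named but not formulated upstream, so this standard form is
the documented choice. Effect sizes use Pearson's R = |Z|/√N, binned null
[0, 0.1), small [0.1, 0.3), medium [0.3, 0.5), large [0.5, 1]. Undefined
feature values are excluded pairwise with counts reported. Two-way mixed
ANOVA with Tukey HSD for conventional features is routine statistics outside
the bespoke core and is left to standard packages.

## Synthetic trajectories

Locomotion is a discrete-time correlated random walk at 5 Hz: step length ~
N(80, 20²) px/s × 0.2 s (16 cm/s mean, a typical exploring mouse), heading =
direction to the current waypoint + N(0, turn_sd²) noise, reflecting arena
boundary. Waypoint policies realize the archetypes: *spatial* runs straight
from the center to the target; *serial* runs out to a start hole then
visits ring-adjacent holes to the target; *random* chains random waypoints,
routing through the center into a different quadrant until the requested
number of center crossings is accumulated. Stops are zero-mean Gaussian
jitter (sd = stop_threshold/8 = 2.5 px) around an anchor for a geometric
number of frames: a start dwell, a dwell at each visited hole, and
additional stops at `stop_rate`. Trials are deterministic given a seed;
cohort seeds derive from a master seed via `numpy.random.SeedSequence`.

The default 6-day learning schedule (used by the acceptance script and the
cohort tests) moves from one day of long random search through three days of
serial sweeps starting progressively closer to the target to two days of
spatial runs (the first hesitant: slower, noisier, more stops). This emulates
the canonical random → serial → spatial progression of arena learning with
3 trials/day and 19 subjects.

The generator emulates the *geometry and event structure* real data feeds
into the pipeline — dwell episodes, hole visits, center traversals, strategy
morphologies — not biophysics: there is no thigmotaxis, no within-trial
learning, no tracking noise or dropout, and dwell jitter is isotropic
Gaussian rather than postural sway. Passing tests therefore establish that
the pipeline's operations implement their definitions correctly and recover
planted structure, not that the archetypes span real mouse behavior.

## Numerical choices and degenerate inputs

Hole disks are closed (distance ≤ 40 px counts inside). Nearest-node ties go
to the lowest id. CCA iteration caps at 100 passes. Zone-chain subdivision
caps at depth 48, then routes via the midpoint zone (never observed in
tests). Trajectories shorter than the stop window yield no stops; empty and
single-node networks propagate NaN features with defined-flags rather than
zeros. Friedman requires ≥ 3 complete subjects; constant data short-circuit
to p = 1 (scipy rejects zero-variance input). LIFT trials that never leave
the start radius are flagged invalid and excluded from classification.

## Problem sizes

The validation suite uses 500 random graphs (n ≤ 8) against brute-force
oracles, 100 simulated trials per trajectory-level suite, 100 seeds per
archetype for classifier agreement, and a 19-subject × 6-day × 3-trial
cohort for the learning-curve property; the full suite runs in well under a
minute. These sizes give binomial confidence intervals comfortably inside
the asserted bounds (e.g. ≥ 95/100 agreement) while keeping the suite quick.

## Known limitations

- Latency is a geometric proxy; true escape-box entries require hardware
  events the package does not see.
- The 25-node static layout approximates an unpublished geometry; results
  depending on exact zone boundaries should supply their own layout JSON.
- CCA partitions depend on point order when clusters are closer than the
  threshold; only separated configurations are order-stable.
- The betweenness indicator/fractional ambiguity matters only on graphs
  with degenerate multiple geodesics; the fractional (standard) form is the
  default.
- Statistics assume independent subjects and complete blocks for Friedman;
  subjects with missing days are dropped, not imputed.
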