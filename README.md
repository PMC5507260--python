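# maznet

Trajectory-to-network analysis of exploratory behavior in circular
spatial-learning arenas (Barnes-maze-style tasks).

Given per-trial 2-D position sequences of a rodent exploring a brightly lit
circular arena with 12 peripheral holes (one hiding an escape box), `maznet`
computes, per trial:

- **conventional metrics** — number of errors (visits to non-target holes),
  latency to the target, travel distance, time spent around each hole,
  occupancy maps;
- **search-strategy labels** — rule-based *spatial* / *serial* / *random*
  classification from quadrant crosses, error counts, and the ring-adjacency
  of the visited-hole sequence;
- **behavioral networks** — *dynamic* networks whose nodes are stop episodes
  clustered with the City Clustering Algorithm (CCA), and *static* planar
  networks over a fixed 25-zone tessellation of the arena; transitions
  between nodes form undirected links (no self-links);
- **eight network features** — number of stops *o*, order *n*, degree *m/n*
  (with *m* = ½∑ᵢⱼAᵢⱼ), density *ρ* = 2m/(n(n−1)), clustering coefficient
  *C*<sub>WS</sub> = mean of *Rᵢ*/(*kᵢ*−1) with *Rᵢ* the neighbor-redundancy,
  mean shortest path *l*, betweenness centrality *x*, and closeness
  centrality *cl* = mean of 1/∑ⱼdᵢⱼ;
- **global networks** — per-group, per-day CCA aggregation of all local
  nodes, with log-scaled node magnitudes and a degree-sorted polar topology
  layout;
- **group statistics** — Kruskal–Wallis / Friedman batteries with
  Mann–Whitney / sign-test follow-ups at Ryan-adjusted levels and Pearson-R
  effect-size bins.

A built-in simulator generates 5-Hz arena trajectories with controllable
strategy archetypes and stop structure, so the entire pipeline can be
developed and validated without animal data.

Intended users: behavioral neuroscientists and computational ethologists
analyzing dry-land spatial-learning tasks from video-tracking output.

## Worked example

```python
import maznet as mz
from maznet.pipeline import analyze_trial

spec = mz.ArenaSpec()                       # 490-px arena, 12 holes, 5 Hz
params = mz.SimParams(strategy="serial", seed=42)
traj = mz.simulate_trial(params, spec)      # one simulated training trial
result = analyze_trial(traj, spec)
for k in ("strategy", "n_errors", "latency_s", "n_quadrant_crosses",
          "dyn_order", "dyn_degree", "dyn_shortest_path"):
    print(k, "=", result.record[k])
```

prints

```
strategy = serial
n_errors = 4
latency_s = 12.8
n_quadrant_crosses = 0
dyn_order = 4
dyn_degree = 0.75
dyn_shortest_path = 1.6666666666666667
```

The simulated animal sweeps the hole ring from hole 8 to the target: it
visits 4 dummy holes (4 errors, ring-adjacent sequence, no center crossings
→ *serial*), reaches the target after 12.8 s, and its stop episodes form a
4-node chain-like dynamic network (degree m/n = 3/4, mean shortest path 5/3).

The same API scales to cohorts:

```python
ts = mz.simulate_cohort(19, mz.simulate.default_learning_schedule(), spec, seed=1)
table, nets = mz.pipeline.analyze_trialset(ts)   # one FeatureRecord row per trial
```

A `maznet` console script wraps the same operations
(`maznet simulate`, `maznet analyze`, `maznet compare`).

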