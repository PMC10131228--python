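# milekin

Markovian milestoning kinetics along a scalar collective variable (CV).

The CV axis (e.g. a ligand–binding-site center-of-mass distance in
ångströms) is tessellated into Voronoi cells separated by milestones.
Each cell is sampled independently with reflective boundaries; every
boundary collision is a milestone touch.  The touch statistics
parameterize a milestone-level continuous-time Markov jump model whose
rate matrix yields

* **mean first passage times** to the outermost (absorbing) milestone —
  the bound milestone's entry is the **residence time** (1/k_off),
* **stationary milestone probabilities** and the **free-energy profile**
  ΔG_i = −k_BT·ln(p_i/p_ref) with transition-state milestones at its
  interior local maxima,
* **replica aggregates** (mean ± SEM) and **rank orderings** of multiple
  systems with pairwise Welch t-tests.

Instead of molecular dynamics, the built-in synthetic engine runs 1D
overdamped Brownian dynamics on configurable potentials (flat, harmonic,
double-barrier, tabulated), plus an exact Gillespie jump-process oracle
and a brute-force first-passage simulator for independent validation.
A slow-pulling routine seeds one starting point per cell, mimicking
steered-MD seeding.

## Library quick start

```python
import numpy as np
import milekin as mk

model = mk.build_radial_model(np.arange(1.0, 11.0))   # 10 milestones
pot = mk.PotentialSpec("flat")

stats = []
for cell in range(model.n_cells):
    lo, hi = model.cell_bounds(cell)
    trace = mk.simulate_confined_bd(
        model, pot, cell, start_cv=0.5 * (lo + hi),
        n_steps=1_000_000, dt=2e-4, seed=cell,
    )
    stats.append(mk.collect_cell_statistics(trace))

result = mk.estimate_kinetics(model, stats)
print(result.residence_time)        # ~ (10^2 - 1^2) / 2 for free diffusion
print(result.dG, result.ts_milestones)
```

Multi-system orchestration goes through `mk.SystemSpec` / `mk.run_system`
/ `mk.rank_systems`, or the CLI below.

## CLI

```sh
milekin model build --milestones 2.5,3.0,3.5,4.0 --out model.json
milekin simulate --config config.yaml --system inhibA --out-dir out/
milekin analyze  --stats stats.json --model model.json --out-prefix out/an
milekin rank     --config config.yaml --out-dir out/
milekin converge --traces cell0.jsonl --traces cell1.jsonl \
                 --model model.json --windows 10
```

Exit codes: 0 success, 2 validation error, 3 numerical failure.  A config
file is a single YAML/JSON document:

```yaml
model: {milestones: [0.5, 1.5, 2.5, 3.5, 4.5], thermal_energy: 1.0}
defaults: {replicas: 3, n_steps: 1000000, dt: 0.0002, diffusion: 1.0, seed: 1}
systems:
  - name: slow
    potential: {kind: double_barrier, barrier_positions: [1.5, 3.0],
                barrier_heights: [3.0, 3.5], barrier_widths: [0.6, 0.6],
                well_depth: 1.5, well_center: 0.5, well_width: 0.6}
  - name: fast
    potential: {kind: double_barrier, barrier_positions: [1.5, 3.0],
                barrier_heights: [1.5, 2.0], barrier_widths: [0.6, 0.6],
                well_depth: 1.5, well_center: 0.5, well_width: 0.6}
```

## File formats

* model: JSON `{"milestones": [...], "thermal_energy": ..., "units": ...}`
* event traces: JSON lines — header record, then `{"t": ..., "m": ...}`
* statistics: versioned JSON (`"schema": "mmvt_stats_v1"`) with per-cell
  sparse `N`, `R`, `T`, `N_boundary`, `excluded_time`; CSV export via
  `milekin.stats.statistics_frame`
* results: per-milestone CSV (milestone, cv_value, mfpt, dG, is_TS) and a
  JSON summary; ranking CSV plus pairwise p-value CSV
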