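# divgrid

Spatially explicit simulation of diversity-dependent diversification on a
bounded grid, for macroevolution and macroecology researchers who want to
know what phylogenies and range-size distributions look like when limits to
diversity arise from *local* coexistence rather than from a clade-level cap.

The model is a continuous-time Markov process on a square lattice of `A`
cells, each holding at most `K_L` species. The unit carrying rates is the
*population* — one species in one cell. Per-population processes are
speciation (λ, relabel a population as a new species), colonization (γ, seed
a cardinal-neighbour cell; attempts at saturated, self-occupied, or off-grid
cells have no effect), and local extinction (μ, remove a population; a
species losing its last population is extinct). Event times follow the
Gillespie algorithm with total rate `N_pop (λ + γ + μ)`. Diversity is
bounded by `K_R = K_L × A`, reached only when every cell is saturated and
every species is a single-cell endemic. From each run the package builds the
full and reconstructed (extant-ancestral) phylogenies and computes:

* **Δr** — net diversification of the second minus the first half of the run,
  `Δr = [ln N(T) − ln N(T/2)] − [ln N(T/2) − ln N(0)]` (per-unit-time by
  default); negative values mean a slowdown;
* **Sackin imbalance**, Yule-centred: `(S_raw − 2n Σ_{j=2..n} 1/j)/n`;
* **evolutionary turnover** — species extinctions per speciation per unit
  time (1 at dynamic equilibrium);
* range-size and species-age distributions, richness series, and
  across-replicate aggregates with percentile CIs.

An exact master-equation solver (`divgrid.oracle`) validates the stochastic
engine on tiny grids. Large runs use a numba kernel; a fully logged
pure-Python engine implements the identical process for inspection and
testing.

## Worked example

One replicate of the headline scenario — `A=256`, `K_L=16`, λ=0.08, γ=80,
μ=1, `T=35`:

```python
from divgrid import SimulationParams, run, compute_summary

params = SimulationParams(area=256, local_limit=16, speciation_rate=0.08,
                          colonization_rate=80.0, local_extinction_rate=1.0,
                          duration=35.0, seed=1)
summary = compute_summary(run(params, engine="fast"))
```

prints (via the fields of `summary`):

```
K_R: 4096
final richness: 1140
mean local richness: 15.98
mean range size: 3.59
range skewness: 1.89
delta_r_full: -0.394
delta_r_reconstructed: -0.239
sackin: -0.224
richness at t=0,5,...,35: [   1  716  924 1026 1079 1105 1093 1140]
mean turnover, second half: 0.99
```

Read: richness climbs fast, then fluctuates around ~1100 — a dynamic
equilibrium well below the ceiling of 4096, held there by species extinction
(turnover ≈ 1 in the second half). Local assemblages are saturated (mean
local richness ≈ 16 = `K_L`), the range-size distribution is strongly
right-skewed (skewness 1.9: many single-cell endemics, few widespread
species), and diversification slowed down (Δr < 0), with the slowdown looking
milder on the reconstructed tree (−0.24) than it truly was (−0.39) because
extinction erases early lineages.

The same scenarios are scriptable from the shell:

```sh
divgrid scenarios                       # list built-in parameter sets
divgrid run --scenario fig5-KL1 --seed 1 --replicates 20 --out out/
divgrid simulate --config cfg.yaml --seed 1 --out one/   # full event log
divgrid metrics --events one/events.tsv --duration 35
divgrid oracle --area 4 --klimit 1 --mu 1 --replicates 1000
```

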