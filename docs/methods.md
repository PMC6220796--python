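# Methods

## The model

`divgrid` simulates the diversification of an ecologically neutral clade on a
square lattice of `A` cells with hard boundaries. The state of the system is a
set of *populations* — (species, cell) pairs — and each cell may hold at most
`K_L` distinct species (the local ecological limit). Three memoryless
processes act on populations with uniform per-population rates:

* **speciation** (rate λ): a uniformly chosen population is relabelled as a
  new species (point/budding speciation), so sister species start with
  disjoint ranges and the parent keeps its identity and origination time. If
  the relabelled population was the parent's last one, the parent is recorded
  as extinct at that instant (pseudoextinction).
* **colonization** (rate γ): the population attempts to seed a new cell.
  Under *local* dispersal the target is one of the four cardinal neighbours,
  chosen uniformly; an attempt aimed off-grid, at a cell the species already
  occupies, or at a saturated cell (local richness = `K_L`) has no effect.
  Under *global* dispersal the target is uniform over all cells where the
  species is absent and local richness < `K_L` (no-op if none exist).
* **local extinction** (rate μ): the population is removed. A species losing
  its last population goes regionally extinct.

Event times follow the exact Gillespie algorithm: waiting times are
exponential with total rate `N_pop (λ + γ + μ)` and the event kind is drawn
with probabilities proportional to λ : γ : μ. A run starts with one species
in one uniformly random cell and ends at time `T`, on clade extinction, or
when a cap on cumulative species (default 384 000) is hit (flagged as a
truncation, never silent). The ceiling on diversity is `K_R = K_L × A`,
attained only when every cell is saturated and every species occupies a
single cell.

Treating failed colonization attempts as no-ops (rather than re-drawing a
target) is what keeps the total propensity exactly `N_pop (λ + γ + μ)`; the
alternative would make per-population colonization propensities depend on
range geometry and invalidate the waiting-time law above.

## Parameters

| symbol | meaning | units | notes |
|--------|---------|-------|-------|
| `A` | number of cells (perfect square) | cells | bounds any range size |
| `K_L` | local ecological limit | species/cell | saturated cells reject colonization |
| λ | speciation rate | 1/time per population | must be > 0 |
| γ | colonization rate | 1/time per population | 0 allowed |
| μ | local extinction rate | 1/time per population | 0 gives an absorbing saturated state |
| `T` | run duration | time | published scenarios use 35 (100 for the μ=0 run) |

The built-in scenarios (`divgrid scenarios`) carry the published parameter
sets: the high-rate pair (λ=0.08, γ=80) with μ ∈ {0, 1}, the fixed-`K_R`
triple (`K_L`, `A`) ∈ {(1, 4096), (16, 256), (256, 16)} at λ=0.05, γ=30,
μ=1, and μ-contrast pairs at μ ∈ {0.5, 5}. The λ, γ pair behind the
μ-contrast panels is not stated in the source text; the high-rate pair is
assumed and labelled as such. Replicate counts default to 100 (50 for
`K_L`=1500, whose clades are very large); tests and the acceptance script
run 20 replicates per batch so a full check stays within desk-scale compute,
and report percentile confidence intervals from those replicates.

## Engines

Two implementations share the model semantics:

* the **Python engine** (`run(..., engine="python")`) keeps a dual-indexed
  `GridState` (per-cell occupant sets, per-species cell sets, and a flat
  population index with swap-with-last deletion for O(1) uniform draws) and
  logs every event, including no-effect colonization attempts;
* the **fast engine** (`engine="fast"`), a numba kernel over flat arrays with
  a per-species cell bitmask for O(1) presence tests. It records the species
  table (parent, origin, extinction, pseudoextinction flag), the final
  population table, and richness/population series at integer times, but no
  per-event log.

Each engine is deterministic given (params, seed); the two consume different
RNG streams, so they produce different realizations of the same process.
Equivalence is tested distributionally: both engines are compared against the
exact master-equation solution on tiny grids (mean clade lifetime and the
full transient state distribution at t=1), and against each other on final
richness via a rank-sum test.

## Trees and metrics

The species table is the lineage tree in tabular form. The binary time-tree
is built by threading each species' lifeline through its daughters'
origination times (budding topology: the parent's branch passes through each
speciation node unbroken). The reconstructed tree keeps only lineages
ancestral to species extant at `T`, suppressing unary nodes created by
pruning while preserving branch lengths; its root is the crown divergence,
with the stem from t=0 retained so that lineage counts can be anchored at
the origin. A fully extinct clade yields an explicit empty tree, and
undefined metric values propagate as NaN, never zeros. All traversals are
iterative, so caterpillar-like trees of tens of thousands of tips do not
exhaust the interpreter stack.

**Δr** measures the change in net diversification between the two halves of
a run: with lineage counts `N(0)=1`, `N(T/2)`, `N(T)`,

    r1 = ln N(T/2) − ln N(0),  r2 = ln N(T) − ln N(T/2),  Δr = r2 − r1,

divided per half by its duration under the default per-unit-time convention
(`normalize=True`); the bare log-change convention is exposed via the same
flag because published values of this statistic exist under both readings,
and the two differ exactly by the factor 2/T. The full-tree variant counts
species alive at each anchor; the reconstructed variant counts branches of
the reconstructed tree crossing each anchor (stem = 1). Δr is zero for
deterministic exponential growth; for a stochastic pure-birth process
started from one lineage its expectation is the small positive Euler-bias
term ≈ γ_E/(T/2), which the test suite pins against the exact geometric law
of the Yule lineage count rather than asserting exact zero.

**Sackin imbalance** is reported in the Yule-centred normalization of Blum &
François: `S = (S_raw − E_Yule[S_n])/n` with `S_raw` the sum of tip depths
(internal nodes per root-to-tip path) and `E_Yule[S_n] = 2n Σ_{j=2..n} 1/j`,
so pure-birth trees sit at 0 and larger values mean more imbalance. The
statistic is topology-only.

**Evolutionary turnover** is species extinctions divided by speciation
events per unit-time bin (NaN where a bin has no speciations); equilibrium
shows turnover fluctuating about 1. Parental pseudoextinctions at speciation
count in the numerator by default — they are recorded species extinctions —
with an `include_pseudo=False` toggle since their treatment in the turnover
numerator is not pinned down by the published description.

**Range and age summaries** report cells occupied and `T − origin` per
extant species, plus the skewness of the range-size distribution (NaN when
degenerate, e.g. the all-singleton saturated state).

## The exact oracle

For grids of a few cells the full master equation is solved directly.
States are canonicalized up to species relabelling (the model is neutral) as
the multiset of occupied cell-sets, with cells kept distinct because
geometry matters under local dispersal; speciation events that map a state
to an isomorphic one (relabelling a singleton) are self-loops and carry no
transition. Local colonization enters the generator at γ/4 per eligible
direction, global at γ/|eligible cells|. Mean time to clade extinction
solves `Q_tt τ = −1` over transient states (exactly 1/μ for the single-cell
system); transient distributions use sparse matrix exponentiation. The
enumeration refuses instances beyond a configurable state bound (default
10^5) with a count estimate.

## Numerical and design choices

* Cells are 0-based (row, col) on an L×L row-major grid in all outputs.
* Per-replicate seeds derive from the master seed through
  `numpy.random.SeedSequence` spawn keys (recorded in the manifest), kept
  below 2^31; scenario outputs are byte-for-byte reproducible.
* Replicates ending in clade extinction are counted and reported separately;
  tree-based metrics aggregate over survivors only, since a tree is required.
* The μ=0 saturated configuration is absorbing up to species relabelling:
  richness `K_R` and all ranges 1 persist even though speciation keeps
  cycling identities. Runs are taken to `T` rather than stopped early so the
  reported state is the literal time-`T` state.
* Newick output writes branch lengths at full double precision (`%.17g`) so
  round-trips through standard parsers preserve lengths to 1e-9 and better.

## What the tests do and do not show

The test suite validates the simulator against independent oracles at small
scale (exact master equation, closed-form Yule expectations, distributional
laws of the Gillespie sampler) and the published qualitative structure at
desk scale: saturation at `K_R` with unit ranges when μ=0, negative Δr with
the reconstructed slowdown weaker than the true one, weaker reconstructed
slowdown at `K_L`=1 than `K_L`=256, right-skewed equilibrium range-size
distributions, and an equilibrium-richness advantage of small-area/high-`K_L`
regions that strengthens with μ. The printed Δr magnitudes for the
fixed-`K_R` panels are not reproduced at the rate pair documented for those
scenarios: with `N(t) ≤ K_R = 4096` and `T = 35`, the per-unit-time
convention bounds Δr_full below by −2 ln(4096)/17.5 ≈ −0.95 (and ≈ −0.47 at
dynamic equilibrium), so a printed mean of −0.971 requires either other
rates or another convention; the package reports both conventions and leaves
the discrepancy visible rather than recalibrating toward it. The model is
neutral and spatially homogeneous by construction; nothing here speaks to
trait-mediated coexistence, heterogeneous `K_L`, or vicariant range-split
speciation, and agreement with the published patterns does not validate
those extensions.
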