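"""Continuous-time stochastic model of diversification on a bounded grid.

The model tracks *populations* — the presence of one species in one cell of a
square lattice with ``A`` cells and hard boundaries.  Each cell holds at most
``K_L`` species (the local ecological limit).  Three per-population processes
run with uniform rates:

* speciation (rate ``lambda``): one population of a species is relabelled as a
  new species, so sister species start with disjoint ranges;
* colonization (rate ``gamma``): the population attempts to seed an adjacent
  cell (local dispersal) or any eligible cell (global dispersal); attempts
  into off-grid, already-occupied-by-self, or saturated cells have no effect;
* local extinction (rate ``mu``): the population is removed; a species whose
  last population is removed goes (regionally) extinct.

Event times follow the Gillespie algorithm: exponential waiting times with
total rate ``N_pop * (lambda + gamma + mu)`` and event kinds drawn in
proportion to their rates.  The run starts from a single species in one
uniformly random cell and stops at time ``T``, on clade extinction, or when a
cap on the cumulative number of species is hit.

Two engines share these semantics: the pure-Python :class:`GridState` engine
in this module, which logs every event and is convenient to introspect, and a
numba-compiled kernel (:mod:`divgrid._kernel`) used for large runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "ConfigError",
    "SimulationParams",
    "EventRecord",
    "GridState",
    "RunResult",
    "init_simulation",
    "total_event_rate",
    "advance_one_event",
    "apply_colonization",
    "apply_local_extinction",
    "apply_speciation",
    "run",
]

# Event kinds
FOUNDING = "founding"
SPECIATION = "speciation"
COLONIZATION = "colonization"
LOCAL_EXTINCTION = "local_extinction"
SPECIES_EXTINCTION = "species_extinction"

# Termination reasons
TERM_DURATION = "duration"
TERM_EXTINCT = "extinct"
TERM_MAX_SPECIES = "max_species"
TERM_SATURATED = "saturated"

# default cap on cumulative species created in one run
DEFAULT_MAX_SPECIES = 384_000

_DIRECTIONS = ((-1, 0), (1, 0), (0, -1), (0, 1))


class ConfigError(ValueError):
    """Raised when a simulation parameter is invalid; names the field."""


@dataclass(frozen=True)
class SimulationParams:
    """Full parameterization of one simulation run.

    Attributes
    ----------
    area
        Number of cells ``A`` in the square region (must be a perfect square).
    local_limit
        Local ecological limit ``K_L``: maximum species per cell.
    speciation_rate, colonization_rate, local_extinction_rate
        Per-population rates (1/time) ``lambda``, ``gamma``, ``mu``.
    duration
        Simulation length ``T`` in time units.
    dispersal_mode
        ``"local"`` (4 cardinal neighbours) or ``"global"`` (any eligible cell).
    max_species
        Cap on cumulative species created; hitting it flags a truncated run.
    seed
        RNG seed; identical (params, seed) gives an identical event log.
    """

    area: int
    local_limit: int
    speciation_rate: float
    colonization_rate: float
    local_extinction_rate: float
    duration: float
    dispersal_mode: str = "local"
    max_species: int = DEFAULT_MAX_SPECIES
    seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.area, (int, np.integer)) and self.area >= 1):
            raise ConfigError(f"area must be a positive integer, got {self.area!r}")
        side = math.isqrt(int(self.area))
        if side * side != self.area:
            raise ConfigError(f"area must be a perfect square, got {self.area}")
        if not (isinstance(self.local_limit, (int, np.integer)) and self.local_limit >= 1):
            raise ConfigError(f"local_limit must be a positive integer, got {self.local_limit!r}")
        if not self.speciation_rate > 0:
            raise ConfigError(f"speciation_rate must be > 0, got {self.speciation_rate!r}")
        if self.colonization_rate < 0:
            raise ConfigError(f"colonization_rate must be >= 0, got {self.colonization_rate!r}")
        if self.local_extinction_rate < 0:
            raise ConfigError(
                f"local_extinction_rate must be >= 0, got {self.local_extinction_rate!r}"
            )
        if not self.duration > 0:
            raise ConfigError(f"duration must be > 0, got {self.duration!r}")
        if self.dispersal_mode not in ("local", "global"):
            raise ConfigError(f"dispersal_mode must be 'local' or 'global', got {self.dispersal_mode!r}")
        if self.max_species < 1:
            raise ConfigError(f"max_species must be >= 1, got {self.max_species!r}")

    @property
    def side(self) -> int:
        """Grid side length L = sqrt(A)."""
        return math.isqrt(int(self.area))

    @property
    def regional_limit(self) -> int:
        """Theoretical diversity ceiling K_R = K_L * A."""
        return int(self.local_limit) * int(self.area)

    @property
    def total_rate_per_population(self) -> float:
        return self.speciation_rate + self.colonization_rate + self.local_extinction_rate

    def with_seed(self, seed: int) -> "SimulationParams":
        return replace(self, seed=int(seed))


@dataclass
class EventRecord:
    """One timestamped event.

    For colonization, ``cell`` is the target cell; for local extinction, the
    vacated cell.  ``no_effect`` marks colonization attempts that changed
    nothing (off-grid target, species already present, or saturated cell).
    ``pseudo`` marks a species extinction caused by speciation relabelling the
    last population of its parent (pseudoextinction).
    """

    time: float
    kind: str
    species: int
    cell: Optional[tuple[int, int]] = None
    daughter: Optional[int] = None
    no_effect: bool = False
    pseudo: bool = False


class GridState:
    """Mutable occupancy state with a dual index for O(1) uniform sampling.

    ``cell_occupants[c]`` is the set of species in flat cell ``c``;
    ``species_populations[s]`` the set of cells in species ``s``'s range; the
    flat ``population_index`` of (species, cell) pairs supports O(1) uniform
    draws with swap-with-last deletion.  Cells are flat indices ``r*L + col``
    (0-based, row-major).
    """

    def __init__(self, params: SimulationParams):
        self.params = params
        self.t = 0.0
        A = params.area
        self.cell_occupants: list[set[int]] = [set() for _ in range(A)]
        self.species_populations: dict[int, set[int]] = {}
        self.population_index: list[tuple[int, int]] = []
        self._pop_pos: dict[tuple[int, int], int] = {}
        # species bookkeeping (creation order = species id)
        self.species_parent: list[int] = []
        self.species_origin: list[float] = []
        self.species_extinction: list[float] = []  # nan while extant
        self.species_pseudo: list[bool] = []
        self.log: list[EventRecord] = []

    # -- derived counters -------------------------------------------------
    @property
    def n_populations(self) -> int:
        return len(self.population_index)

    @property
    def richness(self) -> int:
        return len(self.species_populations)

    @property
    def n_species_created(self) -> int:
        return len(self.species_parent)

    def extant_species(self) -> list[int]:
        return sorted(self.species_populations)

    def cell_richness(self, cell: int) -> int:
        return len(self.cell_occupants[cell])

    def range_size(self, species: int) -> int:
        return len(self.species_populations.get(species, ()))

    def cell_coords(self, cell: int) -> tuple[int, int]:
        L = self.params.side
        return divmod(cell, L)

    # -- mutation primitives ----------------------------------------------
    def _create_species(self, parent: int, origin: float) -> int:
        sid = len(self.species_parent)
        if sid >= self.params.max_species:
            raise RuntimeError("species cap reached")
        self.species_parent.append(parent)
        self.species_origin.append(origin)
        self.species_extinction.append(math.nan)
        self.species_pseudo.append(False)
        self.species_populations[sid] = set()
        return sid

    def _add_population(self, species: int, cell: int) -> None:
        self.cell_occupants[cell].add(species)
        self.species_populations[species].add(cell)
        self._pop_pos[(species, cell)] = len(self.population_index)
        self.population_index.append((species, cell))

    def _remove_population(self, species: int, cell: int) -> None:
        self.cell_occupants[cell].remove(species)
        self.species_populations[species].remove(cell)
        pos = self._pop_pos.pop((species, cell))
        last = self.population_index.pop()
        if pos < len(self.population_index):
            self.population_index[pos] = last
            self._pop_pos[last] = pos

    def _mark_extinct(self, species: int, time: float, pseudo: bool) -> None:
        del self.species_populations[species]
        self.species_extinction[species] = time
        self.species_pseudo[species] = pseudo

    # -- consistency check (used heavily in tests) -------------------------
    def check_consistency(self) -> None:
        K_L = self.params.local_limit
        n_from_cells = 0
        for c, occ in enumerate(self.cell_occupants):
            assert len(occ) <= K_L, f"cell {c} over local limit"
            n_from_cells += len(occ)
            for s in occ:
                assert c in self.species_populations[s]
                assert (s, c) in self._pop_pos
        n_from_species = sum(len(v) for v in self.species_populations.values())
        assert n_from_cells == n_from_species == len(self.population_index)
        for s, cells in self.species_populations.items():
            assert len(cells) >= 1, f"extant species {s} with empty range"
            for c in cells:
                assert s in self.cell_occupants[c]
        for pos, (s, c) in enumerate(self.population_index):
            assert self._pop_pos[(s, c)] == pos


@dataclass
class RunResult:
    """Outcome of one run: final state, species table, and series.

    ``species_parent/origin/extinction/pseudo`` are creation-ordered arrays
    (id = index; parent -1 for the founder; extinction NaN while extant).
    ``richness_series``/``population_series`` sample the state at integer
    times 0..floor(T).  ``log`` is present for the Python engine only.
    """

    params: SimulationParams
    termination: str
    t_final: float
    state: Optional[GridState]
    species_parent: np.ndarray
    species_origin: np.ndarray
    species_extinction: np.ndarray
    species_pseudo: np.ndarray
    richness_series: np.ndarray
    population_series: np.ndarray
    log: Optional[list[EventRecord]] = None
    final_populations: Optional[np.ndarray] = None  # (n_pop, 2): species, flat cell

    @property
    def extinct(self) -> bool:
        return self.termination == TERM_EXTINCT

    @property
    def n_species_created(self) -> int:
        return len(self.species_parent)

    def extant_species(self) -> np.ndarray:
        return np.flatnonzero(np.isnan(self.species_extinction))

    def range_sizes(self) -> np.ndarray:
        """Range size (cells occupied) per extant species, id-ordered."""
        if self.final_populations is None or len(self.final_populations) == 0:
            return np.zeros(0, dtype=np.int64)
        sp = self.final_populations[:, 0]
        counts = np.bincount(sp, minlength=self.n_species_created)
        return counts[self.extant_species()]


def _founding(params: SimulationParams, rng: np.random.Generator) -> GridState:
    state = GridState(params)
    cell = int(rng.integers(params.area))
    sid = state._create_species(parent=-1, origin=0.0)
    state._add_population(sid, cell)
    state.log.append(EventRecord(0.0, FOUNDING, sid, state.cell_coords(cell)))
    return state


def init_simulation(params: SimulationParams, rng: Optional[np.random.Generator] = None) -> GridState:
    """Start a run: one species, one population, in a uniformly random cell."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    return _founding(params, rng)


def total_event_rate(state: GridState, params: SimulationParams) -> float:
    """Total propensity: N_pop * (lambda + gamma + mu)."""
    return state.n_populations * params.total_rate_per_population


def apply_colonization(
    state: GridState,
    population: tuple[int, int],
    params: SimulationParams,
    rng: np.random.Generator,
) -> EventRecord:
    """One colonization attempt from ``population`` = (species, flat cell).

    Local mode: a uniform cardinal direction; off-grid, self-occupied and
    saturated targets are no-ops.  Global mode: a uniform draw over all cells
    where the species is absent and local richness < K_L; no-op if none.
    """
    species, cell = population
    K_L = params.local_limit
    L = params.side
    if params.dispersal_mode == "local":
        dr, dc = _DIRECTIONS[int(rng.integers(4))]
        r, c = divmod(cell, L)
        tr, tc = r + dr, c + dc
        if not (0 <= tr < L and 0 <= tc < L):
            rec = EventRecord(state.t, COLONIZATION, species, (tr, tc), no_effect=True)
            state.log.append(rec)
            return rec
        target = tr * L + tc
    else:
        eligible = [
            c2
            for c2 in range(params.area)
            if species not in state.cell_occupants[c2] and len(state.cell_occupants[c2]) < K_L
        ]
        if not eligible:
            rec = EventRecord(state.t, COLONIZATION, species, None, no_effect=True)
            state.log.append(rec)
            return rec
        target = eligible[int(rng.integers(len(eligible)))]
    occupied = species in state.cell_occupants[target]
    saturated = len(state.cell_occupants[target]) >= K_L
    if occupied or saturated:
        rec = EventRecord(state.t, COLONIZATION, species, state.cell_coords(target), no_effect=True)
    else:
        state._add_population(species, target)
        rec = EventRecord(state.t, COLONIZATION, species, state.cell_coords(target))
    state.log.append(rec)
    return rec


def apply_local_extinction(
    state: GridState, population: tuple[int, int], params: SimulationParams
) -> EventRecord:
    """Remove one population; emit a species_extinction record if it was the last."""
    species, cell = population
    state._remove_population(species, cell)
    rec = EventRecord(state.t, LOCAL_EXTINCTION, species, state.cell_coords(cell))
    state.log.append(rec)
    if state.range_size(species) == 0:
        state._mark_extinct(species, state.t, pseudo=False)
        state.log.append(EventRecord(state.t, SPECIES_EXTINCTION, species))
    return rec


def apply_speciation(
    state: GridState, population: tuple[int, int], params: SimulationParams
) -> EventRecord:
    """Relabel one population of the parent as a new (daughter) species.

    A single-population parent goes extinct at the same timestamp
    (pseudoextinction), since relabelling removes its last population.
    """
    parent, cell = population
    daughter = state._create_species(parent=parent, origin=state.t)
    state._remove_population(parent, cell)
    state._add_population(daughter, cell)
    rec = EventRecord(state.t, SPECIATION, parent, state.cell_coords(cell), daughter=daughter)
    state.log.append(rec)
    if state.range_size(parent) == 0:
        state._mark_extinct(parent, state.t, pseudo=True)
        state.log.append(EventRecord(state.t, SPECIES_EXTINCTION, parent, pseudo=True))
    return rec


def advance_one_event(
    state: GridState, params: SimulationParams, rng: np.random.Generator
) -> EventRecord:
    """One Gillespie step: exponential waiting time, then one event.

    The event kind is drawn with probabilities lambda:gamma:mu (normalized)
    and the affected population uniformly from the flat index.
    """
    rate = total_event_rate(state, params)
    if rate <= 0:
        raise RuntimeError("cannot advance: no populations remain")
    state.t += rng.exponential(1.0 / rate)
    per_pop = params.total_rate_per_population
    u = rng.random() * per_pop
    pop = state.population_index[int(rng.integers(state.n_populations))]
    if u < params.speciation_rate:
        return apply_speciation(state, pop, params)
    elif u < params.speciation_rate + params.colonization_rate:
        return apply_colonization(state, pop, params, rng)
    else:
        return apply_local_extinction(state, pop, params)


def _series_from_log_state(state: GridState, params: SimulationParams) -> tuple[np.ndarray, np.ndarray]:
    """Richness / population-count series at integer times from the event log."""
    n_marks = int(math.floor(params.duration)) + 1
    rich = np.zeros(n_marks, dtype=np.int64)
    pops = np.zeros(n_marks, dtype=np.int64)
    n_pop = 0
    n_sp = 0
    mark = 0
    for rec in state.log:
        while mark < n_marks and rec.time > mark:
            rich[mark] = n_sp
            pops[mark] = n_pop
            mark += 1
        if rec.kind in (FOUNDING, SPECIATION):
            n_sp += 1
            if rec.kind == FOUNDING:
                n_pop += 1
        elif rec.kind == COLONIZATION and not rec.no_effect:
            n_pop += 1
        elif rec.kind == LOCAL_EXTINCTION:
            n_pop -= 1
        elif rec.kind == SPECIES_EXTINCTION:
            n_sp -= 1
    while mark < n_marks:
        rich[mark] = n_sp
        pops[mark] = n_pop
        mark += 1
    return rich, pops


def _result_from_state(state: GridState, params: SimulationParams, termination: str) -> RunResult:
    rich, pops = _series_from_log_state(state, params)
    final_pops = np.array(
        [(s, c) for (s, c) in state.population_index], dtype=np.int64
    ).reshape(-1, 2)
    return RunResult(
        params=params,
        termination=termination,
        t_final=state.t,
        state=state,
        species_parent=np.asarray(state.species_parent, dtype=np.int64),
        species_origin=np.asarray(state.species_origin, dtype=np.float64),
        species_extinction=np.asarray(state.species_extinction, dtype=np.float64),
        species_pseudo=np.asarray(state.species_pseudo, dtype=bool),
        richness_series=rich,
        population_series=pops,
        log=state.log,
        final_populations=final_pops,
    )


def _run_python(params: SimulationParams, debug_checks: bool = False) -> RunResult:
    rng = np.random.default_rng(params.seed)
    state = _founding(params, rng)
    termination = TERM_DURATION
    per_pop = params.total_rate_per_population
    while True:
        if state.n_populations == 0:
            termination = TERM_EXTINCT
            break
        if state.n_species_created >= params.max_species:
            termination = TERM_MAX_SPECIES
            break
        # peek at the waiting time so the clock never overshoots T
        dt = rng.exponential(1.0 / (state.n_populations * per_pop))
        if state.t + dt >= params.duration:
            state.t = params.duration
            break
        state.t += dt
        u = rng.random() * per_pop
        pop = state.population_index[int(rng.integers(state.n_populations))]
        if u < params.speciation_rate:
            apply_speciation(state, pop, params)
        elif u < params.speciation_rate + params.colonization_rate:
            apply_colonization(state, pop, params, rng)
        else:
            apply_local_extinction(state, pop, params)
        if debug_checks:
            state.check_consistency()
    return _result_from_state(state, params, termination)


def _state_from_arrays(params: SimulationParams, pops: np.ndarray, t: float) -> GridState:
    """Rebuild a GridState (occupancy only, no log) from a (species, cell) table."""
    state = GridState(params)
    state.t = t
    seen: set[int] = set()
    for s, c in pops:
        s = int(s)
        if s not in state.species_populations:
            state.species_populations[s] = set()
        state._add_population(s, int(c))
        seen.add(s)
    return state


def run(
    params: SimulationParams,
    engine: str = "python",
    debug_checks: bool = False,
) -> RunResult:
    """Run one replicate to T, clade extinction, or the species cap.

    ``engine="python"`` uses the fully logged reference implementation;
    ``engine="fast"`` dispatches to the numba kernel (no per-event log, same
    model semantics, its own deterministic RNG stream per seed).
    """
    if engine == "python":
        return _run_python(params, debug_checks=debug_checks)
    if engine != "fast":
        raise ConfigError(f"engine must be 'python' or 'fast', got {engine!r}")

    from . import _kernel

    out = _kernel.run_kernel(params)
    (term_code, t_final, pop_sp, pop_cell, sp_parent, sp_origin, sp_ext, sp_pseudo,
     rich_series, pop_series) = out
    termination = {0: TERM_DURATION, 1: TERM_EXTINCT, 2: TERM_MAX_SPECIES}[int(term_code)]
    final_pops = np.stack([pop_sp, pop_cell], axis=1).astype(np.int64) if len(pop_sp) else np.zeros((0, 2), np.int64)
    state = _state_from_arrays(params, final_pops, t_final)
    return RunResult(
        params=params,
        termination=termination,
        t_final=t_final,
        state=state,
        species_parent=sp_parent.astype(np.int64),
        species_origin=sp_origin,
        species_extinction=sp_ext,
        species_pseudo=sp_pseudo.astype(bool),
        richness_series=rich_series,
        population_series=pop_series,
        log=None,
        final_populations=final_pops,
    )
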