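"""Unit and property tests for the Gillespie grid engine."""

import math

import numpy as np
import pytest
from scipy import stats

from divgrid import (
    ConfigError,
    SimulationParams,
    advance_one_event,
    apply_colonization,
    apply_local_extinction,
    apply_speciation,
    init_simulation,
    run,
    total_event_rate,
)
from divgrid.sim_core import (
    COLONIZATION,
    FOUNDING,
    GridState,
    LOCAL_EXTINCTION,
    SPECIATION,
    SPECIES_EXTINCTION,
    TERM_EXTINCT,
    TERM_MAX_SPECIES,
)

from conftest import make_params


# ---------------------------------------------------------------- parameters
@pytest.mark.parametrize(
    "field,value",
    [
        ("area", 0),
        ("area", 15),  # not a perfect square
        ("local_limit", 0),
        ("speciation_rate", 0.0),
        ("colonization_rate", -1.0),
        ("local_extinction_rate", -0.5),
        ("duration", 0.0),
        ("dispersal_mode", "teleport"),
        ("max_species", 0),
    ],
)
def test_invalid_params_name_the_field(field, value):
    with pytest.raises(ConfigError, match=field):
        make_params(**{field: value})


def test_regional_limit_is_product_of_local_limit_and_area():
    assert make_params(area=256, local_limit=16).regional_limit == 4096
    assert make_params(area=4096, local_limit=1).regional_limit == 4096


# -------------------------------------------------------------------- init
def test_init_places_single_founder_population():
    params = make_params(area=256, local_limit=16, seed=1)
    state = init_simulation(params)
    assert state.richness == 1
    assert state.n_populations == 1
    occupied = [c for c in range(256) if state.cell_richness(c) > 0]
    assert len(occupied) == 1
    assert state.cell_richness(occupied[0]) == 1
    assert state.t == 0.0
    assert state.log[0].kind == FOUNDING


def test_init_single_cell_grid():
    state = init_simulation(make_params(area=1, local_limit=1))
    assert state.n_populations == 1
    assert state.cell_richness(0) == 1


def test_init_deterministic_under_fixed_seed():
    params = make_params(area=144, seed=99)
    s1, s2 = init_simulation(params), init_simulation(params)
    assert s1.population_index == s2.population_index


# -------------------------------------------------------------- total rate
def test_total_event_rate_values():
    # ten populations at the high-rate pair
    params = make_params(
        area=16, local_limit=16, speciation_rate=0.08, colonization_rate=80.0,
        local_extinction_rate=1.0,
    )
    state = init_simulation(params)
    founder = state.population_index[0][0]
    for c in range(16):
        if (founder, c) not in state._pop_pos:
            state._add_population(founder, c)
        if state.n_populations == 10:
            break
    assert total_event_rate(state, params) == pytest.approx(810.8)

    params2 = make_params(
        speciation_rate=0.05, colonization_rate=30.0, local_extinction_rate=1.0
    )
    state2 = init_simulation(params2)
    assert total_event_rate(state2, params2) == pytest.approx(31.05)

    apply_local_extinction(state2, state2.population_index[0], params2)
    assert total_event_rate(state2, params2) == 0.0


# ------------------------------------------------------------- colonization
def test_colonization_noop_when_species_fills_neighbourhood(rng):
    # 2x2 grid fully occupied by the founder: every direction is either
    # off-grid or already contains the species
    params = make_params(area=4, local_limit=2)
    state = init_simulation(params, rng)
    founder = state.population_index[0][0]
    for c in range(4):
        if (founder, c) not in state._pop_pos:
            state._add_population(founder, c)
    before = sorted(state.population_index)
    for _ in range(40):
        rec = apply_colonization(state, (founder, 0), params, rng)
        assert rec.no_effect
    assert sorted(state.population_index) == before


def test_colonization_blocked_by_saturated_target(rng):
    # K_L=1; cells 1 and 2 (the on-grid neighbours of cell 0) hold another
    # species, so colonization from cell 0 can never succeed
    params = make_params(area=4, local_limit=1)
    state = GridState(params)
    a = state._create_species(-1, 0.0)
    b = state._create_species(a, 0.0)
    state._add_population(a, 0)
    state._add_population(b, 1)
    state._add_population(b, 2)
    for _ in range(40):
        rec = apply_colonization(state, (a, 0), params, rng)
        assert rec.no_effect
    assert state.range_size(a) == 1
    state.check_consistency()


def test_global_dispersal_targets_only_eligible_cells(rng):
    params = make_params(area=4, local_limit=1, dispersal_mode="global")
    state = GridState(params)
    a = state._create_species(-1, 0.0)
    b = state._create_species(a, 0.0)
    state._add_population(a, 0)
    state._add_population(b, 3)  # only cells 1, 2 remain eligible for a
    targets = set()
    for _ in range(60):
        rec = apply_colonization(state, (a, 0), params, rng)
        if not rec.no_effect:
            targets.add(rec.cell)
            state._remove_population(a, rec.cell[0] * 2 + rec.cell[1])
    assert targets == {(0, 1), (1, 0)}


# --------------------------------------------------------------- speciation
def test_speciation_conserves_populations_and_increments_richness(rng):
    params = make_params(area=25, local_limit=4)
    state = init_simulation(params, rng)
    parent = state.population_index[0][0]
    for c in range(1, 5):
        state._add_population(parent, c)
    assert state.range_size(parent) == 5
    n_pop = state.n_populations
    rich = state.richness
    state.t = 3.0
    rec = apply_speciation(state, (parent, 2), params)
    assert state.range_size(parent) == 4
    assert state.range_size(rec.daughter) == 1
    assert state.richness == rich + 1
    assert state.n_populations == n_pop
    assert state.species_populations[parent].isdisjoint(
        state.species_populations[rec.daughter]
    )


def test_speciation_of_last_population_pseudoextinguishes_parent(rng):
    params = make_params()
    state = init_simulation(params, rng)
    parent = state.population_index[0][0]
    rich = state.richness
    state.t = 1.5
    rec = apply_speciation(state, state.population_index[0], params)
    assert parent not in state.species_populations
    assert state.species_extinction[parent] == 1.5
    assert state.species_pseudo[parent]
    assert state.richness == rich  # one out, one in
    assert state.log[-1].kind == SPECIES_EXTINCTION
    assert state.log[-1].time == rec.time


# --------------------------------------------------------- local extinction
def test_local_extinction_decrements_range(rng):
    params = make_params()
    state = init_simulation(params, rng)
    sp = state.population_index[0][0]
    for c in range(25):
        if state.range_size(sp) == 3:
            break
        if (sp, c) not in state._pop_pos:
            state._add_population(sp, c)
    assert state.range_size(sp) == 3
    target = next(iter(state.species_populations[sp]))
    apply_local_extinction(state, (sp, target), params)
    assert state.range_size(sp) == 2
    assert sp in state.species_populations
    state.check_consistency()


def test_local_extinction_of_last_population_is_species_extinction(rng):
    params = make_params()
    state = init_simulation(params, rng)
    sp, cell = state.population_index[0]
    state.t = 2.25
    apply_local_extinction(state, (sp, cell), params)
    assert sp not in state.species_populations
    assert state.richness == 0
    kinds = [r.kind for r in state.log[-2:]]
    assert kinds == [LOCAL_EXTINCTION, SPECIES_EXTINCTION]
    assert state.log[-1].time == state.log[-2].time == 2.25


# ------------------------------------------------------------------- events
def test_zero_rate_processes_never_fire(rng):
    params = make_params(
        area=4, local_limit=4, colonization_rate=0.0, local_extinction_rate=0.0,
        duration=5.0,
    )
    state = init_simulation(params, rng)
    for _ in range(50):
        advance_one_event(state, params, rng)
    kinds = {r.kind for r in state.log}
    assert kinds <= {FOUNDING, SPECIATION, SPECIES_EXTINCTION}


def test_event_kind_frequencies_and_waiting_times():
    """Event kinds follow the multinomial law lambda:gamma:mu and rescaled
    waiting times are Exponential(1)."""
    params = make_params(
        area=100, local_limit=4, speciation_rate=0.5, colonization_rate=3.0,
        local_extinction_rate=0.5, duration=1e9, seed=11,
    )
    rng = np.random.default_rng(11)
    state = init_simulation(params, rng)
    n_events = 100_000
    scaled_dts = np.empty(n_events)
    t_prev = 0.0
    for i in range(n_events):
        rate = total_event_rate(state, params)
        rec = advance_one_event(state, params, rng)
        scaled_dts[i] = (rec.time - t_prev) * rate
        t_prev = rec.time
    counts = {SPECIATION: 0, COLONIZATION: 0, LOCAL_EXTINCTION: 0}
    for r in state.log:
        if r.kind in counts:
            counts[r.kind] += 1
    observed = np.array([counts[SPECIATION], counts[COLONIZATION], counts[LOCAL_EXTINCTION]])
    expected = np.array([0.5, 3.0, 0.5]) / 4.0 * observed.sum()
    chi2 = stats.chisquare(observed, expected)
    assert chi2.pvalue > 1e-3
    ks = stats.kstest(scaled_dts, "expon")
    assert ks.pvalue > 1e-3


def test_population_count_changes_by_at_most_one(rng):
    params = make_params(area=16, local_limit=2, duration=1e9, seed=3)
    state = init_simulation(params, rng)
    n_prev = state.n_populations
    for _ in range(5000):
        if state.n_populations == 0:
            break
        rec = advance_one_event(state, params, rng)
        delta = state.n_populations - n_prev
        if rec.kind == COLONIZATION and not rec.no_effect:
            assert delta == 1
        elif rec.kind == LOCAL_EXTINCTION:
            assert delta == -1
        else:
            assert delta == 0
        n_prev = state.n_populations


def test_zero_local_extinction_reaches_saturated_absorbing_state():
    params = make_params(
        area=4, local_limit=2, speciation_rate=1.0, colonization_rate=5.0,
        local_extinction_rate=0.0, duration=200.0, seed=5,
    )
    result = run(params, engine="python")
    state = result.state
    assert all(state.cell_richness(c) == 2 for c in range(4))
    assert state.richness == params.regional_limit == 8
    assert all(state.range_size(s) == 1 for s in state.extant_species())
    assert np.all(np.diff(result.richness_series) >= 0)


def test_single_cell_clade_lifetime_is_exponential_in_mu():
    """With A=1, K_L=1 colonization is always a no-op and speciation only
    relabels, so the clade dies at the first local extinction: lifetime
    ~ Exponential(mu)."""
    mu = 2.0
    lifetimes = []
    for seed in range(2000):
        params = make_params(
            area=1, local_limit=1, speciation_rate=0.5, colonization_rate=7.0,
            local_extinction_rate=mu, duration=200.0, seed=seed,
        )
        r = run(params, engine="fast")
        assert r.extinct
        lifetimes.append(r.t_final)
    mean = np.mean(lifetimes)
    se = np.std(lifetimes) / math.sqrt(len(lifetimes))
    assert abs(mean - 1.0 / mu) < 3 * se


def test_single_cell_colonizations_are_all_noops():
    params = make_params(
        area=1, local_limit=1, speciation_rate=0.1, colonization_rate=50.0,
        local_extinction_rate=0.05, duration=50.0, seed=8,
    )
    r = run(params, engine="python")
    colonizations = [rec for rec in r.log if rec.kind == COLONIZATION]
    assert colonizations and all(rec.no_effect for rec in colonizations)


# ------------------------------------------------------------- run contract
def test_run_is_deterministic_per_seed():
    params = make_params(area=16, local_limit=2, duration=5.0, seed=21)
    r1, r2 = run(params, engine="python"), run(params, engine="python")
    assert [(e.time, e.kind, e.species) for e in r1.log] == [
        (e.time, e.kind, e.species) for e in r2.log
    ]
    f1, f2 = run(params, engine="fast"), run(params, engine="fast")
    np.testing.assert_array_equal(f1.species_origin, f2.species_origin)
    np.testing.assert_array_equal(f1.final_populations, f2.final_populations)


def test_species_cap_flags_truncation():
    # mu=0: the clade cannot die, so ongoing speciation must hit the cap
    params = make_params(
        area=16, local_limit=4, speciation_rate=1.0, colonization_rate=5.0,
        local_extinction_rate=0.0, duration=1e6, max_species=25, seed=2,
    )
    for engine in ("python", "fast"):
        r = run(params, engine=engine)
        assert r.termination == TERM_MAX_SPECIES
        assert r.n_species_created <= 25


def test_engines_agree_on_richness_distribution():
    """Python and numba engines sample the same process: compare final
    richness across replicates with a rank-sum test."""
    rich = {"python": [], "fast": []}
    for engine in rich:
        for seed in range(150):
            params = make_params(
                area=9, local_limit=2, speciation_rate=0.5, colonization_rate=4.0,
                local_extinction_rate=0.8, duration=6.0, seed=seed + 1000,
            )
            r = run(params, engine=engine)
            rich[engine].append(r.richness_series[-1])
    test = stats.mannwhitneyu(rich["python"], rich["fast"])
    assert test.pvalue > 1e-3


def test_clade_extinction_terminates_run():
    params = make_params(
        area=4, local_limit=1, speciation_rate=0.05, colonization_rate=0.1,
        local_extinction_rate=5.0, duration=100.0, seed=1,
    )
    r = run(params, engine="python")
    assert r.termination == TERM_EXTINCT
    assert r.state.n_populations == 0
    assert r.t_final < 100.0
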