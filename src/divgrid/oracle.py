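"""Exact master-equation solver for tiny grids.

Enumerates every system configuration reachable from the single-founder
start, canonicalized up to species relabelling (the model is neutral, so a
configuration is fully described by the multiset of occupied cell-sets,
with cells kept distinct because geometry matters under local dispersal).
Builds the sparse generator of the continuous-time Markov chain and solves
linear systems for exact quantities — mean time to clade extinction, and the
transient state distribution at a fixed time — against which the stochastic
engines are validated.  Intended for A and K_L of a few cells only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import expm_multiply, spsolve

from .sim_core import SimulationParams

__all__ = ["StateSpace", "enumerate_states", "expected_absorption_time", "transient_distribution"]

# canonical state: sorted tuple of per-species sorted cell tuples
State = tuple[tuple[int, ...], ...]

EMPTY: State = ()


def _canonical(ranges: list[tuple[int, ...]]) -> State:
    return tuple(sorted(tuple(sorted(r)) for r in ranges if r))


def _cell_counts(state: State, A: int) -> np.ndarray:
    counts = np.zeros(A, dtype=np.int64)
    for rng in state:
        for c in rng:
            counts[c] += 1
    return counts


def _transitions(state: State, params: SimulationParams) -> dict[State, float]:
    """Outgoing rates from one canonical state (no-ops/self-loops omitted)."""
    A = params.area
    L = params.side
    K_L = params.local_limit
    lam, gam, mu = (
        params.speciation_rate,
        params.colonization_rate,
        params.local_extinction_rate,
    )
    counts = _cell_counts(state, A)
    out: dict[State, float] = {}

    def add(new_state: State, rate: float) -> None:
        if new_state != state and rate > 0:
            out[new_state] = out.get(new_state, 0.0) + rate

    ranges = [set(r) for r in state]
    for i, rng in enumerate(ranges):
        for c in rng:
            # speciation: relabel population (i, c) as a new singleton species
            new = [set(r) for r in ranges]
            new[i] = rng - {c}
            new.append({c})
            add(_canonical([tuple(r) for r in new]), lam)
            # local extinction of population (i, c)
            new = [set(r) for r in ranges]
            new[i] = rng - {c}
            add(_canonical([tuple(r) for r in new]), mu)
            # colonization from population (i, c)
            if params.dispersal_mode == "local":
                r0, c0 = divmod(c, L)
                for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    tr, tc = r0 + dr, c0 + dc
                    if not (0 <= tr < L and 0 <= tc < L):
                        continue
                    tgt = tr * L + tc
                    if tgt in rng or counts[tgt] >= K_L:
                        continue
                    new = [set(r) for r in ranges]
                    new[i] = rng | {tgt}
                    add(_canonical([tuple(r) for r in new]), gam / 4.0)
            else:
                eligible = [
                    t for t in range(A) if t not in rng and counts[t] < K_L
                ]
                for tgt in eligible:
                    new = [set(r) for r in ranges]
                    new[i] = rng | {tgt}
                    add(_canonical([tuple(r) for r in new]), gam / len(eligible))
    return out


@dataclass
class StateSpace:
    """Reachable canonical states with their sparse rate generator.

    ``generator`` has Q[i, j] = rate i->j and Q[i, i] = -row sum; ``p0`` is
    the initial distribution (founder cell uniform over the grid).
    """

    params: SimulationParams
    states: list[State]
    index: dict[State, int]
    generator: sparse.csr_matrix
    p0: np.ndarray

    @property
    def n_states(self) -> int:
        return len(self.states)

    def absorbing(self) -> list[State]:
        rates = -self.generator.diagonal()
        return [s for s, r in zip(self.states, rates) if r <= 0]

    def richness_of(self, state: State) -> int:
        return len(state)


def enumerate_states(params: SimulationParams, max_states: int = 100_000) -> StateSpace:
    """BFS over reachable canonical states from the single-founder start."""
    initial = [_canonical([(c,)]) for c in range(params.area)]
    index: dict[State, int] = {}
    states: list[State] = []
    frontier = []
    for s in dict.fromkeys(initial):
        index[s] = len(states)
        states.append(s)
        frontier.append(s)
    rows, cols, vals = [], [], []
    while frontier:
        nxt = []
        for s in frontier:
            i = index[s]
            total = 0.0
            for t, rate in _transitions(s, params).items():
                if t not in index:
                    if len(states) >= max_states:
                        raise RuntimeError(
                            f"state bound {max_states} exceeded (at least "
                            f"{len(states) + 1} reachable states)"
                        )
                    index[t] = len(states)
                    states.append(t)
                    nxt.append(t)
                j = index[t]
                rows.append(i)
                cols.append(j)
                vals.append(rate)
                total += rate
            rows.append(i)
            cols.append(i)
            vals.append(-total)
        frontier = nxt
    n = len(states)
    Q = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    p0 = np.zeros(n)
    for s in initial:
        p0[index[s]] += 1.0 / params.area
    return StateSpace(params=params, states=states, index=index, generator=Q, p0=p0)


def expected_absorption_time(
    space: StateSpace, from_state: Optional[State] = None
) -> float:
    """Mean time to clade extinction (the empty state); inf if unreachable.

    Solves Q_tt tau = -1 over transient states.  ``from_state=None`` averages
    over the initial distribution (uniform founder cell).
    """
    if EMPTY not in space.index:
        return math.inf
    n = space.n_states
    absorbing = {space.index[EMPTY]}
    transient = np.array([i for i in range(n) if i not in absorbing])
    Q_tt = space.generator[transient][:, transient]
    tau_t = spsolve(Q_tt.tocsc(), -np.ones(len(transient)))
    tau = np.zeros(n)
    tau[transient] = tau_t
    if from_state is not None:
        return float(tau[space.index[_canonical([tuple(r) for r in from_state])]])
    return float(space.p0 @ tau)


def transient_distribution(space: StateSpace, t: float) -> np.ndarray:
    """Exact state distribution at time t from the initial distribution."""
    return expm_multiply(space.generator.T.tocsc() * t, space.p0)
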