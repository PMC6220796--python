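"""Lineage trees from the event record: full and reconstructed views.

Speciation in the model is budding: the parent keeps its identity and
origination time while the daughter branches off with a new id aged from the
speciation time.  The full tree therefore has one tip per species ever
created, with each speciation an internal node on the parent's unbroken
lifeline.  The reconstructed tree retains only lineages ancestral to species
extant at the present; pruning suppresses the unary nodes it creates and
preserves branch lengths in simulation time units.

All traversals are iterative so deep (caterpillar-like) trees do not hit the
interpreter recursion limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .sim_core import (
    EventRecord,
    FOUNDING,
    SPECIATION,
    SPECIES_EXTINCTION,
    RunResult,
)

__all__ = [
    "Clade",
    "LineageTree",
    "PhyloTree",
    "build_full_tree",
    "reconstructed_tree",
    "write_newick",
]


@dataclass
class Clade:
    """One node of a binary time-tree; ``time`` is absolute simulation time."""

    time: float
    children: list["Clade"] = field(default_factory=list)
    label: Optional[int] = None

    @property
    def is_tip(self) -> bool:
        return not self.children


class LineageTree:
    """Ancestor–descendant history of species, tabular form.

    Creation-ordered arrays keyed by species id: ``parent`` (-1 for the
    founder), ``origin`` time, ``extinction`` time (NaN while extant at the
    present), ``pseudo`` flag for extinctions caused by speciation.
    ``present`` is the time at which extancy is assessed (usually T).
    """

    def __init__(
        self,
        parent: np.ndarray,
        origin: np.ndarray,
        extinction: np.ndarray,
        present: float,
        pseudo: Optional[np.ndarray] = None,
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.origin = np.asarray(origin, dtype=np.float64)
        self.extinction = np.asarray(extinction, dtype=np.float64)
        self.present = float(present)
        self.pseudo = (
            np.asarray(pseudo, dtype=bool)
            if pseudo is not None
            else np.zeros(len(self.parent), dtype=bool)
        )
        n = len(self.parent)
        if not (len(self.origin) == len(self.extinction) == n):
            raise ValueError("parent/origin/extinction arrays must have equal length")
        bad = (self.parent >= np.arange(n)) & (np.arange(n) > 0)
        if bad.any() or (n > 0 and self.parent[0] != -1):
            raise ValueError("corrupt log: daughter ids must follow their parent")

    @classmethod
    def from_run(cls, result: RunResult) -> "LineageTree":
        present = result.params.duration if not result.extinct else result.t_final
        return cls(
            result.species_parent,
            result.species_origin,
            result.species_extinction,
            present=present,
            pseudo=result.species_pseudo,
        )

    # -- basic accessors ---------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.parent)

    def is_extant(self) -> np.ndarray:
        return np.isnan(self.extinction)

    def extant_ids(self) -> np.ndarray:
        return np.flatnonzero(self.is_extant())

    def tip_time(self, s: int) -> float:
        e = self.extinction[s]
        return self.present if math.isnan(e) else float(e)

    def ages(self, at_time: Optional[float] = None) -> np.ndarray:
        """Age (time since origination) of each extant species."""
        t = self.present if at_time is None else at_time
        return t - self.origin[self.extant_ids()]

    def lineages_alive_at(self, t: float) -> int:
        """Full-tree lineage count: species with origin <= t < extinction."""
        alive = (self.origin <= t) & (np.isnan(self.extinction) | (self.extinction > t))
        return int(alive.sum())

    def total_branch_length(self) -> float:
        ends = np.where(np.isnan(self.extinction), self.present, self.extinction)
        return float((ends - self.origin).sum())

    def _children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_species)]
        for d in range(1, self.n_species):
            ch[self.parent[d]].append(d)  # creation order = time order
        return ch

    # -- binary tree construction -----------------------------------------
    def to_phylo(self) -> "PhyloTree":
        """Full binary time-tree: one tip per species ever created."""
        return self._build(keep=np.ones(self.n_species, dtype=bool), tip_times=None)

    def _build(self, keep: np.ndarray, tip_times) -> "PhyloTree":
        if not keep.any():
            return PhyloTree(None, root_time=0.0, present=self.present)
        children = self._children()
        sub: dict[int, Clade] = {}
        # daughters have larger ids, so reverse creation order guarantees
        # every kept daughter subtree exists before its parent's lifeline
        for s in range(self.n_species - 1, -1, -1):
            if not keep[s]:
                continue
            ds = [d for d in children[s] if keep[d]]
            extant_here = math.isnan(self.extinction[s])
            if extant_here:
                node = Clade(self.present, label=int(s))
            elif tip_times is None:
                node = Clade(float(self.extinction[s]), label=int(s))
            else:
                # extinct species on a reconstructed path: continue into the
                # last surviving daughter (unary node suppressed)
                node = sub.pop(ds[-1])
                ds = ds[:-1]
            for d in reversed(ds):
                node = Clade(float(self.origin[d]), children=[node, sub.pop(d)])
            sub[s] = node
        return PhyloTree(sub[0], root_time=0.0, present=self.present)

    def reconstructed(self) -> "PhyloTree":
        """Tree spanning only lineages ancestral to extant species."""
        keep = self.is_extant().copy()
        for d in range(self.n_species - 1, 0, -1):
            if keep[d]:
                keep[self.parent[d]] = True
        if not keep.any():
            return PhyloTree(None, root_time=0.0, present=self.present)
        return self._build(keep=keep, tip_times="extant")


class PhyloTree:
    """A binary time-tree with an explicit stem.

    ``root_time`` is where the stem starts (0 for simulation trees);
    ``root.time`` is the first node (crown for reconstructed trees).  A
    one-tip tree is a bare stem; ``root is None`` encodes the empty tree of
    a fully extinct clade.
    """

    def __init__(self, root: Optional[Clade], root_time: float, present: float):
        self.root = root
        self.root_time = float(root_time)
        self.present = float(present)

    @property
    def is_empty(self) -> bool:
        return self.root is None

    def _traverse(self) -> Iterable[Clade]:
        if self.root is None:
            return
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    @property
    def n_tips(self) -> int:
        return sum(1 for n in self._traverse() if n.is_tip)

    def tip_labels(self) -> list[int]:
        return [n.label for n in self._traverse() if n.is_tip]

    def internal_node_times(self) -> np.ndarray:
        return np.sort(np.array([n.time for n in self._traverse() if not n.is_tip]))

    def lineages_at(self, t: float) -> int:
        """Lineages crossing time t, counting the stem as 1 from root_time."""
        if self.root is None:
            return 0
        if t < self.root_time:
            return 0
        return 1 + int(np.searchsorted(self.internal_node_times(), t, side="right"))

    def ltt(self) -> tuple[np.ndarray, np.ndarray]:
        """Step function (times, lineage counts) of the tree's LTT."""
        times = self.internal_node_times()
        counts = 1 + np.arange(1, len(times) + 1)
        return np.concatenate([[self.root_time], times]), np.concatenate([[1], counts])

    def total_branch_length(self) -> float:
        total = 0.0
        if self.root is None:
            return 0.0
        stack = [(self.root, self.root_time)]
        while stack:
            node, parent_time = stack.pop()
            total += node.time - parent_time
            for ch in node.children:
                stack.append((ch, node.time))
        return total

    def tip_depths(self) -> list[int]:
        """Number of internal nodes on each root-to-tip path (root counts 1)."""
        if self.root is None:
            return []
        out = []
        stack = [(self.root, 0)]
        while stack:
            node, depth = stack.pop()
            if node.is_tip:
                out.append(depth)
            else:
                for ch in node.children:
                    stack.append((ch, depth + 1))
        return out

    def root_to_tip_lengths(self) -> list[float]:
        if self.root is None:
            return []
        out = []
        stack = [(self.root, self.root_time)]
        while stack:
            node, _ = stack.pop()
            if node.is_tip:
                out.append(node.time - self.root_time)
            else:
                for ch in node.children:
                    stack.append((ch, node.time))
        return [t for t in out]

    def prune_extinct(self, at_time: Optional[float] = None, eps: float = 1e-9) -> "PhyloTree":
        """Drop tips extinct before ``at_time`` and suppress unary nodes."""
        t = self.present if at_time is None else at_time
        if self.root is None:
            return PhyloTree(None, self.root_time, self.present)
        # iterative post-order rebuild
        pruned: dict[int, Optional[Clade]] = {}
        stack: list[tuple[Clade, bool]] = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if node.is_tip:
                pruned[id(node)] = (
                    Clade(node.time, label=node.label) if node.time >= t - eps else None
                )
                continue
            if not done:
                stack.append((node, True))
                for ch in node.children:
                    stack.append((ch, False))
                continue
            kept = [pruned[id(ch)] for ch in node.children]
            kept = [k for k in kept if k is not None]
            if not kept:
                pruned[id(node)] = None
            elif len(kept) == 1:
                pruned[id(node)] = kept[0]
            else:
                pruned[id(node)] = Clade(node.time, children=kept)
        return PhyloTree(pruned[id(self.root)], self.root_time, self.present)

    # -- serialization -----------------------------------------------------
    def to_newick(self, label_prefix: str = "s") -> str:
        """Newick string with branch lengths in simulation time units."""
        if self.root is None:
            raise ValueError("refusing to serialize an empty tree")
        parts: list[str] = []
        # iterative pre/post traversal emitting newick tokens
        stack: list[tuple[object, float]] = [(self.root, self.root_time)]
        while stack:
            item, ptime = stack.pop()
            if isinstance(item, str):
                parts.append(item)
                continue
            node = item
            blen = node.time - ptime
            if node.is_tip:
                parts.append(f"{label_prefix}{node.label}:{blen:.17g}")
            else:
                parts.append("(")
                tail = f"):{blen:.17g}"
                stack.append((tail, 0.0))
                for i, ch in enumerate(reversed(node.children)):
                    if i > 0:
                        stack.append((",", 0.0))
                    stack.append((ch, node.time))
        return "".join(parts) + ";"


def build_full_tree(log: Sequence[EventRecord], present: Optional[float] = None) -> LineageTree:
    """Build the tabular lineage tree from a complete, time-ordered event log."""
    parents: list[int] = []
    origins: list[float] = []
    ids: dict[int, int] = {}
    last_t = -math.inf
    for rec in log:
        if rec.time < last_t:
            raise ValueError("corrupt log: events out of time order")
        last_t = rec.time
        if rec.kind == FOUNDING:
            ids[rec.species] = len(parents)
            parents.append(-1)
            origins.append(rec.time)
        elif rec.kind == SPECIATION:
            if rec.species not in ids:
                raise ValueError(f"corrupt log: unknown parent species {rec.species}")
            ids[rec.daughter] = len(parents)
            parents.append(ids[rec.species])
            origins.append(rec.time)
    ext = np.full(len(parents), np.nan)
    pseudo = np.zeros(len(parents), dtype=bool)
    for rec in log:
        if rec.kind == SPECIES_EXTINCTION:
            ext[ids[rec.species]] = rec.time
            pseudo[ids[rec.species]] = rec.pseudo
    if present is None:
        present = last_t if log else 0.0
    return LineageTree(np.array(parents), np.array(origins), ext, present=present, pseudo=pseudo)


def reconstructed_tree(tree: LineageTree) -> PhyloTree:
    """Prune to lineages ancestral to extant species (empty tree if none)."""
    return tree.reconstructed()


def write_newick(tree: PhyloTree, path) -> None:
    """Write a PhyloTree to a Newick file (refuses on an empty tree)."""
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
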