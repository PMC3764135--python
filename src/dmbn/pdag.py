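"""Causal interpretation of a learned DAG as a partially directed graph.

A learned Bayesian network is one member of a Markov equivalence class: all
members share the skeleton and the v-structures (colliders a -> c <- b with
a, b non-adjacent) but may disagree on other edge directions.  An edge is
*compelled* when it has the same orientation in every member; the compelled
edges plus the undirected remainder form a PDAG.

Template asymmetries (pairs where only one orientation was licensed) are
prior causal knowledge: they are imposed as background orientations before
closing under Meek's rules R1-R4, which extends the compelled set beyond
what the equivalence class alone determines.

  R1: a -> b, b - c, a and c non-adjacent        =>  b -> c
  R2: a -> b -> c, a - c                          =>  a -> c
  R3: a - b, a - c, a - d, c -> b, d -> b,
      c and d non-adjacent                        =>  a -> b
  R4: a - b, a - c, c -> d, d -> b,
      c and b non-adjacent                        =>  a -> b
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx

from .errors import ConsistencyError, StructureError
from .search import DirectedNetwork

__all__ = ["PartiallyDirectedNetwork", "to_pdag", "read_pdag", "write_pdag"]

logger = logging.getLogger(__name__)


@dataclass
class PartiallyDirectedNetwork:
    """Compelled (directed) and non-compelled (undirected) edges."""

    node_ids: tuple[str, ...]
    directed: set[tuple[str, str]] = field(default_factory=set)
    undirected: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.node_ids = tuple(self.node_ids)
        self.undirected = {tuple(sorted(e)) for e in self.undirected}
        dir_pairs = {tuple(sorted(e)) for e in self.directed}
        if dir_pairs & self.undirected:
            clash = sorted(dir_pairs & self.undirected)[0]
            raise StructureError(f"edge {clash} is both directed and undirected")

    def skeleton(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.directed} | self.undirected

    def n_edges(self) -> int:
        return len(self.directed) + len(self.undirected)


class _Pdag:
    """Mutable working representation during rule closure."""

    def __init__(self, nodes: tuple[str, ...], skeleton: set[tuple[str, str]]):
        self.nodes = nodes
        self.adj: dict[str, set[str]] = {n: set() for n in nodes}
        for a, b in skeleton:
            self.adj[a].add(b)
            self.adj[b].add(a)
        self.directed: set[tuple[str, str]] = set()

    def adjacent(self, a: str, b: str) -> bool:
        return b in self.adj[a]

    def is_undirected(self, a: str, b: str) -> bool:
        return self.adjacent(a, b) and (a, b) not in self.directed and (b, a) not in self.directed

    def orient(self, a: str, b: str, why: str) -> bool:
        """Direct a - b as a -> b; returns True if this was new."""
        if (a, b) in self.directed:
            return False
        if (b, a) in self.directed:
            raise ConsistencyError(
                f"cannot orient {a} -> {b} ({why}): already oriented {b} -> {a}"
            )
        self.directed.add((a, b))
        return True


def _v_structures(g: DirectedNetwork) -> set[tuple[str, str]]:
    """Directed edges taking part in some collider a -> c <- b, a,b non-adjacent."""
    parents: dict[str, list[str]] = {n: [] for n in g.node_ids}
    adj: set[tuple[str, str]] = set()
    for a, b in g.edges:
        parents[b].append(a)
        adj.add((a, b))
        adj.add((b, a))
    out: set[tuple[str, str]] = set()
    for c, pars in parents.items():
        for a, b in combinations(sorted(pars), 2):
            if (a, b) not in adj:
                out.add((a, c))
                out.add((b, c))
    return out


def _meek_closure(p: _Pdag) -> None:
    changed = True
    while changed:
        changed = False
        for a in p.nodes:
            for b in p.adj[a]:
                if not p.is_undirected(a, b):
                    continue
                # R1: some c -> a with c, b non-adjacent  =>  a -> b
                if any(
                    (c, a) in p.directed and not p.adjacent(c, b)
                    for c in p.adj[a]
                    if c != b
                ):
                    changed |= p.orient(a, b, "R1")
                    continue
                # R2: a -> c -> b with a - b  =>  a -> b
                if any(
                    (a, c) in p.directed and (c, b) in p.directed
                    for c in p.adj[a]
                    if c != b and p.adjacent(c, b)
                ):
                    changed |= p.orient(a, b, "R2")
                    continue
                # R3: a - c -> b and a - d -> b, c,d non-adjacent  =>  a -> b
                spokes = [
                    c
                    for c in p.adj[a]
                    if c != b and p.is_undirected(a, c) and (c, b) in p.directed
                ]
                if any(
                    not p.adjacent(c, d)
                    for c, d in combinations(sorted(spokes), 2)
                ):
                    changed |= p.orient(a, b, "R3")
                    continue
                # R4: a - c, c -> d, d -> b, c,b non-adjacent  =>  a -> b
                r4 = False
                for c in p.adj[a]:
                    if c == b or not p.is_undirected(a, c) or p.adjacent(c, b):
                        continue
                    if any(
                        (c, d) in p.directed and (d, b) in p.directed
                        for d in p.adj[c]
                        if d not in (a, b)
                    ):
                        r4 = True
                        break
                if r4:
                    changed |= p.orient(a, b, "R4")


def to_pdag(
    g: DirectedNetwork, background: set[tuple[str, str]] | None = None
) -> PartiallyDirectedNetwork:
    """Compelled/non-compelled dissection of a DAG under background knowledge.

    `background` holds directed pairs (typically the template's asymmetric
    constraints); pairs whose edge is absent from the DAG are ignored with a
    warning, while a pair contradicting a v-structure orientation raises
    :class:`ConsistencyError`.
    """
    skeleton = {tuple(sorted(e)) for e in g.edges}
    p = _Pdag(g.node_ids, skeleton)

    for a, b in sorted(_v_structures(g)):
        p.orient(a, b, "v-structure")

    for a, b in sorted(background or set()):
        if (a, b) in g.edges:
            p.orient(a, b, "background")
        elif (b, a) in g.edges:
            # the template licensed a -> b only, yet the DAG carries b -> a;
            # surfacing it beats silently flipping
            raise ConsistencyError(
                f"background {a} -> {b} contradicts learned edge {b} -> {a}"
            )
        else:
            logger.warning("background pair %s -> %s absent from graph; ignored", a, b)

    _meek_closure(p)

    directed = set(p.directed)
    undirected = {
        e for e in skeleton if e not in directed and e[::-1] not in directed
    }
    dg = nx.DiGraph(directed)
    if directed and not nx.is_directed_acyclic_graph(dg):
        raise StructureError("orientation closure produced a directed cycle")
    return PartiallyDirectedNetwork(g.node_ids, directed, undirected)


def write_pdag(net: PartiallyDirectedNetwork, path: str | Path) -> None:
    """Edge-list TSV: source, target, type; undirected rows written once
    with the lexicographically smaller node first."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\ttype\n")
        for a, b in sorted(net.directed):
            fh.write(f"{a}\t{b}\tdirected\n")
        for a, b in sorted(net.undirected):
            fh.write(f"{a}\t{b}\tundirected\n")


def read_pdag(path: str | Path) -> PartiallyDirectedNetwork:
    directed: set[tuple[str, str]] = set()
    undirected: set[tuple[str, str]] = set()
    nodes: set[str] = set()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("source"):
            raise StructureError(f"{path}: missing edge-list header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            a, b, kind = line.split("\t")
            nodes.update((a, b))
            if kind == "directed":
                directed.add((a, b))
            elif kind == "undirected":
                undirected.add((a, b))
            else:
                raise StructureError(f"{path}: unknown edge type {kind!r}")
    return PartiallyDirectedNetwork(tuple(sorted(nodes)), directed, undirected)
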