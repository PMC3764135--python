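"""Penalized-KGV scoring and TABU structure search over template-consistent DAGs.

The local score of a node x with parent set Pa is

    score(x | Pa) = N * ( J({x} u Pa) - J(Pa) )  -  omega * (d |Pa| / 2) * log N

with J the KGV multi-information (nats) over the DM-kernel features, N the
number of genes, and d = 4 the number of parameters a parent contributes:
the DM kernel factorizes through a 2-dimensional feature map, so each
parent-child link is a full 2 x 2 cross-covariance block.  The first term
is the kernel analogue of the fitted log-likelihood gain; the second is the
BIC complexity penalty whose multiplicative weight omega is the sparsity
knob: larger omega yields sparser, higher-precision networks.  Charging the
full block dimension matters: on sparse signed profiles the KGV null
distribution for an irrelevant parent is inflated well beyond the classical
chi-square scale (the residual variance clusters on the few responsive
genes), and a 1-parameter penalty admits spurious edges at the omega values
of practical interest.  The network score is the sum of local scores
(decomposable), so a single edge move touches at most two local terms.

Search is greedy-ascent TABU over add / delete / reverse moves starting from
the empty graph: each step applies the legal move with the largest score
change (possibly negative, which is how the search escapes shallow optima);
the inverse of an applied move is forbidden for `tabu_tenure` steps unless it
would beat the best score seen (aspiration).  Acyclicity is maintained by an
incremental reachability checker rather than a from-scratch traversal per
candidate move.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx

from .errors import DimensionError, StructureError
from .io import PerturbationMatrix
from .kernel import KgvConfig, KgvEngine
from .template import TemplateMatrix

__all__ = [
    "DirectedNetwork",
    "SearchConfig",
    "AcyclicityGuard",
    "local_score",
    "network_score",
    "tabu_search",
]

logger = logging.getLogger(__name__)

# each parent contributes a 2 x 2 cross-covariance block of feature parameters
PARAMS_PER_PARENT = 4


@dataclass
class DirectedNetwork:
    """A DAG over the mutant labels: edges are (parent, child) pairs."""

    node_ids: tuple[str, ...]
    edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.node_ids = tuple(self.node_ids)
        nodes = set(self.node_ids)
        for a, b in self.edges:
            if a == b:
                raise StructureError(f"self-loop on {a!r}")
            if a not in nodes or b not in nodes:
                raise StructureError(f"edge ({a!r}, {b!r}) uses unknown node")
        if not self.is_acyclic():
            raise StructureError("graph contains a directed cycle")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from(self.edges)
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_networkx())

    def parents(self, node: str) -> set[str]:
        return {a for a, b in self.edges if b == node}


@dataclass(frozen=True)
class SearchConfig:
    """Search and scoring settings.

    omega   : weight of the complexity penalty (>= 0); the sparsity knob.
    kappa   : KGV ridge regularization (> 0).
    tabu_tenure : moves for which the inverse of an applied move stays tabu.
    patience    : consecutive non-improving moves before stopping.
    max_iterations : hard cap on moves (default 10 * R^2 when None).
    max_parents    : optional cap on parent-set size.
    seed    : reserved for randomized restarts; the default search is
              deterministic (lexicographic tie-breaking).
    """

    omega: float = 2.0
    kappa: float = 0.01
    tabu_tenure: int = 10
    patience: int = 20
    max_iterations: int | None = None
    max_parents: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.tabu_tenure < 0:
            raise ValueError("tabu_tenure must be >= 0")
        KgvConfig(self.kappa)  # validates kappa


class AcyclicityGuard:
    """Incremental acyclicity oracle for edge add/delete/reverse moves.

    Maintains the full reachability relation (`reach[a]` = nodes reachable
    from a, excluding a itself unless on a cycle, which never happens here).
    Adding a -> b is unsafe iff b already reaches a; reversing a -> b is
    unsafe iff an alternative a ~> b path survives removal of the edge.
    Additions update reachability in O(R^2); deletions recompute the affected
    relation by traversal, which is the standard trade-off for sparse search
    graphs where additions dominate.
    """

    def __init__(self, g: DirectedNetwork) -> None:
        self._children: dict[str, set[str]] = {n: set() for n in g.node_ids}
        for a, b in g.edges:
            self._children[a].add(b)
        self._rebuild()

    def _rebuild(self) -> None:
        self.reach: dict[str, set[str]] = {}
        for n in self._children:
            seen: set[str] = set()
            stack = list(self._children[n])
            while stack:
                x = stack.pop()
                if x in seen:
                    continue
                seen.add(x)
                stack.extend(self._children[x] - seen)
            self.reach[n] = seen

    def has_edge(self, a: str, b: str) -> bool:
        return b in self._children[a]

    def would_create_cycle(self, move: tuple[str, str, str]) -> bool:
        """`move` is (kind, a, b) with kind in {'add', 'delete', 'reverse'}."""
        kind, a, b = move
        if kind == "add":
            if self.has_edge(a, b):
                raise ValueError(f"edge ({a!r}, {b!r}) already present")
            return a in self.reach[b]
        if kind == "delete":
            if not self.has_edge(a, b):
                raise ValueError(f"no edge ({a!r}, {b!r}) to delete")
            return False
        if kind == "reverse":
            if not self.has_edge(a, b):
                raise ValueError(f"no edge ({a!r}, {b!r}) to reverse")
            # unsafe iff another a ~> b path exists besides the edge itself
            seen: set[str] = set()
            stack = [c for c in self._children[a] if c != b]
            while stack:
                x = stack.pop()
                if x == b:
                    return True
                if x in seen:
                    continue
                seen.add(x)
                stack.extend(self._children[x] - seen)
            return False
        raise ValueError(f"unknown move kind {kind!r}")

    def apply(self, move: tuple[str, str, str]) -> None:
        kind, a, b = move
        if kind == "add":
            self._children[a].add(b)
            # a and everything reaching a now also reach b and b's cone
            cone = {b} | self.reach[b]
            for n, r in self.reach.items():
                if n == a or a in r:
                    r |= cone
        elif kind == "delete":
            self._children[a].discard(b)
            self._rebuild()
        elif kind == "reverse":
            self._children[a].discard(b)
            self._children[b].add(a)
            self._rebuild()
        else:
            raise ValueError(f"unknown move kind {kind!r}")


class _Scorer:
    """Cached local-score evaluator over a fixed dataset."""

    def __init__(self, data: PerturbationMatrix, cfg: SearchConfig) -> None:
        self.engine = KgvEngine(data, KgvConfig(cfg.kappa))
        self.n = data.n_genes
        self.omega = cfg.omega
        self._cache: dict[tuple[str, frozenset[str]], float] = {}

    def local(self, child: str, parents: frozenset[str]) -> float:
        if child in parents:
            raise ValueError(f"{child!r} cannot be its own parent")
        if not parents:
            return 0.0
        key = (child, parents)
        if key not in self._cache:
            ordered = sorted(parents)
            gain = self.engine.multiinfo([child] + ordered) - self.engine.multiinfo(ordered)
            penalty = (
                self.omega
                * (PARAMS_PER_PARENT * len(parents) / 2.0)
                * math.log(self.n)
            )
            self._cache[key] = self.n * gain - penalty
        return self._cache[key]


def local_score(
    child: str,
    parents: set[str],
    data: PerturbationMatrix,
    cfg: SearchConfig,
) -> float:
    """Penalized local score of `child` given `parents` (nats)."""
    missing = ({child} | set(parents)) - set(data.mutant_ids)
    if missing:
        raise DimensionError(f"nodes not in matrix: {sorted(missing)}")
    return _Scorer(data, cfg).local(child, frozenset(parents))


def network_score(
    g: DirectedNetwork,
    data: PerturbationMatrix,
    cfg: SearchConfig,
    _scorer: _Scorer | None = None,
) -> float:
    """Sum of local scores over all nodes; empty graph scores 0."""
    if not g.is_acyclic():
        raise StructureError("network_score requires an acyclic graph")
    scorer = _scorer if _scorer is not None else _Scorer(data, cfg)
    return sum(
        scorer.local(n, frozenset(g.parents(n))) for n in g.node_ids
    )


_MOVE_ORDER = {"add": 0, "delete": 1, "reverse": 2}


def _inverse(move: tuple[str, str, str]) -> tuple[str, str, str]:
    kind, a, b = move
    if kind == "add":
        return ("delete", a, b)
    if kind == "delete":
        return ("add", a, b)
    return ("reverse", b, a)


def tabu_search(
    data: PerturbationMatrix,
    template: TemplateMatrix,
    cfg: SearchConfig,
) -> DirectedNetwork:
    """Greedy-ascent TABU search for the best template-consistent DAG.

    Deterministic for a fixed configuration: equal-gain moves are broken
    lexicographically by (kind, parent, child).  Mutants whose columns carry
    no DEGs are kept as nodes but never gain an edge.
    """
    if set(template.node_ids) != set(data.mutant_ids):
        raise ValueError("template node set must equal the matrix mutant set")
    nodes = tuple(data.mutant_ids)
    scorer = _Scorer(data, cfg)
    if scorer.engine.zero_variance:
        logger.warning(
            "mutants with no DEGs excluded from edges: %s",
            sorted(scorer.engine.zero_variance),
        )
    active = [n for n in nodes if n not in scorer.engine.zero_variance]

    parents: dict[str, set[str]] = {n: set() for n in nodes}
    guard = AcyclicityGuard(DirectedNetwork(nodes, set()))
    edges: set[tuple[str, str]] = set()

    current = 0.0
    best_score = 0.0
    best_edges: set[tuple[str, str]] = set()
    tabu: dict[tuple[str, str, str], int] = {}
    max_iter = cfg.max_iterations or 10 * len(nodes) ** 2
    non_improving = 0

    def gain_of(move: tuple[str, str, str]) -> float:
        kind, a, b = move
        if kind == "add":
            pa = frozenset(parents[b])
            return scorer.local(b, pa | {a}) - scorer.local(b, pa)
        if kind == "delete":
            pa = frozenset(parents[b])
            return scorer.local(b, pa - {a}) - scorer.local(b, pa)
        pa_b = frozenset(parents[b])
        pa_a = frozenset(parents[a])
        return (
            scorer.local(b, pa_b - {a})
            - scorer.local(b, pa_b)
            + scorer.local(a, pa_a | {b})
            - scorer.local(a, pa_a)
        )

    for it in range(max_iter):
        candidates: list[tuple[str, str, str]] = []
        for a in active:
            for b in active:
                if a == b:
                    continue
                if (a, b) in edges:
                    candidates.append(("delete", a, b))
                    if template.allows(b, a) and not guard.would_create_cycle(
                        ("reverse", a, b)
                    ):
                        if cfg.max_parents is None or len(parents[a]) < cfg.max_parents:
                            candidates.append(("reverse", a, b))
                elif template.allows(a, b) and not guard.would_create_cycle(
                    ("add", a, b)
                ):
                    if cfg.max_parents is None or len(parents[b]) < cfg.max_parents:
                        candidates.append(("add", a, b))
        best_move = None
        best_gain = -math.inf
        best_key: tuple | None = None
        for move in candidates:
            g = gain_of(move)
            if move in tabu and tabu[move] > it and not (current + g > best_score + 1e-12):
                continue  # tabu and fails aspiration
            key = (_MOVE_ORDER[move[0]], move[1], move[2])
            if (
                best_move is None
                or g > best_gain + 1e-12
                or (g > best_gain - 1e-12 and key < best_key)
            ):
                best_move, best_gain, best_key = move, g, key
        if best_move is None:
            break

        kind, a, b = best_move
        guard.apply(best_move)
        if kind == "add":
            edges.add((a, b))
            parents[b].add(a)
        elif kind == "delete":
            edges.discard((a, b))
            parents[b].discard(a)
        else:
            edges.discard((a, b))
            parents[b].discard(a)
            edges.add((b, a))
            parents[a].add(b)
        current += best_gain
        tabu[_inverse(best_move)] = it + 1 + cfg.tabu_tenure
        logger.debug(
            "iter %d: %s %s->%s gain %.4f score %.4f", it, kind, a, b, best_gain, current
        )
        if current > best_score + 1e-12:
            best_score = current
            best_edges = set(edges)
            non_improving = 0
        else:
            non_improving += 1
            if non_improving >= cfg.patience:
                break

    result = DirectedNetwork(nodes, best_edges)
    for a, b in result.edges:
        assert template.allows(a, b)
    return result
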