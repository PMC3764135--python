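"""Network evaluation: precision/recall, orientation precision, Jaccard baseline.

Matching a predicted network against reference interactions ignores edge
direction (knowledge of causality in interaction databases is scarce); the
denominator of recall counts only reference pairs whose BOTH endpoints are
nodes of the network.  A regulator deleted in two datasets contributes two
network nodes, so duplicate edges between the same gene pair are collapsed
to a single interaction first — consistently directed duplicates keep their
direction, conflicting or mixed ones become undirected.

Orientation precision is scored against a directed regulator -> DEG
reference: among predicted compelled edges overlapping the reference
regardless of direction, the fraction pointing the same way, with an exact
one-sided binomial test against fair-coin orientation (p = 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

from .io import (
    InteractionSet,
    PerturbationMatrix,
    TargetLists,
    base_label,
    constituent_genes,
)
from .pdag import PartiallyDirectedNetwork

__all__ = [
    "EvaluationReport",
    "OrientationReport",
    "collapse_duplicates",
    "precision_recall",
    "orientation_precision",
    "binomial_tail",
    "jaccard_index",
    "jaccard_network",
    "regulator_deg_reference",
]


@dataclass(frozen=True)
class EvaluationReport:
    """Undirected-match precision/recall counts.

    precision is None (undefined) when no edges were predicted; recall is
    None when no reference pair falls inside the network's node set.
    """

    n_tp: int
    n_known: int
    n_pred: int
    precision: float | None
    recall: float | None


@dataclass(frozen=True)
class OrientationReport:
    """Directed-edge orientation agreement with a directed reference."""

    n_total: int
    n_correct: int
    precision: float | None
    binom_p: float


def collapse_duplicates(net: PartiallyDirectedNetwork) -> PartiallyDirectedNetwork:
    """Merge per-dataset node copies onto gene names.

    Parallel edges between the same gene pair collapse to one: a single
    direction survives only if every duplicate is directed the same way;
    any conflict or undirected member yields an undirected edge.  Pairs
    whose endpoints collapse onto the same gene are dropped.
    """
    nodes = tuple(sorted({base_label(n) for n in net.node_ids}))
    status: dict[tuple[str, str], set[str]] = {}
    for a, b in net.directed:
        ga, gb = base_label(a), base_label(b)
        if ga == gb:
            continue
        key = tuple(sorted((ga, gb)))
        status.setdefault(key, set()).add(f"dir:{ga}>{gb}")
    for a, b in net.undirected:
        ga, gb = base_label(a), base_label(b)
        if ga == gb:
            continue
        key = tuple(sorted((ga, gb)))
        status.setdefault(key, set()).add("undir")
    directed: set[tuple[str, str]] = set()
    undirected: set[tuple[str, str]] = set()
    for key, kinds in status.items():
        if len(kinds) == 1 and next(iter(kinds)).startswith("dir:"):
            spec = next(iter(kinds))[4:]
            a, b = spec.split(">")
            directed.add((a, b))
        else:
            undirected.add(key)
    return PartiallyDirectedNetwork(nodes, directed, undirected)


def precision_recall(
    net: PartiallyDirectedNetwork, ref: InteractionSet
) -> EvaluationReport:
    """Direction-blind precision/recall of a (collapsed) network."""
    nodes = set(net.node_ids)
    pred = net.skeleton()
    known = {p for p in ref.pairs() if p[0] in nodes and p[1] in nodes}
    tp = pred & known
    n_pred, n_known, n_tp = len(pred), len(known), len(tp)
    precision = n_tp / n_pred if n_pred else None
    recall = n_tp / n_known if n_known else None
    return EvaluationReport(n_tp, n_known, n_pred, precision, recall)


def orientation_precision(
    net: PartiallyDirectedNetwork, ref_directed: set[tuple[str, str]]
) -> OrientationReport:
    """Orientation agreement of compelled edges with a directed reference."""
    ref_pairs = {tuple(sorted(p)) for p in ref_directed}
    overlapping = [
        e for e in net.directed if tuple(sorted(e)) in ref_pairs
    ]
    n_total = len(overlapping)
    n_correct = sum(1 for e in overlapping if e in ref_directed)
    if n_total == 0:
        return OrientationReport(0, 0, None, 1.0)
    return OrientationReport(
        n_total, n_correct, n_correct / n_total, binomial_tail(n_correct, n_total)
    )


def binomial_tail(k: int, n: int) -> float:
    """Exact one-sided binomial tail P(X >= k | n, p = 0.5).

    Computed with integer binomial coefficients: sum_{j=k}^{n} C(n, j) / 2^n.
    """
    if n < 1:
        raise ValueError("need at least one trial")
    if not 0 <= k <= n:
        raise ValueError(f"successes k={k} outside [0, {n}]")
    total = sum(comb(n, j) for j in range(k, n + 1))
    return total / 2**n


def jaccard_index(targets_a: set[str], targets_b: set[str]) -> float:
    """Intersection over union of two target-gene sets (0 when both empty)."""
    inter = len(targets_a & targets_b)
    union = len(targets_a) + len(targets_b) - inter
    return inter / union if union else 0.0


def jaccard_network(
    targets: TargetLists, threshold: float
) -> PartiallyDirectedNetwork:
    """Similarity baseline: undirected edge wherever pairwise JI > threshold."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    muts = sorted(targets.mutants())
    undirected: set[tuple[str, str]] = set()
    sets = {m: targets.genes(m) for m in muts}
    for i, a in enumerate(muts):
        for b in muts[i + 1 :]:
            if jaccard_index(sets[a], sets[b]) > threshold:
                undirected.add((a, b))
    return PartiallyDirectedNetwork(tuple(muts), set(), undirected)


def regulator_deg_reference(matrix: PerturbationMatrix) -> set[tuple[str, str]]:
    """Directed regulator -> DEG reference pairs from the matrix itself.

    (A, B) is a reference pair when regulator gene B is differentially
    expressed in A's deletion column; labels are collapsed to gene names.
    """
    out: set[tuple[str, str]] = set()
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
    for a in matrix.mutant_ids:
        col = matrix.column(a)
        ga = base_label(a)
        for b in matrix.mutant_ids:
            gb = base_label(b)
            if ga == gb:
                continue
            if any(
                g in gene_index and col[gene_index[g]] != 0
                for g in constituent_genes(b)
            ):
                out.add((ga, gb))
    return out
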