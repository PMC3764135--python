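"""Synthetic deletion-mutant profiles from a planted regulator DAG.

The generator emulates the causal premise of deletion-mutant profiling: the
genome-wide differential-expression profile observed after deleting a
regulator is (approximately) predictable from the profiles of the
regulators acting downstream of it.  Concretely:

1. a random DAG over R regulators is planted (random topological order,
   independent edges);
2. each regulator receives a signed set of direct target genes among the
   non-regulator genes (Poisson-sized, signs mixed);
3. gene-level effects cascade along edges one step at a time: the realized
   perturbation set of regulator r is its own direct targets plus, for every
   regulator p directly upstream (p -> r), each element of p's realized set
   independently with probability `propagation_decay` (signs inherited
   unchanged).  A regulated gene thereby mediates an attenuated copy of its
   regulators' programs — its deletion profile is predictable from the
   deletion profiles of its regulators, reaching an ancestor's direct
   effects with probability decay^L over a length-L path, and only through
   the intermediate regulators' realized sets, so the
   conditional-independence structure of the columns mirrors the planted
   DAG and colliders point regulator -> target;
4. the R regulators are themselves rows of the matrix: column r carries -1
   for r's own row (the gene is deleted) and marks each downstream
   regulator's row as differentially expressed with the same cascading rule
   (deleting a regulator changes the expression of the regulator genes below
   it) — this is what gives the template its one-way orientation
   information;
5. stochastic noise enters *within* the cascade: after a regulator's
   gene-level perturbation set is assembled from its direct targets and its
   regulators' realized sets, each gene coordinate is independently replaced
   by a uniform draw from {-1, 0, +1} with probability `noise_flip`, and it
   is this noisy realized profile that downstream regulators inherit from.
   Modeling the flips as propagating biological stochasticity (rather than
   terminal measurement error) keeps the planted DAG the exact Markov
   structure of the observed columns — conditioning on a regulator's
   observed profile fully explains the dependence it induces among its
   targets, which is the premise the structure learner relies on.
   Regulator rows receive the same entry-wise noise when the matrix is
   assembled.

Default parameters produce profiles of realistic sparsity (tens of DEGs per
mutant out of thousands of genes).  Everything is deterministic for a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PerturbationMatrix
from .search import DirectedNetwork

__all__ = ["SimulationConfig", "simulate_planted_model", "reference_orientation_pairs"]


@dataclass(frozen=True)
class SimulationConfig:
    """Planted-model settings.

    n_regulators          R, number of deleted regulators (columns).
    n_genes               N, total rows; the first R rows are the regulators.
    edge_probability      per ordered pair density of the planted DAG.
    targets_per_regulator mean direct-target count (Poisson).
    propagation_decay     probability a descendant's direct effect is
                          inherited per path step, in (0, 1].
    noise_flip            probability an entry is replaced by a random call.
    sign_mix              probability a direct target is down-regulated.
    """

    n_regulators: int = 10
    n_genes: int = 2000
    edge_probability: float = 0.2
    targets_per_regulator: float = 40.0
    propagation_decay: float = 0.8
    noise_flip: float = 0.02
    sign_mix: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("edge_probability", "propagation_decay", "noise_flip", "sign_mix"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.propagation_decay == 0.0:
            raise ValueError("propagation_decay must be in (0, 1]")
        if self.n_regulators < 2:
            raise ValueError("need at least 2 regulators")
        if self.n_genes < self.n_regulators:
            raise ValueError("n_genes must be >= n_regulators")


def _regulator_names(r: int) -> list[str]:
    return [f"R{i:02d}" for i in range(r)]


def _gene_names(cfg: SimulationConfig) -> list[str]:
    regs = _regulator_names(cfg.n_regulators)
    rest = [f"G{i:04d}" for i in range(cfg.n_genes - cfg.n_regulators)]
    return regs + rest


def _reverse_topological(edges: set[tuple[int, int]], r: int) -> list[int]:
    """Regulator indices ordered children-before-parents."""
    children: dict[int, list[int]] = {i: [] for i in range(r)}
    for a, b in edges:
        children[a].append(b)
    seen: set[int] = set()
    out: list[int] = []

    def visit(x: int) -> None:
        if x in seen:
            return
        seen.add(x)
        for c in sorted(children[x]):
            visit(c)
        out.append(x)

    for i in range(r):
        visit(i)
    return out


def simulate_planted_model(
    cfg: SimulationConfig,
    planted_edges: set[tuple[int, int]] | None = None,
) -> tuple[DirectedNetwork, PerturbationMatrix]:
    """Sample (ground-truth DAG, perturbation matrix) under the planted model.

    `planted_edges` fixes the DAG (ordered regulator-index pairs) instead of
    sampling one; it must be acyclic.
    """
    rng = np.random.default_rng(cfg.seed)
    r, n = cfg.n_regulators, cfg.n_genes
    reg_names = _regulator_names(r)
    gene_names = _gene_names(cfg)
    n_other = n - r

    if planted_edges is None:
        order = rng.permutation(r)
        rank = np.empty(r, dtype=int)
        rank[order] = np.arange(r)
        edges: set[tuple[int, int]] = set()
        for i in range(r):
            for j in range(r):
                if rank[i] < rank[j] and rng.random() < cfg.edge_probability:
                    edges.add((i, j))
    else:
        edges = set(planted_edges)

    # direct targets: indices into the non-regulator gene block, with signs
    direct: list[dict[int, int]] = []
    for i in range(r):
        k = min(int(rng.poisson(cfg.targets_per_regulator)), n_other)
        idx = rng.choice(n_other, size=k, replace=False)
        signs = np.where(rng.random(k) < cfg.sign_mix, -1, 1)
        direct.append({int(g): int(s) for g, s in zip(idx, signs)})

    children: dict[int, list[int]] = {i: [] for i in range(r)}
    parents: dict[int, list[int]] = {i: [] for i in range(r)}
    for a, b in edges:
        children[a].append(b)
        parents[b].append(a)
    rev_topo = _reverse_topological(edges, r)  # children before parents

    # gene effects cascade downward: each regulator inherits from the
    # already-realized (noisy) sets of its direct regulators (parents first);
    # flip noise is applied to the realized profile before it propagates
    realized_genes: list[dict[int, int]] = [dict() for _ in range(r)]
    for i in reversed(rev_topo):
        rg = dict(direct[i])
        for p in sorted(parents[i]):
            for g, s in realized_genes[p].items():
                if g not in rg and rng.random() < cfg.propagation_decay:
                    rg[g] = s
        if cfg.noise_flip > 0:
            flips = np.nonzero(rng.random(n_other) < cfg.noise_flip)[0]
            draws = rng.integers(-1, 2, size=flips.size)
            for g, v in zip(flips, draws):
                if v == 0:
                    rg.pop(int(g), None)
                else:
                    rg[int(g)] = int(v)
        realized_genes[i] = rg

    # regulator-row marks cascade upward: deleting r perturbs the regulator
    # genes downstream of it (children first)
    realized_regs: list[set[int]] = [set() for _ in range(r)]
    for i in rev_topo:
        rr: set[int] = set()
        for c in sorted(children[i]):
            if rng.random() < cfg.propagation_decay:
                rr.add(c)
            for d in sorted(realized_regs[c]):
                if d not in rr and rng.random() < cfg.propagation_decay:
                    rr.add(d)
        realized_regs[i] = rr

    calls = np.zeros((n, r), dtype=np.int8)
    for i in range(r):
        col = calls[:, i]
        col[i] = -1  # the deleted gene itself
        for g, s in realized_genes[i].items():
            col[r + g] = s
        for d in realized_regs[i]:
            col[d] = -1  # downstream regulator row becomes a DEG

    if cfg.noise_flip > 0:
        # regulator rows were not noised during the cascade
        mask = rng.random((r, r)) < cfg.noise_flip
        replacement = rng.integers(-1, 2, size=(r, r)).astype(np.int8)
        calls[:r, :] = np.where(mask, replacement, calls[:r, :])

    truth = DirectedNetwork(
        tuple(reg_names), {(reg_names[a], reg_names[b]) for a, b in edges}
    )
    matrix = PerturbationMatrix(
        pd.DataFrame(calls, index=gene_names, columns=reg_names)
    )
    return truth, matrix


def reference_orientation_pairs(
    truth: DirectedNetwork, matrix: PerturbationMatrix
) -> set[tuple[str, str]]:
    """Directed regulator -> DEG reference: (A, B) iff gene B is nonzero in
    column A.  Used as the orientation gold standard."""
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
    out: set[tuple[str, str]] = set()
    for a in matrix.mutant_ids:
        col = matrix.column(a)
        for b in truth.node_ids:
            if b == a:
                continue
            i = gene_index.get(b)
            if i is not None and col[i] != 0:
                out.add((a, b))
    return out
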