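"""Regulator x regulator template constraining edge existence and orientation.

The template encodes prior knowledge extracted from the perturbation data
itself.  For an unordered pair of mutants {A, B}, in order of precedence:

1. B is a DEG of A and A is a DEG of B  ->  both directions allowed (which
   direction carries the dominant effect is unknown);
2. only B is a DEG of A                 ->  A -> B allowed, B -> A forbidden;
3. only A is a DEG of B                 ->  B -> A allowed, A -> B forbidden;
4. neither, but their target-gene lists share at least one gene
   (sign-insensitive)                   ->  both directions allowed;
5. otherwise                            ->  no edge.

Membership tests compare the partner's constituent gene names (dataset tags
stripped) against the gene ids of a mutant's target list; a double-deletion
strain matches when either constituent gene does.  One-way pairs (cases 2/3)
are the "asymmetric constraints" later fed to the causal interpretation step
as background knowledge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError
from .io import TargetLists, constituent_genes

__all__ = ["TemplateMatrix", "build_template", "asymmetric_constraints",
           "complete_template", "read_template", "write_template"]


@dataclass(frozen=True)
class TemplateMatrix:
    """Binary R x R edge-permission matrix; allow[a][b] = 1 licenses a -> b."""

    node_ids: tuple[str, ...]
    allow: np.ndarray  # (R, R) of {0, 1}, zero diagonal

    def __post_init__(self) -> None:
        r = len(self.node_ids)
        a = np.asarray(self.allow, dtype=np.int8)
        if a.shape != (r, r):
            raise FormatError(f"allow matrix shape {a.shape} != ({r}, {r})")
        if not np.isin(a, (0, 1)).all():
            raise FormatError("template entries must be 0 or 1")
        if np.diagonal(a).any():
            raise FormatError("template diagonal must be 0")
        object.__setattr__(self, "allow", a)
        object.__setattr__(
            self, "_index", {n: i for i, n in enumerate(self.node_ids)}
        )

    def allows(self, a: str, b: str) -> bool:
        return bool(self.allow[self._index[a], self._index[b]])


def build_template(targets: TargetLists, node_ids: list[str]) -> TemplateMatrix:
    """Build the template from per-mutant target lists (rules 1-5 above)."""
    tg: dict[str, set[str]] = {}
    for n in node_ids:
        try:
            tg[n] = targets.genes(n)
        except KeyError:
            raise KeyError(f"mutant {n!r} has no target list") from None
    r = len(node_ids)
    allow = np.zeros((r, r), dtype=np.int8)

    def member(of: str, who: str) -> bool:
        """True if any constituent gene of `who` is a target of `of`."""
        return any(g in tg[of] for g in constituent_genes(who))

    for i in range(r):
        for j in range(i + 1, r):
            a, b = node_ids[i], node_ids[j]
            b_in_a = member(a, b)
            a_in_b = member(b, a)
            if b_in_a and a_in_b:
                allow[i, j] = allow[j, i] = 1
            elif b_in_a:
                allow[i, j] = 1
            elif a_in_b:
                allow[j, i] = 1
            elif tg[a] & tg[b]:
                allow[i, j] = allow[j, i] = 1
    return TemplateMatrix(tuple(node_ids), allow)


def complete_template(node_ids: list[str]) -> TemplateMatrix:
    """Template-free mode: every off-diagonal edge allowed."""
    r = len(node_ids)
    allow = np.ones((r, r), dtype=np.int8) - np.eye(r, dtype=np.int8)
    return TemplateMatrix(tuple(node_ids), allow)


def asymmetric_constraints(t: TemplateMatrix) -> set[tuple[str, str]]:
    """Ordered pairs (a, b) with a -> b allowed but b -> a forbidden."""
    out: set[tuple[str, str]] = set()
    asym = (t.allow == 1) & (t.allow.T == 0)
    for i, j in np.argwhere(asym):
        out.add((t.node_ids[i], t.node_ids[j]))
    return out


def write_template(t: TemplateMatrix, path) -> None:
    pd.DataFrame(t.allow, index=t.node_ids, columns=t.node_ids).to_csv(
        path, sep="\t", index_label="node"
    )


def read_template(path) -> TemplateMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError("template row and column labels differ")
    return TemplateMatrix(tuple(df.index), df.to_numpy())
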