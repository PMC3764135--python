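"""Hypergeometric functional-enrichment testing of target-gene lists.

With G genes in the universe (by default: every gene differentially
expressed in at least one deletion mutant), a functional category of S
genes, and a query of n genes of which m fall in the category, the
enrichment p-value is the hypergeometric upper tail

    P(X >= m) = sum_{k=m}^{min(S, n)} C(S, k) C(G - S, n - k) / C(G, n)

evaluated with exact integer arithmetic for moderate G and in log space
otherwise.  Benjamini-Hochberg adjusted p-values are reported alongside the
raw ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from pathlib import Path

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "hypergeom_tail",
    "enrich_targets",
    "read_gmt",
]

logger = logging.getLogger(__name__)

_EXACT_LIMIT = 10_000


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets plus the universe they live in."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            extra = members - self.universe
            if extra:
                raise ValueError(
                    f"gene set {name!r} has members outside the universe: "
                    f"{sorted(extra)[:5]}"
                )

    @property
    def universe_size(self) -> int:
        return len(self.universe)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    category_size: int
    query_size: int
    overlap: int
    p_value: float
    p_adjusted: float | None = None


def hypergeom_tail(G: int, S: int, n: int, m: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= m)."""
    if not (0 <= S <= G and 0 <= n <= G):
        raise ValueError(f"need 0 <= S, n <= G; got G={G}, S={S}, n={n}")
    if not 0 <= m <= min(S, n):
        raise ValueError(f"overlap m={m} outside [0, min({S}, {n})]")
    if m == 0:
        return 1.0
    if G <= _EXACT_LIMIT:
        num = sum(comb(S, k) * comb(G - S, n - k) for k in range(m, min(S, n) + 1))
        return float(Fraction(num, comb(G, n)))
    return float(hypergeom.sf(m - 1, G, S, n))


def enrich_targets(
    query: set[str], collection: GeneSetCollection
) -> list[EnrichmentResult]:
    """Test a target-gene list against every set in the collection.

    Query genes outside the universe are dropped with a warning.  Results
    are sorted by ascending raw p-value, with BH-adjusted p-values attached.
    """
    if not collection.sets:
        raise ValueError("gene-set collection is empty")
    outside = query - collection.universe
    if outside:
        logger.warning(
            "%d query genes outside universe dropped (e.g. %s)",
            len(outside),
            sorted(outside)[:3],
        )
    query = query & collection.universe
    G = collection.universe_size
    n = len(query)
    raw: list[EnrichmentResult] = []
    for name in sorted(collection.sets):
        members = collection.sets[name]
        m = len(query & members)
        p = hypergeom_tail(G, len(members), n, m)
        raw.append(EnrichmentResult(name, len(members), n, m, p))
    raw.sort(key=lambda r: (r.p_value, r.set_name))
    adjusted = multipletests([r.p_value for r in raw], method="fdr_bh")[1]
    return [
        EnrichmentResult(r.set_name, r.category_size, r.query_size, r.overlap, r.p_value, float(p))
        for r, p in zip(raw, adjusted)
    ]


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Read gene sets from GMT (name, description, members...).

    When no universe is supplied, the union of all set members is used.
    """
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            sets[parts[0]] = frozenset(g for g in parts[2:] if g)
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    else:
        # clip sets to the declared universe so invariants hold
        sets = {k: v & frozenset(universe) for k, v in sets.items()}
    return GeneSetCollection(sets, frozenset(universe))
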