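"""Reading, writing and basic transformation of perturbation data.

The central object is the :class:`PerturbationMatrix`: a genes x mutants
table of signed discrete differential-expression calls.  An entry of +1
means the gene is significantly up-regulated in that deletion-mutant strain
relative to wild type, -1 significantly down-regulated, and 0 no significant
change.  Everything downstream (kernel, template, structure search) consumes
only this matrix.

Mutant labels may carry a dataset-of-origin tag (``GENE@dataset``) so that a
regulator deleted in two independent datasets keeps two columns; labels of
double-deletion strains join the constituent genes with ``+``
(``GENE1+GENE2@dataset``).  Tags are stripped only at evaluation time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError

__all__ = [
    "PerturbationMatrix",
    "TargetLists",
    "InteractionSet",
    "parse_mutant_label",
    "base_label",
    "constituent_genes",
    "read_perturbation_matrix",
    "write_perturbation_matrix",
    "discretize_expression",
    "extract_target_lists",
    "read_interaction_set",
    "write_interaction_set",
    "write_target_lists_gmt",
]

_ALLOWED_CALLS = (-1, 0, 1)

_LABEL_RE = re.compile(r"^(?P<genes>[^@]+?)(?:@(?P<tag>[^@]+))?$")


def parse_mutant_label(label: str) -> tuple[tuple[str, ...], str | None]:
    """Split a mutant label into its constituent gene names and dataset tag.

    ``"SIR2@GSE4654"`` -> ``(("SIR2",), "GSE4654")``;
    ``"PTC1+PTC2"`` -> ``(("PTC1", "PTC2"), None)``.
    """
    m = _LABEL_RE.match(label)
    if m is None:  # pragma: no cover - regex accepts any '@'-sane string
        raise FormatError(f"unparseable mutant label: {label!r}")
    genes = tuple(g for g in m.group("genes").split("+") if g)
    if not genes:
        raise FormatError(f"mutant label has no gene name: {label!r}")
    return genes, m.group("tag")


def base_label(label: str) -> str:
    """Mutant label with the dataset tag stripped (gene-name identity)."""
    genes, _ = parse_mutant_label(label)
    return "+".join(genes)


def constituent_genes(label: str) -> tuple[str, ...]:
    """Gene names deleted in the strain the label denotes."""
    return parse_mutant_label(label)[0]


@dataclass(frozen=True)
class PerturbationMatrix:
    """Genes x mutants table of signed discrete expression calls.

    ``values`` is an int8 DataFrame indexed by gene id with one column per
    mutant; every entry is exactly -1, 0 or +1.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate gene id: {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise FormatError(f"duplicate mutant label: {dup!r}")
        arr = df.to_numpy()
        bad = ~np.isin(arr, _ALLOWED_CALLS)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"value {arr[i, j]!r} at gene {df.index[i]!r}, "
                f"mutant {df.columns[j]!r} is not one of -1, 0, 1"
            )
        object.__setattr__(self, "values", df.astype(np.int8))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def mutant_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def column(self, mutant_id: str) -> np.ndarray:
        """Call vector of one mutant, in gene order."""
        return self.values[mutant_id].to_numpy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PerturbationMatrix):
            return NotImplemented
        return self.values.equals(other.values)


@dataclass(frozen=True)
class TargetLists:
    """Per-mutant signed target-gene sets.

    ``targets[m]`` maps each differentially expressed gene of mutant ``m``
    to its sign (+1 or -1).  Genes with a 0 call are absent.
    """

    targets: Mapping[str, Mapping[str, int]]

    def signed(self, mutant_id: str) -> set[tuple[str, int]]:
        return {(g, s) for g, s in self.targets[mutant_id].items()}

    def genes(self, mutant_id: str) -> set[str]:
        """Sign-insensitive target gene set of a mutant."""
        return set(self.targets[mutant_id])

    def mutants(self) -> list[str]:
        return list(self.targets)


@dataclass
class InteractionSet:
    """Reference interactions over (tag-free) gene names.

    Undirected pairs are stored once with endpoints sorted; a pair never
    appears both directed and undirected.
    """

    directed: set[tuple[str, str]] = field(default_factory=set)
    undirected: set[tuple[str, str]] = field(default_factory=set)

    def add_undirected(self, a: str, b: str) -> None:
        self.undirected.add(tuple(sorted((a, b))))  # type: ignore[arg-type]

    def add_directed(self, a: str, b: str) -> None:
        self.directed.add((a, b))

    def pairs(self) -> set[tuple[str, str]]:
        """All interactions as unordered (sorted) pairs."""
        out = set(self.undirected)
        out.update(tuple(sorted(e)) for e in self.directed)
        return out

    def __len__(self) -> int:
        return len(self.pairs())


def read_perturbation_matrix(path: str | Path) -> PerturbationMatrix:
    """Read a call matrix from TSV (header = mutant labels, first column =
    gene ids).  Raises :class:`FormatError` naming the offending cell when a
    value is not in {-1, 0, 1} or fails to parse as an integer."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    parsed = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        try:
            parsed[col] = df[col].astype(int)
        except (TypeError, ValueError):
            for gene, cell in df[col].items():
                try:
                    int(cell)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"cell at gene {gene!r}, mutant {col!r} is not an "
                        f"integer: {cell!r}"
                    ) from None
            raise
    return PerturbationMatrix(parsed.astype(int))


def write_perturbation_matrix(m: PerturbationMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene")


def discretize_expression(
    log_ratios: pd.DataFrame,
    up_threshold: float = 1.0,
    down_threshold: float = -1.0,
) -> PerturbationMatrix:
    """Threshold a continuous log-ratio table into signed calls.

    An entry becomes +1 when >= ``up_threshold``, -1 when <=
    ``down_threshold``, else 0; missing values are treated as no change.
    """
    if not (down_threshold < 0 < up_threshold):
        raise ValueError(
            "thresholds must satisfy down_threshold < 0 < up_threshold"
        )
    try:
        arr = log_ratios.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric cell in continuous input: {exc}") from None
    calls = np.zeros(arr.shape, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        calls[arr >= up_threshold] = 1
        calls[arr <= down_threshold] = -1
    calls[np.isnan(arr)] = 0
    return PerturbationMatrix(
        pd.DataFrame(calls, index=log_ratios.index, columns=log_ratios.columns)
    )


def extract_target_lists(m: PerturbationMatrix) -> TargetLists:
    """Signed target-gene set of every mutant: the genes with a nonzero call
    in its column."""
    out: dict[str, dict[str, int]] = {}
    arr = m.values.to_numpy()
    genes = np.asarray(m.gene_ids, dtype=object)
    for j, mut in enumerate(m.mutant_ids):
        nz = np.nonzero(arr[:, j])[0]
        out[mut] = {genes[i]: int(arr[i, j]) for i in nz}
    return TargetLists(out)


_DIRECTION_FLAGS = {"--", "->"}


def read_interaction_set(path: str | Path) -> InteractionSet:
    """Read a 3-column interaction TSV: node_a, node_b, flag ('--' or '->')."""
    out = InteractionSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected 3 tab-separated fields"
                )
            a, b, flag = parts
            if flag not in _DIRECTION_FLAGS:
                raise FormatError(
                    f"{path}: line {lineno}: unknown direction flag {flag!r}"
                )
            if flag == "--":
                out.add_undirected(a, b)
            else:
                out.add_directed(a, b)
    return out


def write_interaction_set(s: InteractionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(s.undirected):
            fh.write(f"{a}\t{b}\t--\n")
        for a, b in sorted(s.directed):
            fh.write(f"{a}\t{b}\t->\n")


def write_target_lists_gmt(
    targets: TargetLists, path: str | Path, description: str = "deletion-mutant targets"
) -> None:
    """Export target lists as GMT lines (set name, description, members)."""
    with open(path, "w") as fh:
        for mut in targets.mutants():
            members = "\t".join(sorted(targets.genes(mut)))
            fh.write(f"{mut}\t{description}\t{members}\n" if members else f"{mut}\t{description}\n")
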