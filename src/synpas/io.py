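"""Readers, writers and data-preparation filters for the standard input formats.

The package consumes six plain-text inputs:

* a pathway collection in GMT format (tab-separated: name, description, genes...),
* a gene-expression matrix (TSV, genes x cell lines, TPM-like values),
* a directed gene-interaction network (two-column TSV edge list),
* a drug -> target-gene mapping (TSV),
* a driver-gene catalogue per cell line (TSV),
* an experiment table (CSV/TSV: drug_a, drug_b, cell_line, optional Loewe score).

Loewe synergy scores are expected to be precomputed; dose-response matrices are
out of scope.  Expression values are log2(x+1)-transformed on load so that zero
TPM maps to zero.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PathwayCollection",
    "GeneNetwork",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_network",
    "write_network",
    "read_drug_targets",
    "write_drug_targets",
    "read_drivers",
    "write_drivers",
    "read_experiments",
    "write_experiments",
    "write_predictions",
    "read_predictions",
    "filter_driver_mutations",
    "filter_fusions",
    "canonical_pair",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PathwayCollection:
    """An ordered mapping pathway-name -> gene set.

    Order is preserved from the source file and fixes the column order of the
    PAS feature matrix downstream.
    """

    entries: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for name, genes in self.entries.items():
            if not genes:
                raise ValueError(f"pathway {name!r} has an empty gene set")

    @property
    def n_pathways(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return list(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.entries[name]

    def __iter__(self):
        return iter(self.entries)


@dataclass
class GeneNetwork:
    """A directed gene-interaction network.

    Self-loops are dropped and duplicate edges collapsed on construction.
    ``directed=False`` marks networks produced by degree-preserving rewiring,
    where edge orientation is no longer meaningful.
    """

    graph: nx.DiGraph
    directed: bool = True

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], directed: bool = True
    ) -> "GeneNetwork":
        g = nx.DiGraph()
        for u, v in edges:
            if u != v:
                g.add_edge(u, v)
        return cls(graph=g, directed=directed)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def undirected_edges(self) -> set[frozenset[str]]:
        """Distinct unordered edges; a reciprocal pair collapses to one."""
        return {frozenset((u, v)) for u, v in self.graph.edges}

    def undirected_degrees(self) -> dict[str, int]:
        """Node degrees of the undirected skeleton."""
        deg: dict[str, int] = {n: 0 for n in self.graph.nodes}
        for e in self.undirected_edges():
            u, v = tuple(e)
            deg[u] += 1
            deg[v] += 1
        return deg


# ---------------------------------------------------------------------------
# GMT pathway collections
# ---------------------------------------------------------------------------


def read_gmt(path: str | os.PathLike) -> PathwayCollection:
    """Read a GMT gene-set file (name, description, member genes...).

    Duplicate genes within a line are collapsed; a duplicate pathway name or a
    line with fewer than three fields is a :class:`FormatError` naming the line.
    """
    entries: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields "
                    f"(name, description, genes...), got {len(fields)}"
                )
            name = fields[0]
            if name in entries:
                raise FormatError(f"{path}: line {lineno}: duplicate pathway {name!r}")
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise FormatError(f"{path}: line {lineno}: pathway {name!r} has no genes")
            entries[name] = genes
    if not entries:
        raise FormatError(f"{path}: no pathways")
    return PathwayCollection(entries=entries)


def write_gmt(pathways: PathwayCollection, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, genes in pathways.entries.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


def read_expression(
    path: str | os.PathLike, log_transform: bool = True
) -> pd.DataFrame:
    """Read a genes x cell-lines expression TSV.

    The first column holds gene symbols, the header row cell-line identifiers.
    With ``log_transform`` the values are mapped to ``log2(x + 1)``; negative
    raw values are then rejected.  Duplicate genes or cell lines are errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene rows: {dupes[:5]}")
    if df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate cell-line columns")
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise FormatError(f"{path}: non-finite expression values")
    if log_transform:
        if (values < 0).any():
            raise FormatError(f"{path}: negative raw value with log_transform")
        df = pd.DataFrame(np.log2(values + 1.0), index=df.index, columns=df.columns)
    return df


def write_expression(expression: pd.DataFrame, path: str | os.PathLike) -> None:
    expression.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Networks, drug targets, drivers
# ---------------------------------------------------------------------------


def read_network(path: str | os.PathLike) -> GeneNetwork:
    """Read a directed edge list (source<TAB>target, one edge per line).

    Self-loops are dropped and duplicate edges deduplicated.
    """
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected source<TAB>target"
                )
            edges.append((fields[0], fields[1]))
    return GeneNetwork.from_edges(edges)


def write_network(network: GeneNetwork, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(network.graph.edges):
            fh.write(f"{u}\t{v}\n")


def read_drug_targets(path: str | os.PathLike) -> dict[str, frozenset[str]]:
    """Read drug<TAB>gene rows into a drug -> target-gene-set mapping."""
    targets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}: line {lineno}: expected drug<TAB>gene")
            targets.setdefault(fields[0], set()).add(fields[1])
    return {d: frozenset(g) for d, g in targets.items()}


def write_drug_targets(
    targets: Mapping[str, frozenset[str]], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for drug in sorted(targets):
            for gene in sorted(targets[drug]):
                fh.write(f"{drug}\t{gene}\n")


def read_drivers(path: str | os.PathLike) -> dict[str, frozenset[str]]:
    """Read cell_line<TAB>gene rows into a cell-line -> driver-gene mapping.

    A line with an empty gene field declares a cell line with no drivers.
    """
    drivers: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            cell = fields[0]
            drivers.setdefault(cell, set())
            if len(fields) > 1 and fields[1]:
                drivers[cell].add(fields[1])
    return {c: frozenset(g) for c, g in drivers.items()}


def write_drivers(
    drivers: Mapping[str, frozenset[str]], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for cell in sorted(drivers):
            genes = sorted(drivers[cell])
            if not genes:
                fh.write(f"{cell}\t\n")
            for gene in genes:
                fh.write(f"{cell}\t{gene}\n")


# ---------------------------------------------------------------------------
# Experiment tables and predictions
# ---------------------------------------------------------------------------


def canonical_pair(drug_a: str, drug_b: str) -> tuple[str, str]:
    """Order a drug pair lexicographically; A+B and B+A are one combination."""
    return (drug_a, drug_b) if drug_a <= drug_b else (drug_b, drug_a)


def read_experiments(path: str | os.PathLike) -> pd.DataFrame:
    """Read an experiment table (CSV or TSV by extension).

    Columns: drug_a, drug_b, cell_line and optionally loewe.  Drug pairs are
    canonicalized (lexicographic order) so that featurization is invariant to
    the order in which the two drugs are listed.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"drug_a": str, "drug_b": str, "cell_line": str})
    required = {"drug_a", "drug_b", "cell_line"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return canonicalize_experiments(df)


def canonicalize_experiments(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    pairs = [canonical_pair(a, b) for a, b in zip(df["drug_a"], df["drug_b"])]
    df["drug_a"] = [p[0] for p in pairs]
    df["drug_b"] = [p[1] for p in pairs]
    if "loewe" in df.columns:
        df["loewe"] = pd.to_numeric(df["loewe"])
    return df


def write_experiments(df: pd.DataFrame, path: str | os.PathLike) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=sep, index=False)


def write_predictions(results: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write predictions as TSV in input row order.

    Expects columns drug_a, drug_b, cell_line, predicted_loewe, confidence_score.
    """
    cols = ["drug_a", "drug_b", "cell_line", "predicted_loewe", "confidence_score"]
    missing = [c for c in cols if c not in results.columns]
    if missing:
        raise FormatError(f"prediction table missing columns {missing}")
    results[cols].to_csv(path, sep="\t", index=False)


def read_predictions(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Driver-gene preparation filters
# ---------------------------------------------------------------------------


def filter_driver_mutations(
    mutation_table: Iterable[tuple[str, str]],
    total_cell_lines: int,
    min_frequency: float = 0.025,
) -> dict[str, frozenset[str]]:
    """Retain recurrently mutated genes as putative drivers.

    A gene is kept iff it is mutated in at least ``min_frequency`` (default
    2.5%, inclusive) of ``total_cell_lines``; the catalogue maps each cell line
    to its retained genes.
    """
    if total_cell_lines <= 0:
        raise ValueError("total_cell_lines must be positive")
    carriers: dict[str, set[str]] = {}
    per_cell: dict[str, set[str]] = {}
    for cell, gene in mutation_table:
        carriers.setdefault(gene, set()).add(cell)
        per_cell.setdefault(cell, set()).add(gene)
    kept = {
        g
        for g, cells in carriers.items()
        if len(cells) / total_cell_lines >= min_frequency
    }
    return {c: frozenset(genes & kept) for c, genes in per_cell.items()}


def filter_fusions(
    fusion_table: Iterable[tuple[str, str]],
    catalogue: set[str] | frozenset[str],
    min_count: int = 2,
    drivers: Mapping[str, frozenset[str]] | None = None,
) -> dict[str, frozenset[str]]:
    """Retain catalogued, recurrent gene fusions and append them to drivers.

    A fusion is kept iff it appears in ``catalogue`` AND occurs at least
    ``min_count`` times in total (inclusive).  Retained fusion identifiers are
    appended to the per-cell-line driver sets (``drivers`` is not mutated).
    """
    rows = list(fusion_table)
    counts: dict[str, int] = {}
    for _, fusion in rows:
        counts[fusion] = counts.get(fusion, 0) + 1
    kept = {f for f, n in counts.items() if f in catalogue and n >= min_count}
    result: dict[str, set[str]] = {
        c: set(g) for c, g in (drivers or {}).items()
    }
    for cell, fusion in rows:
        if fusion in kept:
            result.setdefault(cell, set()).add(fusion)
    return {c: frozenset(g) for c, g in result.items()}
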