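"""Pathway activation scores (PAS) for drug combinations.

For an experiment (drug A + drug B, cell line C) and a pathway P the genes of
P are partitioned relative to the combination's target genes on the directed
interaction network:

* ``Gu`` — the target genes of both drugs plus the pathway genes upstream of
  them (directed ancestors of the target set),
* ``Gd`` — the pathway genes downstream of the targets (directed descendants)
  that are not already in ``Gu``,
* ``Gdr`` — the driver genes of cell line C that belong to pathway P.

Pathway genes with no directed path to or from any target carry no positional
information and belong to neither Gu nor Gd.  The three activation scores
PASu, PASd, PASdr are the sums of (log2) expression over the three sets, so a
pathway collection of N pathways yields a K x 3N feature matrix with columns
``{pathway}:u``, ``{pathway}:d``, ``{pathway}:dr`` in collection order.

:class:`PASFeaturizer` packages this as a scikit-learn transformer whose
``transform`` maps an experiment table to the PAS matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import GeneNetwork, PathwayCollection, canonical_pair
from .nea import count_cross_links, nea_zscore, z_to_prob

__all__ = [
    "GenePartition",
    "PASVector",
    "AltFeature",
    "classify_pathway_genes",
    "compute_pas",
    "build_feature_matrix",
    "alt_pathway_feature",
    "PASFeaturizer",
    "pas_columns",
]

PAS_COMPONENTS = ("u", "d", "dr")


@dataclass(frozen=True)
class GenePartition:
    """The Gu/Gd/Gdr gene sets of one (combination, pathway, cell line)."""

    gu: frozenset[str]
    gd: frozenset[str]
    gdr: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.gu & self.gd:
            raise ValueError("Gu and Gd must be disjoint")


@dataclass(frozen=True)
class PASVector:
    """Activation scores of one pathway: upstream, downstream, drivers."""

    pas_u: float
    pas_d: float
    pas_dr: float


@dataclass(frozen=True)
class AltFeature:
    """Sparsity-robust alternative pathway feature S(g) * (w1 + w2).

    ``s_g`` is the total pathway expression, ``w1``/``w2`` are normal
    probability scores of the pathway's NEA z against the combination's
    targets and the cell line's drivers.
    """

    s_g: float
    w1: float
    w2: float

    @property
    def value(self) -> float:
        return self.s_g * (self.w1 + self.w2)


def _reachable(graph: nx.DiGraph, sources: frozenset[str], reverse: bool) -> set[str]:
    """Union of nodes reachable from ``sources`` (ancestors if ``reverse``)."""
    out: set[str] = set()
    g = graph.reverse(copy=False) if reverse else graph
    for s in sources:
        if s in g:
            out.update(nx.descendants(g, s))
    return out


def classify_pathway_genes(
    pathway_genes: frozenset[str] | set[str],
    target_genes: frozenset[str] | set[str],
    network: GeneNetwork,
    targets_in_pathway_only: bool = False,
) -> GenePartition:
    """Partition pathway genes into upstream (Gu) and downstream (Gd) sets.

    Gu holds the drug targets plus pathway genes that are directed ancestors of
    any target; Gd holds pathway genes that are directed descendants of any
    target and not in Gu (so a gene on a cycle through a target stays
    upstream).  With ``targets_in_pathway_only`` targets outside the pathway
    are not force-included in Gu.
    """
    if not target_genes:
        raise ValueError("combination has no targets")
    targets = frozenset(target_genes)
    pathway = frozenset(pathway_genes)
    ancestors = _reachable(network.graph, targets, reverse=True)
    descendants = _reachable(network.graph, targets, reverse=False)
    kept_targets = targets & pathway if targets_in_pathway_only else targets
    gu = frozenset(kept_targets | (ancestors & pathway))
    gd = frozenset((descendants & pathway) - gu)
    return GenePartition(gu=gu, gd=gd)


def compute_pas(
    partition: GenePartition, expression_column: Mapping[str, float]
) -> PASVector:
    """Sum expression over Gu, Gd and Gdr; absent genes contribute 0."""

    def total(genes: frozenset[str]) -> float:
        return float(sum(expression_column.get(g, 0.0) for g in genes))

    return PASVector(
        pas_u=total(partition.gu),
        pas_d=total(partition.gd),
        pas_dr=total(partition.gdr),
    )


def pas_columns(pathways: PathwayCollection) -> list[str]:
    """Feature-column names, three per pathway in collection order."""
    return [f"{name}:{c}" for name in pathways.names for c in PAS_COMPONENTS]


class PASFeaturizer(TransformerMixin, BaseEstimator):
    """Transform an experiment table into the K x 3N PAS feature matrix.

    Parameters
    ----------
    pathways : PathwayCollection
        N pathways; fixes the column order of the output (3 columns each).
    expression : pandas.DataFrame
        Genes x cell lines, log2-transformed.
    network : GeneNetwork
        Directed gene-interaction network defining upstream/downstream.
    drivers : mapping cell line -> driver gene set
        Gdr of pathway P in cell line C is drivers[C] ∩ P.
    targets : mapping drug -> target gene set
    targets_in_pathway_only : bool, default False
        If True, drug targets outside a pathway are not forced into its Gu.

    ``fit`` validates the inputs; ``transform`` accepts a DataFrame with
    columns drug_a, drug_b, cell_line and returns the PAS matrix with the
    input's row index.  Partitions are cached per (drug pair, pathway), so the
    transform is deterministic and pure.
    """

    def __init__(
        self,
        pathways: PathwayCollection,
        expression: pd.DataFrame,
        network: GeneNetwork,
        drivers: Mapping[str, frozenset[str]],
        targets: Mapping[str, frozenset[str]],
        targets_in_pathway_only: bool = False,
    ):
        self.pathways = pathways
        self.expression = expression
        self.network = network
        self.drivers = drivers
        self.targets = targets
        self.targets_in_pathway_only = targets_in_pathway_only

    def fit(self, X: pd.DataFrame | None = None, y=None) -> "PASFeaturizer":
        for drug, tg in self.targets.items():
            if not tg:
                raise ValueError(f"drug {drug!r} has no target genes")
        self.feature_names_ = pas_columns(self.pathways)
        self._gene_index = {g: i for i, g in enumerate(self.expression.index)}
        self._expr_values = self.expression.to_numpy(dtype=float)
        self._cell_index = {c: i for i, c in enumerate(self.expression.columns)}
        self._partition_cache: dict[tuple[str, str], list[GenePartition]] = {}
        self._gdr_cache: dict[str, list[np.ndarray]] = {}
        return self

    # -- internal helpers ---------------------------------------------------

    def _gene_idx(self, genes: frozenset[str]) -> np.ndarray:
        idx = [self._gene_index[g] for g in genes if g in self._gene_index]
        return np.asarray(sorted(idx), dtype=np.intp)

    def _pair_partitions(self, pair: tuple[str, str]) -> list[GenePartition]:
        if pair not in self._partition_cache:
            tg = frozenset(self.targets[pair[0]] | self.targets[pair[1]])
            ancestors = _reachable(self.network.graph, tg, reverse=True)
            descendants = _reachable(self.network.graph, tg, reverse=False)
            parts = []
            for name in self.pathways.names:
                pathway = self.pathways[name]
                kept = tg & pathway if self.targets_in_pathway_only else tg
                gu = frozenset(kept | (ancestors & pathway))
                gd = frozenset((descendants & pathway) - gu)
                parts.append(GenePartition(gu=gu, gd=gd))
            self._partition_cache[pair] = parts
        return self._partition_cache[pair]

    def _cell_gdr(self, cell: str) -> list[np.ndarray]:
        if cell not in self._gdr_cache:
            drv = frozenset(self.drivers.get(cell, frozenset()))
            self._gdr_cache[cell] = [
                self._gene_idx(drv & self.pathways[name]) for name in self.pathways.names
            ]
        return self._gdr_cache[cell]

    # -- sklearn surface ----------------------------------------------------

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "feature_names_")
        for col in ("drug_a", "drug_b", "cell_line"):
            if col not in X.columns:
                raise ValueError(f"experiment table missing column {col!r}")
        n = self.pathways.n_pathways
        out = np.zeros((len(X), 3 * n), dtype=float)
        pair_idx_cache: dict[tuple[str, str], list[tuple[np.ndarray, np.ndarray]]] = {}
        for row_pos, (idx, row) in enumerate(X.iterrows()):
            pair = canonical_pair(str(row["drug_a"]), str(row["drug_b"]))
            cell = str(row["cell_line"])
            for drug in pair:
                if drug not in self.targets:
                    raise ValueError(f"row {idx}: unknown drug {drug!r}")
            if cell not in self._cell_index:
                raise ValueError(f"row {idx}: unknown cell line {cell!r}")
            if pair not in pair_idx_cache:
                parts = self._pair_partitions(pair)
                pair_idx_cache[pair] = [
                    (self._gene_idx(p.gu), self._gene_idx(p.gd)) for p in parts
                ]
            col = self._expr_values[:, self._cell_index[cell]]
            gdr_idx = self._cell_gdr(cell)
            for j, (gu_idx, gd_idx) in enumerate(pair_idx_cache[pair]):
                out[row_pos, 3 * j] = col[gu_idx].sum()
                out[row_pos, 3 * j + 1] = col[gd_idx].sum()
                out[row_pos, 3 * j + 2] = col[gdr_idx[j]].sum()
        return pd.DataFrame(out, index=X.index, columns=self.feature_names_)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        check_is_fitted(self, "feature_names_")
        return np.asarray(self.feature_names_, dtype=object)


def build_feature_matrix(
    experiments: pd.DataFrame,
    pathways: PathwayCollection,
    expression: pd.DataFrame,
    drivers: Mapping[str, frozenset[str]],
    targets: Mapping[str, frozenset[str]],
    network: GeneNetwork,
    targets_in_pathway_only: bool = False,
) -> pd.DataFrame:
    """One-shot functional wrapper over :class:`PASFeaturizer`."""
    feat = PASFeaturizer(
        pathways=pathways,
        expression=expression,
        network=network,
        drivers=drivers,
        targets=targets,
        targets_in_pathway_only=targets_in_pathway_only,
    )
    return feat.fit(experiments).transform(experiments)


def alt_pathway_feature(
    pathway_genes: frozenset[str] | set[str],
    target_genes: frozenset[str] | set[str],
    driver_genes: frozenset[str] | set[str],
    expression_column: Mapping[str, float],
    network: GeneNetwork,
    n_permutations: int = 100,
    swaps_per_edge: int = 10,
    seed: int | None = None,
) -> AltFeature:
    """Alternative pathway feature S(g) * (w1 + w2).

    S(g) sums expression over all pathway genes; w1 and w2 are the normal
    probability scores Φ(z) of the pathway's NEA z-score against the targets
    and the drivers.  The feature is zero exactly when the pathway contains no
    target and no driver gene and shows no cross-links with either set (then
    w1 = w2 = 0).
    """
    pathway = frozenset(pathway_genes)
    s_g = float(sum(expression_column.get(g, 0.0) for g in pathway))
    rng = np.random.default_rng(seed)

    def weight(other: frozenset[str] | set[str]) -> float:
        if not other:
            return 0.0
        res = nea_zscore(
            pathway, frozenset(other), network,
            n_permutations=n_permutations, swaps_per_edge=swaps_per_edge, seed=rng,
        )
        return z_to_prob(res.z)

    no_members = not (pathway & frozenset(target_genes)) and not (
        pathway & frozenset(driver_genes)
    )
    no_links = (
        count_cross_links(pathway, frozenset(target_genes), network) == 0
        and count_cross_links(pathway, frozenset(driver_genes), network) == 0
    )
    if no_members and no_links:
        return AltFeature(s_g=s_g, w1=0.0, w2=0.0)
    return AltFeature(s_g=s_g, w1=weight(target_genes), w2=weight(driver_genes))
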