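"""Mechanism-of-action readouts from a fitted synergy model.

A prediction is interpreted through its pathways: a pathway matters for a
combination when it has both high permutation importance and high activation
(median PAS across the samples treated with the combination), and it is
biologically plausible when its genes functionally interact — in the NEA
sense, z > 1.96 — with both the combination's target genes and the cell
line's driver genes (the "upper-right quadrant").  At the cohort level,
observed synergy is compared between combinations with overlapping vs
non-overlapping targets and across quartiles of the target-target interaction
z-score, and a forest regression of z on PAS quantifies how much of the
interaction signal the features already carry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GeneNetwork, PathwayCollection, canonical_pair
from .model import SynergyForest
from .nea import nea_zscore
from .pas import PAS_COMPONENTS
from .stats import spearman

__all__ = [
    "PathwayReport",
    "pathway_importance",
    "median_pas_per_pathway",
    "top_pathways",
    "quadrant_analysis",
    "synergy_by_target_overlap",
    "synergy_by_interaction_quartile",
    "pas_predicts_interaction",
]

QUADRANT_Z = 1.96


@dataclass(frozen=True)
class PathwayReport:
    """Per-pathway interpretation record."""

    pathway: str
    importance: float
    median_pas: float
    z_target: float
    z_driver: float
    flagged: bool


def pathway_importance(
    feature_importance, feature_names: list[str], aggregate: str = "max"
) -> pd.Series:
    """Collapse per-column importance to per-pathway importance.

    A pathway contributes three PAS columns (u/d/dr); its importance is the
    max (default) or mean over them.
    """
    imp = pd.Series(np.asarray(feature_importance, dtype=float), index=feature_names)
    pathway_of = [name.rsplit(":", 1)[0] for name in feature_names]
    grouped = imp.groupby(pd.Series(pathway_of, index=imp.index), sort=False)
    if aggregate == "max":
        return grouped.max()
    if aggregate == "mean":
        return grouped.mean()
    raise ValueError(f"unknown aggregate {aggregate!r}")


def median_pas_per_pathway(
    features: pd.DataFrame, rows: pd.Index | None = None, aggregate: str = "max"
) -> pd.Series:
    """Median PAS per pathway across the given rows (all rows by default).

    The median is taken per column first, then collapsed across the pathway's
    three columns like :func:`pathway_importance`.  With a single row, the
    single value is the median.
    """
    sub = features.loc[rows] if rows is not None else features
    med = sub.median(axis=0)
    return pathway_importance(med.to_numpy(), list(features.columns), aggregate)


def top_pathways(
    importance: pd.Series,
    median_pas: pd.Series,
    percentile: float = 0.05,
) -> set[str]:
    """Pathways in the top ``percentile`` of BOTH importance and median PAS.

    Rank-based: the top ``floor(percentile * N)`` pathways of each vector are
    intersected, so the shortlist never exceeds ``percentile * N`` entries.
    """
    if set(importance.index) != set(median_pas.index):
        raise ValueError("importance and median_pas cover different pathways")
    n = len(importance)
    k = int(np.floor(percentile * n))
    if k < 1:
        return set()
    top_imp = set(importance.sort_values(ascending=False).index[:k])
    top_pas = set(median_pas.sort_values(ascending=False).index[:k])
    return top_imp & top_pas


def quadrant_analysis(
    pathways: PathwayCollection,
    target_genes: frozenset[str] | set[str],
    driver_genes: frozenset[str] | set[str],
    network: GeneNetwork,
    importance: pd.Series | None = None,
    median_pas: pd.Series | None = None,
    n_permutations: int = 100,
    swaps_per_edge: int = 10,
    seed: int = 0,
) -> list[PathwayReport]:
    """NEA quadrant analysis: pathway-vs-targets and pathway-vs-drivers z.

    A pathway is flagged when both z-scores strictly exceed 1.96 (the
    upper-right quadrant of the z-z scatter).  Reproducible given the seed.
    """
    if not target_genes or not driver_genes:
        raise ValueError("target and driver gene sets must be non-empty")
    rng = np.random.default_rng(seed)
    reports = []
    for name in pathways.names:
        genes = pathways[name]
        sub_seed = int(rng.integers(0, 2**31 - 1))
        z_t = nea_zscore(
            genes, frozenset(target_genes), network,
            n_permutations=n_permutations, swaps_per_edge=swaps_per_edge,
            seed=sub_seed,
        ).z
        z_d = nea_zscore(
            genes, frozenset(driver_genes), network,
            n_permutations=n_permutations, swaps_per_edge=swaps_per_edge,
            seed=sub_seed + 1,
        ).z
        reports.append(
            PathwayReport(
                pathway=name,
                importance=float(importance.get(name, np.nan)) if importance is not None else np.nan,
                median_pas=float(median_pas.get(name, np.nan)) if median_pas is not None else np.nan,
                z_target=z_t,
                z_driver=z_d,
                flagged=bool(z_t > QUADRANT_Z and z_d > QUADRANT_Z),
            )
        )
    return reports


def synergy_by_target_overlap(
    experiments: pd.DataFrame, targets: Mapping[str, frozenset[str]]
) -> dict:
    """Compare observed synergy between target-overlapping and disjoint pairs.

    Groups each experiment by whether its two drugs' target sets intersect;
    reports group medians, sizes, and a two-sided Wilcoxon rank-sum p-value
    (missing when a group is empty).
    """
    if "loewe" not in experiments.columns:
        raise ValueError("experiments lack an observed loewe column")
    overlap_mask = np.array(
        [
            bool(targets[r["drug_a"]] & targets[r["drug_b"]])
            for _, r in experiments.iterrows()
        ]
    )
    loewe = experiments["loewe"].to_numpy(dtype=float)
    with_overlap = loewe[overlap_mask]
    without = loewe[~overlap_mask]
    result = {
        "n_overlapping": int(with_overlap.size),
        "n_non_overlapping": int(without.size),
        "median_overlapping": float(np.median(with_overlap)) if with_overlap.size else np.nan,
        "median_non_overlapping": float(np.median(without)) if without.size else np.nan,
        "p_value": np.nan,
    }
    if with_overlap.size and without.size:
        result["p_value"] = float(
            sps.mannwhitneyu(with_overlap, without, alternative="two-sided").pvalue
        )
    return result


def synergy_by_interaction_quartile(
    experiments: pd.DataFrame,
    targets: Mapping[str, frozenset[str]],
    network: GeneNetwork,
    n_permutations: int = 100,
    swaps_per_edge: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed synergy across quartiles of target-target NEA z-scores.

    The z-score of each unique combination is the NEA enrichment between the
    two drugs' target sets; experiments are binned by z quartiles and each
    bin's median observed Loewe score reported.  Degenerate (all-equal) z
    collapses to a single bin with a warning.
    """
    if "loewe" not in experiments.columns:
        raise ValueError("experiments lack an observed loewe column")
    rng = np.random.default_rng(seed)
    pairs = sorted(
        {canonical_pair(r["drug_a"], r["drug_b"]) for _, r in experiments.iterrows()}
    )
    z_of_pair = {}
    for pair in pairs:
        z_of_pair[pair] = nea_zscore(
            targets[pair[0]], targets[pair[1]], network,
            n_permutations=n_permutations, swaps_per_edge=swaps_per_edge,
            seed=int(rng.integers(0, 2**31 - 1)),
        ).z
    z = np.array(
        [
            z_of_pair[canonical_pair(r["drug_a"], r["drug_b"])]
            for _, r in experiments.iterrows()
        ]
    )
    if np.all(z == z[0]):
        warnings.warn("all interaction z-scores equal; single bin")
        return pd.DataFrame(
            [
                {
                    "z_bin": "all",
                    "n": len(experiments),
                    "median_z": float(z[0]),
                    "median_loewe": float(experiments["loewe"].median()),
                }
            ]
        )
    bins = pd.qcut(z, q=4, duplicates="drop")
    loewe = experiments["loewe"].to_numpy(dtype=float)
    rows = []
    for interval in bins.categories:
        mask = np.asarray(bins == interval)
        rows.append(
            {
                "z_bin": str(interval),
                "n": int(mask.sum()),
                "median_z": float(np.median(z[mask])),
                "median_loewe": float(np.median(loewe[mask])),
            }
        )
    return pd.DataFrame(rows)


def pas_predicts_interaction(
    features: pd.DataFrame,
    z_values,
    test_fraction: float = 0.3,
    n_estimators: int = 200,
    seed: int = 0,
) -> float:
    """Held-out Spearman between NEA z predicted from PAS and observed z.

    Fits a forest regression of the interaction z-score on the PAS features
    and evaluates rank correlation on a random held-out split.
    """
    z = np.asarray(z_values, dtype=float)
    if len(features) != z.size:
        raise ValueError("features and z_values are misaligned")
    rng = np.random.default_rng(seed)
    n = len(features)
    n_test = max(3, int(np.floor(n * test_fraction)))
    test_idx = rng.choice(n, size=n_test, replace=False)
    mask = np.zeros(n, dtype=bool)
    mask[test_idx] = True
    model = SynergyForest(n_estimators=n_estimators, random_state=seed)
    model.fit(features.iloc[~mask], z[~mask])
    pred = model.predict(features.iloc[mask])
    return spearman(pred, z[mask])
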