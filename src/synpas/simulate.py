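"""Synthetic inputs with planted ground truth for end-to-end testing.

The generator emits the seven mutually consistent inputs the pipeline needs —
gene network, pathway collection, expression matrix, driver catalogue, drug
targets, experiment table, ground truth — with a known causal structure:

* a directed Erdős–Rényi (or optionally scale-free) gene network, with extra
  "interaction" edges planted between the target genes of a random subset of
  drug pairs;
* ``n_causal_pathways`` causal pathways, each built around a signature drug
  pair: it contains both drugs' target genes plus a sample of their network
  descendants, so the downstream component of its PAS carries signal;
* expression that is TPM-like Normal noise, with per-(cell line, causal
  pathway) activation shifts on the log2 scale, clipped at zero;
* observed Loewe scores generated as

      loewe = baseline + β·mean_j(standardized PAS of causal pathway j)
                       + γ·(standardized target cross-link count)
                       + Normal(0, noise_sd),

  where the PAS entering the ground truth is computed with the package's own
  featurizer, so the signal is exactly expressible in the features a model
  sees.

Everything is reproducible from ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import networkx as nx
import numpy as np
import pandas as pd

from .io import GeneNetwork, PathwayCollection, canonical_pair, canonicalize_experiments
from .nea import count_cross_links
from .pas import PASFeaturizer

__all__ = ["SimulationConfig", "GroundTruth", "simulate_inputs", "split_experiments"]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic-data generator.

    The defaults define the reference study conditions used throughout the
    test suite: 2000 genes, 20 cell lines, 200 pathways, 600 experiments, a
    strong planted effect and small noise (sd=3 Loewe units), yielding Loewe
    scores with mean ~10, sd ~9 and roughly a tenth of experiments at or above
    the high-synergy cut-off of 20, comparable to a large combination screen.
    """

    n_genes: int = 2000
    n_cell_lines: int = 40
    n_pathways: int = 200
    pathway_size_range: tuple[int, int] = (10, 40)
    n_drugs: int = 15
    targets_per_drug: int = 2
    n_causal_pathways: int = 3
    n_experiments: int = 600
    effect_size_beta: float = 20.0
    interaction_gamma: float = 3.0
    noise_sd: float = 3.0
    baseline_loewe: float = 10.0
    network_edge_density: float = 0.0015
    network_model: Literal["erdos_renyi", "scale_free"] = "erdos_renyi"
    crosslink_rate: float = 0.3
    driver_pool_size: int = 150
    driver_rate: float = 0.2
    base_tpm: float = 100.0
    base_tpm_sd: float = 30.0
    activation_shift: float = 2.0
    activation_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_cell_lines": self.n_cell_lines,
            "n_pathways": self.n_pathways,
            "n_drugs": self.n_drugs,
            "targets_per_drug": self.targets_per_drug,
            "n_experiments": self.n_experiments,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.pathway_size_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid pathway_size_range")
        if hi > self.n_genes:
            raise ValueError("pathway larger than the gene universe")
        if self.n_causal_pathways > self.n_pathways:
            raise ValueError("more causal pathways than pathways")
        n_pairs = self.n_drugs * (self.n_drugs - 1) // 2
        if self.n_causal_pathways > n_pairs:
            raise ValueError("not enough drug pairs for the causal pathways")
        if self.n_experiments > n_pairs * self.n_cell_lines:
            raise ValueError("n_experiments exceeds the pair x cell-line grid")


@dataclass
class GroundTruth:
    """What was planted: causal pathways, noiseless synergy, coefficients."""

    causal_pathways: list[str]
    signature_pairs: dict[str, tuple[str, str]]
    true_loewe: pd.Series
    signal: pd.Series
    crosslink: pd.Series
    beta: float
    gamma: float
    noise_sd: float


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _make_network(cfg: SimulationConfig, rng: np.random.Generator) -> nx.DiGraph:
    seed = int(rng.integers(0, 2**31 - 1))
    if cfg.network_model == "scale_free":
        mg = nx.scale_free_graph(cfg.n_genes, seed=seed)
        g = nx.DiGraph()
        g.add_nodes_from(mg.nodes)
        g.add_edges_from((u, v) for u, v in mg.edges() if u != v)
    else:
        g = nx.fast_gnp_random_graph(
            cfg.n_genes, cfg.network_edge_density, seed=seed, directed=True
        )
    genes = _gene_names(cfg.n_genes)
    return nx.relabel_nodes(g, {i: genes[i] for i in g.nodes})


def simulate_inputs(
    config: SimulationConfig | None = None,
) -> tuple[
    GeneNetwork,
    PathwayCollection,
    pd.DataFrame,
    dict[str, frozenset[str]],
    dict[str, frozenset[str]],
    pd.DataFrame,
    GroundTruth,
]:
    """Generate the seven pipeline inputs with planted structure.

    Returns ``(network, pathways, expression, drivers, targets, experiments,
    ground_truth)``.  The expression matrix is log2(x+1)-transformed, as the
    featurizer expects.
    """
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = np.array(_gene_names(cfg.n_genes))
    cells = [f"CL{i:03d}" for i in range(cfg.n_cell_lines)]
    drugs = [f"D{i:03d}" for i in range(cfg.n_drugs)]

    graph = _make_network(cfg, rng)

    # Drug targets: distinct genes per drug; drugs may share targets only by
    # chance (they do not here since we sample without replacement overall,
    # falling back to per-drug sampling if the universe is small).
    need = cfg.n_drugs * cfg.targets_per_drug
    if need <= cfg.n_genes:
        flat = rng.choice(genes, size=need, replace=False)
        targets = {
            d: frozenset(flat[i * cfg.targets_per_drug : (i + 1) * cfg.targets_per_drug])
            for i, d in enumerate(drugs)
        }
    else:
        targets = {
            d: frozenset(rng.choice(genes, size=cfg.targets_per_drug, replace=False))
            for d in drugs
        }

    # Planted functional-interaction edges between target sets of random pairs.
    all_pairs = [
        canonical_pair(drugs[i], drugs[j])
        for i in range(cfg.n_drugs)
        for j in range(i + 1, cfg.n_drugs)
    ]
    for pair in all_pairs:
        if rng.random() < cfg.crosslink_rate:
            ta, tb = sorted(targets[pair[0]]), sorted(targets[pair[1]])
            n_links = int(rng.integers(1, 3))
            for _ in range(n_links):
                u = ta[int(rng.integers(len(ta)))]
                v = tb[int(rng.integers(len(tb)))]
                if u != v:
                    graph.add_edge(u, v)
    network = GeneNetwork(graph=graph)

    # Causal pathways: signature pair's targets + their network descendants.
    lo, hi = cfg.pathway_size_range
    causal_names = [f"PW{i:04d}" for i in range(cfg.n_causal_pathways)]
    pair_order = rng.permutation(len(all_pairs))
    signature_pairs = {
        causal_names[i]: all_pairs[pair_order[i]] for i in range(cfg.n_causal_pathways)
    }
    entries: dict[str, frozenset[str]] = {}
    for name in causal_names:
        a, b = signature_pairs[name]
        tg = set(targets[a] | targets[b])
        desc: set[str] = set()
        for t in tg:
            if t in graph:
                desc |= nx.descendants(graph, t)
        desc -= tg
        size = int(rng.integers(max(lo, hi - 5), hi + 1))
        n_desc = min(len(desc), size - len(tg))
        members = set(tg)
        if n_desc > 0:
            members |= set(rng.choice(sorted(desc), size=n_desc, replace=False))
        while len(members) < size:
            members.add(str(rng.choice(genes)))
        entries[name] = frozenset(members)
    for i in range(cfg.n_causal_pathways, cfg.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        entries[f"PW{i:04d}"] = frozenset(rng.choice(genes, size=size, replace=False))
    pathways = PathwayCollection(entries=entries)

    # Driver catalogue: a recurrent "cancer gene" pool, sampled per cell line.
    # The pool avoids causal-pathway genes: driver sets are cell-line-only
    # functions, and seeding them with activated genes would hand every random
    # pathway a cell-line proxy of the planted signal through its dr column.
    causal_genes = set().union(*(entries[n] for n in causal_names))
    candidates = np.array(sorted(set(genes) - causal_genes))
    pool = rng.choice(candidates, size=cfg.driver_pool_size, replace=False)
    drivers = {
        c: frozenset(pool[rng.random(len(pool)) < cfg.driver_rate]) for c in cells
    }

    # Expression: TPM-like noise with per-(cell, causal pathway) activation on
    # the log2 scale, clipped at zero, then log2(x+1).
    raw = rng.normal(cfg.base_tpm, cfg.base_tpm_sd, size=(cfg.n_genes, cfg.n_cell_lines))
    gene_index = {g: i for i, g in enumerate(genes)}
    activation = rng.normal(
        cfg.activation_shift,
        cfg.activation_sd,
        size=(cfg.n_cell_lines, cfg.n_causal_pathways),
    )
    for j, name in enumerate(causal_names):
        idx = [gene_index[g] for g in entries[name]]
        raw[np.ix_(idx, range(cfg.n_cell_lines))] *= 2.0 ** activation[:, j][None, :]
    raw = np.clip(raw, 0.0, None)
    expression = pd.DataFrame(
        np.log2(raw + 1.0), index=list(genes), columns=cells
    )

    # Experiment grid: sample (pair, cell line) without replacement.
    grid = [(p, c) for p in all_pairs for c in cells]
    chosen = rng.choice(len(grid), size=cfg.n_experiments, replace=False)
    rows = [
        {"drug_a": grid[i][0][0], "drug_b": grid[i][0][1], "cell_line": grid[i][1]}
        for i in chosen
    ]
    experiments = canonicalize_experiments(pd.DataFrame(rows))

    # Ground-truth synergy from the package's own PAS of the causal pathways.
    causal_collection = PathwayCollection(
        entries={n: entries[n] for n in causal_names}
    )
    feat = PASFeaturizer(
        pathways=causal_collection,
        expression=expression,
        network=network,
        drivers=drivers,
        targets=targets,
    ).fit(experiments)
    causal_pas = feat.transform(experiments)
    per_pathway = pd.DataFrame(
        {
            n: causal_pas[[f"{n}:u", f"{n}:d", f"{n}:dr"]].sum(axis=1)
            for n in causal_names
        }
    )
    standardized = (per_pathway - per_pathway.mean()) / per_pathway.std(ddof=0).replace(
        0.0, 1.0
    )
    signal = standardized.mean(axis=1)

    pair_link = {
        p: count_cross_links(targets[p[0]], targets[p[1]], network) for p in all_pairs
    }
    link = pd.Series(
        [
            pair_link[canonical_pair(r["drug_a"], r["drug_b"])]
            for _, r in experiments.iterrows()
        ],
        index=experiments.index,
        dtype=float,
    )
    link_sd = link.std(ddof=0)
    crosslink = (link - link.mean()) / (link_sd if link_sd > 0 else 1.0)

    true_loewe = (
        cfg.baseline_loewe
        + cfg.effect_size_beta * signal
        + cfg.interaction_gamma * crosslink
    )
    noise = rng.normal(0.0, cfg.noise_sd, size=len(true_loewe))
    experiments["loewe"] = true_loewe + noise

    truth = GroundTruth(
        causal_pathways=causal_names,
        signature_pairs=signature_pairs,
        true_loewe=true_loewe,
        signal=signal,
        crosslink=crosslink,
        beta=cfg.effect_size_beta,
        gamma=cfg.interaction_gamma,
        noise_sd=cfg.noise_sd,
    )
    return network, pathways, expression, drivers, targets, experiments, truth


def split_experiments(
    table: pd.DataFrame,
    mode: Literal["testset1", "testset2"],
    fraction: float = 0.25,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split experiments the way the two evaluation regimes require.

    ``testset1``: held-out rows whose (drug_a, drug_b) combination also occurs
    in the training split (within-combination generalization: new cell lines
    for known combinations).  ``testset2``: whole combinations are held out,
    so train and test share zero combinations (novel-combination
    generalization).
    """
    if table.empty:
        raise ValueError("experiment table is empty")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    combos = [
        canonical_pair(r["drug_a"], r["drug_b"]) for _, r in table.iterrows()
    ]
    combo_key = pd.Series([f"{a}+{b}" for a, b in combos], index=table.index)

    test_idx: list = []
    if mode == "testset1":
        for _, group in table.groupby(combo_key, sort=True):
            if len(group) < 2:
                continue
            n_test = min(int(np.floor(len(group) * fraction)), len(group) - 1)
            if n_test < 1:
                continue
            pick = rng.choice(group.index.to_numpy(), size=n_test, replace=False)
            test_idx.extend(pick.tolist())
    elif mode == "testset2":
        unique = sorted(combo_key.unique())
        order = rng.permutation(len(unique))
        target_rows = int(np.floor(len(table) * fraction))
        picked_rows = 0
        held: set[str] = set()
        for k in order:
            if picked_rows >= target_rows:
                break
            key = unique[k]
            held.add(key)
            picked_rows += int((combo_key == key).sum())
        test_idx = table.index[combo_key.isin(held)].tolist()
    else:
        raise ValueError(f"unknown split mode {mode!r}")

    test_mask = table.index.isin(test_idx)
    return table.loc[~test_mask].copy(), table.loc[test_mask].copy()
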