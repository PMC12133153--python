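"""Network enrichment analysis (NEA): functional-interaction z-scores.

Two gene sets A and B functionally interact when the network contains more
edges between them than expected by chance.  The statistic is

    z = (observed cross-links - null mean) / null sd,

where the null distribution is obtained by degree-preserving rewiring of the
network.  Cross-links are counted on the undirected skeleton (an edge counts
whichever way it points), so the rewiring null also randomizes the undirected
skeleton: a lazy Metropolis double-edge-swap walk whose stationary distribution
is uniform over simple graphs with the observed degree sequence.

z > 1.96 (one-sided 2.5%) is the conventional cut-off for declaring a strong
functional interaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .io import GeneNetwork

__all__ = [
    "NEAResult",
    "count_cross_links",
    "rewire_network",
    "nea_zscore",
    "z_to_prob",
]


@dataclass(frozen=True)
class NEAResult:
    """Cross-link enrichment of two gene sets on a network."""

    observed_links: int
    null_mean: float
    null_sd: float
    z: float
    n_permutations: int
    degenerate_null: bool = False

    @property
    def probability(self) -> float:
        """The z-score mapped through the standard normal CDF."""
        return z_to_prob(self.z)


def count_cross_links(
    set_a: frozenset[str] | set[str],
    set_b: frozenset[str] | set[str],
    network: GeneNetwork,
) -> int:
    """Count distinct undirected edges with one endpoint in A and one in B.

    Direction is ignored; an edge lying inside the intersection A ∩ B is
    counted once.
    """
    count = 0
    for edge in network.undirected_edges():
        u, v = tuple(edge)
        if (u in set_a and v in set_b) or (u in set_b and v in set_a):
            count += 1
    return count


def rewire_network(
    network: GeneNetwork,
    swaps_per_edge: int = 10,
    seed: int | np.random.Generator | None = None,
) -> GeneNetwork:
    """Degree-preserving randomization of the network's undirected skeleton.

    Runs ``swaps_per_edge * n_edges`` attempted double-edge swaps: two edges
    (a,b), (c,d) are replaced by (a,d), (c,b) (or (a,c), (b,d)) unless that
    would create a self-loop or duplicate edge, in which case the walk stays
    put.  Staying put on rejection makes the walk a lazy Metropolis chain with
    a uniform stationary distribution over simple graphs with the input degree
    sequence.  The degree multiset is preserved exactly.
    """
    if swaps_per_edge < 1:
        raise ValueError("swaps_per_edge must be >= 1")
    rng = np.random.default_rng(seed)
    edges = [tuple(sorted(e)) for e in network.undirected_edges()]
    m = len(edges)
    if m < 2:
        warnings.warn("network has fewer than 2 edges; returned unchanged")
        return GeneNetwork.from_edges(list(edges), directed=False)

    edge_set = set(edges)
    n_attempts = swaps_per_edge * m
    before = sorted(network.undirected_degrees().values())
    for _ in range(n_attempts):
        i, j = rng.choice(m, size=2, replace=False)
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            new1, new2 = tuple(sorted((a, d))), tuple(sorted((c, b)))
        else:
            new1, new2 = tuple(sorted((a, c))), tuple(sorted((b, d)))
        if new1[0] == new1[1] or new2[0] == new2[1]:
            continue
        if new1 == new2 or new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(edges[i])
        edge_set.discard(edges[j])
        edge_set.add(new1)
        edge_set.add(new2)
        edges[i], edges[j] = new1, new2
    rewired = GeneNetwork.from_edges(edges, directed=False)
    after = sorted(rewired.undirected_degrees().values())
    assert before == after, "rewiring changed the degree multiset"
    return rewired


def nea_zscore(
    set_a: frozenset[str] | set[str],
    set_b: frozenset[str] | set[str],
    network: GeneNetwork,
    n_permutations: int = 100,
    swaps_per_edge: int = 10,
    seed: int | np.random.Generator | None = None,
) -> NEAResult:
    """NEA z-score of the cross-link count between two gene sets.

    The null mean and sd are the sample statistics of the cross-link count over
    ``n_permutations`` independently rewired networks.  Symmetric in its two
    set arguments at a fixed seed.  A degenerate null (sd = 0) reports z = 0
    with ``degenerate_null=True`` so downstream quadrant analyses stay total.
    """
    if not set_a or not set_b:
        raise ValueError("nea_zscore requires two non-empty gene sets")
    if n_permutations < 2:
        raise ValueError("n_permutations must be >= 2")
    rng = np.random.default_rng(seed)
    observed = count_cross_links(set_a, set_b, network)
    null_counts = np.empty(n_permutations, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(n_permutations):
            rewired = rewire_network(network, swaps_per_edge=swaps_per_edge, seed=rng)
            null_counts[k] = count_cross_links(set_a, set_b, rewired)
    null_mean = float(null_counts.mean())
    null_sd = float(null_counts.std(ddof=1))
    if null_sd == 0.0:
        return NEAResult(
            observed_links=observed,
            null_mean=null_mean,
            null_sd=0.0,
            z=0.0,
            n_permutations=n_permutations,
            degenerate_null=True,
        )
    z = (observed - null_mean) / null_sd
    return NEAResult(
        observed_links=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=float(z),
        n_permutations=n_permutations,
    )


def z_to_prob(z: float) -> float:
    """Map a z-score to a normal probability score, the standard normal CDF."""
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    return float(norm.cdf(z))
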