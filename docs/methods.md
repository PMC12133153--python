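# Methods

## Pathway activation scores

The unit of prediction is the experiment (drug A + drug B, cell line C) with
a precomputed Loewe synergy score. Dose–response processing is out of scope:
the package consumes per-experiment Loewe scalars.

For each pathway P the gene partition is computed on the directed
gene-interaction network supplied by the user (the method is agnostic to
which curated network it is):

* **Gu** contains all target genes of the two drugs — including targets that
  are not members of P, taken literally from the subgroup definition; a
  `targets_in_pathway_only` flag restricts to members — plus every pathway
  gene from which some target is reachable along directed edges (ancestors,
  found by breadth-first search over the full network, then intersected with
  P).
* **Gd** contains the pathway genes reachable from some target (descendants)
  that are not already in Gu. On cycles a gene can be both ancestor and
  descendant; upstream wins, keeping Gu ∩ Gd = ∅ (Gu already absorbs the
  targets themselves).
* Pathway genes with no directed path to or from any target belong to
  neither set: they carry no positional information relative to the targets.
* **Gdr** is the intersection of C's driver catalogue with P.

PAS are plain sums of log2-transformed expression over these sets; genes
missing from the expression matrix contribute 0, so absent gene sets yield
PAS = 0 rather than missing values. Expression files are transformed as
log2(x + 1) on load — the pseudocount maps zero TPM to 0 and avoids −∞; raw
negative values under the log flag are rejected. Drug pairs are
canonicalized lexicographically on load, so (A, B) and (B, A) featurize
identically.

Driver catalogues are prepared with the filters used for public cell-line
panels: a mutated gene is retained when it occurs in at least 2.5% of all
cell lines (inclusive), and a gene fusion when it appears in a supplied
catalogue of known fusions and occurs at least twice (inclusive). Fusion
identifiers are appended verbatim to the per-cell-line driver sets; no
splitting of fusion names into partner genes is attempted, and no gene-alias
resolution is performed anywhere (symbols match exactly, case-sensitively).

## Synergy regression and confidence scores

The regressor is a random forest with 500 trees and mtry = p/3 (the
regression default of the classic R forest implementations), unlimited depth;
all hyperparameters are exposed. The bootstrap ensemble refits the forest on
Nb = 100 resamples of the training experiments (by row, with replacement,
size preserved; no stratification by cell line — configurable). The
confidence score of a prediction is the fraction of ensemble predictions at
or above the synergy threshold of 20 Loewe units (inclusive). A display
cut-off of 0.75 for "confident" calls is a presentation default only.
Feature importance is the permutation (Breiman–Cutler) importance: the
increase in mean-squared prediction error when one feature column is
shuffled, averaged over repeats.

Test-set Spearman correlations (average ranks for ties; a constant vector is
an error, not 0) get bootstrap standard errors (sd of replicate
correlations, ddof = 1), normal 95% intervals ρ̂ ± 1.96·se, and the
bias-corrected estimate 2ρ̂ − mean(ρ̂*). Method comparisons use the
two-sided bootstrap p-value 2·min{P(d < 0), P(d > 0)} computed under a
normal fit to the replicate differences d, capped at 1; replicates with
numerically zero spread are rejected as degenerate rather than yielding
p = 0.

Monotherapy sensitivity grouping treats a drug as sensitive in an experiment
when its response meets or exceeds (inclusive) the drug's median response
across all experiments. The response column is used as given — larger =
more sensitive; a `negate_response` flag accommodates raw IC50 inputs where
the orientation is reversed.

## Network enrichment analysis

The functional interaction between two gene sets is
z = (observed − null mean)/null sd, where the observed statistic counts
distinct undirected edges with one endpoint in each set (an edge inside the
intersection counts once). The null rewires the network's undirected
skeleton by double-edge swaps: `swaps_per_edge × m` attempted swaps, with
invalid proposals (self-loop, duplicate) rejected in place. Because
rejection leaves the state unchanged and proposals are symmetric, the walk
is a lazy Metropolis chain whose stationary distribution is uniform over
simple graphs with the observed degree sequence, and the double-edge-swap
chain is connected over that space — which is what makes the exhaustive
enumeration oracle in the test suite a valid reference. Counting ignores
direction, so randomizing the undirected skeleton is the matching null;
degree multisets are asserted preserved on every call. Defaults:
100 permutations, 10 swaps per edge. A degenerate null (sd = 0, e.g. a
network too small to rewire) reports z = 0 with a flag instead of ±∞ so that
quadrant analyses stay total.

z-scores are mapped to normal probability scores Φ(z) for the alternative
sparsity-robust pathway feature S(g)·(w1 + w2), where S(g) is the total
pathway expression and w1, w2 are Φ(z) against the combination's targets and
the cell line's drivers; the feature is exactly zero when the pathway
contains no target and no driver gene and has no cross-links with either
set.

## Interpretation conventions

Per-pathway importance aggregates the pathway's three PAS columns by
maximum (a pathway is interesting if any component is; mean is available).
The "median PAS" of a pathway for a combination is the median over the
supplied experiments of that combination (a single experiment is its own
median). The shortlist takes the top ⌊0.05·N⌋ pathways by rank on each axis
and intersects, so it never exceeds 5% of N. Quadrant flags require both
NEA z-scores strictly above 1.96. The target-overlap synergy comparison
uses a two-sided Wilcoxon rank-sum test; the interaction analysis bins
experiments by quartiles of the target–target z-score (right-closed
empirical quartiles) and reports per-bin medians.

## Synthetic data generator

The generator emulates a pan-cancer combination screen at reference
conditions of 2000 genes, 40 cell lines, 15 drugs (2 targets each),
200 pathways (3 causal), and 600 experiments sampled without replacement
from the pair × cell-line grid:

* **Network**: directed Erdős–Rényi with edge density 0.0015 (mean degree
  ≈ 3, supporting non-trivial ancestor/descendant structure); a scale-free
  option exists. Extra edges are planted between the target sets of a
  random 30% of drug pairs so that target cross-linkage varies.
* **Causal pathways** are built around a signature drug pair: both drugs'
  targets plus a sample of their network descendants (sizes at the top of
  the 10–40 range), so the downstream PAS component carries signal.
* **Expression** is TPM-like Normal noise (mean 100, sd 30, clipped at 0)
  with per-(cell line, causal pathway) activation shifts of 2.0 ± 0.5 on the
  log2 scale, then log2(x + 1).
* **Drivers** are drawn per cell line from a recurrent 150-gene pool kept
  disjoint from causal-pathway genes: driver sets are functions of the cell
  line alone, and seeding them with activated genes would hand every pathway
  a cell-line proxy of the signal through its PASdr column, making
  importance attribution meaningless.
* **Observed synergy** is baseline 10 + β·(mean standardized total PAS of
  the causal pathways, computed with the package's own featurizer so the
  signal is expressible in the features a model sees) + γ·(standardized
  target cross-link count) + Normal(0, noise_sd), with β = 20, γ = 3,
  noise_sd = 3. This yields Loewe scores with mean ≈ 10, sd ≈ 9 and roughly
  a tenth of experiments at or above 20, comparable to large public screens.

Split semantics mirror the two evaluation regimes: `testset1` holds out rows
whose combination stays represented in training; `testset2` holds out whole
combinations.

What the generator does **not** emulate: correlated co-expression modules,
dose–response measurement error structure, tissue heterogeneity, overlapping
or hierarchical pathway collections, hub-dominated interaction networks
(unless the scale-free option is chosen), and drug off-target effects.
Passing tests therefore demonstrate that the machinery recovers signal that
is expressible in PAS under clean conditions — not that comparable accuracy
is attainable on real screens, where reported correlations are far lower.

## Problem sizes and numerical choices in tests

The test suite and `scripts/acceptance.py` run the reference conditions with
forests of 100–200 trees and bootstrap ensembles of 20–30 refits of 30–100
trees: at 600 features these sizes leave the forest's ranking behavior
converged while keeping multi-seed experiments (20 seeds) practical on one
CPU; model defaults remain 500 trees / Nb = 100. The null-safety check uses
a held-out fraction of 0.8 (test n ≈ 440) so that the ±0.15 acceptance band
on a null correlation sits at ≈ 3 sampling standard errors. The NEA oracle
comparison uses 2000 permutations on a 5-edge graph against exhaustive
enumeration, with agreement required within 3 Monte-Carlo standard errors
(delta-method se for the z-score). Quartile bins are right-closed; empty
calibration bins are reported missing rather than 0; all randomness flows
from per-call seeds through `numpy.random.default_rng`.

## Known limitations

* Reachability-based up/downstream assignment ignores edge sign (activation
  vs inhibition) and path length; a gene ten hops upstream counts like a
  direct regulator.
* PAS sums are not normalized by gene-set size, so larger pathways have
  larger scores; the forest is scale-tolerant, but cross-pathway PAS
  comparisons inherit size effects.
* The rewiring null preserves degrees only, not clustering or community
  structure; NEA z-scores on highly modular networks can overstate
  enrichment.
* Bootstrap confidence scores quantify training-resampling uncertainty, not
  input noise or model misspecification.
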