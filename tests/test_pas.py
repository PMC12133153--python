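import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synpas.io import GeneNetwork, PathwayCollection
from synpas.pas import (
    AltFeature,
    GenePartition,
    PASFeaturizer,
    alt_pathway_feature,
    build_feature_matrix,
    classify_pathway_genes,
    compute_pas,
    pas_columns,
)


class TestClassify:
    def test_chain_partition(self, chain_network):
        """On a->b->t->c->d with target t: ancestors upstream, descendants down."""
        part = classify_pathway_genes(
            {"a", "b", "t", "c", "d"}, {"t"}, chain_network
        )
        assert part.gu == {"a", "b", "t"}
        assert part.gd == {"c", "d"}

    def test_edgeless_network(self):
        net = GeneNetwork.from_edges([])
        part = classify_pathway_genes({"x", "y"}, {"t"}, net)
        assert part.gu == {"t"}
        assert part.gd == frozenset()

    def test_unreachable_genes_in_neither_set(self, chain_network):
        part = classify_pathway_genes({"a", "d", "q"}, {"t"}, chain_network)
        assert "q" not in part.gu and "q" not in part.gd

    def test_cycle_gene_assigned_upstream(self):
        # t -> x -> t: x is both ancestor and descendant; upstream wins
        net = GeneNetwork.from_edges([("t", "x"), ("x", "t")])
        part = classify_pathway_genes({"x"}, {"t"}, net)
        assert "x" in part.gu
        assert part.gd == frozenset()

    def test_targets_outside_pathway_configurable(self, chain_network):
        pathway = {"c", "d"}
        default = classify_pathway_genes(pathway, {"t"}, chain_network)
        assert "t" in default.gu
        restricted = classify_pathway_genes(
            pathway, {"t"}, chain_network, targets_in_pathway_only=True
        )
        assert "t" not in restricted.gu

    def test_empty_targets_rejected(self, chain_network):
        with pytest.raises(ValueError, match="no targets"):
            classify_pathway_genes({"a"}, set(), chain_network)

    def test_gu_gd_disjoint_invariant(self, small_world):
        net = small_world["network"]
        targets = small_world["targets"]
        drug_pair = sorted(targets)[:2]
        tset = frozenset(targets[drug_pair[0]] | targets[drug_pair[1]])
        for name in small_world["pathways"].names[:10]:
            part = classify_pathway_genes(small_world["pathways"][name], tset, net)
            assert not (part.gu & part.gd)
            assert tset <= part.gu


class TestComputePas:
    def test_zero_expression(self):
        part = GenePartition(gu=frozenset("ab"), gd=frozenset("c"), gdr=frozenset())
        v = compute_pas(part, {"a": 0.0, "b": 0.0, "c": 0.0})
        assert (v.pas_u, v.pas_d, v.pas_dr) == (0.0, 0.0, 0.0)

    def test_direct_sum_and_missing_genes(self):
        part = GenePartition(gu=frozenset({"g1", "g2", "absent"}), gd=frozenset())
        v = compute_pas(part, {"g1": 1.5, "g2": 2.5})
        assert v.pas_u == 4.0
        assert v.pas_dr == 0.0  # empty Gdr

    @given(
        values=st.lists(
            st.floats(0, 100, allow_nan=False), min_size=2, max_size=10
        ),
        split=st.integers(1, 9),
    )
    @settings(max_examples=40, deadline=None)
    def test_additive_over_partition(self, values, split):
        """PAS of a gene set equals the sum of PAS over any two-way split."""
        split = min(split, len(values) - 1)
        genes = [f"g{i}" for i in range(len(values))]
        expr = dict(zip(genes, values))
        whole = GenePartition(gu=frozenset(genes), gd=frozenset())
        left = GenePartition(gu=frozenset(genes[:split]), gd=frozenset())
        right = GenePartition(gu=frozenset(genes[split:]), gd=frozenset())
        total = compute_pas(whole, expr).pas_u
        assert total == pytest.approx(
            compute_pas(left, expr).pas_u + compute_pas(right, expr).pas_u
        )


class TestFeatureMatrix:
    def test_three_columns_per_pathway(self, small_world):
        X = build_feature_matrix(
            small_world["experiments"].head(5),
            small_world["pathways"],
            small_world["expression"],
            small_world["drivers"],
            small_world["targets"],
            small_world["network"],
        )
        n = small_world["pathways"].n_pathways
        assert X.shape == (5, 3 * n)
        assert list(X.columns) == pas_columns(small_world["pathways"])

    def test_swapping_drug_order_identical_row(self, small_world):
        exp = small_world["experiments"].head(1).copy()
        swapped = exp.copy()
        swapped[["drug_a", "drug_b"]] = exp[["drug_b", "drug_a"]].to_numpy()
        args = (
            small_world["pathways"],
            small_world["expression"],
            small_world["drivers"],
            small_world["targets"],
            small_world["network"],
        )
        X1 = build_feature_matrix(exp, *args)
        X2 = build_feature_matrix(swapped, *args)
        np.testing.assert_array_equal(X1.to_numpy(), X2.to_numpy())

    def test_repeated_builds_bit_identical(self, small_world):
        args = (
            small_world["experiments"].head(8),
            small_world["pathways"],
            small_world["expression"],
            small_world["drivers"],
            small_world["targets"],
            small_world["network"],
        )
        X1, X2 = build_feature_matrix(*args), build_feature_matrix(*args)
        assert X1.equals(X2)

    def test_unknown_drug_or_cell_line_named_in_error(self, small_world):
        bad = small_world["experiments"].head(1).copy()
        bad.loc[bad.index[0], "drug_a"] = "NOSUCH"
        with pytest.raises(ValueError, match="NOSUCH"):
            build_feature_matrix(
                bad,
                small_world["pathways"],
                small_world["expression"],
                small_world["drivers"],
                small_world["targets"],
                small_world["network"],
            )

    def test_gdr_is_driver_pathway_intersection(self, small_world):
        """The dr column equals the expression sum over drivers ∩ pathway."""
        exp = small_world["experiments"].head(3)
        X = build_feature_matrix(
            exp,
            small_world["pathways"],
            small_world["expression"],
            small_world["drivers"],
            small_world["targets"],
            small_world["network"],
        )
        name = small_world["pathways"].names[0]
        for idx, row in exp.iterrows():
            cell = row["cell_line"]
            genes = small_world["drivers"].get(cell, frozenset()) & small_world[
                "pathways"
            ][name]
            expected = sum(
                small_world["expression"].loc[g, cell]
                for g in genes
                if g in small_world["expression"].index
            )
            assert X.loc[idx, f"{name}:dr"] == pytest.approx(expected)


class TestAltFeature:
    def _toy(self):
        net = GeneNetwork.from_edges(
            [("p1", "t1"), ("p2", "d1"), ("x1", "x2"), ("x2", "x3"), ("x3", "x4")]
        )
        expr = {"p1": 2.0, "p2": 3.0}
        return net, expr

    def test_zero_when_isolated(self):
        net, expr = self._toy()
        feat = alt_pathway_feature(
            {"q1", "q2"}, {"t1"}, {"d1"}, {"q1": 5.0, "q2": 5.0}, net, seed=0
        )
        assert feat.w1 == 0.0 and feat.w2 == 0.0 and feat.value == 0.0

    def test_zero_expression_zero_value(self):
        net, _ = self._toy()
        feat = alt_pathway_feature(
            {"p1", "p2"}, {"t1"}, {"d1"}, {}, net, n_permutations=20, seed=0
        )
        assert feat.s_g == 0.0 and feat.value == 0.0

    def test_phi_of_zero_gives_half(self):
        # value = S(g) * (Φ(z1) + Φ(z2)) = S(g) * 1.0 when both z are 0
        f = AltFeature(s_g=6.0, w1=0.5, w2=0.5)
        assert f.value == 6.0
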