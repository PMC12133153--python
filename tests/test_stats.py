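import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm, rankdata

from synpas.stats import (
    bootstrap_ci,
    bootstrap_pvalue,
    compare_methods,
    cs_calibration,
    overlap_groups,
    sensitivity_groups,
    spearman,
)


def rank_formula_spearman(x, y):
    """1 - 6*sum(d^2)/(n(n^2-1)), valid for tie-free vectors."""
    rx, ry = rankdata(x), rankdata(y)
    d = rx - ry
    n = len(x)
    return 1 - 6 * (d**2).sum() / (n * (n**2 - 1))


class TestSpearman:
    def test_perfect_and_reversed(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [40, 30, 20, 10]) == pytest.approx(-1.0)

    def test_rank_formula_oracle(self):
        # (1,2,3,4) vs (1,3,2,4): d = (0,-1,1,0), 1 - 6*2/60 = 0.8
        assert spearman([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_rank_formula_on_tie_free_vectors(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        x = rng.permutation(n).astype(float)
        y = rng.permutation(n).astype(float)
        assert spearman(x, y) == pytest.approx(rank_formula_spearman(x, y))

    def test_average_rank_tie_handling(self):
        """With ties, correlation of average ranks equals the reported value."""
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0])
        y = np.array([3.0, 1.0, 4.0, 4.0, 2.0, 6.0, 5.0])
        rx, ry = rankdata(x), rankdata(y)  # average ranks
        pearson_of_ranks = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y) == pytest.approx(pearson_of_ranks)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert spearman(np.exp(x), y) == pytest.approx(spearman(x, y))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBootstrapCI:
    def test_degenerate_replicates(self):
        s = bootstrap_ci(0.5, [0.5, 0.5, 0.5])
        assert s.se == 0.0 and s.bias == 0.0
        assert s.ci_low == s.ci_high == 0.5

    def test_bias_corrected_identity(self):
        s = bootstrap_ci(0.5, [0.4, 0.5, 0.45, 0.45])
        assert s.bias_corrected == pytest.approx(2 * 0.5 - np.mean([0.4, 0.5, 0.45, 0.45]))

    def test_hand_computed_two_replicates(self):
        # sd({0.4, 0.6}) = 0.1414..., CI = 0.5 ± 1.96*0.1414
        s = bootstrap_ci(0.5, [0.4, 0.6])
        assert s.se == pytest.approx(np.sqrt(0.02), rel=1e-12)
        assert s.ci_low == pytest.approx(0.5 - 1.96 * np.sqrt(0.02))
        assert s.ci_high == pytest.approx(0.5 + 1.96 * np.sqrt(0.02))

    @given(
        rho=st.floats(-1, 1),
        boots=st.lists(st.floats(-1, 1), min_size=2, max_size=50),
    )
    @settings(max_examples=40, deadline=None)
    def test_invariants(self, rho, boots):
        s = bootstrap_ci(rho, boots)
        assert s.ci_low <= s.rho_hat <= s.ci_high
        assert s.bias_corrected == pytest.approx(2 * rho - np.mean(boots), abs=1e-12)


class TestBootstrapPValue:
    def test_zero_mean_gives_one(self):
        assert bootstrap_pvalue([-1.0, 1.0, -2.0, 2.0]) == pytest.approx(1.0)

    def test_two_sd_mean_closed_form(self):
        # construct d with mean = 2*sd exactly: mean 2, sd 1
        d = np.array([1.0, 3.0, 1.0, 3.0])
        m, s = d.mean(), d.std(ddof=1)
        expected = 2 * norm.cdf(-m / s)
        assert bootstrap_pvalue(d) == pytest.approx(expected)

    def test_sign_flip_invariance(self):
        d = np.array([0.1, 0.3, 0.2, 0.25, 0.15])
        assert bootstrap_pvalue(d) == pytest.approx(bootstrap_pvalue(-d))

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            bootstrap_pvalue([0.2, 0.2, 0.2])


class TestCompareMethods:
    def test_better_method_small_p_identical_methods_large_p(self):
        rng = np.random.default_rng(0)
        obs = rng.normal(size=120)
        good = obs + rng.normal(0, 0.3, size=120)
        bad = rng.normal(size=120)
        res = compare_methods(good, bad, obs, n_bootstrap=60, seed=1)
        assert res.p_value < 0.01
        assert res.d.mean() > 0
        # swapping the two methods flips d but leaves the two-sided p alone
        res_swapped = compare_methods(bad, good, obs, n_bootstrap=60, seed=1)
        np.testing.assert_allclose(res_swapped.d, -res.d)
        assert res_swapped.p_value == pytest.approx(res.p_value)


class TestSensitivityGroups:
    def _mono(self, rows):
        return pd.DataFrame(rows, columns=["experiment", "drug", "response"])

    def test_all_identical_responses_all_sensitive(self):
        exps = pd.DataFrame(
            {"drug_a": ["A", "A"], "drug_b": ["B", "B"], "cell_line": ["c1", "c2"]},
            index=[0, 1],
        )
        mono = self._mono(
            [(0, "A", 1.0), (0, "B", 1.0), (1, "A", 1.0), (1, "B", 1.0)]
        )
        labels = sensitivity_groups(mono, exps)
        assert (labels == 2).all()  # S == median counts as sensitive (inclusive)

    def test_hand_computed_medians(self):
        # A responses: 1, 5, 9 -> T_A = 5; B responses: 2, 2, 8 -> T_B = 2
        exps = pd.DataFrame(
            {
                "drug_a": ["A", "A", "A"],
                "drug_b": ["B", "B", "B"],
                "cell_line": ["c1", "c2", "c3"],
            },
            index=[0, 1, 2],
        )
        mono = self._mono(
            [
                (0, "A", 1.0), (0, "B", 2.0),
                (1, "A", 5.0), (1, "B", 2.0),
                (2, "A", 9.0), (2, "B", 8.0),
            ]
        )
        labels = sensitivity_groups(mono, exps)
        assert labels.tolist() == [1, 2, 2]

    def test_missing_record_names_experiment(self):
        exps = pd.DataFrame(
            {"drug_a": ["A"], "drug_b": ["B"], "cell_line": ["c1"]}, index=[42]
        )
        mono = self._mono([(42, "A", 1.0)])
        with pytest.raises(ValueError, match="42"):
            sensitivity_groups(mono, exps)

    def test_negate_flag_flips_ic50_orientation(self):
        # raw IC50: lower = more sensitive
        exps = pd.DataFrame(
            {"drug_a": ["A", "A"], "drug_b": ["B", "B"], "cell_line": ["c1", "c2"]},
            index=[0, 1],
        )
        mono = self._mono(
            [(0, "A", 0.1), (0, "B", 10.0), (1, "A", 9.0), (1, "B", 10.0)]
        )
        plain = sensitivity_groups(mono, exps)
        flipped = sensitivity_groups(mono, exps, negate_response=True)
        assert plain[0] != flipped[0] or plain[1] != flipped[1]


class TestOverlapGroups:
    def test_counts(self):
        test = pd.DataFrame(
            {
                "drug_a": ["A", "A", "X"],
                "drug_b": ["B", "Y", "Y"],
                "cell_line": ["c"] * 3,
            }
        )
        labels = overlap_groups(test, training_drugs={"A", "B"})
        assert labels.tolist() == ["two drugs", "one drug", "no drug"]

    def test_empty_training_set(self):
        test = pd.DataFrame(
            {"drug_a": ["A"], "drug_b": ["B"], "cell_line": ["c"]}
        )
        assert overlap_groups(test, set()).tolist() == ["no drug"]


class TestCSCalibration:
    def test_all_correct_predictions(self):
        cs = np.linspace(0, 1, 40)
        pred = np.full(40, 25.0)
        obs = np.full(40, 30.0)
        table = cs_calibration(cs, pred, obs)
        assert (table["validated_proportion"] == 1.0).all()

    def test_empty_bin_reported_missing(self):
        cs = np.linspace(0, 1, 40)
        pred = np.where(cs > 0.75, 25.0, 5.0)  # no high predictions in low bins
        obs = np.full(40, 30.0)
        table = cs_calibration(cs, pred, obs)
        assert table["validated_proportion"].isna().sum() == 3
        assert table["validated_proportion"].iloc[-1] == 1.0

    def test_few_distinct_values_merges_with_warning(self):
        cs = np.array([0.0] * 30 + [1.0] * 10)
        with pytest.warns(UserWarning, match="merged"):
            table = cs_calibration(cs, np.full(40, 25.0), np.full(40, 25.0))
        assert len(table) < 4
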