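"""Evaluation statistics: Spearman correlation, bootstrap inference, groupings.

Prediction quality is summarized by the Spearman correlation between predicted
and observed Loewe scores.  Bootstrap replicates of the training set yield a
standard error (sd of the replicate correlations), the usual normal interval
ρ̂ ± 1.96·se, and a bias-corrected estimate 2ρ̂ − mean(ρ̂*).  Two methods are
compared by a two-sided bootstrap p-value computed from the per-replicate
correlation differences under a normal approximation.

Grouping analyses stratify test experiments by monotherapy sensitivity (a drug
is sensitive in an experiment when its response meets or exceeds the drug's
median response) and by how many of the combination's drugs occur in the
training set; CS calibration checks that the proportion of validated
high-synergy predictions rises across confidence-score quartiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import canonical_pair
from .model import SYNERGY_THRESHOLD

__all__ = [
    "CorrelationSummary",
    "ComparisonResult",
    "spearman",
    "bootstrap_ci",
    "bootstrap_pvalue",
    "compare_methods",
    "sensitivity_groups",
    "overlap_groups",
    "cs_calibration",
]


@dataclass(frozen=True)
class CorrelationSummary:
    """Observed Spearman correlation with bootstrap se, CI and bias correction."""

    rho_hat: float
    boot_rhos: np.ndarray
    se: float
    ci_low: float
    ci_high: float
    bias: float
    bias_corrected: float


@dataclass(frozen=True)
class ComparisonResult:
    """Bootstrap comparison of two methods' test-set correlations."""

    r1: np.ndarray
    r2: np.ndarray
    d: np.ndarray
    p_value: float


def compare_methods(
    pred1, pred2, obs, n_bootstrap: int = 100, seed: int = 0
) -> ComparisonResult:
    """Two-sided bootstrap p-value for a difference in Spearman correlations.

    For each bootstrap resample of the test experiments, the Spearman
    correlation of each method's predictions with the observed scores is
    computed; the replicate differences d = r1 - r2 feed
    :func:`bootstrap_pvalue`.
    """
    pred1 = np.asarray(pred1, dtype=float)
    pred2 = np.asarray(pred2, dtype=float)
    obs = np.asarray(obs, dtype=float)
    rng = np.random.default_rng(seed)
    n = obs.size
    r1, r2 = [], []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        o = obs[idx]
        if np.all(o == o[0]):
            continue
        r1.append(spearman(pred1[idx], o))
        r2.append(spearman(pred2[idx], o))
    r1, r2 = np.asarray(r1), np.asarray(r2)
    d = r1 - r2
    return ComparisonResult(r1=r1, r2=r2, d=d, p_value=bootstrap_pvalue(d))


def spearman(pred, obs) -> float:
    """Spearman rank correlation with average ranks for ties, in [-1, 1]."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("pred and obs must be equal-length 1-D vectors")
    if pred.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(pred == pred[0]) or np.all(obs == obs[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho = sps.spearmanr(pred, obs).statistic
    return float(rho)


def bootstrap_ci(rho_hat: float, boot_rhos) -> CorrelationSummary:
    """Bootstrap se, 95% CI and bias-corrected estimate for a correlation.

    se is the sd (ddof=1) of the bootstrap replicates, the interval is
    ρ̂ ± 1.96·se, and the bias-corrected estimate 2ρ̂ − mean(ρ̂*).
    """
    boot = np.asarray(boot_rhos, dtype=float)
    if boot.size < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    se = float(boot.std(ddof=1))
    bias = float(boot.mean() - rho_hat)
    return CorrelationSummary(
        rho_hat=float(rho_hat),
        boot_rhos=boot,
        se=se,
        ci_low=float(rho_hat - 1.96 * se),
        ci_high=float(rho_hat + 1.96 * se),
        bias=bias,
        bias_corrected=float(rho_hat - bias),
    )


def bootstrap_pvalue(d) -> float:
    """Two-sided bootstrap p-value for a difference of correlations.

    The per-replicate differences d are summarized by a normal fit
    N(mean(d), sd(d)); the p-value is twice the smaller of the two tail
    proportions P(d < 0) and P(d > 0), capped at 1.
    """
    d = np.asarray(d, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 replicates")
    s = d.std(ddof=1)
    m = d.mean()
    # identical replicates can leave a float-epsilon sd; treat as degenerate
    if s <= 1e-14 * max(1.0, abs(m)):
        raise ValueError("degenerate difference distribution (sd = 0)")
    lower = sps.norm.cdf(-m / s)  # P(d < 0) under the normal fit
    p = 2.0 * min(lower, 1.0 - lower)
    return float(min(p, 1.0))


def sensitivity_groups(
    mono: pd.DataFrame,
    experiments: pd.DataFrame,
    negate_response: bool = False,
) -> pd.Series:
    """Label each experiment by its count of monotherapy-sensitive drugs (0/1/2).

    ``mono`` has columns experiment, drug, response.  T_drug is the median
    response of that drug across all its experiments; the drug is sensitive in
    an experiment iff its response there meets or exceeds T_drug (inclusive).
    ``negate_response`` flips the sign first, for raw IC50-style inputs where
    lower means more sensitive.
    """
    mono = mono.copy()
    if negate_response:
        mono["response"] = -mono["response"]
    medians = mono.groupby("drug")["response"].median()
    lookup = {
        (r["experiment"], r["drug"]): r["response"] for _, r in mono.iterrows()
    }
    labels = []
    for idx, row in experiments.iterrows():
        count = 0
        for drug in (row["drug_a"], row["drug_b"]):
            key = (idx, drug)
            if key not in lookup:
                raise ValueError(
                    f"experiment {idx!r}: no monotherapy record for drug {drug!r}"
                )
            if lookup[key] >= medians[drug]:
                count += 1
        labels.append(count)
    return pd.Series(labels, index=experiments.index, name="n_sensitive")


def overlap_groups(test: pd.DataFrame, training_drugs: set[str]) -> pd.Series:
    """Label each test combination by its count of drugs seen in training.

    Returns 'no drug', 'one drug' or 'two drugs' per row.
    """
    names = {0: "no drug", 1: "one drug", 2: "two drugs"}
    labels = []
    for _, row in test.iterrows():
        a, b = canonical_pair(row["drug_a"], row["drug_b"])
        count = int(a in training_drugs) + int(b in training_drugs)
        labels.append(names[count])
    return pd.Series(labels, index=test.index, name="drugs_in_training")


def cs_calibration(
    confidence_scores,
    predicted,
    observed,
    synergy_threshold: float = SYNERGY_THRESHOLD,
) -> pd.DataFrame:
    """Validated-proportion of high-synergy calls per confidence-score quartile.

    Confidence scores are binned by their empirical quartiles (bins closed on
    the right).  Within each bin, the proportion of predictions >= threshold
    whose observed score is also >= threshold; a bin with no high-synergy
    prediction reports NaN.  Fewer than 4 distinct CS values merge bins with a
    warning.
    """
    cs = np.asarray(confidence_scores, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if not (cs.shape == pred.shape == obs.shape):
        raise ValueError("inputs must have equal length")
    try:
        bins = pd.qcut(cs, q=4, duplicates="raise")
    except ValueError:
        warnings.warn("fewer than 4 distinct confidence-score quantiles; bins merged")
        bins = pd.qcut(cs, q=4, duplicates="drop")
    rows = []
    for interval in bins.categories:
        in_bin = bins == interval
        high = in_bin & (pred >= synergy_threshold)
        prop = float((obs[high] >= synergy_threshold).mean()) if high.any() else np.nan
        rows.append(
            {
                "cs_bin": str(interval),
                "n": int(in_bin.sum()),
                "n_high_pred": int(high.sum()),
                "validated_proportion": prop,
            }
        )
    return pd.DataFrame(rows)
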