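"""Forest regression of Loewe synergy on PAS features.

The predictor is a random forest regressor (500 trees, mtry = p/3, the
regression defaults of the classic R implementations) trained on the K x 3N
PAS matrix.  Around the point prediction the module provides:

* a bootstrap ensemble — Nb refits of the forest on bootstrap resamples of the
  training experiments — whose per-experiment prediction spread carries the
  statistical uncertainty of the prediction;
* the confidence score CS = #(bootstrap predictions >= 20) / Nb, the fraction
  of the ensemble that calls the experiment synergistic (Loewe >= 20 being the
  conventional high-synergy cut-off);
* permutation (Breiman–Cutler) feature importance: the increase in prediction
  error when one feature column is shuffled.

All randomness flows from a single seed through named substreams.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.utils.validation import check_is_fitted

SYNERGY_THRESHOLD = 20.0

__all__ = [
    "SYNERGY_THRESHOLD",
    "SynergyForest",
    "BootstrapSynergyEnsemble",
    "train_model",
    "predict",
    "fit_bootstrap_ensemble",
    "confidence_score",
    "permutation_importance",
]


def _check_columns(X: pd.DataFrame, expected: list[str]) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if list(X.columns) != list(expected):
            missing = sorted(set(expected) - set(X.columns))
            extra = sorted(set(X.columns) - set(expected))
            if missing or extra:
                raise ValueError(
                    f"feature columns mismatch: missing {missing[:5]}, extra {extra[:5]}"
                )
            raise ValueError("feature columns are in a different order than at fit")
        return X.to_numpy(dtype=float)
    arr = np.asarray(X, dtype=float)
    if arr.shape[1] != len(expected):
        raise ValueError(
            f"expected {len(expected)} feature columns, got {arr.shape[1]}"
        )
    return arr


class SynergyForest(RegressorMixin, BaseEstimator):
    """Random-forest regressor of Loewe synergy on PAS features.

    Parameters
    ----------
    n_estimators : int, default 500
        Number of trees.
    max_features : float or str, default 1/3
        Features considered per split; 1/3 mirrors the mtry = p/3 regression
        default of the R random-forest packages.
    random_state : int, default 0
        Training seed; fixed seed + fixed data => identical predictions.

    Attributes
    ----------
    forest_ : fitted RandomForestRegressor
    feature_names_ : list of str
        Column order required by :meth:`predict`.
    """

    def __init__(
        self,
        n_estimators: int = 500,
        max_features: float | str = 1.0 / 3.0,
        max_depth: int | None = None,
        min_samples_leaf: int = 1,
        random_state: int = 0,
        n_jobs: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state
        self.n_jobs = n_jobs

    def fit(self, X: pd.DataFrame, y) -> "SynergyForest":
        y = np.asarray(y, dtype=float)
        if isinstance(X, pd.DataFrame):
            self.feature_names_ = list(X.columns)
            arr = X.to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
            self.feature_names_ = [f"x{i}" for i in range(arr.shape[1])]
        if arr.shape[0] < 2:
            raise ValueError("need at least 2 training experiments")
        if arr.shape[0] != y.shape[0]:
            raise ValueError("feature matrix and target length differ")
        if not np.isfinite(arr).all() or not np.isfinite(y).all():
            raise ValueError("features and target must be finite")
        self.forest_ = RandomForestRegressor(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.random_state,
            n_jobs=self.n_jobs,
        )
        self.forest_.fit(arr, y)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "forest_")
        arr = _check_columns(X, self.feature_names_)
        return self.forest_.predict(arr)


class BootstrapSynergyEnsemble(RegressorMixin, BaseEstimator):
    """Nb forest refits on bootstrap resamples of the training experiments.

    Resampling is by experiment row, with replacement, size preserved; the
    resample index sets are reproducible from ``random_state``.  ``predict``
    returns the ensemble-mean prediction; :meth:`predict_all` the full K x Nb
    matrix of bootstrap predictions and :meth:`confidence_score` the fraction
    of them at or above the synergy threshold.
    """

    def __init__(
        self,
        n_bootstrap: int = 100,
        n_estimators: int = 500,
        max_features: float | str = 1.0 / 3.0,
        max_depth: int | None = None,
        min_samples_leaf: int = 1,
        random_state: int = 0,
        n_jobs: int | None = None,
    ):
        self.n_bootstrap = n_bootstrap
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state
        self.n_jobs = n_jobs

    def fit(self, X: pd.DataFrame, y) -> "BootstrapSynergyEnsemble":
        if self.n_bootstrap < 2:
            raise ValueError("n_bootstrap must be >= 2")
        y = np.asarray(y, dtype=float)
        rng = np.random.default_rng(self.random_state)
        n = len(y)
        self.models_: list[SynergyForest] = []
        self.resample_indices_: list[np.ndarray] = []
        X_df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        for b in range(self.n_bootstrap):
            idx = rng.integers(0, n, size=n)
            model = SynergyForest(
                n_estimators=self.n_estimators,
                max_features=self.max_features,
                max_depth=self.max_depth,
                min_samples_leaf=self.min_samples_leaf,
                random_state=int(rng.integers(0, 2**31 - 1)),
                n_jobs=self.n_jobs,
            )
            model.fit(X_df.iloc[idx], y[idx])
            self.models_.append(model)
            self.resample_indices_.append(idx)
        self.feature_names_ = self.models_[0].feature_names_
        return self

    def predict_all(self, X: pd.DataFrame) -> np.ndarray:
        """K x Nb matrix of per-model bootstrap predictions."""
        check_is_fitted(self, "models_")
        return np.column_stack([m.predict(X) for m in self.models_])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.predict_all(X).mean(axis=1)

    def confidence_score(
        self, X: pd.DataFrame, threshold: float = SYNERGY_THRESHOLD
    ) -> np.ndarray:
        """Per-row fraction of bootstrap predictions >= threshold."""
        return (self.predict_all(X) >= threshold).mean(axis=1)


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------


def train_model(
    features: pd.DataFrame,
    observed_loewe,
    n_estimators: int = 500,
    max_features: float | str = 1.0 / 3.0,
    seed: int = 0,
    n_jobs: int | None = None,
) -> SynergyForest:
    model = SynergyForest(
        n_estimators=n_estimators,
        max_features=max_features,
        random_state=seed,
        n_jobs=n_jobs,
    )
    return model.fit(features, observed_loewe)


def predict(model: SynergyForest, features: pd.DataFrame) -> np.ndarray:
    return model.predict(features)


def fit_bootstrap_ensemble(
    features: pd.DataFrame,
    observed_loewe,
    n_bootstrap: int = 100,
    n_estimators: int = 500,
    seed: int = 0,
    n_jobs: int | None = None,
) -> BootstrapSynergyEnsemble:
    ens = BootstrapSynergyEnsemble(
        n_bootstrap=n_bootstrap,
        n_estimators=n_estimators,
        random_state=seed,
        n_jobs=n_jobs,
    )
    return ens.fit(features, observed_loewe)


def confidence_score(
    bootstrap_predictions, threshold: float = SYNERGY_THRESHOLD
) -> float:
    """CS = #(bootstrap predictions >= threshold) / Nb, in [0, 1]."""
    preds = np.asarray(bootstrap_predictions, dtype=float)
    if preds.size == 0:
        raise ValueError("bootstrap prediction vector is empty")
    return float((preds >= threshold).mean())


def permutation_importance(
    model: SynergyForest,
    features: pd.DataFrame,
    observed,
    n_repeats: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Permutation (Breiman–Cutler) importance per feature.

    The increase in mean-squared prediction error when a feature column is
    randomly permuted, averaged over ``n_repeats`` shuffles; length equals the
    number of feature columns.
    """
    check_is_fitted(model, "forest_")
    arr = _check_columns(features, model.feature_names_)
    res = _sk_permutation_importance(
        model.forest_,
        arr,
        np.asarray(observed, dtype=float),
        scoring="neg_mean_squared_error",
        n_repeats=n_repeats,
        random_state=seed,
    )
    return res.importances_mean
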