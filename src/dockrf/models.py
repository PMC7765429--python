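"""Affinity regressors: training, persistence, prediction, validation.

The production configuration is a random forest with 500 regression trees
and max_features = 0.33 of the inputs, exposing its out-of-bag score.  The
exploratory presets used for algorithm comparison (RF with 100 trees, an
RBF-kernel SVM, ordinary linear regression and a k = 10 nearest-neighbour
regressor) are available by name; SVM and LR are fit on standardised
features.  All preprocessing — the zero-variance mask and, where used, the
standardiser — is fit on the training partition only and persisted with the
estimator, together with the schema hash of the raw feature ordering.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold, RandomizedSearchCV
from sklearn.neighbors import KNeighborsRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .features import FeatureMask, schema_hash, variance_filter
from .metrics import EvalReport, evaluate

#: Final-model and exploratory hyperparameter presets.
PRESETS = {
    "RF": {"n_estimators": 500, "max_features": 0.33},
    "RF100": {"n_estimators": 100, "max_features": 0.33},
    "SVM": {"kernel": "rbf"},
    "LR": {},
    "KNN": {"n_neighbors": 10},
}
_NORMALIZED = {"SVM", "LR"}


class SchemaMismatchError(ValueError):
    """Raised when a model is applied to a differently ordered feature set."""


@dataclass
class TrainingSet:
    """Aligned feature matrix, pKd labels and complex identifiers."""

    features: pd.DataFrame
    labels: np.ndarray
    ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.float64)
        if len(self.labels) != len(self.features):
            raise ValueError("labels misaligned with feature rows")
        if not np.all(np.isfinite(self.labels)):
            raise ValueError("non-finite labels")
        if not self.ids:
            self.ids = list(self.features.index)


def pkd_from_affinity(value: float, measure: str = "Kd",
                      qualifier: str = "=") -> Optional[float]:
    """Convert a molar Kd/Ki/IC50 to pKd = -log10(value).

    Values with inequality qualifiers are excluded (returns None).  IC50 is
    accepted as a pKd surrogate, as is common when pooling affinity data.
    """
    if qualifier.strip() not in ("=", ""):
        return None
    if measure not in ("Kd", "Ki", "IC50"):
        raise ValueError(f"unknown affinity measure {measure!r}")
    if value <= 0:
        raise ValueError("affinity must be positive molar concentration")
    return -math.log10(value)


@dataclass
class ScoringModel:
    """A trained regressor plus everything needed to apply it safely."""

    algorithm: str
    estimator: object
    feature_mask: FeatureMask
    schema_hash: str
    feature_names: tuple[str, ...]
    hyperparameters: dict
    seed: int
    scaler: Optional[StandardScaler] = None
    oob_score: Optional[float] = None
    training_fingerprint: str = ""

    def _prepare(self, values: np.ndarray, names: Sequence[str]) -> np.ndarray:
        incoming = schema_hash(names)
        if incoming != self.schema_hash:
            raise SchemaMismatchError(
                f"feature schema {incoming} does not match model schema "
                f"{self.schema_hash}")
        X = self.feature_mask.apply_values(np.atleast_2d(values))
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return X

    def predict(self, values: np.ndarray, names: Sequence[str]) -> np.ndarray:
        """Predicted pKd; batch input preserves row order."""
        return self.estimator.predict(self._prepare(values, names))

    def predict_frame(self, features: pd.DataFrame) -> np.ndarray:
        return self.predict(features.to_numpy(), tuple(features.columns))

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        meta = {
            "algorithm": self.algorithm,
            "schema_hash": self.schema_hash,
            "feature_names": list(self.feature_names),
            "kept_indices": self.feature_mask.kept_indices.tolist(),
            "mask_provenance": self.feature_mask.provenance,
            "hyperparameters": self.hyperparameters,
            "seed": self.seed,
            "oob_score": self.oob_score,
            "training_fingerprint": self.training_fingerprint,
        }
        joblib.dump({"estimator": self.estimator, "scaler": self.scaler,
                     "meta": json.dumps(meta)}, path)

    @classmethod
    def load(cls, path: str | Path) -> "ScoringModel":
        bundle = joblib.load(path)
        meta = json.loads(bundle["meta"])
        return cls(
            algorithm=meta["algorithm"],
            estimator=bundle["estimator"],
            feature_mask=FeatureMask(np.asarray(meta["kept_indices"]),
                                     meta["mask_provenance"]),
            schema_hash=meta["schema_hash"],
            feature_names=tuple(meta["feature_names"]),
            hyperparameters=meta["hyperparameters"],
            seed=meta["seed"],
            scaler=bundle["scaler"],
            oob_score=meta["oob_score"],
            training_fingerprint=meta["training_fingerprint"],
        )


def _make_estimator(algorithm: str, params: dict, seed: int):
    if algorithm.startswith("RF"):
        kw = dict(n_estimators=500, max_features=0.33, oob_score=True,
                  random_state=seed, n_jobs=1)
        kw.update(params)
        return RandomForestRegressor(**kw)
    if algorithm == "SVM":
        return SVR(**{"kernel": "rbf", **params})
    if algorithm == "LR":
        return LinearRegression(**params)
    if algorithm == "KNN":
        return KNeighborsRegressor(**{"n_neighbors": 10, **params})
    raise ValueError(f"unknown algorithm {algorithm!r}")


def train(ts: TrainingSet, algorithm: str = "RF",
          hyperparameters: Optional[dict] = None, seed: int = 0,
          min_samples: int = 20) -> ScoringModel:
    """Fit a scoring model; preprocessing is fit on this data only."""
    n = len(ts.features)
    if n < min_samples:
        raise ValueError(f"need >= {min_samples} samples, got {n}")
    if np.var(ts.labels) == 0.0:
        raise ValueError("degenerate labels: zero variance")
    params = dict(PRESETS.get(algorithm, {}))
    params.update(hyperparameters or {})
    names = tuple(ts.features.columns)
    X_raw = ts.features.to_numpy(dtype=np.float64)
    mask = variance_filter(X_raw, dataset_id=f"{n}-sample training set")
    X = mask.apply_values(X_raw)
    scaler = None
    if algorithm in _NORMALIZED:
        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)
    est = _make_estimator(algorithm, params, seed)
    est.fit(X, ts.labels)
    oob = getattr(est, "oob_score_", None)
    fingerprint = schema_hash([f"{i}:{y:.6f}" for i, y in zip(ts.ids, ts.labels)])
    return ScoringModel(algorithm=algorithm, estimator=est, feature_mask=mask,
                        schema_hash=schema_hash(names), feature_names=names,
                        hyperparameters=params, seed=seed, scaler=scaler,
                        oob_score=None if oob is None else float(oob),
                        training_fingerprint=fingerprint)


def cross_validate(ts: TrainingSet, k: int = 10, algorithm: str = "RF",
                   hyperparameters: Optional[dict] = None, seed: int = 0,
                   min_samples: int = 20) -> list[EvalReport]:
    """k-fold cross-validation with per-fold refit of mask and scaler."""
    n = len(ts.features)
    if k > n:
        raise ValueError(f"k={k} exceeds sample count {n}")
    reports = []
    for train_idx, test_idx in KFold(n_splits=k, shuffle=True,
                                     random_state=seed).split(ts.features):
        sub = TrainingSet(ts.features.iloc[train_idx],
                          ts.labels[train_idx],
                          [ts.ids[i] for i in train_idx])
        model = train(sub, algorithm, hyperparameters, seed,
                      min_samples=min(min_samples, len(train_idx)))
        pred = model.predict_frame(ts.features.iloc[test_idx])
        reports.append(evaluate(pred, ts.labels[test_idx]))
    return reports


#: Artifact-chosen randomized-search space (the original space is unpublished).
DEFAULT_SEARCH_SPACE = {
    "n_estimators": [100, 250, 500, 750],
    "max_features": [0.2, 0.33, 0.5, "sqrt"],
    "min_samples_leaf": [1, 2, 4],
}


def randomized_search(ts: TrainingSet, n_iter: int = 10, cv: int = 5,
                      seed: int = 0,
                      search_space: Optional[dict] = None) -> dict:
    """Randomised RF hyperparameter search; returns the best parameters."""
    mask = variance_filter(ts.features.to_numpy())
    X = mask.apply_values(ts.features.to_numpy())
    base = RandomForestRegressor(random_state=seed, n_jobs=1)
    search = RandomizedSearchCV(
        base, search_space or copy.deepcopy(DEFAULT_SEARCH_SPACE),
        n_iter=n_iter, cv=cv, random_state=seed, scoring="r2")
    search.fit(X, ts.labels)
    return dict(search.best_params_)
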