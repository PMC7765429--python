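"""Model training, prediction, persistence, validation and leakage guards."""

import numpy as np
import pandas as pd
import pytest

from dockrf.metrics import evaluate
from dockrf.models import (PRESETS, ScoringModel, SchemaMismatchError,
                           TrainingSet, cross_validate, pkd_from_affinity,
                           train)


def _linear_frame(rng, n, p=12, noise=0.1):
    X = rng.normal(size=(n, p))
    w = np.zeros(p)
    w[:3] = [1.5, -1.0, 0.5]
    y = 5.0 + X @ w + rng.normal(0, noise, n)
    cols = [f"f{i}" for i in range(p)]
    return pd.DataFrame(X, columns=cols), y


def test_memorization_with_single_unbagged_tree():
    rng = np.random.default_rng(0)
    X, y = _linear_frame(rng, 10)
    model = train(TrainingSet(X, y), algorithm="RF",
                  hyperparameters={"n_estimators": 1, "bootstrap": False,
                                   "oob_score": False},
                  min_samples=10)
    rep = evaluate(model.predict_frame(X), y)
    assert rep.r == pytest.approx(1.0, abs=1e-9)
    assert rep.rmse == pytest.approx(0.0, abs=1e-9)


def test_degenerate_labels_rejected():
    rng = np.random.default_rng(1)
    X, _ = _linear_frame(rng, 25)
    with pytest.raises(ValueError):
        train(TrainingSet(X, np.full(25, 5.0)))


def test_too_few_samples_rejected():
    rng = np.random.default_rng(2)
    X, y = _linear_frame(rng, 10)
    with pytest.raises(ValueError):
        train(TrainingSet(X, y))


def test_rf_prediction_is_mean_of_trees():
    rng = np.random.default_rng(3)
    X, y = _linear_frame(rng, 40)
    model = train(TrainingSet(X, y),
                  hyperparameters={"n_estimators": 25}, seed=4)
    Xm = model.feature_mask.apply_values(X.to_numpy())
    per_tree = np.mean([t.predict(Xm) for t in model.estimator.estimators_],
                       axis=0)
    np.testing.assert_allclose(model.predict_frame(X), per_tree, rtol=1e-12)


def test_same_vector_scored_twice_is_identical():
    rng = np.random.default_rng(4)
    X, y = _linear_frame(rng, 30)
    model = train(TrainingSet(X, y), hyperparameters={"n_estimators": 50})
    a = model.predict_frame(X.iloc[[5]])
    b = model.predict_frame(X.iloc[[5]])
    assert a[0] == b[0]


def test_schema_mismatch_names_both_hashes():
    rng = np.random.default_rng(5)
    X, y = _linear_frame(rng, 30)
    model = train(TrainingSet(X, y), hyperparameters={"n_estimators": 10})
    wrong = X.rename(columns={"f0": "weird"})
    with pytest.raises(SchemaMismatchError) as err:
        model.predict_frame(wrong)
    assert model.schema_hash in str(err.value)


def test_normalization_only_for_svm_and_lr():
    rng = np.random.default_rng(6)
    X, y = _linear_frame(rng, 60)
    assert train(TrainingSet(X, y), algorithm="SVM").scaler is not None
    assert train(TrainingSet(X, y), algorithm="LR").scaler is not None
    assert train(TrainingSet(X, y), algorithm="KNN").scaler is None
    assert train(TrainingSet(X, y),
                 hyperparameters={"n_estimators": 10}).scaler is None


def test_presets_match_published_configuration():
    assert PRESETS["RF"] == {"n_estimators": 500, "max_features": 0.33}
    assert PRESETS["RF100"]["n_estimators"] == 100
    assert PRESETS["SVM"]["kernel"] == "rbf"
    assert PRESETS["KNN"]["n_neighbors"] == 10


def test_persistence_round_trip(tmp_path):
    rng = np.random.default_rng(7)
    X, y = _linear_frame(rng, 40)
    model = train(TrainingSet(X, y), hyperparameters={"n_estimators": 20},
                  seed=11)
    path = tmp_path / "model.joblib"
    model.save(path)
    loaded = ScoringModel.load(path)
    assert loaded.schema_hash == model.schema_hash
    assert loaded.seed == 11
    assert loaded.hyperparameters["n_estimators"] == 20
    np.testing.assert_allclose(loaded.predict_frame(X),
                               model.predict_frame(X), rtol=1e-12)


def test_reproducibility_same_seed_same_predictions():
    rng = np.random.default_rng(8)
    X, y = _linear_frame(rng, 50, noise=0.5)
    a = train(TrainingSet(X, y), hyperparameters={"n_estimators": 30}, seed=9)
    b = train(TrainingSet(X, y), hyperparameters={"n_estimators": 30}, seed=9)
    np.testing.assert_array_equal(a.predict_frame(X), b.predict_frame(X))


def test_leakage_guard_canary_feature():
    # a column constant in training must be dropped by the fitted mask, so
    # test-time variation in it cannot change predictions
    rng = np.random.default_rng(10)
    X, y = _linear_frame(rng, 40)
    X["canary"] = 1.0
    model = train(TrainingSet(X, y), hyperparameters={"n_estimators": 20})
    probe_a = X.iloc[[0]].copy()
    probe_b = probe_a.copy()
    probe_b["canary"] = 99.0
    assert model.predict_frame(probe_a)[0] == model.predict_frame(probe_b)[0]


def test_cross_validation_fold_structure():
    rng = np.random.default_rng(12)
    X, y = _linear_frame(rng, 100)
    reports = cross_validate(TrainingSet(X, y), k=10,
                             hyperparameters={"n_estimators": 10},
                             min_samples=20)
    assert len(reports) == 10
    assert all(r.n == 10 for r in reports)
    with pytest.raises(ValueError):
        cross_validate(TrainingSet(X.iloc[:5], y[:5]), k=10)


def test_label_shuffle_gives_no_signal():
    rng = np.random.default_rng(13)
    X, y = _linear_frame(rng, 200, noise=0.1)
    ys = y.copy()
    rng.shuffle(ys)
    model = train(TrainingSet(X.iloc[:150], ys[:150]),
                  hyperparameters={"n_estimators": 100})
    rep = evaluate(model.predict_frame(X), y)
    assert abs(rep.r) < 0.2


def test_pkd_conversion():
    assert pkd_from_affinity(1e-9, "Kd") == pytest.approx(9.0)
    assert pkd_from_affinity(1e-6, "Ki") == pytest.approx(6.0)
    assert pkd_from_affinity(2e-8, "IC50") == pytest.approx(7.699, abs=1e-3)
    assert pkd_from_affinity(1e-9, "Kd", qualifier=">") is None
    with pytest.raises(ValueError):
        pkd_from_affinity(-1e-9, "Kd")
    with pytest.raises(ValueError):
        pkd_from_affinity(1e-9, "EC50")


def test_cv_mean_r_close_to_holdout_r(planted_dataset, planted_holdout):
    """Ten-fold CV and the 80:20 holdout agree on the planted-signal set."""
    ds = planted_dataset
    reports = cross_validate(TrainingSet(ds.features, ds.labels), k=10, seed=1)
    mean_r = float(np.mean([r.r for r in reports]))
    assert mean_r == pytest.approx(planted_holdout["report"].r, abs=0.05)
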