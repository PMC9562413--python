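"""Subject-wise splitting, metric formulas, model training, grid search,
and leakage/importance invariants."""

import numpy as np
import pytest
from sklearn.model_selection import KFold, cross_val_score

from cuffless.errors import ConfigError, DataError
from cuffless.features import FEATURE_NAMES, FeatureDataset, FeatureRecord
from cuffless.regress import (DEFAULT_HYPERPARAMS, RegressorConfig, evaluate_predictions,
                              mdi_importances, run_experiment, split_by_subject,
                              train_regressor, tune_hyperparameters, _make_estimator)
from cuffless.synth import generate_planted_features


def _dataset(n=200, n_subjects=21, seed=0, y_fn=None):
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        vals = dict(zip(FEATURE_NAMES, rng.normal(100, 10, 10)))
        y = y_fn(vals, rng) if y_fn else float(rng.normal(120, 10))
        records.append(FeatureRecord(subject_id=f"S{i % n_subjects + 1:02d}", state="rest",
                                     repetition=1, beat_index=i, sbp=y, **vals))
    return FeatureDataset(records=records, gate="raw")


# ------------------------------------------------------------------ splits

def test_subject_split_is_disjoint_partition():
    ds = _dataset(n=210)
    train, test = split_by_subject(ds, 17, 4, seed=0)
    tr, te = set(train.subjects), set(test.subjects)
    assert tr & te == set()
    assert len(tr) == 17 and len(te) == 4
    assert len(train) + len(test) == sum(
        1 for r in ds.records if r.subject_id in tr | te)


def test_subject_split_deterministic():
    ds = _dataset()
    a = split_by_subject(ds, 17, 4, seed=5)
    b = split_by_subject(ds, 17, 4, seed=5)
    assert a[1].subjects == b[1].subjects


def test_split_with_too_few_subjects_rejected():
    ds = _dataset(n=30, n_subjects=5)
    with pytest.raises(ConfigError):
        split_by_subject(ds, 17, 4, seed=0)


# ----------------------------------------------------------------- metrics

def test_perfect_and_null_predictions():
    y = np.array([100.0, 110.0, 120.0, 130.0])
    m = evaluate_predictions(y, y)
    assert (m["evs"], m["r2"], m["mae"], m["mse"]) == (1.0, 1.0, 0.0, 0.0)
    m = evaluate_predictions(y, np.full_like(y, y.mean()))
    assert m["r2"] == pytest.approx(0.0, abs=1e-12)
    assert m["evs"] == pytest.approx(0.0, abs=1e-12)


def test_metrics_match_direct_summation_oracle():
    rng = np.random.default_rng(8)
    for _ in range(100):
        n = int(rng.integers(2, 50))
        y = rng.normal(120, 15, n)
        if np.var(y) == 0:
            continue
        yhat = y + rng.normal(0, 5, n)
        m = evaluate_predictions(y, yhat)
        r = y - yhat
        evs = 1.0 - np.sum((r - r.mean()) ** 2) / np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum(r ** 2) / np.sum((y - y.mean()) ** 2)
        assert m["evs"] == pytest.approx(evs, abs=1e-10)
        assert m["r2"] == pytest.approx(r2, abs=1e-10)
        assert m["mae"] == pytest.approx(sum(abs(v) for v in r) / n, abs=1e-10)
        assert m["mse"] == pytest.approx(sum(v * v for v in r) / n, abs=1e-10)


def test_evs_equals_r2_for_centered_residuals():
    rng = np.random.default_rng(9)
    y = rng.normal(120, 10, 50)
    resid = rng.normal(0, 3, 50)
    resid -= resid.mean()
    m = evaluate_predictions(y, y - resid)
    assert m["evs"] == pytest.approx(m["r2"], abs=1e-12)


def test_constant_y_rejected():
    with pytest.raises(DataError):
        evaluate_predictions(np.full(5, 120.0), np.arange(5.0))


# ---------------------------------------------------------------- training

def test_lr_recovers_exact_linear_coefficients():
    ds = _dataset(n=100, y_fn=lambda v, rng: 2.0 * v["s1j_ms"] + 5.0)
    est = train_regressor(RegressorConfig.default("LR"), ds)
    coefs = dict(zip(FEATURE_NAMES, est.coef_))
    assert coefs["s1j_ms"] == pytest.approx(2.0, abs=1e-8)
    assert est.intercept_ == pytest.approx(5.0, abs=1e-6)


def test_rf_tree_count_matches_config():
    ds = _dataset(n=60)
    cfg = RegressorConfig(model="RF", hyperparams={"n_trees": 139})
    est = train_regressor(cfg, ds)
    assert len(est.estimators_) == 139


def test_published_working_points_complete():
    for model, by_gate in DEFAULT_HYPERPARAMS.items():
        for gate in ("D1", "D2"):
            RegressorConfig(model=model, hyperparams=dict(by_gate[gate]),
                            dataset_gate=gate)


def test_degenerate_single_row_training():
    ds = _dataset(n=1)
    with pytest.raises(DataError):
        train_regressor(RegressorConfig.default("RF"), ds)
    train_regressor(RegressorConfig.default("LR"), ds)  # allowed, warns


def test_missing_hyperparameters_rejected():
    with pytest.raises(ConfigError):
        RegressorConfig(model="SVR_rbf", hyperparams={"c": 1.0})


# --------------------------------------------------------------------- MDI

def test_mdi_nonnegative_sums_to_one_and_permutes():
    ds = generate_planted_features(n_records=250, seed=3)
    cfg = RegressorConfig(model="RF", hyperparams={"n_trees": 60}, seed=3)
    est = train_regressor(cfg, ds)
    imp = mdi_importances(est)
    assert np.all(imp >= 0)
    assert imp.sum() == pytest.approx(1.0, abs=1e-9)
    # permuting feature columns permutes importances (up to the forest's
    # internal feature-order tie-breaking, which is not column-invariant)
    X, y = ds.matrix()
    perm = np.array([3, 1, 4, 0, 2, 9, 7, 8, 5, 6])
    est2 = _make_estimator(cfg)
    est2.fit(X[:, perm], y)
    np.testing.assert_allclose(mdi_importances(est2), imp[perm], atol=0.01)
    assert int(np.argmax(mdi_importances(est2))) == int(np.argmax(imp[perm]))


# ------------------------------------------------------------- grid search

def test_grid_of_one_point_returned():
    ds = _dataset(n=60)
    best = tune_hyperparameters("RF", ds, {"n_trees": [17]}, seed=0)
    assert best == {"n_trees": 17}


def test_grid_search_selects_cv_argmin():
    # noiseless linear data: the KR grid point matching the generator is CV-best
    ds = _dataset(n=120, y_fn=lambda v, rng: 0.8 * v["s1j_ms"] - 20.0)
    grid = {"alpha": [0.005, 50.0], "gamma": [0.05, 5.0]}
    best = tune_hyperparameters("KernelRidge_laplacian", ds, grid, seed=0)
    X, y = ds.matrix()
    # independent check: recompute the CV MAE of every grid point
    scores = {}
    for alpha in grid["alpha"]:
        for gamma in grid["gamma"]:
            cfg = RegressorConfig(model="KernelRidge_laplacian",
                                  hyperparams={"alpha": alpha, "gamma": gamma})
            s = cross_val_score(_make_estimator(cfg), X, y,
                                scoring="neg_mean_absolute_error",
                                cv=KFold(5, shuffle=False)).mean()
            scores[(alpha, gamma)] = -s
    assert scores[(best["alpha"], best["gamma"])] == min(scores.values())


def test_grid_search_deterministic():
    ds = _dataset(n=80)
    grid = {"n_trees": [10, 20]}
    assert tune_hyperparameters("RF", ds, grid, seed=1) == \
        tune_hyperparameters("RF", ds, grid, seed=1)


def test_empty_grid_and_excess_folds_rejected():
    ds = _dataset(n=3)
    with pytest.raises(ConfigError):
        tune_hyperparameters("RF", ds, {}, seed=0)
    with pytest.raises(ConfigError):
        tune_hyperparameters("RF", ds, {"n_trees": [5]}, cv_folds=5, seed=0)


# -------------------------------------------------------------- experiment

def test_no_leakage_from_test_subjects():
    ds = _dataset(n=210, y_fn=lambda v, rng: 0.5 * v["s1j_ms"] + rng.normal(0, 1))
    train, test = split_by_subject(ds, 17, 4, seed=2)
    cfg = RegressorConfig(model="RF", hyperparams={"n_trees": 30}, seed=2)
    est_a = train_regressor(cfg, train)
    # deleting all test-subject records changes nothing about training
    pruned = FeatureDataset(records=[r for r in ds.records
                                     if r.subject_id in set(train.subjects)], gate="raw")
    est_b = train_regressor(cfg, pruned)
    X_tr, _ = train.matrix()
    np.testing.assert_array_equal(est_a.predict(X_tr), est_b.predict(X_tr))


def test_run_experiment_bookkeeping():
    ds = _dataset(n=210)
    reports = run_experiment(ds, "D1", models=["LR", "RF"], seed=0)
    assert [r.model for r in reports] == ["LR", "RF"]
    from cuffless.features import apply_gate
    gated = apply_gate(ds, "D1")
    for rep in reports:
        test_subjects = set(rep.test_subjects)
        expected = sum(1 for r in gated.records if r.subject_id in test_subjects)
        assert rep.n_test == expected
        assert len(rep.per_sample_errors) == rep.n_test
    assert reports[1].mdi_importances is not None
    assert reports[0].mdi_importances is None
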