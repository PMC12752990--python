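"""Sparse L0L2 logistic regression and the tree-per-cluster forest route."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from dmrkit import (
    evaluate_multi,
    fit_forest,
    fit_l0l2_logistic,
    kmeans_cluster,
    lambda_max,
    ridge_logistic_refit,
    select_by_tree_per_cluster,
)
from dmrkit.models_multi import _fit_at_lambda, _l0l2_objective


def _instance(seed=0, n=40, p=8, informative=(0, 1), coef=1.6):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    eta = sum(coef * X[:, j] for j in informative) - 0.2
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    if y.sum() < 5 or y.sum() > n - 5:
        return _instance(seed + 100, n, p, informative, coef)
    return X, y


def test_ridge_refit_matches_sklearn():
    X, y = _instance(seed=1)
    gamma = 0.05
    b0, beta, obj = ridge_logistic_refit(X, y, gamma)
    # sklearn minimizes sum log-loss + (1/(2C)) ||w||^2 -> C = 1/(2 gamma)
    sk = LogisticRegression(C=1 / (2 * gamma), tol=1e-12, max_iter=5000)
    sk.fit(X, y)
    assert beta == pytest.approx(sk.coef_[0], abs=1e-5)
    assert b0 == pytest.approx(sk.intercept_[0], abs=1e-5)
    # the returned objective is the attained minimum
    eta = b0 + X @ beta
    loss = np.sum(np.logaddexp(0, eta) - y * eta) + gamma * beta @ beta
    assert obj == pytest.approx(loss, abs=1e-9)


def _best_subset_objective(X, y, lam, gamma, max_size=None):
    """Exhaustive best-subset-with-ridge oracle for the L0L2 objective."""
    p = X.shape[1]
    best = np.inf
    sizes = range(0, (max_size or p) + 1)
    for size in sizes:
        for subset in itertools.combinations(range(p), size):
            idx = list(subset)
            _, _, obj = ridge_logistic_refit(X[:, idx], y, gamma)
            best = min(best, obj + lam * size)
    return best


def test_single_lambda_fit_reaches_exhaustive_optimum():
    X, y = _instance(seed=2, n=36, p=6)
    gamma = 0.001
    for lam in (0.5, 2.0, 8.0):
        b0, beta, obj, sweeps = _fit_at_lambda(X, y, lam, gamma)
        oracle = _best_subset_objective(X, y, lam, gamma)
        assert obj <= oracle + 1e-6
        assert obj >= oracle - 1e-8  # cannot beat the global optimum
        assert (np.diff(sweeps) <= 1e-8).all()


def test_lambda_max_boundary():
    X, y = _instance(seed=3, n=40, p=5)
    gamma = 0.001
    lmax = lambda_max(X, y, gamma)
    _, beta_above, _, _ = _fit_at_lambda(X, y, lmax * 1.05, gamma, refine=False)
    assert np.count_nonzero(beta_above) == 0
    _, beta_below, _, _ = _fit_at_lambda(X, y, lmax * 0.5, gamma, refine=False)
    assert np.count_nonzero(beta_below) >= 1


def _frame(X, y):
    x = pd.DataFrame(
        X.T,
        index=[f"reg{j}" for j in range(X.shape[1])],
        columns=[f"s{i}" for i in range(X.shape[0])],
    )
    return x, y


def test_fit_l0l2_recovers_informative_support():
    X, y = _instance(seed=4, n=120, p=8, informative=(0, 3), coef=2.5)
    x, y = _frame(X, y)
    model = fit_l0l2_logistic(x, y, gamma=0.001, cv_folds=4, seed=0, n_lambda=25)
    assert set(model.selected) == {"reg0", "reg3"}
    assert (np.diff(model.sweep_objectives) <= 1e-8).all()
    assert len(model.cv_path) == 25
    # refit objective consistent with the reported coefficients
    dense = np.zeros(X.shape[1])
    for name, c in zip(model.selected, model.coefficients):
        dense[x.index.get_loc(name)] = c
    obj = _l0l2_objective(model.intercept, dense, X, y, model.lam, model.gamma)
    assert np.isfinite(obj)
    probs = model.predict_proba(x)
    assert probs.shape == (120,) and ((probs >= 0) & (probs <= 1)).all()


def test_fit_l0l2_deterministic_and_guards():
    X, y = _instance(seed=5, n=40, p=6)
    x, y = _frame(X, y)
    m1 = fit_l0l2_logistic(x, y, seed=3, n_lambda=15)
    m2 = fit_l0l2_logistic(x, y, seed=3, n_lambda=15)
    assert m1.selected == m2.selected and m1.lam == m2.lam
    with pytest.raises(ValueError, match="per class"):
        fit_l0l2_logistic(x.iloc[:, :6], np.array([1, 1, 1, 1, 1, 0.0]), cv_folds=4)


def _clustered_regions(seed=0):
    rng = np.random.default_rng(seed)
    n = 24
    y = np.tile([1, 0], n // 2)
    # two feature groups with distinct profiles; group A carries the signal
    a = rng.uniform(0.3, 0.5, size=(6, n)) + 0.35 * y
    b = rng.uniform(0.6, 0.8, size=(6, n))
    x = pd.DataFrame(
        np.clip(np.vstack([a, b]), 0, 1),
        index=[f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)],
        columns=[f"s{i}" for i in range(n)],
    )
    return x, y


def test_tree_per_cluster_selection_and_forest():
    x, y = _clustered_regions()
    clusters = kmeans_cluster(x, k=2, seed=0)
    selected = select_by_tree_per_cluster(x, y, clusters, max_depth=2, seed=0)
    assert set(selected) == set(clusters.assignments.unique())
    for c, regs in selected.items():
        members = set(clusters.assignments.index[clusters.assignments == c])
        assert set(regs) <= members
    panel = sorted({r for regs in selected.values() for r in regs})
    assert any(r.startswith("a") for r in panel)  # signal cluster contributes
    forest = fit_forest(x, y, panel, n_trees=50, seed=0)
    probs = forest.predict_proba(x)
    assert ((probs >= 0) & (probs <= 1)).all()
    res = evaluate_multi(forest, x, y)
    assert res["test_auroc"] > 0.9  # in-sample on strong signal


def test_fit_forest_guards():
    x, y = _clustered_regions()
    with pytest.raises(ValueError, match="at least one"):
        fit_forest(x, y, [])
    x.loc["a0"] = 0.5
    with pytest.raises(ValueError, match="constant"):
        fit_forest(x, y, ["a0"])


def test_evaluate_multi_leakage_guard():
    x, y = _clustered_regions()
    forest = fit_forest(x, y, ["a0", "a1"], n_trees=20, seed=0)
    with pytest.raises(ValueError, match="overlap"):
        evaluate_multi(forest, x.iloc[:, :4], y[:4], x_train=x)
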