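"""Multi-probe predictive models.

Two routes to a small panel of regions:

1. L0+L2-penalized sparse logistic regression.  The objective is

       sum_i [log(1 + exp(eta_i)) - y_i * eta_i] + lambda * ||beta||_0
                                                 + gamma * ||beta||_2^2

   minimized by cyclic coordinate descent with hard-threshold updates
   (majorization steps, so the objective never increases within a sweep)
   followed by local support refinement (drop/add/swap moves, each scored
   by an exact ridge-logistic refit on the candidate support).  The L0
   weight lambda is chosen by stratified k-fold cross-validated logistic
   loss over a geometric grid descending from lambda_max (the smallest
   penalty with an empty support); gamma is held fixed (default 0.001).

2. Cluster-wise decision trees: one depth-bounded tree per methylation
   cluster selects the regions used at its split nodes; the union feeds a
   random forest classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .cluster import ClusterModel
from .models_single import auprc, auroc


@dataclass
class SparseLogisticModel:
    selected: list[str]
    coefficients: np.ndarray  # aligned with selected
    intercept: float
    lam: float
    gamma: float
    cv_path: pd.DataFrame  # lambda, mean_cv_loss, support_size
    sweep_objectives: list[float] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)

    def predict_proba(self, x: pd.DataFrame) -> np.ndarray:
        """x: regions x samples with all selected regions present."""
        eta = np.full(x.shape[1], self.intercept)
        for name, coef in zip(self.selected, self.coefficients):
            eta = eta + coef * x.loc[name].to_numpy(dtype=float)
        return expit(eta)


@dataclass
class ForestModel:
    selected: list[str]
    forest: RandomForestClassifier
    seed: int
    n_trees: int

    def predict_proba(self, x: pd.DataFrame) -> np.ndarray:
        X = x.loc[self.selected].to_numpy(dtype=float).T
        return self.forest.predict_proba(X)[:, 1]


# ---------------------------------------------------------------------------
# ridge-logistic refit on a fixed support (convex; Newton with step halving)
# ---------------------------------------------------------------------------


def _logistic_loss(eta: np.ndarray, y: np.ndarray) -> float:
    # log(1+exp(eta)) - y*eta, numerically stable
    return float(np.sum(np.logaddexp(0.0, eta) - y * eta))


def ridge_logistic_refit(
    X: np.ndarray, y: np.ndarray, gamma: float, max_iter: int = 100, tol: float = 1e-10
) -> tuple[float, np.ndarray, float]:
    """Exact minimizer of logistic loss + gamma*||beta||^2 (intercept
    unpenalized) on the given feature block.  Returns (intercept, beta,
    penalized loss excluding the L0 term)."""
    n, p = X.shape
    Z = np.column_stack([np.ones(n), X])
    w = np.zeros(p + 1)
    pen = np.zeros(p + 1)
    pen[1:] = 2.0 * gamma

    def objective(wv):
        eta = Z @ wv
        return _logistic_loss(eta, y) + gamma * float(np.sum(wv[1:] ** 2))

    obj = objective(w)
    for _ in range(max_iter):
        eta = np.clip(Z @ w, -35, 35)
        mu = expit(eta)
        g = Z.T @ (mu - y) + pen * w
        H = (Z * (mu * (1 - mu) + 1e-12)[:, None]).T @ Z + np.diag(pen) + 1e-12 * np.eye(p + 1)
        step = np.linalg.solve(H, g)
        t = 1.0
        for _ in range(40):
            cand = w - t * step
            new_obj = objective(cand)
            if new_obj <= obj + 1e-14:
                break
            t *= 0.5
        w = w - t * step
        if abs(obj - new_obj) < tol and np.abs(t * step).max() < 1e-8:
            obj = new_obj
            break
        obj = new_obj
    return float(w[0]), w[1:], obj


# ---------------------------------------------------------------------------
# L0L2 coordinate descent
# ---------------------------------------------------------------------------


def _l0l2_objective(b0: float, beta: np.ndarray, X: np.ndarray, y: np.ndarray,
                    lam: float, gamma: float) -> float:
    eta = b0 + X @ beta
    nnz = int(np.count_nonzero(beta))
    return _logistic_loss(eta, y) + lam * nnz + gamma * float(beta @ beta)


def _cd_l0l2(
    X: np.ndarray, y: np.ndarray, lam: float, gamma: float,
    b0: float, beta: np.ndarray, max_sweeps: int = 200, tol: float = 1e-9,
) -> tuple[float, np.ndarray, list[float]]:
    """Cyclic coordinate descent with hard thresholding (majorization steps).

    Every coordinate update minimizes a quadratic upper bound of the
    smooth part, so the penalized objective is non-increasing sweep to
    sweep; this is asserted.
    """
    n, p = X.shape
    L = 0.25 * (X**2).sum(axis=0) + 1e-12
    L0 = 0.25 * n
    eta = b0 + X @ beta
    objs = [_l0l2_objective(b0, beta, X, y, lam, gamma)]
    for _ in range(max_sweeps):
        # intercept (unpenalized, majorized step)
        mu = expit(np.clip(eta, -35, 35))
        g0 = float(np.sum(mu - y))
        d0 = -g0 / L0
        b0 += d0
        eta += d0
        for j in range(p):
            mu = expit(np.clip(eta, -35, 35))
            gj = float(X[:, j] @ (mu - y))
            bt = (L[j] * beta[j] - gj) / (L[j] + 2.0 * gamma)
            new = bt if 0.5 * (L[j] + 2.0 * gamma) * bt * bt > lam else 0.0
            if new != beta[j]:
                eta += (new - beta[j]) * X[:, j]
                beta[j] = new
        obj = _l0l2_objective(b0, beta, X, y, lam, gamma)
        if obj > objs[-1] + 1e-8:
            raise AssertionError("coordinate-descent objective increased")
        if objs[-1] - obj < tol:
            objs.append(obj)
            break
        objs.append(obj)
    return b0, beta, objs


def _local_search(
    X: np.ndarray, y: np.ndarray, lam: float, gamma: float, support: np.ndarray,
    max_rounds: int = 30, max_add_candidates: int = 15,
) -> tuple[np.ndarray, float, float, np.ndarray]:
    """Drop/add/swap refinement over supports, each candidate scored by an
    exact ridge-logistic refit.  When no single-feature move improves, pair
    moves (add two / drop two) are tried, which resolves features that are
    only jointly informative (neither clears the L0 entry threshold alone).
    Returns (support mask, intercept, objective, beta on support)."""
    p = X.shape[1]

    def score(mask: np.ndarray):
        idx = np.flatnonzero(mask)
        b0, beta, obj = ridge_logistic_refit(X[:, idx], y, gamma)
        return b0, beta, obj + lam * len(idx)

    def apply(mask, kind, j, k):
        cand = mask.copy()
        if kind == "drop":
            cand[j] = False
        elif kind == "add":
            cand[j] = True
        elif kind == "swap":
            cand[j] = False
            cand[k] = True
        elif kind == "add2":
            cand[j] = True
            cand[k] = True
        else:  # drop2
            cand[j] = False
            cand[k] = False
        return cand

    mask = support.copy()
    b0, beta, best = score(mask)
    for _ in range(max_rounds):
        improved = False
        # gradient at current fit guides which absent features to try
        eta = b0 + X[:, np.flatnonzero(mask)] @ beta
        mu = expit(np.clip(eta, -35, 35))
        grad = np.abs(X.T @ (mu - y))
        absent = np.flatnonzero(~mask)
        absent = absent[np.argsort(-grad[absent])][:max_add_candidates]
        present = np.flatnonzero(mask)
        singles = (
            [("drop", j, -1) for j in present]
            + [("add", k, -1) for k in absent]
            + [("swap", j, k) for k in absent for j in present]
        )
        pairs = (
            [("add2", absent[a], absent[b])
             for a in range(len(absent)) for b in range(a + 1, len(absent))]
            + [("drop2", present[a], present[b])
               for a in range(len(present)) for b in range(a + 1, len(present))]
        )
        for moves in (singles, pairs):
            for kind, j, k in moves:
                cand = apply(mask, kind, j, k)
                cb0, cbeta, cobj = score(cand)
                if cobj < best - 1e-12:
                    mask, b0, beta, best = cand, cb0, cbeta, cobj
                    improved = True
                    break
            if improved:
                break
        if not improved:
            break
    return mask, b0, best, beta


def lambda_max(X: np.ndarray, y: np.ndarray, gamma: float) -> float:
    """Smallest L0 weight at which the optimal support is empty (from the
    intercept-only fit's coordinate entry conditions)."""
    b0, _, _ = ridge_logistic_refit(X[:, :0], y, gamma)
    mu = expit(np.full(len(y), np.clip(b0, -35, 35)))
    g = X.T @ (mu - y)
    L = 0.25 * (X**2).sum(axis=0) + 1e-12
    return float(np.max(g**2 / (2.0 * (L + 2.0 * gamma))))


def _fit_at_lambda(
    X: np.ndarray, y: np.ndarray, lam: float, gamma: float,
    warm: tuple[float, np.ndarray] | None = None, refine: bool = True,
) -> tuple[float, np.ndarray, float, list[float]]:
    """CD + optional local search at one lambda.  Returns (intercept, dense
    beta, objective, sweep objectives)."""
    p = X.shape[1]
    b0 = 0.0 if warm is None else warm[0]
    beta = np.zeros(p) if warm is None else warm[1].copy()
    b0, beta, objs = _cd_l0l2(X, y, lam, gamma, b0, beta)
    support = beta != 0.0
    if refine:
        mask, b0r, obj, beta_s = _local_search(X, y, lam, gamma, support)
        dense = np.zeros(p)
        dense[np.flatnonzero(mask)] = beta_s
        if obj <= objs[-1] + 1e-12:
            return b0r, dense, obj, objs
    idx = np.flatnonzero(support)
    b0r, beta_s, obj = ridge_logistic_refit(X[:, idx], y, gamma)
    dense = np.zeros(p)
    dense[idx] = beta_s
    return b0r, dense, obj + lam * len(idx), objs


def fit_l0l2_logistic(
    x: pd.DataFrame,
    labels: np.ndarray,
    gamma: float = 0.001,
    lambda_grid: np.ndarray | None = None,
    cv_folds: int = 4,
    seed: int = 0,
    n_lambda: int = 50,
    lambda_decades: float = 4.0,
) -> SparseLogisticModel:
    """L0+L2 sparse logistic regression with cross-validated L0 weight.

    ``x`` is regions x training samples.  The grid descends geometrically
    from lambda_max over ``lambda_decades`` decades; each fold's models are
    warm-started along the path; the lambda minimizing mean validation
    logistic loss (ties to the sparser/larger lambda) is refit on the full
    training split.
    """
    X = x.to_numpy(dtype=float).T  # samples x regions
    y = np.asarray(labels, dtype=float)
    n, p = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < cv_folds:
        raise ValueError(f"need >= {cv_folds} samples per class for {cv_folds}-fold CV")
    if lambda_grid is None:
        lmax = lambda_max(X, y, gamma)
        lambda_grid = np.geomspace(lmax, lmax * 10.0 ** (-lambda_decades), n_lambda)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    cv_loss = np.zeros((cv_folds, len(lambda_grid)))
    cv_ok = np.ones(len(lambda_grid), dtype=bool)
    for f, (tr, va) in enumerate(skf.split(X, y)):
        warm = None
        for li, lam in enumerate(lambda_grid):
            try:
                b0, beta, _, _ = _fit_at_lambda(X[tr], y[tr], lam, gamma, warm=warm)
            except AssertionError:
                cv_ok[li] = False
                warnings.warn(f"lambda {lam:.4g} failed to converge in fold {f}; skipped")
                continue
            warm = (b0, beta)
            eta = b0 + X[va] @ beta
            cv_loss[f, li] = _logistic_loss(eta, y[va]) / len(va)
    mean_loss = cv_loss.mean(axis=0)
    mean_loss[~cv_ok] = np.inf
    # ties break toward the larger (sparser) lambda; grid is descending
    best_li = int(np.flatnonzero(mean_loss <= mean_loss.min() + 1e-12)[0])
    lam_best = float(lambda_grid[best_li])

    b0, beta, _, sweep_objs = _fit_at_lambda(X, y, lam_best, gamma)
    support = np.flatnonzero(beta != 0.0)
    path = pd.DataFrame(
        {"lam": lambda_grid, "mean_cv_loss": np.where(cv_ok, mean_loss, np.nan)}
    )
    return SparseLogisticModel(
        selected=[x.index[j] for j in support],
        coefficients=beta[support],
        intercept=b0,
        lam=lam_best,
        gamma=gamma,
        cv_path=path,
        sweep_objectives=sweep_objs,
        feature_names=list(x.index),
    )


# ---------------------------------------------------------------------------
# tree-per-cluster selection and random forest
# ---------------------------------------------------------------------------


def select_by_tree_per_cluster(
    x: pd.DataFrame,
    labels: np.ndarray,
    clusters: ClusterModel,
    max_depth: int = 2,
    seed: int = 0,
) -> dict[int, list[str]]:
    """Per-cluster decision-tree feature selection.

    Fits one depth-bounded Gini tree per cluster on that cluster's regions
    only; the regions used at any split node are selected.  A cluster where
    no split improves impurity contributes nothing (warning).  Returns
    {cluster -> [region, ...]}; the union is the panel.
    """
    y = np.asarray(labels, dtype=int)
    out: dict[int, list[str]] = {}
    for c in sorted(clusters.assignments.unique()):
        members = clusters.assignments.index[clusters.assignments == c]
        if len(members) == 0:
            raise ValueError(f"cluster {c} is empty")
        Xc = x.loc[members].to_numpy(dtype=float).T
        tree = DecisionTreeClassifier(max_depth=max_depth, random_state=seed)
        tree.fit(Xc, y)
        used = np.unique(tree.tree_.feature[tree.tree_.feature >= 0])
        if len(used) == 0:
            warnings.warn(f"cluster {c}: no impurity-reducing split; no region selected")
            out[c] = []
        else:
            out[c] = [members[j] for j in used]
    return out


def fit_forest(
    x: pd.DataFrame,
    labels: np.ndarray,
    selected: list[str],
    n_trees: int = 500,
    seed: int = 0,
) -> ForestModel:
    """Random forest on the selected panel (sqrt features per split, seeded)."""
    if len(selected) == 0:
        raise ValueError("at least one selected region required")
    Xs = x.loc[selected].to_numpy(dtype=float)
    if len(selected) == 1 and np.ptp(Xs[0]) == 0:
        raise ValueError("the single selected feature is constant")
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed
    )
    forest.fit(Xs.T, np.asarray(labels, dtype=int))
    return ForestModel(selected=list(selected), forest=forest, seed=seed, n_trees=n_trees)


def evaluate_multi(
    model: "SparseLogisticModel | ForestModel",
    x_test: pd.DataFrame,
    labels_test: np.ndarray,
    x_train: pd.DataFrame | None = None,
) -> dict[str, float]:
    """AU-ROC / AU-PRC of a multi-probe model on the held-out split.

    If ``x_train`` is given, its sample ids must be disjoint from the test
    ids (leakage guard).
    """
    if x_train is not None:
        overlap = set(x_train.columns) & set(x_test.columns)
        if overlap:
            raise ValueError(f"train/test sample overlap: {sorted(overlap)}")
    scores = model.predict_proba(x_test)
    y = np.asarray(labels_test, dtype=float)
    return {"test_auroc": auroc(scores, y), "test_auprc": auprc(scores, y)}
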