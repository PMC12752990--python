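"""Per-DMR logistic models: bootstrap AU-ROC screening and held-out evaluation.

Each region gets a univariate logistic regression of disease status on its
mean methylation.  A preliminary screen ranks regions by the mean AU-ROC
over stratified bootstrap resamples of the training split; the ranked
models are then evaluated once on the held-out test split with AU-ROC and
AU-PRC (average precision).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata


@dataclass
class SingleDmrModel:
    region: str
    intercept: float
    slope: float
    converged: bool
    separated: bool
    constant_feature: bool

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return expit(self.intercept + self.slope * np.asarray(x, dtype=float))


@dataclass
class ModelEval:
    region: str
    train_auroc: float
    train_auprc: float
    boot_mean_auroc: float | None
    boot_ci95: tuple[float, float] | None  # None marks a degenerate CI, printed "(-, -)"
    test_auroc: float
    test_auprc: float


DEGENERATE_CI_MARKER = "(-, -)"


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def auroc(scores: np.ndarray, labels: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Probability that a random positive outscores a random negative; ties
    count 1/2 (Mann-Whitney).  Optional nonnegative multiplicity weights."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if weights is None:
        weights = np.ones(len(scores))
    weights = np.asarray(weights, dtype=float)
    pos = labels == 1
    w_pos = weights[pos].sum()
    w_neg = weights[~pos].sum()
    if w_pos == 0 or w_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(scores, kind="mergesort")
    s, w, y = scores[order], weights[order], pos[order]
    # concordant mass: for each positive, weight of negatives with lower score
    # plus half the weight of tied negatives
    uniq, inv = np.unique(s, return_inverse=True)
    neg_w = np.bincount(inv, weights=w * (~y), minlength=len(uniq))
    cum_below = np.concatenate([[0.0], np.cumsum(neg_w)[:-1]])
    conc = (w * y * (cum_below[inv] + 0.5 * neg_w[inv])).sum()
    return float(conc / (w_pos * w_neg))


def auprc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Average precision: the step-function integral of the precision-recall
    curve over score thresholds, without interpolation.  Ties are handled at
    the threshold level (a tie group enters or leaves as a block)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise ValueError("at least one positive label required")
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], (labels[order] == 1).astype(float)
    tp = np.cumsum(y)
    fp = np.cumsum(1.0 - y)
    # threshold boundaries: last index of each tie group
    boundary = np.append(s[1:] != s[:-1], True)
    tp_b, fp_b = tp[boundary], fp[boundary]
    precision = tp_b / (tp_b + fp_b)
    recall = tp_b / n_pos
    recall_prev = np.concatenate([[0.0], recall[:-1]])
    return float(((recall - recall_prev) * precision).sum())


# ---------------------------------------------------------------------------
# univariate logistic fit
# ---------------------------------------------------------------------------

_SLOPE_BOUND = 500.0  # optimizer bound signalling separation on a [0,1] feature


def _logistic_fit_1d(
    x: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None,
    max_iter: int = 60, tol: float = 1e-10,
) -> tuple[float, float, bool]:
    """Weighted ML logistic fit of binary y on one feature.  Returns
    (intercept, slope, converged); damped Newton with clipped coefficients."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones(len(x)) if weights is None else np.asarray(weights, dtype=float)
    X = np.column_stack([np.ones(len(x)), x])
    beta = np.zeros(2)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -35, 35)
        mu = expit(eta)
        g = X.T @ (w * (y - mu))
        W = w * mu * (1 - mu) + 1e-12
        H = (X * W[:, None]).T @ X + 1e-10 * np.eye(2)
        step = np.linalg.solve(H, g)
        step = np.clip(step, -25, 25)
        beta = np.clip(beta + step, -_SLOPE_BOUND, _SLOPE_BOUND)
        if np.abs(step).max() < tol:
            converged = True
            break
    return float(beta[0]), float(beta[1]), converged


def fit_single_dmr(region_betas_train: np.ndarray, labels_train: np.ndarray,
                   region: str = "") -> SingleDmrModel:
    """Univariate logistic model of status on a region's mean methylation.

    Perfect separation drives the slope to the optimizer bound and is
    flagged; scores still rank correctly.  A constant feature is flagged and
    yields a slope of 0 (AUC falls back to 0.5).
    """
    x = np.asarray(region_betas_train, dtype=float)
    y = np.asarray(labels_train, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required in training labels")
    if np.ptp(x) == 0:
        return SingleDmrModel(region, 0.0, 0.0, True, False, True)
    b0, b1, conv = _logistic_fit_1d(x, y)
    separated = (not conv) or abs(b1) >= _SLOPE_BOUND * 0.99
    return SingleDmrModel(region, b0, b1, conv, separated, False)


# ---------------------------------------------------------------------------
# bootstrap screening
# ---------------------------------------------------------------------------


def bootstrap_screen(
    x: pd.DataFrame,
    labels: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    top_n: int = 20,
) -> pd.DataFrame:
    """Rank per-region models by mean in-bag bootstrap AU-ROC.

    ``x`` is regions x training samples.  Each bootstrap resamples training
    samples with replacement, stratified within class (so both classes are
    always present), refits the univariate model on the resample, and scores
    AU-ROC on the same resample.  Reports mean and 2.5/97.5 percentile CI per
    region; a CI over identical bootstrap AUCs is degenerate and reported as
    the "(-, -)" marker.  Returns the top ``top_n`` regions by bootstrap
    mean (all regions if ``top_n`` is None), with deterministic ranking for
    a fixed seed.
    """
    y = np.asarray(labels, dtype=float)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError("both classes required for bootstrap screening")
    rng = np.random.default_rng(seed)
    # shared resamples across regions: stratified with replacement
    boots = [
        np.concatenate(
            [rng.choice(pos_idx, size=len(pos_idx), replace=True),
             rng.choice(neg_idx, size=len(neg_idx), replace=True)]
        )
        for _ in range(n_boot)
    ]
    rows = []
    X = x.to_numpy(dtype=float)
    for r, region in enumerate(x.index):
        feats = X[r]
        aucs = np.empty(n_boot)
        for b, idx in enumerate(boots):
            xb, yb = feats[idx], y[idx]
            if np.ptp(xb) == 0:
                aucs[b] = 0.5
                continue
            b0, b1, _ = _logistic_fit_1d(xb, yb)
            aucs[b] = auroc(expit(b0 + b1 * xb), yb)
        mean = float(aucs.mean())
        lo, hi = np.percentile(aucs, [2.5, 97.5])
        degenerate = bool(np.all(aucs == aucs[0]))
        rows.append(
            {
                "region": region,
                "boot_mean_auroc": mean,
                "boot_ci_lo": None if degenerate else float(lo),
                "boot_ci_hi": None if degenerate else float(hi),
                "boot_ci": DEGENERATE_CI_MARKER if degenerate
                else f"({lo:.3f}, {hi:.3f})",
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["boot_mean_auroc", "region"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    if top_n is not None:
        out = out.head(top_n).reset_index(drop=True)
    return out


def evaluate_models(
    x_train: pd.DataFrame,
    labels_train: np.ndarray,
    x_test: pd.DataFrame,
    labels_test: np.ndarray,
    screen: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fit per-region models on the training split and evaluate on both splits.

    ``screen`` (from :func:`bootstrap_screen`) restricts and annotates the
    evaluated regions.  Train and test sample sets must be disjoint — a
    shared id is a leakage error.
    """
    overlap = set(x_train.columns) & set(x_test.columns)
    if overlap:
        raise ValueError(f"train/test sample overlap: {sorted(overlap)}")
    regions = list(screen["region"]) if screen is not None else list(x_train.index)
    y_tr = np.asarray(labels_train, dtype=float)
    y_te = np.asarray(labels_test, dtype=float)
    rows = []
    for region in regions:
        model = fit_single_dmr(x_train.loc[region].to_numpy(), y_tr, region=region)
        p_tr = model.predict_proba(x_train.loc[region].to_numpy())
        p_te = model.predict_proba(x_test.loc[region].to_numpy())
        rows.append(
            {
                "region": region,
                "train_auroc": 0.5 if model.constant_feature else auroc(p_tr, y_tr),
                "train_auprc": auprc(p_tr, y_tr),
                "test_auroc": 0.5 if model.constant_feature else auroc(p_te, y_te),
                "test_auprc": auprc(p_te, y_te),
                "separated": model.separated,
            }
        )
    out = pd.DataFrame(rows)
    if screen is not None:
        out = screen.merge(out, on="region")
    return out
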