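"""Ranking metrics against brute-force oracles; univariate models; bootstrap screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import average_precision_score, roc_auc_score

from dmrkit import auprc, auroc, bootstrap_screen, evaluate_models, fit_single_dmr
from dmrkit.models_single import DEGENERATE_CI_MARKER


def oracle_auroc(scores, labels, weights=None):
    """All-pairs concordance with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    w = np.ones(len(scores)) if weights is None else np.asarray(weights, float)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    num = den = 0.0
    for i in pos:
        for j in neg:
            wij = w[i] * w[j]
            den += wij
            if scores[i] > scores[j]:
                num += wij
            elif scores[i] == scores[j]:
                num += 0.5 * wij
    return num / den


def oracle_auprc_distinct(scores, labels):
    """Mean precision at each positive's rank (valid for distinct scores)."""
    order = np.argsort(-np.asarray(scores, dtype=float))
    y = np.asarray(labels)[order]
    precs = []
    tp = 0
    for rank, yi in enumerate(y, start=1):
        if yi == 1:
            tp += 1
            precs.append(tp / rank)
    return float(np.mean(precs))


def _random_instance(rng, with_ties):
    n = int(rng.integers(4, 51))
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
    if labels.sum() == n or labels.sum() == 0:
        labels[0] = 1 - labels[0]
    if with_ties:
        scores = rng.integers(0, 5, size=n).astype(float)
    else:
        scores = rng.normal(size=n)
    return scores, labels


def test_auroc_matches_all_pairs_oracle():
    rng = np.random.default_rng(0)
    for trial in range(40):
        scores, labels = _random_instance(rng, with_ties=trial % 2 == 0)
        assert auroc(scores, labels) == pytest.approx(
            oracle_auroc(scores, labels), abs=1e-12
        )


def test_auroc_matches_sklearn_including_ties():
    rng = np.random.default_rng(1)
    for trial in range(20):
        scores, labels = _random_instance(rng, with_ties=True)
        assert auroc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )


def test_weighted_auroc_equals_sample_replication():
    rng = np.random.default_rng(2)
    for _ in range(10):
        scores, labels = _random_instance(rng, with_ties=True)
        weights = rng.integers(1, 4, size=len(scores))
        rep_scores = np.repeat(scores, weights)
        rep_labels = np.repeat(labels, weights)
        assert auroc(scores, labels, weights=weights) == pytest.approx(
            auroc(rep_scores, rep_labels), abs=1e-12
        )


def test_auprc_matches_per_positive_oracle_and_sklearn():
    rng = np.random.default_rng(3)
    for trial in range(40):
        scores, labels = _random_instance(rng, with_ties=False)
        assert auprc(scores, labels) == pytest.approx(
            oracle_auprc_distinct(scores, labels), abs=1e-12
        )
    for trial in range(20):  # tie blocks: step-integral must match sklearn
        scores, labels = _random_instance(rng, with_ties=True)
        assert auprc(scores, labels) == pytest.approx(
            average_precision_score(labels, scores), abs=1e-12
        )


@given(st.integers(0, 10_000))
def test_metrics_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    scores, labels = _random_instance(rng, with_ties=seed % 2 == 0)
    warped = np.exp(scores / 3.0) + 5.0
    assert auroc(warped, labels) == pytest.approx(auroc(scores, labels), abs=1e-12)
    assert auprc(warped, labels) == pytest.approx(auprc(scores, labels), abs=1e-12)


def test_auroc_constant_scores_is_half():
    assert auroc(np.ones(6), np.array([1, 1, 1, 0, 0, 0])) == pytest.approx(0.5)


def test_auprc_constant_scores_is_prevalence():
    y = np.array([1, 0, 0, 1, 0])
    assert auprc(np.ones(5), y) == pytest.approx(2 / 5)


def test_metric_guards():
    with pytest.raises(ValueError, match="classes"):
        auroc(np.ones(3), np.ones(3))
    with pytest.raises(ValueError, match="positive"):
        auprc(np.ones(3), np.zeros(3))


def test_fit_single_dmr_sign_and_flags():
    rng = np.random.default_rng(4)
    x = np.concatenate([rng.uniform(0.6, 0.9, 10), rng.uniform(0.1, 0.4, 10)])
    y = np.concatenate([np.ones(10), np.zeros(10)])
    model = fit_single_dmr(x, y, region="r")
    assert model.slope > 0 and model.separated  # perfectly separated
    scores = model.predict_proba(x)
    assert auroc(scores, y) == pytest.approx(1.0)

    x_noisy = rng.uniform(0, 1, 20)
    model2 = fit_single_dmr(x_noisy, y)
    assert model2.converged and not model2.separated

    flat = fit_single_dmr(np.full(20, 0.5), y)
    assert flat.constant_feature and flat.slope == 0.0

    with pytest.raises(ValueError, match="both classes"):
        fit_single_dmr(x, np.ones(20))


def _screen_data(seed=0, n_regions=5, n_samples=16):
    rng = np.random.default_rng(seed)
    y = np.tile([1, 0], n_samples // 2)  # interleaved so any prefix split keeps both classes
    x = rng.uniform(0.2, 0.8, size=(n_regions, n_samples))
    x[0, y == 1] += 0.4  # region 0 is strongly informative
    return pd.DataFrame(
        np.clip(x, 0, 1.2),
        index=[f"reg{i}" for i in range(n_regions)],
        columns=[f"s{j}" for j in range(n_samples)],
    ), y


def test_bootstrap_screen_ranks_informative_region_first():
    x, y = _screen_data()
    screen = bootstrap_screen(x, y, n_boot=60, seed=1)
    assert screen.loc[0, "region"] == "reg0"
    assert screen.loc[0, "boot_mean_auroc"] > screen["boot_mean_auroc"].iloc[-1]
    again = bootstrap_screen(x, y, n_boot=60, seed=1)
    pd.testing.assert_frame_equal(screen, again)


def test_bootstrap_screen_degenerate_ci_marker():
    x, y = _screen_data()
    x.loc["reg1"] = 0.5  # constant region: every bootstrap AUC is exactly 0.5
    screen = bootstrap_screen(x, y, n_boot=30, seed=2, top_n=None)
    row = screen.set_index("region").loc["reg1"]
    assert row["boot_ci"] == DEGENERATE_CI_MARKER
    assert pd.isna(row["boot_ci_lo"]) and pd.isna(row["boot_ci_hi"])


def test_bootstrap_screen_top_n():
    x, y = _screen_data(n_regions=8)
    assert len(bootstrap_screen(x, y, n_boot=20, seed=0, top_n=3)) == 3
    assert len(bootstrap_screen(x, y, n_boot=20, seed=0, top_n=None)) == 8


def test_evaluate_models_leakage_guard_and_metrics():
    x, y = _screen_data(n_samples=20)
    x_train, x_test = x.iloc[:, :14], x.iloc[:, 14:]
    y_train, y_test = y[:14], y[14:]
    out = evaluate_models(x_train, y_train, x_test, y_test)
    assert set(out["region"]) == set(x.index)
    best = out.set_index("region").loc["reg0"]
    assert best["train_auroc"] > 0.9
    with pytest.raises(ValueError, match="overlap"):
        evaluate_models(x_train, y_train, x_train.iloc[:, :2], y_train[:2])
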