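"""DMC testing against GLM oracles, BH behaviour, and the permutation filter."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from dmrkit import (
    MethCountMatrix,
    build_design,
    call_dmcs,
    filter_cpgs,
    permutation_filter,
)
from dmrkit.dmc import test_cpg as score_single_cpg
from dmrkit.dmc import fit_binomial_glm_batched

from conftest import make_sheet


def _statsmodels_lrt(meth, total, X):
    """Oracle: binomial GLM likelihood-ratio p for the group column (index 1)."""
    endog = np.column_stack([meth, total - meth])
    full = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
    null = sm.GLM(endog, np.delete(X, 1, axis=1), family=sm.families.Binomial()).fit()
    stat = max(null.deviance - full.deviance, 0.0)
    return float(chi2.sf(stat, df=1)), full.params


def test_single_cpg_matches_statsmodels_no_covariates():
    rng = np.random.default_rng(0)
    sheet = make_sheet(10, 10)
    group = (sheet.df["group"] == "case").to_numpy().astype(float)
    for trial in range(10):
        total = rng.integers(20, 120, size=20)
        p_true = np.where(group == 1, 0.6, 0.45)
        meth = rng.binomial(total, p_true)
        p_pkg, diff = score_single_cpg(meth, total, sheet)
        X, _ = build_design(sheet.df, [], group)
        p_orc, _ = _statsmodels_lrt(meth, total, X)
        assert p_pkg == pytest.approx(p_orc, abs=1e-6)
        beta = meth / total
        expected_diff = 100 * (beta[group == 1].mean() - beta[group == 0].mean())
        assert diff == pytest.approx(expected_diff, abs=1e-12)


def test_single_cpg_matches_statsmodels_with_covariates():
    rng = np.random.default_rng(1)
    sheet = make_sheet(12, 12, seed=1)
    group = (sheet.df["group"] == "case").to_numpy().astype(float)
    ages = sheet.df["age_years"].to_numpy()
    for trial in range(5):
        total = rng.integers(30, 100, size=24)
        logits = -0.3 + 0.5 * group + 0.05 * (ages - ages.mean())
        meth = rng.binomial(total, 1 / (1 + np.exp(-logits)))
        p_pkg, _ = score_single_cpg(meth, total, sheet, covariates=["age", "breed"])
        X, _ = build_design(sheet.df, ["age", "breed"], group)
        p_orc, _ = _statsmodels_lrt(meth, total, X)
        assert p_pkg == pytest.approx(p_orc, abs=1e-5)


def test_batched_glm_matches_statsmodels_coefficients():
    rng = np.random.default_rng(2)
    sheet = make_sheet(15, 15, seed=2)
    group = (sheet.df["group"] == "case").to_numpy().astype(float)
    X, _ = build_design(sheet.df, ["age"], group)
    total = rng.integers(30, 100, size=(8, 30)).astype(float)
    p_true = rng.uniform(0.2, 0.8, size=(8, 1))
    meth = rng.binomial(total.astype(int), p_true).astype(float)
    B, dev, conv = fit_binomial_glm_batched(meth, total, X)
    assert conv.all()
    for s in range(8):
        endog = np.column_stack([meth[s], total[s] - meth[s]])
        fit = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
        assert B[s] == pytest.approx(fit.params, abs=1e-5)
        assert dev[s] == pytest.approx(fit.deviance, abs=1e-6)


def test_design_pools_rare_breeds():
    sheet = make_sheet(8, 8, seed=3)
    df = sheet.df.copy()
    df["breed"] = ["beagle"] * 10 + ["poodle"] * 5 + ["unicorn"]
    group = (df["group"] == "case").to_numpy().astype(float)
    X, names = build_design(df, ["breed"], group)
    assert not any("unicorn" in n for n in names)  # singleton pooled into "other"
    assert "breed[other]" in names or "breed[poodle]" in names
    assert names[1] == "group"


def test_test_cpg_guards():
    sheet = make_sheet(1, 5)
    with pytest.raises(ValueError, match="2 samples per group"):
        score_single_cpg(np.ones(6), np.full(6, 10), sheet)
    sheet = make_sheet(3, 3)
    with pytest.raises(ValueError, match="totals"):
        score_single_cpg(np.zeros(6), np.array([10, 10, 0, 10, 10, 10]), sheet)


def _cohort_with_signal(n_sites=120, n_signal=12, seed=0, n_per_group=10, delta=0.35):
    rng = np.random.default_rng(seed)
    sheet = make_sheet(n_per_group, n_per_group, seed=seed)
    n = 2 * n_per_group
    group = (sheet.df["group"] == "case").to_numpy()
    total = rng.integers(40, 90, size=(n_sites, n))
    p = np.full((n_sites, n), 0.5)
    p[:n_signal, group] += delta
    meth = rng.binomial(total, p)
    sites = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(1, n_sites + 1) * 1000, "strand": "+"}
    )
    m = MethCountMatrix(sites, sheet.sample_ids, meth, total)
    return m, sheet


def test_call_dmcs_matches_manual_mask():
    m, sheet = _cohort_with_signal()
    dmcs = call_dmcs(m, sheet, covariates=[])
    # signal sites dominate the calls
    assert len(dmcs) >= 10
    assert (dmcs["site_idx"] < 12).all()
    assert (dmcs["direction"] == "hyper").all()
    # definition check: q < 0.05 AND |diff| > 10, with genome-wide BH
    group = (sheet.df["group"] == "case").to_numpy().astype(float)
    ps = np.array(
        [score_single_cpg(m.methylated[i], m.total[i], sheet)[0] for i in range(m.n_sites)]
    )
    _, qs, _, _ = multipletests(ps, method="fdr_bh")
    beta = m.methylated / m.total
    diff = 100 * (beta[:, group == 1].mean(axis=1) - beta[:, group == 0].mean(axis=1))
    expected = np.flatnonzero((qs < 0.05) & (np.abs(diff) > 10))
    assert list(dmcs["site_idx"]) == list(expected)
    assert dmcs["q_value"].to_numpy() == pytest.approx(qs[expected], abs=1e-8)


def test_bh_qvalues_preserve_p_order():
    m, sheet = _cohort_with_signal(seed=4)
    dmcs = call_dmcs(m, sheet, covariates=[])
    d = dmcs.sort_values("p_value")
    assert (np.diff(d["q_value"].to_numpy()) >= -1e-15).all()


def test_permutation_filter_deterministic_and_monotone():
    m, sheet = _cohort_with_signal(seed=5)
    dmcs = call_dmcs(m, sheet, covariates=[])
    r1, led1 = permutation_filter(m, sheet, [], dmcs, n_perm=20, seed=9)
    r2, led2 = permutation_filter(m, sheet, [], dmcs, n_perm=20, seed=9)
    assert r1.equals(r2)
    assert led1.hits.equals(led2.hits)
    # retained set grows (weakly) with the allowed hit count
    strict, _ = permutation_filter(m, sheet, [], dmcs, n_perm=20, max_hits=0, seed=9)
    loose, _ = permutation_filter(m, sheet, [], dmcs, n_perm=20, max_hits=3, seed=9)
    strict_keys = set(zip(strict["chrom"], strict["pos"]))
    loose_keys = set(zip(loose["chrom"], loose["pos"]))
    assert strict_keys <= loose_keys
    # the ledger explains every removal
    removed = len(dmcs) - len(r1)
    assert removed == int((led1.hits["hits"] > led1.max_hits).sum())


def test_permutation_filter_empty_candidates():
    m, sheet = _cohort_with_signal(n_signal=0, seed=6)
    empty = call_dmcs(m, sheet, covariates=[]).iloc[:0]
    retained, ledger = permutation_filter(m, sheet, [], empty, n_perm=5, seed=0)
    assert len(retained) == 0 and len(ledger.hits) == 0


def test_permutation_filter_requires_permutations():
    m, sheet = _cohort_with_signal(seed=7)
    dmcs = call_dmcs(m, sheet, covariates=[])
    with pytest.raises(ValueError, match="n_perm"):
        permutation_filter(m, sheet, [], dmcs, n_perm=0)


def test_call_dmcs_on_alternative_flag():
    """group_col lets the same machinery contrast a binary treatment flag."""
    rng = np.random.default_rng(8)
    sheet = make_sheet(10, 10, seed=8)
    flag = sheet.df["steroid"].to_numpy()
    if flag.sum() < 2 or len(flag) - flag.sum() < 2:
        pytest.skip("fixture lacks both flag levels")
    n_sites = 60
    total = rng.integers(40, 90, size=(n_sites, 20))
    p = np.full((n_sites, 20), 0.4)
    p[:6, flag.astype(bool)] += 0.4
    meth = rng.binomial(total, p)
    sites = pd.DataFrame(
        {"chrom": "chr2", "pos": np.arange(1, n_sites + 1) * 500, "strand": "+"}
    )
    m = MethCountMatrix(sites, sheet.sample_ids, meth, total)
    dmcs = call_dmcs(m, sheet, covariates=[], group_col="steroid")
    assert len(dmcs) >= 4 and (dmcs["site_idx"] < 6).all()
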