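"""Per-CpG covariate-adjusted differential methylation and the permutation filter.

Each CpG is tested with a binomial logistic regression of per-sample
(methylated, unmethylated) read counts on group plus covariates; the group
term's significance comes from a likelihood-ratio chi-square.  Benjamini-
Hochberg q-values control the FDR across all tested sites, and candidates
must also clear an absolute methylation-difference cutoff (percentage
points, case minus control, unweighted per-sample beta means).

The permutation filter then re-runs the complete genome-wide call under
randomly shuffled case/control labels (covariates stay attached to their
samples); a candidate that re-appears in more than ``max_hits`` permuted
calls is discarded as a small-sample false positive.

All fits run through one IRLS engine vectorized across sites: the design
matrix is shared, only the counts differ, so a genome of sites is a single
batched Newton solve per iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .io import MethCountMatrix, SampleSheet

_MAX_ITER = 40
_TOL = 1e-8
_ETA_CLIP = 30.0
_RIDGE = 1e-8


@dataclass
class PermutationLedger:
    """Per-candidate permutation hit counts, for audit."""

    hits: pd.DataFrame  # chrom, pos, hits
    n_permutations: int
    seed: int
    max_hits: int


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------


def build_design(
    sheet_df: pd.DataFrame,
    covariates: list[str],
    group: np.ndarray,
    rare_breed_min: int = 2,
) -> tuple[np.ndarray, list[str]]:
    """Intercept + group + encoded covariates.

    ``breed`` becomes one-hot with levels carried by fewer than
    ``rare_breed_min`` samples pooled into "other" (a heterogeneous case
    population makes a full one-hot singular); ``age`` is continuous years.
    The group column is always column index 1.
    """
    n = len(sheet_df)
    cols = [np.ones(n), np.asarray(group, dtype=float)]
    names = ["intercept", "group"]
    for cov in covariates:
        if cov == "age":
            cols.append(sheet_df["age_years"].to_numpy(dtype=float))
            names.append("age")
        elif cov in ("breed", "setting", "sex"):
            raw = sheet_df[cov].astype(str).to_numpy()
            if cov == "breed":
                counts = pd.Series(raw).value_counts()
                rare = set(counts[counts < rare_breed_min].index)
                raw = np.array(["other" if b in rare else b for b in raw])
            levels = pd.Series(raw).value_counts().index.tolist()  # ref = most frequent
            for level in levels[1:]:
                cols.append((raw == level).astype(float))
                names.append(f"{cov}[{level}]")
        elif cov == "steroid":
            cols.append(sheet_df["steroid"].to_numpy(dtype=float))
            names.append("steroid")
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    X = np.column_stack(cols)
    return X, names


# ---------------------------------------------------------------------------
# batched binomial GLM
# ---------------------------------------------------------------------------


def _deviance(y: np.ndarray, n: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Binomial deviance per site (rows), with 0*log(0) = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = y * (np.log(y) - np.log(n * mu))
        t2 = (n - y) * (np.log(n - y) - np.log(n - n * mu))
    t1 = np.where(y > 0, t1, 0.0)
    t2 = np.where(n - y > 0, t2, 0.0)
    return 2.0 * (t1 + t2).sum(axis=1)


def fit_binomial_glm_batched(
    y: np.ndarray,
    n: np.ndarray,
    X: np.ndarray,
    start: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit logit(E[y/n]) = X beta independently for every row of (y, n).

    Returns (coefficients (S, P), deviance (S,), converged (S,)).  The
    Newton step is damped (elementwise cap) and the Hessian gets a tiny
    ridge, so separated or degenerate sites flatten out and are flagged
    instead of diverging.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    S, N = y.shape
    P = X.shape[1]
    B = np.zeros((S, P)) if start is None else start.copy()
    if start is None:
        rate = (y.sum(axis=1) + 0.5) / (n.sum(axis=1) + 1.0)
        B[:, 0] = np.log(rate / (1.0 - rate))
    converged = np.zeros(S, dtype=bool)
    eye = np.eye(P) * _RIDGE
    for _ in range(_MAX_ITER):
        active = ~converged
        if not active.any():
            break
        Ba = B[active]
        eta = np.clip(Ba @ X.T, -_ETA_CLIP, _ETA_CLIP)
        mu = expit(eta)
        W = n[active] * mu * (1.0 - mu) + 1e-12
        G = (y[active] - n[active] * mu) @ X
        H = np.einsum("sn,np,nq->spq", W, X, X, optimize=True) + eye
        delta = np.linalg.solve(H, G[..., None])[..., 0]
        delta = np.clip(delta, -10.0, 10.0)
        B[active] = Ba + delta
        done = np.abs(delta).max(axis=1) < _TOL
        idx = np.flatnonzero(active)
        converged[idx[done]] = True
    eta = np.clip(B @ X.T, -_ETA_CLIP, _ETA_CLIP)
    mu = expit(eta)
    dev = _deviance(y, n, mu)
    return B, dev, converged


def lrt_group_pvalues(
    y: np.ndarray,
    n: np.ndarray,
    X_full: np.ndarray,
    null_dev: np.ndarray | None = None,
    X_null: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Likelihood-ratio p-values for the group column (index 1) of X_full.

    ``null_dev`` may be supplied to reuse a covariate-only fit (the null
    model does not involve the group labels, so it is shared across label
    permutations).  Non-converged sites get p = 1.
    """
    if null_dev is None:
        if X_null is None:
            X_null = np.delete(X_full, 1, axis=1)
        _, null_dev, null_conv = fit_binomial_glm_batched(y, n, X_null)
    else:
        null_conv = np.ones(len(null_dev), dtype=bool)
    _, full_dev, full_conv = fit_binomial_glm_batched(y, n, X_full)
    stat = np.clip(null_dev - full_dev, 0.0, None)
    p = chi2.sf(stat, df=1)
    ok = null_conv & full_conv
    p = np.where(ok, p, 1.0)
    return p, ok


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def test_cpg(
    methylated: np.ndarray,
    total: np.ndarray,
    sheet: SampleSheet,
    covariates: list[str] = (),
) -> tuple[float, float]:
    """Test a single CpG; returns (p_value, meth_diff in percentage points).

    meth_diff is 100 x (mean case beta - mean control beta), using
    unweighted per-sample betas.  Degenerate fits yield p = 1 rather than
    an exception.
    """
    methylated = np.asarray(methylated, dtype=float)
    total = np.asarray(total, dtype=float)
    if (total < 1).any():
        raise ValueError("all totals must be >= 1")
    group = (sheet.df["group"] == "case").to_numpy().astype(float)
    if group.sum() < 2 or (1 - group).sum() < 2:
        raise ValueError("need at least 2 samples per group")
    X, _ = build_design(sheet.df, list(covariates), group)
    p, _ = lrt_group_pvalues(methylated[None, :], total[None, :], X)
    beta = methylated / total
    diff = 100.0 * (beta[group == 1].mean() - beta[group == 0].mean())
    return float(p[0]), float(diff)


def _dmc_mask(
    y: np.ndarray,
    n: np.ndarray,
    X_full: np.ndarray,
    group: np.ndarray,
    diff_cutoff: float,
    q_cutoff: float,
    null_dev: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Genome-wide call: returns (mask, meth_diff, p, q)."""
    p, _ = lrt_group_pvalues(y, n, X_full, null_dev=null_dev)
    beta = y / n
    diff = 100.0 * (
        beta[:, group == 1].mean(axis=1) - beta[:, group == 0].mean(axis=1)
    )
    _, q, _, _ = multipletests(p, method="fdr_bh")
    mask = (q < q_cutoff) & (np.abs(diff) > diff_cutoff)
    return mask, diff, p, q


def call_dmcs(
    m: MethCountMatrix,
    sheet: SampleSheet,
    covariates: list[str] = ("breed", "age"),
    diff_cutoff: float = 10.0,
    q_cutoff: float = 0.05,
    group_col: str = "group",
) -> pd.DataFrame:
    """Call differentially methylated cytosines on (training) samples.

    Tests every site, adjusts p-values genome-wide by Benjamini-Hochberg,
    and returns the sites with q < ``q_cutoff`` and |meth_diff| >
    ``diff_cutoff``, tagged hyper/hypo by the sign of the difference.  The
    returned frame carries ``site_idx`` into ``m.sites`` plus chrom, pos,
    strand, meth_diff, p_value, q_value, direction.

    ``group_col`` may name any binary 0/1 flag column (e.g. ``steroid``) to
    contrast instead of case/control.
    """
    sheet_df = sheet.df.set_index("sample_id").loc[list(m.samples)].reset_index()
    for cov in covariates:
        col = "age_years" if cov == "age" else cov
        if col not in sheet_df.columns:
            raise ValueError(f"covariate column {col!r} missing from sample sheet")
    if group_col == "group":
        group = (sheet_df["group"] == "case").to_numpy().astype(float)
    else:
        group = sheet_df[group_col].to_numpy().astype(float)
    if group.sum() < 2 or len(group) - group.sum() < 2:
        raise ValueError("need at least 2 samples per group level")
    if (m.total < 1).any():
        raise ValueError("matrix must be coverage-filtered (totals >= 1)")
    X, _ = build_design(sheet_df, list(covariates), group)
    y = m.methylated.astype(float)
    n = m.total.astype(float)
    mask, diff, p, q = _dmc_mask(y, n, X, group, diff_cutoff, q_cutoff)
    idx = np.flatnonzero(mask)
    out = m.sites.iloc[idx].reset_index(drop=True).copy()
    out["site_idx"] = idx
    out["meth_diff"] = diff[idx]
    out["p_value"] = p[idx]
    out["q_value"] = q[idx]
    out["direction"] = np.where(diff[idx] > 0, "hyper", "hypo")
    return out


def permutation_filter(
    m: MethCountMatrix,
    sheet: SampleSheet,
    covariates: list[str],
    dmcs: pd.DataFrame,
    n_perm: int = 100,
    max_hits: int = 1,
    seed: int = 0,
    diff_cutoff: float = 10.0,
    q_cutoff: float = 0.05,
    permute_with_covariates: bool = True,
) -> tuple[pd.DataFrame, PermutationLedger]:
    """Remove DMC candidates that recur under shuffled case/control labels.

    For each of ``n_perm`` seeded permutations the full genome-wide DMC call
    is re-run (same thresholds, same genome-wide BH) with the labels
    shuffled among the same samples; covariates stay attached to their
    samples.  A candidate appearing in more than ``max_hits`` permuted calls
    is removed.  Bit-reproducible for a fixed seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    sheet_df = sheet.df.set_index("sample_id").loc[list(m.samples)].reset_index()
    group = (sheet_df["group"] == "case").to_numpy().astype(float)
    y = m.methylated.astype(float)
    n = m.total.astype(float)
    cand_idx = dmcs["site_idx"].to_numpy()
    hits = np.zeros(len(cand_idx), dtype=int)
    if len(cand_idx) > 0:
        covs = list(covariates) if permute_with_covariates else []
        X_base, _ = build_design(sheet_df, covs, group)
        # The covariate-only null model never sees the labels: fit it once.
        X_null = np.delete(X_base, 1, axis=1)
        _, null_dev, _ = fit_binomial_glm_batched(y, n, X_null)
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            perm = rng.permutation(len(group))
            g_perm = group[perm]
            X_perm = X_base.copy()
            X_perm[:, 1] = g_perm
            mask, _, _, _ = _dmc_mask(
                y, n, X_perm, g_perm, diff_cutoff, q_cutoff, null_dev=null_dev
            )
            hits += mask[cand_idx].astype(int)
    ledger = PermutationLedger(
        hits=pd.DataFrame(
            {
                "chrom": dmcs["chrom"].to_numpy(),
                "pos": dmcs["pos"].to_numpy(),
                "hits": hits,
            }
        ),
        n_permutations=n_perm,
        seed=seed,
        max_hits=max_hits,
    )
    retained = dmcs.loc[hits <= max_hits].reset_index(drop=True).copy()
    retained["perm_hits"] = hits[hits <= max_hits]
    return retained, ledger
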