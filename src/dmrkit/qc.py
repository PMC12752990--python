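"""Coverage filtering, beta values, sequencing summaries, PCA, and PVCA.

PVCA (principal variance component analysis) retains principal components
until a cumulative-variance threshold, attributes each retained PC's
variance to known sample factors with a random-effects fit, and averages
the per-PC attributions with eigenvalue weights.  It is the standard way to
ask "how much of the major variation is explained by batch-like factors?"
before differential testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .io import MethCountMatrix, SampleSheet


@dataclass
class BetaMatrix:
    """Per-CpG methylation proportions (methylated / total), sites x samples."""

    sites: pd.DataFrame
    samples: list[str]
    beta: np.ndarray

    def __post_init__(self):
        if np.nanmin(self.beta) < 0 or np.nanmax(self.beta) > 1:
            raise ValueError("beta values must lie in [0, 1]")

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return BetaMatrix(self.sites.copy(), list(sample_ids), self.beta[:, idx].copy())


@dataclass
class PvcaResult:
    fractions: dict[str, float]  # factor -> weighted variance fraction
    residual: float
    n_components: int
    eigenvalues: np.ndarray

    def as_series(self) -> pd.Series:
        s = pd.Series(self.fractions, dtype=float)
        s["residual"] = self.residual
        return s


def filter_cpgs(
    m: MethCountMatrix, min_cov: int = 10, max_cov: int = 500
) -> tuple[MethCountMatrix, dict]:
    """Keep sites covered by >= min_cov reads in *every* sample and <= max_cov
    in every sample; a single sample below or above the bounds removes the site.

    Returns the filtered matrix and a {kept, removed_low, removed_high} report.
    """
    if min_cov > max_cov:
        raise ValueError(f"min_cov {min_cov} > max_cov {max_cov}")
    low_ok = (m.total >= min_cov).all(axis=1)
    high_ok = (m.total <= max_cov).all(axis=1)
    keep = low_ok & high_ok
    report = {
        "kept": int(keep.sum()),
        "removed_low": int((~low_ok).sum()),
        "removed_high": int((low_ok & ~high_ok).sum()),
        "input": int(m.n_sites),
    }
    return m.subset_sites(keep), report


def compute_beta(m: MethCountMatrix) -> BetaMatrix:
    """Elementwise methylated/total.  Requires a filtered matrix (all totals >= 1).

    Note the matrix-level mean beta is the mean of elementwise ratios, not
    the ratio of summed counts; coverage does not weight the average.
    """
    if (m.total < 1).any():
        i, j = np.argwhere(m.total < 1)[0]
        site = m.sites.iloc[i]
        raise ValueError(
            f"total = 0 at {site.chrom}:{site.pos} sample {m.samples[j]}; "
            "apply filter_cpgs first"
        )
    beta = m.methylated / m.total
    return BetaMatrix(sites=m.sites.copy(), samples=list(m.samples), beta=beta)


# ---------------------------------------------------------------------------
# sequencing summary
# ---------------------------------------------------------------------------

SEQ_SUMMARY_COLUMNS = [
    "sequenced_reads",
    "data_gbp",
    "mapped_reads",
    "mapping_rate_pct",
    "dedup_reads",
    "dup_pct",
    "conversion_rate",
]

# Printed precision of the report layer, per column (decimal places).
_SUMMARY_PRECISION = {
    "sequenced_reads": 0,
    "data_gbp": 1,
    "mapped_reads": 1,
    "mapping_rate_pct": 1,
    "dedup_reads": 1,
    "dup_pct": 1,
    "conversion_rate": 2,
}


def _round_half_up(value: float, ndigits: int) -> float:
    """Round with halves away from zero (report-table convention), applied to
    the shortest decimal representation of ``value`` so a mean that is exactly
    x.x5 in decimal rounds up even when its binary double sits just below."""
    import decimal

    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def load_bundled_sequencing_stats() -> pd.DataFrame:
    """Per-sample sequencing/mapping statistics for the packaged lymphoma cohort."""
    with resources.files("dmrkit.data").joinpath(
        "lymphoma_sequencing_stats.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def summarize_sequencing(
    table: pd.DataFrame, group_col: str = "group", round_for_report: bool = False
) -> pd.DataFrame:
    """Arithmetic per-group mean of each numeric summary column.

    Full precision is retained unless ``round_for_report`` asks for the
    printed-table precision.  Rates are validated to [0, 100] and conversion
    to [0, 1].
    """
    missing = [c for c in SEQ_SUMMARY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"summary table missing columns: {missing}")
    if ((table["mapping_rate_pct"] < 0) | (table["mapping_rate_pct"] > 100)).any():
        raise ValueError("mapping_rate_pct outside [0, 100]")
    if ((table["conversion_rate"] < 0) | (table["conversion_rate"] > 1)).any():
        raise ValueError("conversion_rate outside [0, 1]")
    counts = table.groupby(group_col).size()
    if (counts < 1).any():
        raise ValueError("every group needs at least one row")
    means = table.groupby(group_col)[SEQ_SUMMARY_COLUMNS].mean()
    if round_for_report:
        for col, nd in _SUMMARY_PRECISION.items():
            means[col] = means[col].map(lambda v: _round_half_up(v, nd))
    return means


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x PCs
    loadings: np.ndarray  # PCs x sites (kept sites)
    variance_fraction: np.ndarray
    kept_sites: np.ndarray  # boolean mask over input sites


def run_pca(b: BetaMatrix) -> PcaResult:
    """PCA of samples over CpG features, with per-feature unit-variance scaling.

    Sites constant across samples carry no variance and are dropped before
    scaling (they would divide by zero).  Exact SVD; with tens of samples the
    sample-space decomposition is cheap at any site count.
    """
    if len(b.samples) < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = b.beta.T  # samples x sites
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if keep.sum() < 2:
        raise ValueError("fewer than 2 non-constant sites")
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    u, s, vt = np.linalg.svd(Xs, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive per component
    for k in range(len(s)):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    n = Xs.shape[0]
    eigvals = s**2 / (n - 1)
    frac = eigvals / eigvals.sum()
    scores = pd.DataFrame(
        u * s,
        index=pd.Index(b.samples, name="sample_id"),
        columns=[f"PC{k + 1}" for k in range(len(s))],
    )
    return PcaResult(scores=scores, loadings=vt, variance_fraction=frac, kept_sites=keep)


# ---------------------------------------------------------------------------
# PVCA
# ---------------------------------------------------------------------------


def _variance_components(score: np.ndarray, factors: pd.DataFrame) -> dict[str, float]:
    """Random-effects variance components of one PC score for each factor.

    Fits a linear mixed model with a crossed random intercept per factor
    (REML); on fit failure falls back to a one-factor-at-a-time method-of-
    moments estimate, which is the classical ANOVA estimator.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = factors.copy()
    data["score"] = score
    data["_one"] = 1
    vc = {f: f"0 + C({f})" for f in factors.columns}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("score ~ 1", data=data, groups="_one", vc_formula=vc)
            fit = model.fit(reml=True, method="lbfgs", maxiter=200)
        comps = {f: max(float(fit.vcomp[i]), 0.0) for i, f in enumerate(vc)}
        comps["residual"] = max(float(fit.scale), 0.0)
        return comps
    except Exception:
        comps = {}
        resid = float(np.var(score, ddof=1))
        for f in factors.columns:
            groups = factors[f].to_numpy()
            levels, idx = np.unique(groups, return_inverse=True)
            grand = score.mean()
            between = 0.0
            within = []
            n_per = []
            for li in range(len(levels)):
                sel = idx == li
                n_i = sel.sum()
                n_per.append(n_i)
                between += n_i * (score[sel].mean() - grand) ** 2
                if n_i > 1:
                    within.append(score[sel].var(ddof=1) * (n_i - 1))
            k = len(levels)
            n = len(score)
            if k < 2 or n <= k:
                comps[f] = 0.0
                continue
            msb = between / (k - 1)
            msw = sum(within) / (n - k) if within else 0.0
            n0 = (n - sum(np.square(n_per)) / n) / (k - 1)
            comps[f] = max((msb - msw) / n0, 0.0) if n0 > 0 else 0.0
        comps["residual"] = resid
        return comps


def run_pvca(
    b: BetaMatrix,
    sheet: SampleSheet,
    factors: list[str] = ("breed", "age_years", "sex", "setting"),
    var_threshold: float = 0.6,
    age_bin_years: float = 1.0,
) -> PvcaResult:
    """Principal variance component analysis of a beta matrix.

    PCs are retained until their cumulative variance fraction reaches
    ``var_threshold``; each retained PC's variance is partitioned across the
    factors by a random-effects fit, and factor fractions are averaged with
    eigenvalue weights.  Continuous age is binned to whole years (variance
    attribution needs levels).  A single-level factor contributes 0 with a
    warning.
    """
    factors = list(factors)
    fdata = {}
    sheet_idx = sheet.df.set_index("sample_id").loc[list(b.samples)]
    for f in factors:
        if f not in sheet_idx.columns:
            raise ValueError(f"factor {f!r} not in sample sheet")
        col = sheet_idx[f]
        if f == "age_years":
            col = (col.astype(float) / age_bin_years).round().astype(int)
        fdata[f] = col.astype(str).to_numpy()
    fdf = pd.DataFrame(fdata)
    usable = []
    for f in factors:
        if fdf[f].nunique() < 2:
            warnings.warn(f"factor {f!r} has a single level; contribution set to 0")
        else:
            usable.append(f)

    pca = run_pca(b)
    eig = pca.variance_fraction
    cum = np.cumsum(eig)
    n_keep = int(np.searchsorted(cum, var_threshold) + 1)
    n_keep = min(n_keep, pca.scores.shape[1])

    weights = eig[:n_keep] / eig[:n_keep].sum()
    acc = {f: 0.0 for f in factors}
    acc["residual"] = 0.0
    for k in range(n_keep):
        score = pca.scores.iloc[:, k].to_numpy()
        comps = _variance_components(score, fdf[usable]) if usable else {"residual": 1.0}
        total = sum(comps.values())
        if total <= 0:
            comps = {"residual": 1.0}
            total = 1.0
        for f in factors:
            acc[f] += weights[k] * comps.get(f, 0.0) / total
        acc["residual"] += weights[k] * comps.get("residual", 0.0) / total
    residual = acc.pop("residual")
    return PvcaResult(
        fractions=acc, residual=residual, n_components=n_keep, eigenvalues=eig[:n_keep]
    )
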