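"""k-means clustering of DMR methylation profiles and term enrichment.

Clustering operates on the region x sample mean-methylation matrix: each
region is one observation whose features are the per-sample betas, so
regions sharing a case/control change pattern cluster together.  Cluster
count is advised by the within-cluster-sum-of-squares (WCSS) elbow; the
pipeline default of k = 4 can override the suggestion.

Region-to-gene assignment distinguishes gene-body overlap, strand-aware
promoter hits (upstream of the TSS only), and proximity within an adjacency
window; hypergeometric upper-tail tests with Benjamini-Hochberg FDR score
term enrichment of the resulting gene sets against a background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .dmr import RegionSet
from .io import GeneAnnotation


@dataclass
class ClusterModel:
    k: int
    assignments: pd.Series  # region -> cluster label (0-based, ordered by size)
    centroids: np.ndarray
    wcss: float
    seed: int


def _best_kmeans(X: np.ndarray, k: int, seed: int, n_init: int, extra_init=None):
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    km.fit(X)
    best = km
    if extra_init is not None:
        km2 = KMeans(n_clusters=k, n_init=1, init=extra_init, random_state=seed)
        km2.fit(X)
        if km2.inertia_ < best.inertia_:
            best = km2
    return best


def elbow_wcss(
    x: pd.DataFrame,
    k_range: range = range(2, 11),
    seed: int = 0,
    n_init: int = 10,
    drop_ratio: float = 0.1,
) -> tuple[pd.Series, int]:
    """WCSS for each candidate k plus a suggested k.

    Restarts are nested: the best k-solution, augmented by the point
    farthest from its assigned centroid, seeds one extra (k+1)-init, which
    guarantees the WCSS curve is non-increasing in k.  Suggested k is the
    smallest k whose relative WCSS drop to k+1 falls below ``drop_ratio``;
    if no k qualifies the largest candidate is suggested.
    """
    ks = list(k_range)
    X = x.to_numpy(dtype=float)
    if min(ks) < 2 or max(ks) > len(X):
        raise ValueError(f"k_range must lie within [2, {len(X)}]")
    wcss = {}
    prev = None
    for k in ks:
        extra = None
        if prev is not None and prev.cluster_centers_.shape[0] == k - 1:
            d = np.linalg.norm(X - prev.cluster_centers_[prev.labels_], axis=1)
            extra = np.vstack([prev.cluster_centers_, X[np.argmax(d)]])
        best = _best_kmeans(X, k, seed, n_init, extra_init=extra)
        wcss[k] = float(best.inertia_)
        prev = best
    curve = pd.Series(wcss, name="wcss")
    suggested = ks[-1]
    for a, b in zip(ks[:-1], ks[1:]):
        if curve[a] <= 0:
            suggested = a
            break
        if (curve[a] - curve[b]) / curve[a] < drop_ratio:
            suggested = a
            break
    return curve, suggested


def kmeans_cluster(x: pd.DataFrame, k: int = 4, seed: int = 0, n_init: int = 10) -> ClusterModel:
    """Lloyd's k-means on region betas (Euclidean, no re-scaling: all features
    already share the [0, 1] beta scale).  Cluster labels are re-ordered by
    descending cluster size for stable reporting."""
    if k < 2:
        raise ValueError("k must be >= 2")
    X = x.to_numpy(dtype=float)
    if k > len(X):
        raise ValueError(f"k = {k} exceeds the {len(X)} regions available")
    km = _best_kmeans(X, k, seed, n_init)
    labels = km.labels_
    sizes = pd.Series(labels).value_counts()
    order = sizes.index.to_list()  # descending size, ties by first appearance
    remap = {old: new for new, old in enumerate(order)}
    relabeled = np.array([remap[l] for l in labels])
    centroids = km.cluster_centers_[order]
    return ClusterModel(
        k=k,
        assignments=pd.Series(relabeled, index=x.index, name="cluster"),
        centroids=centroids,
        wcss=float(km.inertia_),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# gene mapping
# ---------------------------------------------------------------------------


def map_regions_to_genes(
    regions: RegionSet,
    genes: GeneAnnotation,
    promoter_bp: int = 1500,
    adjacent_bp: int = 10_000,
    report_ties: bool = False,
) -> pd.DataFrame:
    """Classify each region's relation to genes.

    A region links to a gene as ``overlap`` (any shared base with the gene
    body), ``promoter`` (intersects the ``promoter_bp`` window immediately
    upstream of the TSS, strand-aware, TSS-exclusive), or
    ``within_adjacent`` (nearest gene within ``adjacent_bp``; ties broken by
    lexical gene_id, or all reported with ``report_ties``).  A gene with
    unknown strand is excluded from promoter logic with a warning.  Returns
    a tall frame: region, gene_id, link, distance.
    """
    gdf = genes.df
    unknown = ~gdf["strand"].isin(["+", "-"])
    if unknown.any():
        warnings.warn(
            f"{int(unknown.sum())} gene(s) with unknown strand excluded from "
            "promoter logic"
        )
    rows = []
    genes_by_chrom = dict(tuple(gdf.groupby("chrom")))
    for reg in regions.df.itertuples(index=False):
        sub = genes_by_chrom.get(reg.chrom)
        if sub is None:
            continue
        linked = False
        # gene-body overlap
        hit = sub[(sub["start"] <= reg.end) & (sub["end"] >= reg.start)]
        for g in hit.itertuples(index=False):
            rows.append((reg.chrom, reg.start, reg.end, g.gene_id, "overlap", 0))
            linked = True
        # promoter: [TSS - promoter_bp, TSS - 1], strand-aware
        for g in sub[sub["strand"].isin(["+", "-"])].itertuples(index=False):
            if g.strand == "+":
                p_start, p_end = g.start - promoter_bp, g.start - 1
            else:
                p_start, p_end = g.end + 1, g.end + promoter_bp
            if p_start <= reg.end and p_end >= reg.start:
                dist = min(abs(reg.start - (g.start if g.strand == "+" else g.end)),
                           abs(reg.end - (g.start if g.strand == "+" else g.end)))
                rows.append((reg.chrom, reg.start, reg.end, g.gene_id, "promoter", int(dist)))
                linked = True
        if not linked:
            # nearest gene within the adjacency window
            gap_left = reg.start - sub["end"]  # positive if gene upstream of region
            gap_right = sub["start"] - reg.end
            dist = np.maximum(np.maximum(gap_left, gap_right), 0).to_numpy()
            order = np.lexsort((sub["gene_id"].to_numpy(), dist))
            if len(order) == 0:
                continue
            best = dist[order[0]]
            if best <= adjacent_bp:
                chosen = [order[0]]
                if report_ties:
                    chosen = [i for i in order if dist[i] == best]
                for i in chosen:
                    g = sub.iloc[i]
                    rows.append(
                        (reg.chrom, reg.start, reg.end, g["gene_id"],
                         "within_adjacent", int(dist[i]))
                    )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "gene_id", "link", "distance"]
    )


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def hypergeom_enrich(
    selected_genes: set[str] | list[str],
    background_genes: set[str] | list[str],
    term_map: pd.DataFrame,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of terms in a gene selection.

    For each term with K annotated genes in a background of N, and a
    selection of n genes of which k carry the term, p = P(X >= k) for
    X ~ Hypergeom(N, K, n); BH-adjusted FDR across terms.  Terms with no
    annotated background gene are skipped.
    """
    background = set(background_genes)
    selected = set(selected_genes)
    if not selected <= background:
        raise ValueError("selected genes must be a subset of the background")
    tm = term_map[term_map["gene_id"].isin(background)]
    N = len(background)
    n_sel = len(selected)
    rows = []
    for term, genes_of_term in tm.groupby("term_id")["gene_id"]:
        ann = set(genes_of_term)
        K = len(ann)
        if K == 0:
            continue
        k = len(ann & selected)
        p = float(hypergeom.sf(k - 1, N, K, n_sel))
        rows.append({"term_id": term, "k_hit": k, "K_ann": K, "n_sel": n_sel,
                     "N_bg": N, "p_value": p})
    out = pd.DataFrame(rows, columns=["term_id", "k_hit", "K_ann", "n_sel", "N_bg", "p_value"])
    if len(out):
        _, fdr, _, _ = multipletests(out["p_value"], method="fdr_bh")
        out["fdr"] = fdr
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
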