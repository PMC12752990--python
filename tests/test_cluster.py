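"""Clustering, the WCSS elbow, gene mapping, and hypergeometric enrichment."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from dmrkit import (
    GeneAnnotation,
    RegionSet,
    elbow_wcss,
    hypergeom_enrich,
    kmeans_cluster,
    map_regions_to_genes,
)


def _blob_data(seed=0, n_per=10, k=3):
    rng = np.random.default_rng(seed)
    centers = rng.uniform(0, 1, size=(k, 5))
    rows = np.concatenate(
        [c + rng.normal(0, 0.02, size=(n_per, 5)) for c in centers]
    )
    return pd.DataFrame(
        np.clip(rows, 0, 1),
        index=[f"r{i}" for i in range(k * n_per)],
        columns=[f"s{j}" for j in range(5)],
    )


def test_kmeans_labels_ordered_by_size():
    x = _blob_data(seed=1)
    # unbalance the blobs: drop most of one
    x = x.drop(index=[f"r{i}" for i in range(20, 28)])
    model = kmeans_cluster(x, k=3, seed=0)
    sizes = model.assignments.value_counts().sort_index()
    assert list(sizes.index) == [0, 1, 2]
    assert (np.diff(sizes.to_numpy()) <= 0).all()
    # deterministic
    model2 = kmeans_cluster(x, k=3, seed=0)
    assert model.assignments.equals(model2.assignments)


def test_kmeans_guards():
    x = _blob_data()
    with pytest.raises(ValueError, match="k must be >= 2"):
        kmeans_cluster(x, k=1)
    with pytest.raises(ValueError, match="exceeds"):
        kmeans_cluster(x.head(3), k=5)


def test_elbow_wcss_monotone_and_suggestion():
    for seed in range(3):
        x = _blob_data(seed=seed, n_per=8, k=4)
        curve, suggested = elbow_wcss(x, range(2, 9), seed=seed)
        assert (np.diff(curve.to_numpy()) <= 1e-9).all()
        assert 2 <= suggested <= 8
    # well-separated loose blobs: the big WCSS drops stop at the true k
    for seed in range(3):
        rng = np.random.default_rng(seed)
        centers = rng.normal(scale=10, size=(4, 8))
        rows = np.concatenate([c + rng.normal(0, 1.0, size=(12, 8)) for c in centers])
        _, suggested = elbow_wcss(pd.DataFrame(rows), range(2, 9), seed=seed)
        assert suggested == 4


def _genes(rows):
    return GeneAnnotation(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "strand"])
    )


def _region_set(rows):
    return RegionSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "n_dmcs", "direction", "label"])
    )


def test_gene_mapping_overlap_promoter_adjacent():
    genes = _genes(
        [
            ("chr1", 5000, 6000, "body", "+"),
            ("chr1", 20000, 21000, "plusTSS", "+"),
            ("chr1", 40000, 41000, "minusTSS", "-"),
            ("chr1", 80000, 81000, "far", "+"),
        ]
    )
    regions = _region_set(
        [
            ("chr1", 5500, 5600, 6, "hypo", "dmr"),      # inside body
            ("chr1", 18600, 18700, 6, "hypo", "dmr"),    # in [TSS-1500, TSS-1] of plusTSS
            ("chr1", 41100, 41300, 6, "hypo", "dmr"),    # upstream of minus-strand TSS (end+1..end+1500)
            ("chr1", 70000, 70100, 6, "hypo", "dmr"),    # within 10 kb of "far"
            ("chr1", 300000, 300100, 6, "hypo", "dmr"),  # beyond every window
        ]
    )
    links = map_regions_to_genes(regions, genes)
    by_region = {(r.start): (r.gene_id, r.link) for r in links.itertuples()}
    assert by_region[5500] == ("body", "overlap")
    assert by_region[18600] == ("plusTSS", "promoter")
    assert by_region[41100] == ("minusTSS", "promoter")
    assert by_region[70000] == ("far", "within_adjacent")
    assert 300000 not in by_region


def test_promoter_window_is_tss_exclusive_and_bounded():
    genes = _genes([("chr1", 20000, 21000, "g", "+")])
    # window is [18500, 19999]: a region ending at 18499 misses, at 18500 hits
    miss = _region_set([("chr1", 18400, 18499, 6, "hypo", "dmr")])
    hit = _region_set([("chr1", 18400, 18500, 6, "hypo", "dmr")])
    assert (map_regions_to_genes(miss, genes)["link"] != "promoter").all()
    assert (map_regions_to_genes(hit, genes)["link"] == "promoter").any()
    # a region covering the TSS itself is an overlap, not (only) a promoter hit
    tss = _region_set([("chr1", 20000, 20010, 6, "hypo", "dmr")])
    assert set(map_regions_to_genes(tss, genes)["link"]) >= {"overlap"}


def test_adjacent_tie_breaks_lexically_or_reports_all():
    # both promoters face away from the region (plus-strand gene upstream,
    # minus-strand gene downstream), leaving a pure nearest-gene tie
    genes = _genes(
        [("chr1", 1000, 2000, "zeta", "+"), ("chr1", 4000, 5000, "alpha", "-")]
    )
    region = _region_set([("chr1", 2501, 3499, 6, "hypo", "dmr")])
    links = map_regions_to_genes(region, genes)
    assert list(links["gene_id"]) == ["alpha"]  # equidistant (500 bp), lexical winner
    links_all = map_regions_to_genes(region, genes, report_ties=True)
    assert sorted(links_all["gene_id"]) == ["alpha", "zeta"]


def test_unknown_strand_excluded_from_promoters():
    genes = _genes([("chr1", 20000, 21000, "g", ".")])
    region = _region_set([("chr1", 18600, 18700, 6, "hypo", "dmr")])
    with pytest.warns(UserWarning, match="unknown strand"):
        links = map_regions_to_genes(region, genes)
    assert (links["link"] != "promoter").all()


def _exact_sf(k, N, K, n) -> Fraction:
    """P(X >= k) for X ~ Hypergeom(N, K, n), exact rational."""
    denom = comb(N, n)
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(comb(K, j) * comb(N - K, n - j), denom)
    return total


def test_hypergeom_enrichment_small_exact_cases():
    background = {f"g{i}" for i in range(10)}
    selected = {"g0", "g1", "g2", "g3"}
    term_map = pd.DataFrame(
        {
            "gene_id": ["g0", "g1", "g5", "g6", "g7", "g0", "g9"],
            "term_id": ["T1", "T1", "T1", "T1", "T1", "T2", "T2"],
        }
    )
    out = hypergeom_enrich(selected, background, term_map).set_index("term_id")
    # T1: K=5, k=2, n=4, N=10; T2: K=2, k=1
    assert out.loc["T1", "p_value"] == pytest.approx(float(_exact_sf(2, 10, 5, 4)), rel=1e-12)
    assert out.loc["T2", "p_value"] == pytest.approx(float(_exact_sf(1, 10, 2, 4)), rel=1e-12)
    assert (out["fdr"] >= out["p_value"] - 1e-15).all()


def test_hypergeom_selection_must_be_subset():
    with pytest.raises(ValueError, match="subset"):
        hypergeom_enrich({"gX"}, {"g0"}, pd.DataFrame({"gene_id": ["g0"], "term_id": ["T"]}))


def test_hypergeom_terms_outside_background_ignored():
    out = hypergeom_enrich(
        {"g0"},
        {"g0", "g1"},
        pd.DataFrame({"gene_id": ["zz"], "term_id": ["T"]}),
    )
    assert len(out) == 0
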