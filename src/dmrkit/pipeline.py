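"""End-to-end orchestration: hold-out split, stage sequencing, run manifests.

Every selection stage (DMC calling, permutation filter, DMR construction,
confounder subtraction, clustering, model fitting) consumes training
samples only; held-out test methylation enters solely at evaluation.  The
pipeline enforces this physically: selection stages receive a matrix from
which test columns have been removed, and the evaluators assert train/test
disjointness.

A run manifest records the configuration hash, per-output checksums, seeds
and stage timings; identical config + seed reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import dmc as _dmc
from . import dmr as _dmr
from . import models_multi as _mm
from . import models_single as _ms
from . import qc as _qc
from .io import (
    GeneAnnotation,
    MethCountMatrix,
    SampleSheet,
    write_regions_bed,
    write_sample_sheet,
)

logger = logging.getLogger("dmrkit")


@dataclass
class RunConfig:
    """All stage parameters, defaulting to the pipeline's canonical values."""

    min_cov: int = 10
    max_cov: int = 500
    covariates: tuple[str, ...] = ("breed", "age")
    diff_cutoff: float = 10.0
    q_cutoff: float = 0.05
    n_perm: int = 100
    max_perm_hits: int = 1
    merge_gap: int = 100
    min_dmcs: int = 6
    steroid_min_dmcs: int = 4
    drop_chroms: tuple[str, ...] = ("chrX",)
    k_clusters: int = 4
    n_boot: int = 1000
    top_n: int = 20
    gamma: float = 0.001
    cv_folds: int = 4
    forest_trees: int = 500
    tree_depth: int = 2
    train_fraction: float = 0.72
    train_counts: dict | None = None  # e.g. {"case": 16, "control": 12}
    promoter_bp: int = 1500
    adjacent_bp: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.min_cov > self.max_cov:
            raise ValueError("min_cov > max_cov")
        for name in ("n_perm", "merge_gap", "min_dmcs", "k_clusters", "n_boot",
                     "cv_folds", "forest_trees", "tree_depth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    checksums: dict[str, str]
    timings: dict[str, float]
    versions: dict[str, str]
    stage_info: dict[str, object] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=str)


def holdout_split(
    sheet: SampleSheet,
    train_fraction: float = 0.72,
    seed: int = 0,
    train_counts: dict | None = None,
) -> SampleSheet:
    """Stratified random train/test assignment by group.

    Samples already assigned (split != "unassigned") are respected.  With
    ``train_counts`` (e.g. {"case": 16, "control": 12}) exact per-group
    training counts are drawn instead of a fraction.  Both splits must end
    up containing both groups.
    """
    df = sheet.df.copy()
    rng = np.random.default_rng(seed)
    for group, gdf in df[df["split"] == "unassigned"].groupby("group"):
        idx = gdf.index.to_numpy()
        if train_counts is not None:
            n_train = int(train_counts[group])
        else:
            n_train = int(round(train_fraction * len(idx)))
        if not 0 < n_train <= len(idx):
            raise ValueError(
                f"group {group!r}: requested {n_train} training samples of {len(idx)}"
            )
        chosen = rng.choice(idx, size=n_train, replace=False)
        df.loc[idx, "split"] = "test"
        df.loc[chosen, "split"] = "train"
    for split in ("train", "test"):
        part = df[df["split"] == split]
        present = set(part["group"])
        if present != {"case", "control"}:
            raise ValueError(
                f"{split} split lacks a class (has {sorted(present)}); "
                "adjust train_fraction or counts"
            )
    out = SampleSheet(df)
    counts = df.groupby(["split", "group"]).size()
    logger.info("hold-out split:\n%s", counts)
    return out


def assert_no_leakage(train_ids, test_ids) -> None:
    overlap = set(train_ids) & set(test_ids)
    if overlap:
        raise ValueError(f"train/test sample overlap: {sorted(overlap)}")


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    matrix: MethCountMatrix,
    sheet: SampleSheet,
    config: RunConfig,
    out_dir: str | Path,
    genes: GeneAnnotation | None = None,
    term_map: pd.DataFrame | None = None,
) -> RunManifest:
    """Execute the full analysis and write all reports under ``out_dir``.

    Stage order: split -> coverage filter -> DMC call -> permutation filter
    -> DMR merge -> confounder subtraction / X censoring -> region betas ->
    clustering -> (optional) gene mapping + enrichment -> single-DMR models
    -> multi-probe models -> held-out evaluation -> manifest.  Any stage
    error aborts with the stage name; outputs written so far are left in
    place for debugging.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    checksums: dict[str, str] = {}
    timings: dict[str, float] = {}
    info: dict[str, object] = {}
    stage = "setup"

    def emit(name: str, writer) -> None:
        path = out_dir / name
        writer(path)
        checksums[name] = _sha256_file(path)

    def tic(name):
        timings[name] = time.perf_counter()

    def toc(name):
        timings[name] = round(time.perf_counter() - timings[name], 3)

    try:
        stage = "split"
        tic(stage)
        if "unassigned" in set(sheet.df["split"]):
            sheet = holdout_split(
                sheet, config.train_fraction, seed=config.seed,
                train_counts=config.train_counts,
            )
        train_ids = sheet.train_ids
        test_ids = sheet.test_ids
        assert_no_leakage(train_ids, test_ids)
        emit("split.tsv", lambda p: write_sample_sheet(sheet, p))
        toc(stage)

        # Selection stages see the training matrix only.
        stage = "filter"
        tic(stage)
        train_matrix = matrix.subset_samples(train_ids)
        train_sheet = sheet.subset(train_ids)
        filtered, filt_report = _qc.filter_cpgs(train_matrix, config.min_cov, config.max_cov)
        info["filter"] = filt_report
        toc(stage)

        stage = "dmc"
        tic(stage)
        dmcs = _dmc.call_dmcs(
            filtered, train_sheet, covariates=list(config.covariates),
            diff_cutoff=config.diff_cutoff, q_cutoff=config.q_cutoff,
        )
        info["n_dmc_candidates"] = int(len(dmcs))
        toc(stage)

        stage = "permutation_filter"
        tic(stage)
        retained, ledger = _dmc.permutation_filter(
            filtered, train_sheet, list(config.covariates), dmcs,
            n_perm=config.n_perm, max_hits=config.max_perm_hits,
            seed=config.seed, diff_cutoff=config.diff_cutoff,
            q_cutoff=config.q_cutoff,
        )
        info["n_dmc_retained"] = int(len(retained))
        emit("dmc.tsv", lambda p: retained.to_csv(p, sep="\t", index=False))
        emit("perm_ledger.tsv", lambda p: ledger.hits.to_csv(p, sep="\t", index=False))
        toc(stage)

        stage = "dmr_merge"
        tic(stage)
        candidates = _dmr.merge_dmcs(retained, gap=config.merge_gap, min_dmcs=config.min_dmcs)
        emit("dmr_candidates.bed", lambda p: write_regions_bed(candidates, p))
        toc(stage)

        stage = "confounder"
        tic(stage)
        steroid = _dmr.call_confounder_regions(
            filtered, train_sheet, min_dmcs=config.steroid_min_dmcs,
            gap=config.merge_gap, diff_cutoff=config.diff_cutoff,
            q_cutoff=config.q_cutoff,
        )
        emit("steroid_regions.bed", lambda p: write_regions_bed(steroid, p))
        final = _dmr.subtract_and_censor(candidates, steroid, set(config.drop_chroms))
        info["n_dmr_final"] = int(len(final))
        emit("final_dmrs.bed", lambda p: write_regions_bed(final, p))
        toc(stage)

        stage = "region_beta"
        tic(stage)
        if len(final) == 0:
            logger.warning("no final DMRs; model stages skipped")
            manifest = _finish(config, checksums, timings, info, out_dir)
            return manifest
        # Region betas for all samples come from the full matrix, but only
        # at the final regions (fixed by training data); the coverage filter
        # itself was learned on training samples.
        keep_mask = np.zeros(matrix.n_sites, dtype=bool)
        site_key = pd.MultiIndex.from_frame(matrix.sites[["chrom", "pos"]])
        kept_key = pd.MultiIndex.from_frame(filtered.sites[["chrom", "pos"]])
        keep_mask[site_key.isin(kept_key)] = True
        full_filtered = matrix.subset_sites(keep_mask)
        observed = (full_filtered.total >= 1).all(axis=1)
        full_filtered = full_filtered.subset_sites(observed)
        betas = _qc.compute_beta(full_filtered)
        region_b = _dmr.region_beta(betas, final)
        emit("region_beta.tsv", lambda p: region_b.to_csv(p, sep="\t"))
        x_train = region_b[train_ids]
        x_test = region_b[test_ids]
        y_train = (sheet.subset(train_ids).df["group"] == "case").to_numpy().astype(int)
        y_test = (sheet.subset(test_ids).df["group"] == "case").to_numpy().astype(int)
        toc(stage)

        stage = "clustering"
        tic(stage)
        k = min(config.k_clusters, max(2, len(final) - 1))
        if len(final) >= 2 and len(final) > k:
            curve, suggested = _cluster.elbow_wcss(
                x_train, range(2, min(10, len(final) - 1) + 1), seed=config.seed
            )
            clusters = _cluster.kmeans_cluster(x_train, k=k, seed=config.seed)
            info["elbow_suggested_k"] = int(suggested)
            emit("wcss.tsv", lambda p: curve.to_csv(p, sep="\t"))
            emit(
                "clusters.tsv",
                lambda p: clusters.assignments.to_csv(p, sep="\t"),
            )
        else:
            clusters = None
        toc(stage)

        stage = "enrichment"
        if genes is not None and term_map is not None:
            tic(stage)
            links = _cluster.map_regions_to_genes(
                final, genes, promoter_bp=config.promoter_bp,
                adjacent_bp=config.adjacent_bp,
            )
            emit("gene_links.tsv", lambda p: links.to_csv(p, sep="\t", index=False))
            background = set(genes.df["gene_id"])
            for link_class in ("overlap", "promoter", "within_adjacent"):
                sel = set(links.loc[links["link"] == link_class, "gene_id"])
                if sel:
                    enr = _cluster.hypergeom_enrich(sel, background, term_map)
                    emit(
                        f"enrichment_{link_class}.tsv",
                        lambda p, e=enr: e.to_csv(p, sep="\t", index=False),
                    )
            toc(stage)

        stage = "single_models"
        tic(stage)
        screen = _ms.bootstrap_screen(
            x_train, y_train, n_boot=config.n_boot, seed=config.seed,
            top_n=config.top_n,
        )
        singles = _ms.evaluate_models(x_train, y_train, x_test, y_test, screen=screen)
        emit("single_models.tsv", lambda p: singles.to_csv(p, sep="\t", index=False))
        toc(stage)

        stage = "multi_models"
        tic(stage)
        results = {}
        try:
            sparse = _mm.fit_l0l2_logistic(
                x_train, y_train, gamma=config.gamma, cv_folds=config.cv_folds,
                seed=config.seed,
            )
            results["sparse"] = {
                "selected": sparse.selected,
                **_mm.evaluate_multi(sparse, x_test, y_test, x_train=x_train),
            }
            coef = pd.DataFrame(
                {"region": sparse.selected, "coefficient": sparse.coefficients}
            )
            emit("sparse_model.tsv", lambda p: coef.to_csv(p, sep="\t", index=False))
        except ValueError as exc:
            logger.warning("sparse model skipped: %s", exc)
        if clusters is not None:
            per_cluster = _mm.select_by_tree_per_cluster(
                x_train, y_train, clusters, max_depth=config.tree_depth,
                seed=config.seed,
            )
            panel = sorted({r for regs in per_cluster.values() for r in regs})
            if panel:
                forest = _mm.fit_forest(
                    x_train, y_train, panel, n_trees=config.forest_trees,
                    seed=config.seed,
                )
                results["forest"] = {
                    "selected": panel,
                    **_mm.evaluate_multi(forest, x_test, y_test, x_train=x_train),
                }
        info["multi_models"] = results
        emit(
            "evaluation.tsv",
            lambda p: pd.DataFrame(
                [
                    {"model": name, "n_regions": len(res["selected"]),
                     "test_auroc": res["test_auroc"], "test_auprc": res["test_auprc"]}
                    for name, res in results.items()
                ]
            ).to_csv(p, sep="\t", index=False),
        )
        toc(stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return _finish(config, checksums, timings, info, out_dir)


def _finish(config, checksums, timings, info, out_dir: Path) -> RunManifest:
    import sklearn
    import scipy

    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=config.seed,
        checksums=dict(sorted(checksums.items())),
        timings=timings,
        versions={
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "sklearn": sklearn.__version__,
        },
        stage_info=info,
    )
    with open(out_dir / "manifest.json", "w") as fh:
        fh.write(manifest.to_json())
    return manifest
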