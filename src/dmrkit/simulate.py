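"""Synthetic WGBS cohort generator with known truth.

Emulates the statistical structure of a blood whole-genome bisulfite
case/control study: ~70x negative-binomial coverage per CpG, a bimodal
per-CpG baseline methylation landscape (most CpGs highly methylated, a
minority — promoter/island-like — lowly methylated), beta-binomial count
noise, planted hypo-dominant disease DMRs of modest effect (|delta beta|
around 10-15 percentage points), planted corticosteroid-responsive regions
tied to a treatment flag, covariate structure (age, sex, breed, collection
setting), and an X chromosome carrying a sex effect.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import (
    MethCountMatrix,
    SampleSheet,
    write_meth_calls,
    write_regions_bed,
    write_sample_sheet,
)

# Cohort demographics defaults mirror the study population the generator
# emulates: control ages ~ Normal(7.79, 3.66), case ages ~ Normal(10.2, 2.02),
# truncated at 1 year; a control group dominated by two breeds and a
# heterogeneous case group.
CONTROL_AGE = (7.79, 3.66)
CASE_AGE = (10.2, 2.02)
CONTROL_BREEDS = {"Poodle (Toy)": 13, "Shiba": 3, "Dachshund (Miniature)": 3}
CASE_BREEDS = {
    "Bichon frize": 1, "Boston terrier": 1, "Cavalier": 1, "Chihuahua": 1,
    "Dachshund (Miniature)": 1, "French bulldog": 1, "Golden retriever": 1,
    "Norfolk terrier": 1, "Papillon": 1, "Pug": 2, "Shetland sheepdog": 1,
    "Shiba": 4, "Poodle (Standard)": 1, "Poodle (Toy)": 2, "Yorkshire terrier": 1,
}


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort.

    Planted effect sizes are on the methylation-proportion scale: a hypo
    region lowers case (or steroid-treated) methylation by ``delta_beta``.
    ``overdispersion`` is the beta-binomial concentration (larger = closer
    to binomial); 300 corresponds to an inter-individual beta SD of ~0.02
    at mid-range methylation, typical of unremarkable blood CpGs.
    """

    n_cases: int = 20
    n_controls: int = 19
    n_cpgs: int = 20_000
    chroms: tuple[str, ...] = ("chr1", "chr2", "chr3", "chr4", "chr5", "chrX")
    mean_coverage: float = 70.0
    coverage_dispersion: float = 10.0  # negative-binomial shape
    baseline_mix: tuple = ((0.75, 12.0, 2.0), (0.25, 1.5, 8.0))  # (weight, a, b)
    n_dmrs: int = 50
    dmr_cpg_count: int = 6
    dmr_spacing: int = 100  # max bp between CpGs inside a planted region
    delta_beta: float = 0.10
    hypo_fraction: float = 0.8
    n_steroid_regions: int = 20
    steroid_effect: float = 0.15
    overdispersion: float = 300.0
    sex_effect: float = 0.5  # pull of female chrX betas toward 0.5
    age_cpg_fraction: float = 0.05
    age_slope_sd: float = 0.02  # logit units per year on affected CpGs
    breed_cpg_fraction: float = 0.05
    breed_offset_sd: float = 0.2
    setting_cpg_fraction: float = 0.05
    setting_offset_sd: float = 0.2
    steroid_prevalence: tuple[float, float] = (0.45, 0.15)  # (cases, controls)
    region_buffer: int = 500  # bp clearance around planted regions
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cases", "n_controls", "n_cpgs", "dmr_cpg_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_dmrs", "n_steroid_regions"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.delta_beta < 1.0:
            raise ValueError("delta_beta must be in [0, 1)")
        if not 0.0 <= self.hypo_fraction <= 1.0:
            raise ValueError("hypo_fraction must be in [0, 1]")
        if self.mean_coverage <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage parameters must be positive")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion concentration must be positive")
        if "chrX" not in self.chroms:
            raise ValueError("chroms must include 'chrX'")


@dataclass
class TruthSet:
    """Planted ground truth: disease regions, steroid regions, covariates used."""

    regions: pd.DataFrame  # chrom, start, end, direction, delta_beta
    steroid_regions: pd.DataFrame
    covariates: pd.DataFrame  # the generated sample sheet rows


def _allocate_cpgs(config: SimConfig, rng: np.random.Generator) -> dict[str, int]:
    """Split the CpG budget over chromosomes (chrX gets half an autosome's share)."""
    weights = np.array([0.5 if c == "chrX" else 1.0 for c in config.chroms])
    counts = np.floor(config.n_cpgs * weights / weights.sum()).astype(int)
    counts[0] += config.n_cpgs - counts.sum()
    return dict(zip(config.chroms, counts))


def _plan_regions(
    config: SimConfig, budgets: dict[str, int], rng: np.random.Generator
) -> dict[str, list[dict]]:
    """Assign planted regions to autosomes, respecting each CpG budget."""
    autosomes = [c for c in config.chroms if c != "chrX"]
    specs = []
    for _ in range(config.n_dmrs):
        hypo = rng.random() < config.hypo_fraction
        specs.append(
            {
                "kind": "disease",
                "direction": "hypo" if hypo else "hyper",
                "delta_beta": config.delta_beta,
            }
        )
    for _ in range(config.n_steroid_regions):
        hypo = rng.random() < 0.5
        specs.append(
            {
                "kind": "steroid",
                "direction": "hypo" if hypo else "hyper",
                "delta_beta": config.steroid_effect,
            }
        )
    per_chrom: dict[str, list[dict]] = {c: [] for c in config.chroms}
    remaining = {c: budgets[c] for c in autosomes}
    order = rng.permutation(len(specs))
    for idx in order:
        spec = specs[idx]
        fits = [c for c in autosomes if remaining[c] >= config.dmr_cpg_count]
        if not fits:
            raise ValueError(
                f"cannot place {len(specs)} planted regions of "
                f"{config.dmr_cpg_count} CpGs on {len(autosomes)} autosomes with a "
                f"budget of {config.n_cpgs} CpGs; reduce region count or size"
            )
        chrom = fits[rng.integers(len(fits))]
        per_chrom[chrom].append(spec)
        remaining[chrom] -= config.dmr_cpg_count
    return per_chrom


def _layout_chromosome(
    chrom: str,
    n_cpgs: int,
    regions: list[dict],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[dict]]:
    """Lay CpG positions along one chromosome, interleaving planted regions.

    Background inter-CpG gaps exceed the merge distance (so spurious DMCs do
    not chain into regions by construction of the genome, only by chance
    colocation of calls), while CpGs inside a planted region are spaced at
    most ``dmr_spacing`` apart.  Planted regions are buffered from background
    CpGs and can never overlap one another.
    """
    n_region_cpgs = len(regions) * config.dmr_cpg_count
    n_bg = n_cpgs - n_region_cpgs
    if n_bg < 0:
        raise ValueError(f"{chrom}: planted regions exceed the CpG budget")
    blocks = ["bg"] * n_bg + list(range(len(regions)))
    rng.shuffle(blocks)
    positions = np.empty(n_cpgs, dtype=np.int64)
    placed_regions: list[dict] = [dict(r) for r in regions]
    pos = 1000
    i = 0
    for block in blocks:
        if block == "bg":
            pos += 101 + int(rng.exponential(400.0))
            positions[i] = pos
            i += 1
        else:
            pos += config.region_buffer
            spacings = rng.integers(30, config.dmr_spacing + 1, size=config.dmr_cpg_count - 1)
            start = pos
            positions[i] = pos
            i += 1
            for sp in spacings:
                pos += int(sp)
                positions[i] = pos
                i += 1
            placed_regions[block]["chrom"] = chrom
            placed_regions[block]["start"] = int(start)
            placed_regions[block]["end"] = int(pos)
            placed_regions[block]["cpg_index"] = (i - config.dmr_cpg_count, i)
            pos += config.region_buffer
    return positions, placed_regions


def _sample_sheet(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for group, n, (mu, sd) in (
        ("case", config.n_cases, CASE_AGE),
        ("control", config.n_controls, CONTROL_AGE),
    ):
        breeds = CASE_BREEDS if group == "case" else CONTROL_BREEDS
        breed_names = list(breeds)
        breed_p = np.array(list(breeds.values()), dtype=float)
        breed_p /= breed_p.sum()
        p_female = 0.5 if group == "case" else 13 / 19
        p_steroid = config.steroid_prevalence[0 if group == "case" else 1]
        for k in range(n):
            age = float(np.clip(rng.normal(mu, sd), 1.0, None))
            rows.append(
                {
                    "sample_id": f"{'S' if group == 'case' else 'C'}{k + 1:03d}",
                    "group": group,
                    "age_years": round(age, 1),
                    "sex": "F" if rng.random() < p_female else "M",
                    "neutered": int(rng.random() < 0.5),
                    "breed": breed_names[rng.choice(len(breed_names), p=breed_p)],
                    "steroid": int(rng.random() < p_steroid),
                    "setting": "site_A" if rng.random() < 0.7 else "site_B",
                    "split": "unassigned",
                }
            )
    return pd.DataFrame(rows)


def simulate_cohort(config: SimConfig) -> tuple[MethCountMatrix, SampleSheet, TruthSet]:
    """Generate a full cohort: counts, sample sheet, and planted truth.

    Coverage is negative binomial around ``mean_coverage``; methylated counts
    are beta-binomial around a per-CpG, per-sample target proportion that
    combines the baseline landscape, covariate effects (logit scale), and
    planted group/steroid effects (proportion scale, clipped to [0.01, 0.99]
    so the beta-binomial stays valid at extreme baselines).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    sheet_df = _sample_sheet(config, rng)
    n_samples = len(sheet_df)

    budgets = _allocate_cpgs(config, rng)
    planned = _plan_regions(config, budgets, rng)

    site_frames = []
    all_regions: list[dict] = []
    offset = 0
    region_rows = []
    for chrom in config.chroms:
        positions, placed = _layout_chromosome(
            chrom, budgets[chrom], planned[chrom], config, rng
        )
        site_frames.append(
            pd.DataFrame({"chrom": chrom, "pos": positions, "strand": "+"})
        )
        for reg in placed:
            lo, hi = reg.pop("cpg_index")
            reg["cpg_slice"] = (offset + lo, offset + hi)
            region_rows.append(reg)
        offset += len(positions)
    sites = pd.concat(site_frames, ignore_index=True)
    n_sites = len(sites)

    # Baseline methylation landscape: two-component beta mixture for
    # background CpGs; planted regions get a direction-appropriate baseline
    # (hypo regions start high, hyper regions start low) shared across the
    # region with small per-CpG jitter.
    weights = np.array([w for w, _, _ in config.baseline_mix])
    comp = rng.choice(len(weights), size=n_sites, p=weights / weights.sum())
    baseline = np.empty(n_sites)
    for ci, (_, a, b) in enumerate(config.baseline_mix):
        sel = comp == ci
        baseline[sel] = rng.beta(a, b, size=int(sel.sum()))
    for reg in region_rows:
        lo, hi = reg["cpg_slice"]
        if reg["direction"] == "hypo":
            base = rng.uniform(0.65, 0.90)
        else:
            base = rng.uniform(0.10, 0.35)
        baseline[lo:hi] = np.clip(base + rng.normal(0.0, 0.02, hi - lo), 0.02, 0.98)

    # Covariate effects on the logit scale, each touching a random CpG subset.
    base_logit = logit(np.clip(baseline, 1e-4, 1 - 1e-4))
    eta = np.tile(base_logit[:, None], (1, n_samples))

    ages = sheet_df["age_years"].to_numpy()
    age_sel = rng.random(n_sites) < config.age_cpg_fraction
    age_slopes = np.where(age_sel, rng.normal(0.0, config.age_slope_sd, n_sites), 0.0)
    eta += age_slopes[:, None] * (ages - ages.mean())[None, :]

    breeds = sheet_df["breed"].to_numpy()
    breed_levels, breed_idx = np.unique(breeds, return_inverse=True)
    breed_sel = rng.random(n_sites) < config.breed_cpg_fraction
    breed_offsets = rng.normal(0.0, config.breed_offset_sd, (n_sites, len(breed_levels)))
    breed_offsets[~breed_sel] = 0.0
    eta += breed_offsets[:, breed_idx]

    settings = sheet_df["setting"].to_numpy()
    set_levels, set_idx = np.unique(settings, return_inverse=True)
    set_sel = rng.random(n_sites) < config.setting_cpg_fraction
    set_offsets = rng.normal(0.0, config.setting_offset_sd, (n_sites, len(set_levels)))
    set_offsets[~set_sel] = 0.0
    eta += set_offsets[:, set_idx]

    p = expit(eta)

    # Planted effects on the proportion scale (clipped), so the realized
    # group difference estimates delta_beta regardless of baseline.
    is_case = (sheet_df["group"] == "case").to_numpy()
    on_steroid = sheet_df["steroid"].to_numpy().astype(bool)
    for reg in region_rows:
        lo, hi = reg["cpg_slice"]
        sign = -1.0 if reg["direction"] == "hypo" else 1.0
        affected = is_case if reg["kind"] == "disease" else on_steroid
        p[lo:hi, affected] = np.clip(
            p[lo:hi, affected] + sign * reg["delta_beta"], 0.01, 0.99
        )

    # Sex effect on chrX: female betas pulled toward 0.5 (X-inactivation-like
    # intermediate methylation); autosomes untouched.
    is_x = (sites["chrom"] == "chrX").to_numpy()
    is_female = (sheet_df["sex"] == "F").to_numpy()
    if is_x.any() and config.sex_effect != 0.0:
        px = p[np.ix_(is_x, is_female)]
        p[np.ix_(is_x, is_female)] = px + config.sex_effect * (0.5 - px)

    # Counts: NB coverage, beta-binomial methylated reads.  Biological
    # (between-individual) deviation is drawn per CpG for background sites
    # but once per (region, sample) for planted regions — a region's
    # methylation shifts coherently within an individual, the only
    # within-sample CpG dependence in the model; read sampling stays
    # independent per CpG.
    nb_n = config.coverage_dispersion
    nb_p = nb_n / (nb_n + config.mean_coverage)
    total = rng.negative_binomial(nb_n, nb_p, size=(n_sites, n_samples))
    c = config.overdispersion
    pi = rng.beta(np.clip(p * c, 1e-6, None), np.clip((1.0 - p) * c, 1e-6, None))
    for reg in region_rows:
        lo, hi = reg["cpg_slice"]
        p_bar = p[lo:hi].mean(axis=0)
        u = rng.beta(np.clip(p_bar * c, 1e-6, None), np.clip((1.0 - p_bar) * c, 1e-6, None))
        pi[lo:hi] = np.clip(p[lo:hi] + (u - p_bar)[None, :], 0.001, 0.999)
    methylated = rng.binomial(total, pi)

    matrix = MethCountMatrix(
        sites=sites, samples=list(sheet_df["sample_id"]),
        methylated=methylated, total=total,
    )
    sheet = SampleSheet(sheet_df)

    def _truth_frame(kind: str) -> pd.DataFrame:
        rows = [
            {
                "chrom": r["chrom"],
                "start": r["start"],
                "end": r["end"],
                "direction": r["direction"],
                "delta_beta": r["delta_beta"],
            }
            for r in region_rows
            if r["kind"] == kind
        ]
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "direction", "delta_beta"])
        return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    truth = TruthSet(
        regions=_truth_frame("disease"),
        steroid_regions=_truth_frame("steroid"),
        covariates=sheet_df.copy(),
    )
    return matrix, sheet, truth


def write_fixture(
    matrix: MethCountMatrix,
    sheet: SampleSheet,
    truth: TruthSet,
    directory: str | Path,
    seed: int | None = None,
) -> dict:
    """Write a cohort fixture to disk and return a manifest of what was written.

    Layout: one methylation-call TSV per sample, ``sample_sheet.tsv``, and
    the planted truth as BED (half-open, 0-based on disk, converted from the
    internal 1-based inclusive convention).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    try:
        call_paths = write_meth_calls(matrix, directory / "calls")
        sheet_path = directory / "sample_sheet.tsv"
        write_sample_sheet(sheet, sheet_path)
        truth_path = directory / "truth_regions.bed"
        steroid_path = directory / "steroid_regions.bed"
        write_regions_bed(truth.regions, truth_path)
        write_regions_bed(truth.steroid_regions, steroid_path)
    except OSError as exc:
        raise OSError(f"cannot write fixture under {directory}: {exc}") from exc
    manifest = {
        "seed": seed,
        "samples": list(matrix.samples),
        "files": {
            "calls": [str(p) for p in call_paths],
            "sample_sheet": str(sheet_path),
            "truth_regions": str(truth_path),
            "steroid_regions": str(steroid_path),
        },
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
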