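"""Merge DMCs into regions and clean the region set.

Single-linkage chaining: consecutive DMCs no more than ``gap`` bp apart
(inclusive) on the same chromosome join one region whose span runs from the
first to the last member position (1-based inclusive).  Regions keep only
chains with at least ``min_dmcs`` members.  Confounder (steroid-associated)
regions detected without covariate adjustment are subtracted by any-base
overlap, and X-chromosome regions are censored from the final set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MethCountMatrix, SampleSheet, region_name
from .qc import BetaMatrix
from . import dmc as _dmc

REGION_COLUMNS = ["chrom", "start", "end", "n_dmcs", "direction", "label"]


@dataclass
class RegionSet:
    """Sorted genomic regions, 1-based inclusive, with DMC counts and direction."""

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df.copy()
        for col in REGION_COLUMNS:
            if col not in df.columns:
                df[col] = 0 if col == "n_dmcs" else "."
        df = df[REGION_COLUMNS]
        if len(df):
            if (df["start"] > df["end"]).any():
                raise ValueError("region with start > end")
            if df.duplicated(["chrom", "start", "end"]).any():
                raise ValueError("duplicate region coordinates")
            df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def names(self) -> list[str]:
        return [region_name(r.chrom, r.start, r.end) for r in self.df.itertuples()]

    def overlaps_any(self, chrom: str, start: int, end: int) -> bool:
        sub = self.df[self.df["chrom"] == chrom]
        return bool(((sub["start"] <= end) & (sub["end"] >= start)).any())


def merge_dmcs(dmcs: pd.DataFrame, gap: int = 100, min_dmcs: int = 6, label: str = "dmr") -> RegionSet:
    """Chain DMCs within ``gap`` bp (inclusive) and keep chains of >= ``min_dmcs``.

    Direction is the majority sign of member meth_diff; an exact tie falls
    back to the sign of the summed difference, and a zero sum is labeled
    "mixed".  Empty input yields an empty set.
    """
    if len(dmcs) == 0:
        return RegionSet(pd.DataFrame(columns=REGION_COLUMNS))
    d = dmcs.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    new_chain = (d["chrom"] != d["chrom"].shift()) | (
        d["pos"] - d["pos"].shift() > gap
    )
    chain_id = new_chain.cumsum()
    rows = []
    for _, grp in d.groupby(chain_id):
        if len(grp) < min_dmcs:
            continue
        n_hyper = int((grp["meth_diff"] > 0).sum())
        n_hypo = int((grp["meth_diff"] < 0).sum())
        if n_hyper > n_hypo:
            direction = "hyper"
        elif n_hypo > n_hyper:
            direction = "hypo"
        else:
            s = grp["meth_diff"].sum()
            direction = "hyper" if s > 0 else ("hypo" if s < 0 else "mixed")
        rows.append(
            {
                "chrom": grp["chrom"].iloc[0],
                "start": int(grp["pos"].min()),
                "end": int(grp["pos"].max()),
                "n_dmcs": len(grp),
                "direction": direction,
                "label": label,
            }
        )
    return RegionSet(pd.DataFrame(rows, columns=REGION_COLUMNS))


def call_confounder_regions(
    m: MethCountMatrix,
    sheet: SampleSheet,
    contrast_flag: str = "steroid",
    min_dmcs: int = 4,
    gap: int = 100,
    diff_cutoff: float = 10.0,
    q_cutoff: float = 0.05,
) -> RegionSet:
    """Regions differentially methylated with respect to a binary flag.

    Deliberately looser than the disease call: no covariate adjustment and a
    smaller minimum DMC count, to remove confounded regions comprehensively.
    A single-level flag yields an empty set with a warning.
    """
    sheet_df = sheet.df.set_index("sample_id").loc[list(m.samples)]
    flag = sheet_df[contrast_flag].to_numpy()
    if len(np.unique(flag)) < 2 or flag.sum() < 2 or len(flag) - flag.sum() < 2:
        warnings.warn(
            f"contrast flag {contrast_flag!r} lacks two usable levels; "
            "returning empty confounder set"
        )
        return RegionSet(pd.DataFrame(columns=REGION_COLUMNS))
    dmcs = _dmc.call_dmcs(
        m,
        sheet,
        covariates=(),
        diff_cutoff=diff_cutoff,
        q_cutoff=q_cutoff,
        group_col=contrast_flag,
    )
    return merge_dmcs(dmcs, gap=gap, min_dmcs=min_dmcs, label=contrast_flag)


def subtract_and_censor(
    candidates: RegionSet,
    exclusions: RegionSet,
    drop_chroms: set[str] = frozenset({"chrX"}),
) -> RegionSet:
    """Drop candidates overlapping any exclusion by >= 1 bp, then drop whole
    chromosomes (sex-chromosome censoring).  Order is preserved."""
    drop_chroms = set(drop_chroms)
    keep_rows = []
    excl_by_chrom = {
        chrom: grp[["start", "end"]].to_numpy()
        for chrom, grp in exclusions.df.groupby("chrom")
    }
    for row in candidates.df.itertuples(index=False):
        if row.chrom in drop_chroms:
            continue
        ivs = excl_by_chrom.get(row.chrom)
        if ivs is not None and ((ivs[:, 0] <= row.end) & (ivs[:, 1] >= row.start)).any():
            continue
        keep_rows.append(row._asdict())
    return RegionSet(pd.DataFrame(keep_rows, columns=REGION_COLUMNS))


def region_beta(b: BetaMatrix, regions: RegionSet) -> pd.DataFrame:
    """Region x sample matrix of unweighted mean member-CpG betas.

    Rows are region names ("chrom:start-end", 1-based inclusive); a region
    containing no covered CpG is an error naming the region.
    """
    chroms = b.sites["chrom"].to_numpy()
    pos = b.sites["pos"].to_numpy()
    out = {}
    for row in regions.df.itertuples(index=False):
        sel = (chroms == row.chrom) & (pos >= row.start) & (pos <= row.end)
        if not sel.any():
            raise ValueError(
                f"region {region_name(row.chrom, row.start, row.end)} contains no "
                "covered CpG"
            )
        out[region_name(row.chrom, row.start, row.end)] = b.beta[sel].mean(axis=0)
    df = pd.DataFrame(out, index=pd.Index(b.samples, name="sample_id")).T
    df.index.name = "region"
    return df
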