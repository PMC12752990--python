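"""Readers and writers for the on-disk formats the pipeline touches.

Internal coordinate convention: 1-based, inclusive on both ends, everywhere.
Only BED input/output converts (BED is 0-based, half-open).  Methylation-call
tables are per-sample TSVs with columns ``chrom, pos, strand, context,
methylated_count, total_count``; a sample sheet is a TSV with one row per
sample; gene annotations are BED6; term maps are two-column TSVs.
"""

from __future__ import annotations

import dataclasses
import io as _stdio
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING_TOTAL = 0  # total == 0 encodes "site not observed in this sample"

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "group",
    "age_years",
    "sex",
    "neutered",
    "breed",
    "steroid",
    "setting",
    "split",
]

GROUP_LEVELS = {"case", "control"}
SPLIT_LEVELS = {"train", "test", "unassigned"}
SEX_LEVELS = {"F", "M"}


class FormatError(ValueError):
    """A malformed on-disk record, reported with file and line context."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CpGSite:
    chrom: str
    pos: int  # 1-based
    strand: str = "+"

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"CpG position must be >= 1, got {self.pos}")
        if not self.chrom:
            raise ValueError("CpG chrom must be non-empty")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class MethCountMatrix:
    """CpG sites x samples paired (methylated, total) counts.

    ``sites`` is a DataFrame with columns chrom, pos, strand sorted by
    (chrom, pos) and free of duplicates.  ``total == 0`` marks a site not
    observed in that sample; it is never imputed.
    """

    sites: pd.DataFrame
    samples: list[str]
    methylated: np.ndarray
    total: np.ndarray

    def __post_init__(self):
        self.sites = self.sites.reset_index(drop=True)
        self.methylated = np.asarray(self.methylated, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        n_sites, n_samples = self.methylated.shape
        if self.total.shape != (n_sites, n_samples):
            raise ValueError("methylated and total shapes differ")
        if len(self.sites) != n_sites:
            raise ValueError("site table and count matrix row counts differ")
        if len(self.samples) != n_samples:
            raise ValueError("sample list and count matrix column counts differ")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if (self.methylated < 0).any() or (self.total < 0).any():
            raise ValueError("negative counts")
        if (self.methylated > self.total).any():
            i, j = np.argwhere(self.methylated > self.total)[0]
            site = self.sites.iloc[i]
            raise ValueError(
                f"methylated > total at {site.chrom}:{site.pos} "
                f"sample {self.samples[j]}"
            )
        key = self.sites[["chrom", "pos"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValueError(f"duplicate site {dup.chrom}:{dup.pos}")
        order = self.sites.sort_values(["chrom", "pos"], kind="mergesort").index
        if not (order.values == np.arange(len(order))).all():
            raise ValueError("sites must be sorted by (chrom, pos)")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethCountMatrix":
        """Return a matrix restricted to ``sample_ids`` (column order follows the argument)."""
        idx = [self.samples.index(s) for s in sample_ids]
        return MethCountMatrix(
            sites=self.sites.copy(),
            samples=list(sample_ids),
            methylated=self.methylated[:, idx].copy(),
            total=self.total[:, idx].copy(),
        )

    def subset_sites(self, mask: np.ndarray) -> "MethCountMatrix":
        mask = np.asarray(mask, dtype=bool)
        return MethCountMatrix(
            sites=self.sites.loc[mask].reset_index(drop=True),
            samples=list(self.samples),
            methylated=self.methylated[mask],
            total=self.total[mask],
        )

    def equals(self, other: "MethCountMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.sites.reset_index(drop=True).equals(other.sites.reset_index(drop=True))
            and np.array_equal(self.methylated, other.methylated)
            and np.array_equal(self.total, other.total)
        )


class SampleSheet:
    """Validated per-sample labels and covariates."""

    def __init__(self, df: pd.DataFrame):
        self.df = _validate_sheet(df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    def ids_for_split(self, split: str) -> list[str]:
        return list(self.df.loc[self.df["split"] == split, "sample_id"])

    @property
    def train_ids(self) -> list[str]:
        return self.ids_for_split("train")

    @property
    def test_ids(self) -> list[str]:
        return self.ids_for_split("test")

    def groups_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        lookup = self.df.set_index("sample_id")["group"]
        return lookup.loc[list(sample_ids)].to_numpy()

    def subset(self, sample_ids: Sequence[str]) -> "SampleSheet":
        df = self.df.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleSheet(df)

    def copy(self) -> "SampleSheet":
        return SampleSheet(self.df.copy())

    def __len__(self) -> int:
        return len(self.df)


def _validate_sheet(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns and c != "split"]
    if missing:
        raise FormatError(f"sample sheet missing columns: {missing}")
    if "split" not in df.columns:
        df["split"] = "unassigned"
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample id {dup!r}")
    # categorical levels normalized case-insensitively
    df["group"] = df["group"].astype(str).str.strip().str.lower()
    bad = ~df["group"].isin(GROUP_LEVELS)
    if bad.any():
        row = df.loc[bad].iloc[0]
        raise FormatError(
            f"unknown group {row['group']!r} for sample {row['sample_id']!r}"
        )
    df["split"] = df["split"].astype(str).str.strip().str.lower()
    bad = ~df["split"].isin(SPLIT_LEVELS)
    if bad.any():
        row = df.loc[bad].iloc[0]
        raise FormatError(
            f"unknown split {row['split']!r} for sample {row['sample_id']!r}"
        )
    df["sex"] = df["sex"].astype(str).str.strip().str.upper()
    bad = ~df["sex"].isin(SEX_LEVELS)
    if bad.any():
        row = df.loc[bad].iloc[0]
        raise FormatError(f"unknown sex {row['sex']!r} for sample {row['sample_id']!r}")
    ages = pd.to_numeric(df["age_years"], errors="coerce")
    if ages.isna().any():
        row = df.loc[ages.isna()].iloc[0]
        raise FormatError(
            f"non-numeric age {row['age_years']!r} for sample {row['sample_id']!r}"
        )
    df["age_years"] = ages.astype(float)
    for flag in ("neutered", "steroid"):
        vals = pd.to_numeric(df[flag], errors="coerce")
        if vals.isna().any() or not vals.isin([0, 1]).all():
            row = df.loc[~vals.isin([0, 1]) | vals.isna()].iloc[0]
            raise FormatError(
                f"{flag} must be 0/1, got {row[flag]!r} for sample {row['sample_id']!r}"
            )
        df[flag] = vals.astype(int)
    df["breed"] = df["breed"].astype(str).str.strip()
    df["setting"] = df["setting"].astype(str).str.strip()
    return df[SAMPLE_SHEET_COLUMNS].reset_index(drop=True)


@dataclass
class GeneAnnotation:
    """Gene intervals, 1-based inclusive internally, unique gene ids."""

    df: pd.DataFrame  # columns chrom, start, end, gene_id, strand

    def __post_init__(self):
        df = self.df
        if (df["start"] > df["end"]).any():
            raise ValueError("gene with start > end")
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id {dup!r}")
        self.df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
            drop=True
        )


# ---------------------------------------------------------------------------
# methylation-call tables
# ---------------------------------------------------------------------------

METH_CALL_COLUMNS = ["chrom", "pos", "strand", "context", "methylated_count", "total_count"]


def write_meth_calls(matrix: MethCountMatrix, directory: str | Path) -> list[Path]:
    """Write one methylation-call TSV per sample; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for j, sample in enumerate(matrix.samples):
        observed = matrix.total[:, j] > 0
        df = pd.DataFrame(
            {
                "chrom": matrix.sites["chrom"][observed],
                "pos": matrix.sites["pos"][observed],
                "strand": matrix.sites["strand"][observed],
                "context": "CpG",
                "methylated_count": matrix.methylated[observed, j],
                "total_count": matrix.total[observed, j],
            }
        )
        path = directory / f"{sample}.meth.tsv"
        df.to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths


def _read_one_meth_file(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    except Exception as exc:  # surface path and cause
        raise FormatError(f"{path}: cannot parse methylation calls: {exc}") from exc
    missing = [c for c in METH_CALL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for col in ("pos", "methylated_count", "total_count"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(vals.index[vals.isna()][0]) + 2  # header is line 1
            raise FormatError(f"{path}:{line}: non-numeric {col}")
        df[col] = vals.astype(np.int64)
    bad = df["methylated_count"] > df["total_count"]
    if bad.any():
        row = df.loc[bad].iloc[0]
        line = int(df.index[bad][0]) + 2
        raise FormatError(
            f"{path}:{line}: methylated_count {row.methylated_count} > "
            f"total_count {row.total_count} at {row.chrom}:{row.pos}"
        )
    if (df["pos"] < 1).any():
        line = int(df.index[df["pos"] < 1][0]) + 2
        raise FormatError(f"{path}:{line}: position < 1")
    return df


def read_meth_calls(
    paths: Sequence[str | Path],
    sample_ids: Sequence[str],
    destrand: bool = True,
) -> MethCountMatrix:
    """Read per-sample call TSVs into one matrix over the union of sites.

    Sites absent from a sample get total = 0 in that sample's column.  With
    ``destrand`` (default), a minus-strand call is collapsed onto the plus
    strand of its CpG dyad (position - 1) and counts at the same collapsed
    position are summed; symmetric CpG methylation makes the two strands
    redundant.
    """
    if len(paths) != len(sample_ids):
        raise ValueError("one path per sample id required")
    frames = []
    for path, sample in zip(paths, sample_ids):
        df = _read_one_meth_file(path)
        if destrand:
            minus = df["strand"] == "-"
            df.loc[minus, "pos"] = df.loc[minus, "pos"] - 1
            df["strand"] = "+"
            if (df["pos"] < 1).any():
                raise FormatError(f"{path}: destranding produced position < 1")
            df = (
                df.groupby(["chrom", "pos", "strand"], as_index=False)[
                    ["methylated_count", "total_count"]
                ].sum()
            )
        df["sample"] = sample
        frames.append(df[["chrom", "pos", "strand", "methylated_count", "total_count", "sample"]])
    tall = pd.concat(frames, ignore_index=True)
    meth = tall.pivot_table(
        index=["chrom", "pos", "strand"], columns="sample", values="methylated_count",
        fill_value=0, aggfunc="first",
    )
    tot = tall.pivot_table(
        index=["chrom", "pos", "strand"], columns="sample", values="total_count",
        fill_value=0, aggfunc="first",
    )
    meth = meth[list(sample_ids)].sort_index()
    tot = tot[list(sample_ids)].sort_index()
    sites = meth.index.to_frame(index=False)
    sites = sites.rename(columns={0: "chrom", 1: "pos", 2: "strand"})
    return MethCountMatrix(
        sites=sites[["chrom", "pos", "strand"]],
        samples=list(sample_ids),
        methylated=meth.to_numpy(dtype=np.int64),
        total=tot.to_numpy(dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------


def read_sample_sheet(path: str | Path) -> SampleSheet:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse sample sheet: {exc}") from exc
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# regions / BED
# ---------------------------------------------------------------------------


def region_name(chrom: str, start: int, end: int) -> str:
    """Report-layer region id, 1-based inclusive, e.g. ``chr6:15948237-15948396``."""
    return f"{chrom}:{start}-{end}"


def write_regions_bed(regions: "pd.DataFrame | object", path: str | Path) -> None:
    """Write a region table to BED (0-based half-open on disk).

    Accepts a RegionSet-like object with a ``df`` attribute or a DataFrame
    with columns chrom, start, end (1-based inclusive) and optionally
    n_dmcs, direction, label.  The BED name field carries direction and DMC
    count; score carries delta-beta in mille when a ``delta_beta`` column is
    present, else the DMC count.  Overlapping regions are written as-is.
    """
    df = getattr(regions, "df", regions)
    path = Path(path)
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            start0 = int(row.start) - 1
            end0 = int(row.end)
            direction = getattr(row, "direction", ".")
            n_dmcs = getattr(row, "n_dmcs", 0)
            name = f"{direction}|n_dmcs={n_dmcs}"
            if hasattr(row, "delta_beta"):
                score = int(round(float(row.delta_beta) * 1000))
            else:
                score = int(n_dmcs)
            fh.write(f"{row.chrom}\t{start0}\t{end0}\t{name}\t{score}\t.\n")


def read_regions_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file into a 1-based inclusive region table."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            direction, n_dmcs = ".", 0
            if "|" in name:
                direction, _, rest = name.partition("|")
                if rest.startswith("n_dmcs="):
                    n_dmcs = int(rest[len("n_dmcs="):])
            rows.append(
                {
                    "chrom": chrom,
                    "start": start0 + 1,
                    "end": end0,
                    "n_dmcs": n_dmcs,
                    "direction": direction,
                }
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_dmcs", "direction"])
    return df


def read_gene_bed(path: str | Path) -> GeneAnnotation:
    """Read a BED6 gene annotation into 1-based inclusive coordinates."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: BED6 requires 6 fields")
            rows.append(
                {
                    "chrom": parts[0],
                    "start": int(parts[1]) + 1,
                    "end": int(parts[2]),
                    "gene_id": parts[3],
                    "strand": parts[5],
                }
            )
    return GeneAnnotation(pd.DataFrame(rows))


def read_term_map(path: str | Path) -> pd.DataFrame:
    """Two-column gene_id -> term_id TSV (GAF-style flat map)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term_id"], dtype=str)
    if df.isna().any().any():
        raise FormatError(f"{path}: term map rows must have two fields")
    return df
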