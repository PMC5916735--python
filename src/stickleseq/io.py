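"""Readers, writers and the internal data model for annotations and counts.

All genomic coordinates are 0-based, half-open (BED convention).  GFF3
input (1-based, closed) is converted on read.  Strand is parsed when
present but ignored by every statistic in the package: the distance and
overlap procedures downstream are strand-blind.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class InputError(ValueError):
    """Malformed or inconsistent user input (file contents, group maps...)."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneAnnotation:
    """Per-gene chromosome, interval and id; sorted by (chromosome, start).

    ``df`` has columns ``chrom``, ``start``, ``end``, ``gene_id`` and,
    optionally, ``strand``.  Intervals may overlap: clustering statistics
    use midpoints only, so exclusive gene bodies are not required.
    """

    df: pd.DataFrame = field(repr=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneAnnotation":
        required = ["chrom", "start", "end", "gene_id"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise InputError(f"annotation frame lacks columns {missing}")
        df = df.copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["chrom"] = df["chrom"].astype(str)
        df["gene_id"] = df["gene_id"].astype(str)
        if (df["start"] < 0).any():
            raise InputError("negative start coordinate in annotation")
        if (df["start"] >= df["end"]).any():
            bad = df.loc[df["start"] >= df["end"], "gene_id"].iloc[0]
            raise InputError(f"start >= end for gene {bad!r}")
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise InputError(f"duplicate gene id {dup!r}")
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        return cls(df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def gene_ids(self) -> pd.Series:
        return self.df["gene_id"]

    @property
    def midpoints(self) -> pd.Series:
        """Integer midpoint floor((start + end) / 2) of each gene."""
        return (self.df["start"] + self.df["end"]) // 2

    @property
    def chromosomes(self) -> list[str]:
        # preserve order of first appearance (file order after sorting)
        return list(dict.fromkeys(self.df["chrom"]))

    def genes_on(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]

    def midpoints_on(self, chrom: str) -> np.ndarray:
        sub = self.genes_on(chrom)
        return ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2)

    def to_bed(self, path: str | Path) -> None:
        write_bed(self, path)


@dataclass
class CountMatrix:
    """Integer read counts (genes x samples) with a two-group design.

    ``library_size`` defaults to per-sample column sums but can be
    overridden with externally known mapped-read totals, which is the
    denominator CPM should use when the matrix covers only annotated
    genes rather than every mapped read.
    """

    counts: pd.DataFrame                    # genes x samples, integers
    group: pd.Series                        # sample -> group label (2 levels)
    library_size: pd.Series | None = None   # sample -> reads; None = colsums

    def __post_init__(self) -> None:
        counts = self.counts
        vals = counts.to_numpy()
        if np.issubdtype(vals.dtype, np.floating):
            if not np.all(np.isfinite(vals)) or np.any(vals != np.round(vals)):
                bad = np.argwhere((vals != np.round(vals)) | ~np.isfinite(vals))[0]
                raise InputError(
                    f"non-integer count for gene {counts.index[bad[0]]!r}, "
                    f"sample {counts.columns[bad[1]]!r}"
                )
            counts = counts.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise InputError("negative counts")
        self.counts = counts
        self.group = self.group.reindex(counts.columns)
        if self.group.isna().any():
            missing = list(self.group.index[self.group.isna()])
            raise InputError(f"samples without a group assignment: {missing}")
        levels = sorted(self.group.unique())
        if len(levels) != 2:
            raise InputError(f"two groups required, got {levels}")
        if self.library_size is None:
            self.library_size = counts.sum(axis=0).astype(float)
        else:
            self.library_size = self.library_size.reindex(counts.columns).astype(float)
            if self.library_size.isna().any() or (self.library_size <= 0).any():
                raise InputError("library sizes must be positive for every sample")
        if (self.library_size <= 0).any():
            raise InputError("library sizes must be positive (empty sample?)")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def group_levels(self) -> tuple[str, str]:
        levels = sorted(self.group.unique())
        return levels[0], levels[1]

    def samples_in(self, level: str) -> pd.Index:
        return self.group.index[self.group == level]


# ---------------------------------------------------------------------------
# BED / GFF3
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> GeneAnnotation:
    """Read a 3-6 column BED file into a :class:`GeneAnnotation`.

    ``browser``/``track`` headers and ``#`` comment lines are skipped.
    With only three columns, gene ids are auto-generated as
    ``chrom:start-end``.  Errors report the offending line number.
    """
    records = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("browser", "track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}: line {lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise InputError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if start < 0:
                raise InputError(f"{path}: line {lineno}: negative coordinate {start}")
            if start >= end:
                raise InputError(f"{path}: line {lineno}: start {start} >= end {end}")
            name = fields[3] if len(fields) >= 4 and fields[3] not in ("", ".") else f"{chrom}:{start}-{end}"
            if name in seen:
                raise InputError(f"{path}: line {lineno}: duplicate gene id {name!r}")
            seen.add(name)
            strand = fields[5] if len(fields) >= 6 else "."
            records.append((chrom, start, end, name, strand))
    df = pd.DataFrame(records, columns=["chrom", "start", "end", "gene_id", "strand"])
    return GeneAnnotation.from_frame(df)


def read_gff3_genes(path: str | Path) -> GeneAnnotation:
    """Read ``gene`` features from a GFF3 file (1-based closed -> 0-based half-open)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                continue
            if fields[2] != "gene":
                continue
            chrom = fields[0]
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise InputError(f"{path}: line {lineno}: non-integer coordinate") from exc
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            name = attrs.get("ID") or attrs.get("gene_id") or f"{chrom}:{start1 - 1}-{end1}"
            records.append((chrom, start1 - 1, end1, name, fields[6]))
    df = pd.DataFrame(records, columns=["chrom", "start", "end", "gene_id", "strand"])
    return GeneAnnotation.from_frame(df)


def write_bed(annotation: GeneAnnotation, path: str | Path) -> None:
    cols = annotation.df[["chrom", "start", "end", "gene_id"]]
    cols.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def read_counts(
    path: str | Path,
    group_map: Mapping[str, str],
    library_sizes: Mapping[str, float] | None = None,
) -> CountMatrix:
    """Read a TSV count matrix (first column gene id, header row sample ids).

    ``group_map`` must assign every sample to one of exactly two groups;
    each group needs at least two samples (replicates) for downstream
    dispersion estimation.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise InputError(f"{path}: no sample columns")
    missing = [s for s in df.columns if s not in group_map]
    if missing:
        raise InputError(f"samples missing from group map: {missing}")
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        coerced = df.apply(pd.to_numeric, errors="coerce")
        if coerced.isna().any().any():
            gi, si = np.argwhere(coerced.isna().to_numpy())[0]
            raise InputError(
                f"non-numeric count for gene {df.index[gi]!r}, sample {df.columns[si]!r}"
            )
        df, vals = coerced, coerced.to_numpy()
    frac = vals != np.floor(vals)
    if frac.any():
        gi, si = np.argwhere(frac)[0]
        raise InputError(
            f"non-integer count {vals[gi, si]} for gene {df.index[gi]!r}, "
            f"sample {df.columns[si]!r}"
        )
    group = pd.Series({s: group_map[s] for s in df.columns})
    levels = sorted(group.unique())
    if len(levels) != 2:
        raise InputError(f"two groups required, got {levels}")
    sizes = group.value_counts()
    if (sizes < 2).any():
        small = list(sizes.index[sizes < 2])
        raise InputError(f"fewer than 2 samples in group(s) {small}")
    lib = None
    if library_sizes is not None:
        lib = pd.Series({s: float(library_sizes[s]) for s in df.columns})
    return CountMatrix(df.astype(np.int64), group, lib)


def read_group_file(path: str | Path) -> dict[str, str]:
    """Read ``sample<TAB>group`` (or ``sample=group``) pairs, one per line."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" in line and "\t" not in line:
                sample, grp = line.split("=", 1)
            else:
                parts = line.split("\t")
                if len(parts) != 2:
                    raise InputError(f"{path}: line {lineno}: expected 'sample<TAB>group'")
                sample, grp = parts
            out[sample.strip()] = grp.strip()
    return out


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

_SCI_COLS = {"pvalue", "fdr", "perm_pvalue", "alt_pvalue"}


def _format_cell(col: str, x) -> str:
    if pd.isna(x):
        return "NA"
    if col in _SCI_COLS:
        return f"{x:.6e}"
    if isinstance(x, (float, np.floating)):
        return f"{x:.6f}"
    return str(x)


def write_results(table: pd.DataFrame, path: str | Path, columns: Iterable[str] | None = None) -> None:
    """Write a result table as TSV; P-value-like columns in 6-figure scientific notation."""
    if columns is not None:
        table = table[list(columns)]
    out = pd.DataFrame(
        {c: [_format_cell(c, x) for x in table[c]] for c in table.columns}
    )
    out.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Re-read a result TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def read_de_gene_ids(path: str | Path, fdr: float | None = None) -> set[str]:
    """Load DE gene ids from a plain id list or a DE result table.

    A table is recognised by its ``gene_id`` column; ``fdr`` re-thresholds
    the table, otherwise the stored ``is_de`` flag is used.
    """
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first and "gene_id" in first.split("\t"):
        df = read_results(path)
        if fdr is not None:
            return set(df.loc[df["fdr"] < fdr, "gene_id"])
        if "is_de" in df.columns:
            return set(df.loc[df["is_de"].astype(str).isin(["True", "true", "1"]), "gene_id"])
        raise InputError(f"{path}: no is_de column and no --fdr given")
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}
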