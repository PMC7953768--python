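"""Readers, writers and the data model for strand-resolved CpG methylation.

A CpG site is keyed by the 1-based coordinate of its forward-strand C; the
palindromic reverse-strand C sits at ``pos + 1``.  Per sample the model keeps
four read counts per site (methylated/total on each strand); methylation
levels are always derived as ``meth/total`` downstream.

The canonical on-disk dialect is a five-column TSV per sample::

    chrom<TAB>pos<TAB>strand<TAB>meth<TAB>total

where ``pos`` is the 1-based C position on the named strand and comment
lines start with ``#``.  An adapter for Bismark-style coverage files (one
file per strand) is also provided.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Cohort",
    "GeneModel",
    "FormatError",
    "read_stranded_table",
    "write_stranded_table",
    "read_bismark_coverage",
    "coverage_filter",
    "read_gene_models",
]

_SAMPLE_COLUMNS = ["fwd_meth", "fwd_total", "rev_meth", "rev_total"]


class FormatError(ValueError):
    """A parse error in an input file, carrying the offending line number."""


@dataclass
class Cohort:
    """A cohort of paired samples with aligned per-site count matrices.

    The four count arrays are shaped ``(n_sites, n_samples)`` and share row
    order with ``sites`` (sorted by chrom, pos) and column order with
    ``sample_ids``.  Tumor and normal cohorts of one study must share the
    sample ordering: the design is paired.
    """

    label: str
    sample_ids: list[str]
    sites: pd.DataFrame  # columns chrom, pos; sorted
    fwd_meth: np.ndarray = field(repr=False)
    fwd_total: np.ndarray = field(repr=False)
    rev_meth: np.ndarray = field(repr=False)
    rev_total: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not self.sample_ids:
            raise ValueError("sample_ids must be nonempty")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be duplicate-free")
        shape = (len(self.sites), len(self.sample_ids))
        for name in _SAMPLE_COLUMNS:
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if np.any(self.fwd_meth > self.fwd_total) or np.any(self.rev_meth > self.rev_total):
            raise ValueError("methylated counts exceed totals")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_sample_tables(cls, label: str, tables: dict[str, pd.DataFrame]) -> "Cohort":
        """Assemble a cohort from per-sample tables keyed by sample id.

        Each table has columns chrom, pos plus the four count columns, one
        row per site; sites missing from a sample get zero counts.
        """
        if not tables:
            raise ValueError("at least one sample table is required")
        sample_ids = list(tables)
        all_sites = (
            pd.concat([t[["chrom", "pos"]] for t in tables.values()])
            .drop_duplicates()
            .sort_values(["chrom", "pos"], kind="mergesort")
            .reset_index(drop=True)
        )
        index = pd.MultiIndex.from_frame(all_sites)
        mats = {name: np.zeros((len(all_sites), len(sample_ids)), dtype=np.int64) for name in _SAMPLE_COLUMNS}
        for j, sid in enumerate(sample_ids):
            t = tables[sid].set_index(["chrom", "pos"])
            locs = index.get_indexer(t.index)
            for name in _SAMPLE_COLUMNS:
                mats[name][locs, j] = t[name].to_numpy()
        return cls(label, sample_ids, all_sites, **mats)


def _merge_strand_rows(rows: pd.DataFrame) -> pd.DataFrame:
    """Merge per-strand rows into one record per CpG forward-C position.

    Forward rows keep their position; a reverse-strand row at ``pos``
    belongs to the CpG whose forward C is at ``pos - 1``.
    """
    fwd = rows[rows["strand"] == "+"].copy()
    rev = rows[rows["strand"] == "-"].copy()
    fwd = fwd.rename(columns={"meth": "fwd_meth", "total": "fwd_total"})[
        ["chrom", "pos", "fwd_meth", "fwd_total"]
    ]
    rev["pos"] = rev["pos"] - 1
    rev = rev.rename(columns={"meth": "rev_meth", "total": "rev_total"})[
        ["chrom", "pos", "rev_meth", "rev_total"]
    ]
    merged = fwd.merge(rev, on=["chrom", "pos"], how="outer")
    for col in _SAMPLE_COLUMNS:
        if col not in merged:
            merged[col] = 0
    merged[_SAMPLE_COLUMNS] = (
        merged[_SAMPLE_COLUMNS].astype("float64").fillna(0.0).astype(np.int64)
    )
    return merged.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def read_stranded_table(path, sample_id: str | None = None) -> pd.DataFrame:
    """Read one sample's canonical stranded methylation TSV.

    Returns a per-sample table (chrom, pos, fwd_meth, fwd_total, rev_meth,
    rev_total) with the two strands of each CpG merged by the ``pos + 1``
    convention.  Malformed rows raise :class:`FormatError` naming the line.
    """
    path = Path(path)
    records: list[tuple[str, int, str, int, int]] = []
    seen: set[tuple[str, int, str]] = set()
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[:3] == ["chrom", "pos", "strand"]:
                continue
            if len(parts) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 tab-separated fields, got {len(parts)}")
            chrom, pos_s, strand, meth_s, total_s = parts
            try:
                pos, meth, total = int(pos_s), int(meth_s), int(total_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field ({exc})") from None
            if strand not in "+-" or len(strand) != 1:
                raise FormatError(f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}")
            if pos < 1:
                raise FormatError(f"{path}:{lineno}: pos must be >= 1")
            if not 0 <= meth <= total:
                raise FormatError(f"{path}:{lineno}: meth={meth} outside [0, total={total}]")
            key = (chrom, pos, strand)
            if key in seen:
                raise FormatError(f"{path}:{lineno}: duplicate record for {key}")
            seen.add(key)
            records.append((chrom, pos, strand, meth, total))
    rows = pd.DataFrame(records, columns=["chrom", "pos", "strand", "meth", "total"])
    if rows.empty:
        return pd.DataFrame(columns=["chrom", "pos", *_SAMPLE_COLUMNS])
    return _merge_strand_rows(rows)


def write_stranded_table(table: pd.DataFrame, path) -> None:
    """Write a per-sample table back to the canonical TSV dialect.

    Strand rows with zero total reads are omitted; they are reconstructed
    as zero counts on re-read.
    """
    out: list[tuple[str, int, str, int, int]] = []
    for row in table.itertuples(index=False):
        if row.fwd_total > 0:
            out.append((row.chrom, row.pos, "+", row.fwd_meth, row.fwd_total))
        if row.rev_total > 0:
            out.append((row.chrom, row.pos + 1, "-", row.rev_meth, row.rev_total))
    frame = pd.DataFrame(out, columns=["chrom", "pos", "strand", "meth", "total"])
    frame.to_csv(path, sep="\t", index=False)


def read_bismark_coverage(fwd_path, rev_path, sample_id: str | None = None) -> pd.DataFrame:
    """Adapter for Bismark-style coverage files, one file per strand.

    Layout: chrom, start, end, methylation percent, count_meth,
    count_unmeth.  Counts are authoritative; a percent column inconsistent
    with the counts by more than 0.5 only triggers a warning.
    """
    names = ["chrom", "pos", "end", "percent", "count_meth", "count_unmeth"]

    def _one(path, strand):
        try:
            raw = pd.read_csv(path, sep="\t", names=names, comment="#", header=None)
        except pd.errors.EmptyDataError:
            raw = pd.DataFrame(columns=names)
        if raw.empty:
            return pd.DataFrame(columns=["chrom", "pos", "strand", "meth", "total"])
        total = raw["count_meth"] + raw["count_unmeth"]
        with np.errstate(invalid="ignore", divide="ignore"):
            implied = 100.0 * raw["count_meth"] / total.replace(0, np.nan)
        bad = (implied - raw["percent"]).abs() > 0.5
        if bad.any():
            warnings.warn(
                f"{path}: {int(bad.sum())} rows with percent inconsistent with counts; counts win",
                stacklevel=2,
            )
        return pd.DataFrame(
            {
                "chrom": raw["chrom"],
                "pos": raw["pos"].astype(np.int64),
                "strand": strand,
                "meth": raw["count_meth"].astype(np.int64),
                "total": total.astype(np.int64),
            }
        )

    rows = pd.concat([_one(fwd_path, "+"), _one(rev_path, "-")], ignore_index=True)
    if rows.empty:
        return pd.DataFrame(columns=["chrom", "pos", *_SAMPLE_COLUMNS])
    return _merge_strand_rows(rows)


def coverage_filter(cohort: Cohort, min_reads: int = 4, pooled: bool = False) -> np.ndarray:
    """Per-site, per-sample informativeness mask.

    A sample is informative at a site iff both strands carry at least
    ``min_reads`` reads there.  ``pooled=True`` instead compares the
    cohort-pooled per-strand totals, broadcasting one decision per site.
    """
    if pooled:
        ok = (cohort.fwd_total.sum(axis=1) >= min_reads) & (
            cohort.rev_total.sum(axis=1) >= min_reads
        )
        return np.repeat(ok[:, None], cohort.n_samples, axis=1)
    return (cohort.fwd_total >= min_reads) & (cohort.rev_total >= min_reads)


@dataclass(frozen=True)
class GeneModel:
    """One gene's body span and derived strand-aware promoter window.

    Coordinates are 1-based inclusive.  An empty promoter (upstream and
    downstream extents both zero) is encoded as ``promoter_end <
    promoter_start``.
    """

    gene_name: str
    chrom: str
    strand: str
    start: int
    end: int
    tss: int
    promoter_start: int
    promoter_end: int

    @property
    def has_promoter(self) -> bool:
        return self.promoter_end >= self.promoter_start


def _promoter(strand: str, tss: int, upstream: int, downstream: int) -> tuple[int, int]:
    if upstream == 0 and downstream == 0:
        return (1, 0)
    if strand == "+":
        lo, hi = tss - upstream, tss - 1 + downstream
    else:
        lo, hi = tss + 1 - downstream, tss + upstream
    lo = max(1, lo)
    return (lo, hi) if hi >= lo else (1, 0)


_GTF_NAME_RE = re.compile(r'gene_name "([^"]+)"')
_GTF_ID_RE = re.compile(r'gene_id "([^"]+)"')


def read_gene_models(
    path,
    format: str | None = None,
    promoter_upstream: int = 2000,
    promoter_downstream: int = 0,
) -> list[GeneModel]:
    """Load gene models from BED6 or GTF and derive promoter windows.

    BED is 0-based half-open, GTF 1-based inclusive; everything is
    normalized to 1-based inclusive internally.  The promoter covers
    ``promoter_upstream`` bp upstream of the TSS plus
    ``promoter_downstream`` bp downstream, strand-aware and clipped at
    position 1.  Records with an unknown strand symbol are skipped with a
    warning.
    """
    path = Path(path)
    if format is None:
        format = "GTF" if path.suffix.lower() in {".gtf", ".gff"} else "BED"
    format = format.upper()
    models: list[GeneModel] = []
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if format == "BED":
                if len(parts) < 6:
                    raise FormatError(f"{path}:{lineno}: BED6 requires 6 columns")
                chrom, start0, end0, name, _score, strand = parts[:6]
                start, end = int(start0) + 1, int(end0)
            elif format == "GTF":
                if len(parts) < 9:
                    raise FormatError(f"{path}:{lineno}: GTF requires 9 columns")
                chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = parts[:9]
                if feature != "gene":
                    continue
                start, end = int(start_s), int(end_s)
                m = _GTF_NAME_RE.search(attrs) or _GTF_ID_RE.search(attrs)
                if m is None:
                    raise FormatError(f"{path}:{lineno}: no gene_name/gene_id attribute")
                name = m.group(1)
            else:
                raise ValueError(f"unknown gene model format {format!r}")
            if strand not in {"+", "-"}:
                warnings.warn(f"{path}:{lineno}: unknown strand {strand!r}, record skipped", stacklevel=2)
                continue
            if start > end:
                raise FormatError(f"{path}:{lineno}: start > end")
            tss = start if strand == "+" else end
            p_lo, p_hi = _promoter(strand, tss, promoter_upstream, promoter_downstream)
            models.append(GeneModel(name, chrom, strand, start, end, tss, p_lo, p_hi))
    return models
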