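"""Genomic regions and read counting.

Query loci come from BED6+ files (tab-separated, 0-based half-open
coordinates).  ChIP-seq signal is quantified from coordinate-sorted,
indexed BAM files: a mapped read contributes to every locus (and, in
windowed mode, every window) that its aligned reference span overlaps by
at least one base.  Row order of every downstream matrix follows the BED
file, so :class:`RegionSet` preserves input order exactly.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "CountMatrix",
    "read_regions",
    "count_reads",
    "build_count_matrix",
    "windowed_counts",
]

_SKIP_PREFIXES = ("#", "track", "browser")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with a locus identifier."""

    chrom: str
    start: int
    end: int
    name: str
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class RegionSet:
    """Ordered collection of loci; defines the row space of the signal matrix."""

    intervals: list[GenomicInterval]
    source_path: str = "<memory>"

    def __post_init__(self) -> None:
        # duplicate names are disambiguated by suffixing, preserving order
        seen: dict[str, int] = {}
        fixed: list[GenomicInterval] = []
        for iv in self.intervals:
            n = seen.get(iv.name, 0)
            seen[iv.name] = n + 1
            if n:
                iv = GenomicInterval(
                    iv.chrom, iv.start, iv.end, f"{iv.name}_{n + 1}", iv.score, iv.strand
                )
            fixed.append(iv)
        self.intervals = fixed

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    @property
    def names(self) -> list[str]:
        return [iv.name for iv in self.intervals]


@dataclass
class CountMatrix:
    """Loci x marks matrix of non-negative integer read counts."""

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("count matrix must be 2-dimensional")
        if np.any(self.values < 0):
            raise ValueError("negative counts")
        if len(self.row_ids) != self.values.shape[0]:
            raise ValueError("row_ids length mismatch")
        if len(self.col_ids) != self.values.shape[1]:
            raise ValueError("col_ids length mismatch")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise ValueError(f"duplicate mark labels: {self.col_ids}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="locus")


def read_regions(path: str | os.PathLike) -> RegionSet:
    """Parse a BED6+ file into a :class:`RegionSet`.

    Three-column records are accepted and receive generated names
    ``locus_<i>`` (1-based).  Track/browser/comment lines are skipped.
    Records whose coordinates do not satisfy ``start < end`` are rejected
    with a warning naming the line number; an input yielding no valid
    interval is an error.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().lower().startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                warnings.warn(
                    f"{path} line {lineno}: fewer than 3 columns, skipped"
                )
                continue
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                warnings.warn(
                    f"{path} line {lineno}: non-integer coordinates, skipped"
                )
                continue
            if not (0 <= start < end):
                warnings.warn(
                    f"{path} line {lineno}: malformed coordinates "
                    f"start={start} end={end} (need 0 <= start < end), skipped"
                )
                continue
            name = fields[3] if len(fields) > 3 and fields[3] else f"locus_{len(intervals) + 1}"
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            intervals.append(GenomicInterval(chrom, start, end, name, score, strand))
    if not intervals:
        raise ValueError(f"no valid BED intervals in {path}")
    return RegionSet(intervals, source_path=str(path))


def _open_indexed(bam: str | os.PathLike) -> pysam.AlignmentFile:
    handle = pysam.AlignmentFile(str(bam), "rb")
    if not handle.has_index():
        handle.close()
        try:
            pysam.index(str(bam))
        except Exception as exc:  # pragma: no cover - depends on filesystem
            raise OSError(f"{bam}: no index and indexing failed: {exc}") from exc
        handle = pysam.AlignmentFile(str(bam), "rb")
    return handle


def _keep_read(read: pysam.AlignedSegment, filter_dup: bool, min_mapq: int) -> bool:
    if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_qcfail:
        return False
    if filter_dup and read.is_duplicate:
        return False
    if min_mapq and read.mapping_quality < min_mapq:
        return False
    return True


def count_reads(
    bam: str | os.PathLike,
    regions: RegionSet,
    *,
    filter_dup: bool = False,
    min_mapq: int = 0,
) -> np.ndarray:
    """Count mapped reads overlapping each locus by >= 1 reference base.

    Unmapped, secondary, supplementary and QC-fail records are excluded;
    duplicates are kept unless ``filter_dup``.  Overlap is evaluated on
    the aligned reference span, strand-blind.  A read overlapping several
    loci contributes to each of them.  Loci on chromosomes absent from
    the BAM header count 0 (with a warning).
    """
    counts = np.zeros(len(regions), dtype=np.int64)
    with _open_indexed(bam) as handle:
        refs = set(handle.references)
        missing: set[str] = set()
        for i, iv in enumerate(regions):
            if iv.chrom not in refs:
                missing.add(iv.chrom)
                continue
            counts[i] = sum(
                1
                for read in handle.fetch(iv.chrom, iv.start, iv.end)
                if _keep_read(read, filter_dup, min_mapq)
            )
    if missing:
        warnings.warn(
            f"{bam}: chromosomes {sorted(missing)} absent from BAM header; "
            "affected loci counted as 0"
        )
    return counts


def windowed_counts(
    bam: str | os.PathLike,
    regions: RegionSet,
    window: int,
    *,
    filter_dup: bool = False,
    min_mapq: int = 0,
) -> list[np.ndarray]:
    """Per-locus window count vectors.

    Each locus is tiled left-to-right into ``ceil(len/window)`` fixed-width
    non-overlapping windows (the last may be short).  A read is counted in
    every window its aligned span overlaps, so window sums can exceed the
    whole-locus count.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    out: list[np.ndarray] = []
    with _open_indexed(bam) as handle:
        refs = set(handle.references)
        missing: set[str] = set()
        for iv in regions:
            n_win = -(-len(iv) // window)
            vec = np.zeros(n_win, dtype=np.int64)
            if iv.chrom not in refs:
                missing.add(iv.chrom)
                out.append(vec)
                continue
            for read in handle.fetch(iv.chrom, iv.start, iv.end):
                if not _keep_read(read, filter_dup, min_mapq):
                    continue
                lo = max(read.reference_start, iv.start) - iv.start
                hi = min(read.reference_end, iv.end) - iv.start
                if hi <= lo:
                    continue
                vec[lo // window : (hi - 1) // window + 1] += 1
            out.append(vec)
    if missing:
        warnings.warn(
            f"{bam}: chromosomes {sorted(missing)} absent from BAM header; "
            "affected loci counted as 0"
        )
    return out


def _label_from_path(path: str | os.PathLike) -> str:
    base = os.path.basename(str(path))
    return base[:-4] if base.endswith(".bam") else base


def build_count_matrix(
    bams: Sequence[str | os.PathLike],
    regions: RegionSet,
    *,
    labels: Sequence[str] | None = None,
    filter_dup: bool = False,
    min_mapq: int = 0,
) -> CountMatrix:
    """Stack per-BAM count vectors into a loci x marks :class:`CountMatrix`."""
    if not bams:
        raise ValueError("at least one BAM file is required")
    if labels is None:
        labels = [_label_from_path(b) for b in bams]
    if len(labels) != len(bams):
        raise ValueError("labels/bams length mismatch")
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate mark labels: {list(labels)}")
    cols = [
        count_reads(b, regions, filter_dup=filter_dup, min_mapq=min_mapq) for b in bams
    ]
    return CountMatrix(np.column_stack(cols), regions.names, list(labels))
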