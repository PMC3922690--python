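"""The three user-facing factorization pipelines.

* **absolute** — one condition, one region class: count reads per locus
  and mark, sigmoid-scale columns, factorize.
* **discriminatory** — one condition, k >= 2 region classes: scale and
  factorize each class separately, stack the per-class code matrices
  into one H, then recover a single weight matrix W for *all* loci by
  row-wise non-negative least squares against the combined H.  Codes
  that transfer poorly across classes are the discriminatory ones.
* **differential** — two conditions, one region class: window each
  locus, depth-correct with median-of-ratios factors (per mark), build
  per-locus gain/loss scores and factorize the 2m-column matrix; codes
  are patterns of coordinated mark changes.

Each pipeline has a matrix-level entry point (``*_from_*``) used by the
tests and a BAM/BED-level wrapper matching the command-line tool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .nmf import NMFResults, SparseNMF, nmf, nnls_weights
from .regions import CountMatrix, RegionSet, build_count_matrix, read_regions, windowed_counts
from .signal import (
    SignalMatrix,
    build_differential_matrix,
    gain_loss,
    scale_matrix,
    size_factors,
)

__all__ = [
    "ClassPartition",
    "absolute_mode",
    "absolute_from_matrix",
    "discriminatory_mode",
    "discriminatory_from_matrices",
    "differential_mode",
    "differential_from_windows",
    "nnls_weights",
]


@dataclass
class ClassPartition:
    """Row-space bookkeeping for discriminatory fits."""

    labels: list[str]
    row_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)

    def class_of_row(self, i: int) -> str:
        for label, (lo, hi) in self.row_ranges.items():
            if lo <= i < hi:
                return label
        raise IndexError(i)

    def codes_of_class(self, code_labels: list[str], label: str) -> list[int]:
        return [j for j, c in enumerate(code_labels) if c.startswith(f"{label}:")]


def _ensure_scaled(M: SignalMatrix | CountMatrix) -> SignalMatrix:
    if isinstance(M, SignalMatrix) and M.scaled:
        return M
    return scale_matrix(M)


def absolute_from_matrix(M: SignalMatrix | CountMatrix, rank: int, **nmf_kwargs) -> NMFResults:
    """Scale (if needed) and factorize a single-condition signal matrix."""
    return nmf(_ensure_scaled(M), rank, mode="absolute", **nmf_kwargs)


def absolute_mode(
    bams: Sequence[str],
    bed: str,
    rank: int,
    *,
    labels: Sequence[str] | None = None,
    filter_dup: bool = False,
    min_mapq: int = 0,
    **nmf_kwargs,
) -> NMFResults:
    regions = read_regions(bed)
    counts = build_count_matrix(
        bams, regions, labels=labels, filter_dup=filter_dup, min_mapq=min_mapq
    )
    return absolute_from_matrix(counts, rank, **nmf_kwargs)


def discriminatory_from_matrices(
    class_matrices: dict[str, SignalMatrix | CountMatrix],
    rank: int | dict[str, int],
    **nmf_kwargs,
) -> NMFResults:
    """Per-class factorization + joint NNLS reconstruction.

    Each class is sigmoid-scaled with its own column percentiles and
    factorized independently; the per-class H matrices are stacked
    (codes labeled ``<class>:code_<j>``) and a single W is solved
    row-wise by NNLS over the class-scaled rows of every class.
    """
    if not class_matrices:
        raise ValueError("no classes provided")
    labels = list(class_matrices)
    ranks = (
        {lab: int(rank) for lab in labels} if isinstance(rank, int) else dict(rank)
    )
    col_ids: list[str] | None = None
    scaled: dict[str, SignalMatrix] = {}
    results: dict[str, NMFResults] = {}
    for lab in labels:
        S = _ensure_scaled(class_matrices[lab])
        if col_ids is None:
            col_ids = S.col_ids
        elif S.col_ids != col_ids:
            raise ValueError(f"class {lab!r}: mark labels differ between classes")
        c = ranks[lab]
        if S.shape[0] < c:
            raise ValueError(
                f"class {lab!r} has {S.shape[0]} loci, fewer than its rank {c}"
            )
        scaled[lab] = S
        results[lab] = nmf(S, c, mode="absolute", **nmf_kwargs)
    H = np.vstack([results[lab].H for lab in labels])
    code_labels = [
        f"{lab}:code_{j + 1}" for lab in labels for j in range(results[lab].rank)
    ]
    V_all = np.vstack([scaled[lab].values for lab in labels])
    row_ids: list[str] = []
    ranges: dict[str, tuple[int, int]] = {}
    pos = 0
    for lab in labels:
        ids = scaled[lab].row_ids
        ranges[lab] = (pos, pos + len(ids))
        pos += len(ids)
        row_ids += [f"{lab}:{r}" for r in ids] if len(labels) > 1 else list(ids)
    W = nnls_weights(V_all, H)
    err = float(np.linalg.norm(V_all - W @ H, "fro"))
    first = results[labels[0]]
    return NMFResults(
        W=W,
        H=H,
        rank=H.shape[0],
        reconstruction_error=err,
        n_iter=sum(results[lab].n_iter for lab in labels),
        init_method=first.init_method,
        mode="discriminatory" if len(labels) > 1 else "absolute",
        row_ids=row_ids,
        col_ids=list(col_ids),
        code_labels=code_labels if len(labels) > 1 else first.code_labels,
        converged=all(results[lab].converged for lab in labels),
        l1_h=first.l1_h,
        class_partition=ClassPartition(labels, ranges),
    )


def discriminatory_mode(
    bams: Sequence[str],
    beds: Sequence[str],
    rank: int | Sequence[int],
    *,
    labels: Sequence[str] | None = None,
    class_labels: Sequence[str] | None = None,
    filter_dup: bool = False,
    min_mapq: int = 0,
    **nmf_kwargs,
) -> NMFResults:
    if len(beds) < 2:
        raise ValueError("discriminatory mode needs >= 2 region classes")
    if class_labels is None:
        class_labels = [f"class{i + 1}" for i in range(len(beds))]
    matrices: dict[str, CountMatrix] = {}
    for lab, bed in zip(class_labels, beds):
        regions = read_regions(bed)
        matrices[lab] = build_count_matrix(
            bams, regions, labels=labels, filter_dup=filter_dup, min_mapq=min_mapq
        )
    if not isinstance(rank, int):
        rank = {lab: int(c) for lab, c in zip(class_labels, rank)}
    return discriminatory_from_matrices(matrices, rank, **nmf_kwargs)


def differential_from_windows(
    windows_a: dict[str, list[np.ndarray]],
    windows_b: dict[str, list[np.ndarray]],
    locus_ids: list[str],
    rank: int,
    **nmf_kwargs,
) -> NMFResults:
    """Gain/loss construction and factorization from per-window counts.

    ``windows_a``/``windows_b`` map mark label -> per-locus window count
    vectors for conditions A and B.  Size factors are estimated per mark
    from the pooled (A, B) window-count matrix; identical mark label
    sets are required in both conditions.
    """
    if set(windows_a) != set(windows_b):
        raise ValueError(
            f"mark labels differ between conditions: "
            f"{sorted(windows_a)} vs {sorted(windows_b)}"
        )
    profiles = {}
    for mark in windows_a:
        wa, wb = windows_a[mark], windows_b[mark]
        pooled = np.column_stack(
            [np.concatenate([w.ravel() for w in wa]), np.concatenate([w.ravel() for w in wb])]
        )
        fa, fb = size_factors(pooled)
        profiles[mark] = gain_loss(wa, wb, (fa, fb), locus_ids)
    V = build_differential_matrix(profiles)
    return nmf(V, rank, mode="differential", **nmf_kwargs)


def differential_mode(
    bams_a: Sequence[str],
    bams_b: Sequence[str],
    bed: str,
    rank: int,
    *,
    window: int = 100,
    labels_a: Sequence[str] | None = None,
    labels_b: Sequence[str] | None = None,
    filter_dup: bool = False,
    min_mapq: int = 0,
    **nmf_kwargs,
) -> NMFResults:
    """Two-condition differential pipeline from BAM/BED inputs.

    Replicate BAMs sharing a mark label within a condition are merged by
    summing their window counts before differencing.
    """
    from .regions import _label_from_path

    regions = read_regions(bed)

    def collect(bams: Sequence[str], labels: Sequence[str] | None) -> dict[str, list[np.ndarray]]:
        if labels is None:
            labels = [_label_from_path(b) for b in bams]
        if len(labels) != len(bams):
            raise ValueError("labels/bams length mismatch")
        out: dict[str, list[np.ndarray]] = {}
        for lab, bam in zip(labels, bams):
            wc = windowed_counts(
                bam, regions, window, filter_dup=filter_dup, min_mapq=min_mapq
            )
            if lab in out:  # replicate: sum counts
                out[lab] = [a + b for a, b in zip(out[lab], wc)]
            else:
                out[lab] = wc
        return out

    wins_a = collect(bams_a, labels_a)
    wins_b = collect(bams_b, labels_b)
    return differential_from_windows(wins_a, wins_b, regions.names, rank, **nmf_kwargs)
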