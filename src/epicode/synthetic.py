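"""Synthetic benchmarks: planted factor models and miniature alignments.

Two kinds of ground-truthed inputs:

* planted non-negative matrices ``V = W* H* + noise`` with sparse basis
  rows (each code dominated by at most a few marks, each locus by one
  primary and occasionally one secondary code), sigmoid-scaled so they
  enter the factorizer exactly like real data;
* tiny BAM+BED datasets on a 100 kb synthetic contig ("chrS"), with
  36 bp single-end perfect alignments placed deterministically to
  realize hand-specified coverage — including a two-condition
  "broadened peak" scenario in which condition B spreads the same reads
  over the whole locus, producing simultaneous loss at the summit and
  gain at the flanks.

Every generator ships a machine-readable truth record so downstream
tests assert against construction, not re-derived constants.  None of
this models fragment-length, GC or mappability structure of real
ChIP-seq.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .signal import SignalMatrix, scale_matrix

__all__ = [
    "PlantedModel",
    "ToyAlignments",
    "make_planted_matrix",
    "make_two_class_fixture",
    "make_toy_alignments",
    "write_reads_bam",
    "CONTIG",
    "CONTIG_LEN",
    "READ_LEN",
]

CONTIG = "chrS"
CONTIG_LEN = 100_000
READ_LEN = 36


@dataclass
class PlantedModel:
    """Ground truth of a planted factorization problem."""

    H_true: np.ndarray
    W_true: np.ndarray
    noise_sd: float
    seed: int
    supports: list[list[int]] = field(default_factory=list)


def _support_sizes(c: int, m: int, sparsity: int) -> list[int]:
    if sparsity < 1 or c < 1:
        raise ValueError("sparsity and c must be >= 1")
    sizes = [min(sparsity, 3)] * c  # codes use at most 3 dominant marks
    while sum(sizes) > m:
        k = int(np.argmax(sizes))
        sizes[k] -= 1
        if sizes[k] < 1:
            raise ValueError(
                f"infeasible sparsity: cannot give {c} codes disjoint supports "
                f"over {m} columns"
            )
    return sizes


def _planted_factors(
    n: int,
    c: int,
    supports: list[list[int]],
    m: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    H = np.zeros((c, m))
    for k, cols in enumerate(supports):
        H[k, cols] = 1.0
    W = np.zeros((n, c))
    primary = rng.integers(0, c, size=n)
    primary[:c] = np.arange(c)  # every code used at least once
    for i in range(n):
        W[i, primary[i]] = rng.uniform(0.6, 1.4)
        if c > 1 and rng.uniform() < 0.3:
            other = (primary[i] + rng.integers(1, c)) % c
            W[i, other] = 0.25 * W[i, primary[i]]
    return W, H


def make_planted_matrix(
    n: int = 200,
    m: int = 8,
    c: int = 3,
    sparsity: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[SignalMatrix, PlantedModel]:
    """Planted sparse factorization benchmark, sigmoid-scaled.

    Codes receive disjoint dominant column sets of at most ``sparsity``
    (and at most 3) marks; each locus carries one primary code weight
    (uniform 0.6-1.4) and, with probability 0.3, a secondary code at a
    quarter of that weight.  Gaussian noise of sd ``noise_sd`` is added
    and clipped at zero before per-column sigmoid scaling.
    """
    if not (n > c and m >= c):
        raise ValueError("need n > c and m >= c")
    rng = np.random.default_rng(seed)
    sizes = _support_sizes(c, m, sparsity)
    cols = list(range(m))
    supports, pos = [], 0
    for s in sizes:
        supports.append(cols[pos : pos + s])
        pos += s
    W, H = _planted_factors(n, c, supports, m, rng)
    V = W @ H + rng.normal(0.0, noise_sd, size=(n, m))
    np.clip(V, 0.0, None, out=V)
    raw = SignalMatrix(
        V,
        [f"locus_{i + 1}" for i in range(n)],
        [f"mark{j + 1}" for j in range(m)],
        scaled=False,
    )
    return scale_matrix(raw), PlantedModel(H, W, noise_sd, seed, supports)


def make_two_class_fixture(
    n_per_class: int = 150,
    m: int = 8,
    c_per_class: int = 2,
    seed: int = 0,
    *,
    shared_codes: bool = False,
) -> dict[str, tuple[SignalMatrix, PlantedModel]]:
    """Two planted classes whose codes use disjoint halves of the marks.

    Class "A" codes draw their dominant columns from the first half of
    the mark set, class "B" from the second half, so the discriminatory
    pipeline should reconstruct each locus mostly from its own class's
    codes.  With ``shared_codes`` both classes reuse the class-A basis
    (the interchangeable-codes control).
    """
    half = m // 2
    if c_per_class > half:
        raise ValueError(
            f"m={m} too small for {c_per_class} disjoint codes per class"
        )
    rng = np.random.default_rng(seed)
    out: dict[str, tuple[SignalMatrix, PlantedModel]] = {}
    for k, label in enumerate(("A", "B")):
        offset = 0 if (shared_codes or label == "A") else half
        sizes = _support_sizes(c_per_class, half, 3)
        supports, pos = [], offset
        for s in sizes:
            supports.append(list(range(pos, pos + s)))
            pos += s
        W, H = _planted_factors(n_per_class, c_per_class, supports, m, rng)
        V = np.clip(W @ H + rng.normal(0.0, 0.02, size=(n_per_class, m)), 0.0, None)
        raw = SignalMatrix(
            V,
            [f"{label}_locus_{i + 1}" for i in range(n_per_class)],
            [f"mark{j + 1}" for j in range(m)],
            scaled=False,
        )
        out[label] = (scale_matrix(raw), PlantedModel(H, W, 0.02, seed, supports))
    return out


# ---------------------------------------------------------------------------
# miniature BAM/BED datasets


def write_reads_bam(
    path: str | os.PathLike,
    starts: list[int],
    *,
    chrom: str = CONTIG,
    contig_len: int = CONTIG_LEN,
    read_len: int = READ_LEN,
) -> str:
    """Write perfect 36 bp single-end alignments at the given starts.

    The output BAM is coordinate-sorted and indexed.
    """
    path = str(path)
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": chrom, "LN": contig_len}]}
    )
    tmp = path + ".unsorted.bam"
    with pysam.AlignmentFile(tmp, "wb", header=header) as out:
        for i, s in enumerate(starts):
            a = pysam.AlignedSegment(header=header)
            a.query_name = f"read_{i + 1}"
            a.query_sequence = "A" * read_len
            a.flag = 0
            a.reference_id = 0
            a.reference_start = int(s)
            a.mapping_quality = 60
            a.cigartuples = [(0, read_len)]
            a.query_qualities = pysam.qualitystring_to_array("I" * read_len)
            out.write(a)
    pysam.sort("-o", path, tmp)
    os.remove(tmp)
    pysam.index(path)
    return path


def _even_starts(lo: int, hi: int, k: int) -> list[int]:
    """k deterministic positions spread over [lo, hi] inclusive."""
    if k <= 0:
        return []
    if k == 1:
        return [(lo + hi) // 2]
    return [lo + round(t * (hi - lo) / (k - 1)) for t in range(k)]


def _write_bed(path: str, loci: list[tuple[int, int, str]]) -> str:
    with open(path, "w") as fh:
        for start, end, name in loci:
            fh.write(f"{CONTIG}\t{start}\t{end}\t{name}\t0\t+\n")
    return path


def _window_counts(starts: list[int], start: int, end: int, window: int) -> np.ndarray:
    n_win = -(-(end - start) // window)
    vec = np.zeros(n_win, dtype=np.int64)
    for s in starts:
        lo = max(s, start) - start
        hi = min(s + READ_LEN, end) - start
        if hi > lo:
            vec[lo // window : (hi - 1) // window + 1] += 1
    return vec


@dataclass
class ToyAlignments:
    """A generated miniature dataset plus its ground truth."""

    scenario: str
    bed: str
    bams: dict[str, str] = field(default_factory=dict)
    bams_a: dict[str, str] = field(default_factory=dict)
    bams_b: dict[str, str] = field(default_factory=dict)
    truth: pd.DataFrame | None = None
    truth_path: str = ""
    meta: dict = field(default_factory=dict)


def _absolute_dataset(out_dir: str, seed: int) -> ToyAlignments:
    rng = np.random.default_rng(seed)
    n, length, gap = 24, 1000, 2000
    loci = [(2000 + i * gap, 2000 + i * gap + length, f"L{i + 1}") for i in range(n)]
    marks = ["mark1", "mark2", "mark3", "mark4"]
    patterns = {0: (0, 1), 1: (2, 3)}  # two planted co-occurrence patterns
    assign = rng.integers(0, 2, size=n)
    counts = np.zeros((n, 4), dtype=np.int64)
    for i in range(n):
        active = patterns[int(assign[i])]
        for j in range(4):
            counts[i, j] = (
                rng.integers(25, 60) if j in active else rng.integers(0, 3)
            )
    bams: dict[str, str] = {}
    extra_truth = np.zeros((n, 4), dtype=np.int64)
    for j, mark in enumerate(marks):
        starts: list[int] = []
        for i, (s, e, _name) in enumerate(loci):
            starts += _even_starts(s, e - READ_LEN, int(counts[i, j]))
        if j == 0:
            # boundary cases: partial overlaps at the first locus, plus an
            # intergenic read that must count nowhere
            s0, e0, _ = loci[0]
            starts += [s0 - 10, e0 - 10, e0 + 500]
            extra_truth[0, 0] = 2
        bams[mark] = write_reads_bam(os.path.join(out_dir, f"{mark}.bam"), starts)
    truth = pd.DataFrame(
        counts + extra_truth, index=[name for _s, _e, name in loci], columns=marks
    )
    truth_path = os.path.join(out_dir, "truth_counts.tsv")
    truth.to_csv(truth_path, sep="\t", index_label="locus")
    bed = _write_bed(os.path.join(out_dir, "loci.bed"), loci)
    return ToyAlignments(
        "absolute",
        bed,
        bams=bams,
        truth=truth,
        truth_path=truth_path,
        meta={"patterns": {"code_a": ["mark1", "mark2"], "code_b": ["mark3", "mark4"]}},
    )


def _differential_dataset(out_dir: str, seed: int) -> ToyAlignments:
    """Condition B duplicates every condition-A read twice: pure depth shift."""
    rng = np.random.default_rng(seed)
    n, length, gap = 8, 600, 2000
    loci = [(2000 + i * gap, 2000 + i * gap + length, f"L{i + 1}") for i in range(n)]
    marks = ["mark1", "mark2"]
    bams_a, bams_b = {}, {}
    for mark in marks:
        starts: list[int] = []
        for s, e, _name in loci:
            k = int(rng.integers(12, 30))
            starts += _even_starts(s, e - READ_LEN, k)
        bams_a[mark] = write_reads_bam(os.path.join(out_dir, f"{mark}.A.bam"), starts)
        bams_b[mark] = write_reads_bam(
            os.path.join(out_dir, f"{mark}.B.bam"), starts + starts
        )
    truth = pd.DataFrame(
        {"gain": np.zeros(n), "loss": np.zeros(n)},
        index=[name for _s, _e, name in loci],
    )
    truth_path = os.path.join(out_dir, "truth_gain_loss.tsv")
    truth.to_csv(truth_path, sep="\t", index_label="locus")
    bed = _write_bed(os.path.join(out_dir, "loci.bed"), loci)
    return ToyAlignments(
        "differential",
        bed,
        bams_a=bams_a,
        bams_b=bams_b,
        truth=truth,
        truth_path=truth_path,
        meta={"expected_factor_ratio": 2.0},
    )


def _broadened_peak_dataset(out_dir: str, seed: int, window: int = 100) -> ToyAlignments:
    """Same read total, redistributed: sharp summit in A, broad peak in B."""
    fs, fe = 2000, 3000  # focal locus
    loci = [(fs, fe, "focal")] + [
        (6000 + i * 2000, 6000 + i * 2000 + 600, f"bg{i + 1}") for i in range(4)
    ]
    starts_a = (
        _even_starts(fs + 400, fs + 600 - READ_LEN, 60)  # summit concentration
        + _even_starts(fs, fs + 400 - READ_LEN, 5)
        + _even_starts(fs + 600, fe - READ_LEN, 5)
    )
    starts_b = _even_starts(fs, fe - READ_LEN, 70)  # broadened: spread evenly
    flat = []
    for s, e, name in loci[1:]:
        flat += _even_starts(s, e - READ_LEN, 18)
    bam_a = write_reads_bam(os.path.join(out_dir, "mark1.A.bam"), starts_a + flat)
    bam_b = write_reads_bam(os.path.join(out_dir, "mark1.B.bam"), starts_b + flat)
    # truth computed from the placed reads by the same window arithmetic
    win_a = [_window_counts(starts_a + flat, s, e, window) for s, e, _n in loci]
    win_b = [_window_counts(starts_b + flat, s, e, window) for s, e, _n in loci]
    pooled = np.column_stack([np.concatenate(win_a), np.concatenate(win_b)])
    from .signal import gain_loss, size_factors

    fa, fb = size_factors(pooled)
    profiles = gain_loss(win_a, win_b, (fa, fb), [n for _s, _e, n in loci])
    truth = pd.DataFrame(
        {"gain": [p.gain for p in profiles], "loss": [p.loss for p in profiles]},
        index=[n for _s, _e, n in loci],
    )
    truth_path = os.path.join(out_dir, "truth_gain_loss.tsv")
    truth.to_csv(truth_path, sep="\t", index_label="locus")
    bed = _write_bed(os.path.join(out_dir, "loci.bed"), loci)
    return ToyAlignments(
        "broadened_peak",
        bed,
        bams_a={"mark1": bam_a},
        bams_b={"mark1": bam_b},
        truth=truth,
        truth_path=truth_path,
        meta={"window": window, "focal": "focal", "size_factors": (float(fa), float(fb))},
    )


def make_toy_alignments(
    scenario: str, out_dir: str | os.PathLike, seed: int = 0
) -> ToyAlignments:
    """Write a miniature sorted+indexed BAM/BED dataset with a truth table.

    Scenarios: ``absolute`` (two planted mark-co-occurrence patterns over
    four marks), ``differential`` (condition B = condition A at exactly
    twice the depth; all true gain/loss zero) and ``broadened_peak``
    (equal totals, summit-concentrated in A vs spread-out in B).
    """
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    if scenario == "absolute":
        return _absolute_dataset(out_dir, seed)
    if scenario == "differential":
        return _differential_dataset(out_dir, seed)
    if scenario == "broadened_peak":
        return _broadened_peak_dataset(out_dir, seed)
    raise ValueError(f"unknown scenario {scenario!r}")
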