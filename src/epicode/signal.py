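"""Signal scaling and differential gain/loss quantification.

Columns of the locus x mark matrix V are brought to a common [0, 1)
range with a sigmoid that is approximately linear up to the 95th
percentile of each column::

    x_scaled = 2 / (1 + exp(-2 x / u)) - 1,   u = 95th percentile of x

The mapping is scale-invariant (u rescales with the data), maps 0 to 0
and saturates below 1, so marks with very different dynamic ranges enter
the factorization on equal footing.

For two-condition comparisons, per-window counts are depth-corrected by
median-of-ratios size factors, subtracted (B - A), and the positive and
negative parts of the per-window differences are integrated into
per-locus "gain" and "loss" magnitudes.  A broadened peak — lower at the
summit, higher on the flanks — therefore shows both gain and loss at the
same locus, which whole-locus subtraction would cancel away.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import CountMatrix

__all__ = [
    "SignalMatrix",
    "GainLossProfile",
    "sigmoid_scale",
    "scale_matrix",
    "size_factors",
    "gain_loss",
    "build_differential_matrix",
]


@dataclass
class SignalMatrix:
    """Non-negative loci x columns signal matrix (the model input V)."""

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    scaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("signal matrix must be 2-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite entries in signal matrix")
        if np.any(self.values < 0):
            raise ValueError("negative entries in signal matrix")
        if self.scaled and np.any(self.values >= 1.0):
            raise ValueError("scaled matrix must have entries in [0, 1)")
        if len(self.row_ids) != self.values.shape[0]:
            raise ValueError("row_ids length mismatch")
        if len(self.col_ids) != self.values.shape[1]:
            raise ValueError("col_ids length mismatch")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise ValueError(f"duplicate column labels: {self.col_ids}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="locus", float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike, scaled: bool = False) -> "SignalMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        return cls(df.to_numpy(float), [str(i) for i in df.index], list(df.columns), scaled)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scaled: bool = False) -> "SignalMatrix":
        return cls(df.to_numpy(float), [str(i) for i in df.index], list(df.columns), scaled)


@dataclass
class GainLossProfile:
    """Integrated positive/negative depth-corrected difference at one locus."""

    locus_id: str
    window_diffs: np.ndarray
    gain: float = 0.0
    loss: float = 0.0

    def __post_init__(self) -> None:
        self.window_diffs = np.asarray(self.window_diffs, dtype=float)
        self.gain = float(np.sum(np.maximum(self.window_diffs, 0.0)))
        self.loss = float(np.sum(np.maximum(-self.window_diffs, 0.0)))


def sigmoid_scale(x: np.ndarray) -> np.ndarray:
    """Scale a non-negative vector into [0, 1) with the percentile sigmoid.

    ``u`` is the 95th percentile (linear-interpolation estimator).  An
    all-zero vector is returned unchanged with a warning (u undefined);
    if >= 95% of entries are zero so that u = 0, the smallest positive
    value is used instead.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty vector")
    if np.any(x < 0):
        raise ValueError("sigmoid_scale requires non-negative input")
    if not np.any(x > 0):
        warnings.warn("all-zero column: sigmoid scale undefined, returning zeros")
        return np.zeros_like(x)
    u = float(np.percentile(x, 95))
    if u == 0.0:
        u = float(x[x > 0].min())
        warnings.warn(
            "95th percentile is zero (column is >=95% zeros); "
            "using smallest positive value as u"
        )
    return 2.0 / (1.0 + np.exp(-2.0 * x / u)) - 1.0


def scale_matrix(M: SignalMatrix | CountMatrix) -> SignalMatrix:
    """Apply :func:`sigmoid_scale` independently to every column of V."""
    if isinstance(M, SignalMatrix):
        if M.scaled:
            raise ValueError("matrix is already scaled")
        values, row_ids, col_ids = M.values, M.row_ids, M.col_ids
    else:
        values, row_ids, col_ids = M.values.astype(float), M.row_ids, M.col_ids
    scaled = np.column_stack([sigmoid_scale(values[:, j]) for j in range(values.shape[1])])
    return SignalMatrix(scaled, list(row_ids), list(col_ids), scaled=True)


def size_factors(K: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Median-of-ratios sequencing-depth factors, one per sample (column).

    factor_j = median over rows i of K_ij / geomean(K_i.), taken over
    rows whose geometric mean is positive (no zero entry).
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[1] < 2:
        raise ValueError("need a rows x samples matrix with >= 2 samples")
    positive = np.all(K > 0, axis=1)
    if not np.any(positive):
        raise ValueError(
            "no row with all-positive counts; use coarser windows or larger loci"
        )
    Kp = K[positive]
    log_geo = np.mean(np.log(Kp), axis=1)
    return np.exp(np.median(np.log(Kp) - log_geo[:, None], axis=0))


def gain_loss(
    windows_a: list[np.ndarray],
    windows_b: list[np.ndarray],
    factors: tuple[float, float],
    locus_ids: list[str] | None = None,
) -> list[GainLossProfile]:
    """Integrate depth-corrected per-window differences into gain/loss scores.

    ``window_diff_w = B_w / factor_B - A_w / factor_A``; gain sums the
    positive part across windows, loss the negative part.  Window grids
    of the two conditions must be identical.
    """
    if len(windows_a) != len(windows_b):
        raise ValueError("conditions cover different numbers of loci")
    fa, fb = float(factors[0]), float(factors[1])
    if fa <= 0 or fb <= 0:
        raise ValueError("size factors must be positive")
    if locus_ids is None:
        locus_ids = [f"locus_{i + 1}" for i in range(len(windows_a))]
    profiles = []
    for lid, a, b in zip(locus_ids, windows_a, windows_b):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError(f"{lid}: window grids differ between conditions")
        diff = b / fb - a / fa
        # snap float dust from exactly-cancelling depth corrections to zero:
        # the scale-invariant sigmoid would otherwise amplify it into signal
        scale = max(np.max(np.abs(a)) / fa, np.max(np.abs(b)) / fb, 1.0)
        diff[np.abs(diff) < 1e-9 * scale] = 0.0
        profiles.append(GainLossProfile(lid, diff))
    return profiles


def build_differential_matrix(
    profiles: dict[str, list[GainLossProfile]],
) -> SignalMatrix:
    """Assemble the 2m-column gain/loss matrix and sigmoid-scale it.

    Columns are interleaved ``<mark>.gain``, ``<mark>.loss`` in input mark
    order; every mark must provide one profile per locus of the same
    region set, in the same order.
    """
    if not profiles:
        raise ValueError("no marks provided")
    marks = list(profiles)
    row_ids = [p.locus_id for p in profiles[marks[0]]]
    cols: list[np.ndarray] = []
    col_ids: list[str] = []
    for mark in marks:
        plist = profiles[mark]
        if [p.locus_id for p in plist] != row_ids:
            raise ValueError(f"mark {mark!r}: locus set differs from other marks")
        cols.append(np.array([p.gain for p in plist]))
        cols.append(np.array([p.loss for p in plist]))
        col_ids += [f"{mark}.gain", f"{mark}.loss"]
    raw = SignalMatrix(np.column_stack(cols), row_ids, col_ids, scaled=False)
    return scale_matrix(raw)
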