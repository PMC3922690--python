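"""Sparse non-negative matrix factorization of chromatin signal.

The model is V ~ W H with V a scaled non-negative loci x marks matrix,
H a small ``rank x marks`` matrix of sparse basis patterns ("codes") and
W the ``loci x rank`` matrix of non-negative code weights.  The fitted
objective is

    ||V - WH||_F^2 + l1_h * sum(H),    W >= 0, H >= 0,

i.e. an l1 sparsity penalty on H only, favouring codes built from few
marks.  Because the penalty touches only H, the objective alone would
be scale-degenerate (inflate W, deflate H); during optimization the
columns of W are therefore constrained to the unit l2 ball and H rows
carry the signal magnitude.  Optimization is alternating
block-coordinate non-negative least squares (HALS); each block
objective is an isotropic quadratic, so the constrained block minimum
is the projection of the unconstrained one and the penalized objective
decreases monotonically.  The recorded ``reconstruction_error`` is
always the unpenalized Frobenius norm ||V - WH||_F.

Initialization follows the non-negative double SVD family: ``nndsvd``
(deterministic; each singular pair split into positive/negative parts,
the pair with the larger norm product kept), ``nndsvdar`` (zeros
replaced by small seeded uniform values, breaking the zero pattern) and
``random`` (uniform [0, 1) entries).  NNDSVD orders codes roughly by
explained variance, which keeps code numbering comparable across
datasets.

:class:`SparseNMF` is the model object (data + hyperparameters);
``fit()`` returns :class:`NMFResults` carrying W, H, the objective
trace, sparsity diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _scipy_nnls

from .signal import SignalMatrix

__all__ = [
    "SparseNMF",
    "NMFResults",
    "nndsvd_init",
    "nmf",
    "nnls_weights",
    "hoyer_sparsity",
    "matrix_sparsity",
    "rank_scan",
]

_EPS = np.finfo(float).eps


def hoyer_sparsity(v: np.ndarray) -> float:
    """Hoyer sparseness of a vector: (sqrt(n) - l1/l2) / (sqrt(n) - 1).

    0 for a constant vector, 1 for a single non-zero component.
    Requires n >= 2; an all-zero vector is reported as 0 with a warning.
    """
    v = np.asarray(v, dtype=float).ravel()
    n = v.size
    if n < 2:
        raise ValueError("Hoyer sparsity needs a vector of length >= 2")
    l2 = float(np.linalg.norm(v))
    if l2 == 0.0:
        warnings.warn("all-zero vector: Hoyer sparsity undefined, returning 0")
        return 0.0
    l1 = float(np.sum(np.abs(v)))
    rn = np.sqrt(n)
    return float((rn - l1 / l2) / (rn - 1.0))


def matrix_sparsity(M: np.ndarray, axis: str = "rows") -> float:
    """Mean Hoyer sparsity over the rows (or columns) of a matrix.

    All-zero rows are skipped with a warning; a matrix with no non-zero
    row is an error.
    """
    M = np.asarray(M, dtype=float)
    if axis == "columns":
        M = M.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'columns'")
    nonzero = np.linalg.norm(M, axis=1) > 0
    if not np.any(nonzero):
        raise ValueError("all rows are zero")
    if not np.all(nonzero):
        warnings.warn(f"{int(np.sum(~nonzero))} all-zero rows skipped in sparsity mean")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(np.mean([hoyer_sparsity(row) for row in M[nonzero]]))


def _as_array(V) -> np.ndarray:
    if isinstance(V, SignalMatrix):
        return V.values
    if isinstance(V, pd.DataFrame):
        return V.to_numpy(float)
    return np.asarray(V, dtype=float)


def nndsvd_init(
    V,
    rank: int,
    variant: str = "plain",
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative double SVD initialization (W0, H0).

    ``plain`` is fully deterministic: the leading singular triplet is
    taken with absolute values; each further triplet is split into its
    positive and negative parts and the part pair with the larger norm
    product is kept (ties go to the positive part) and rescaled by its
    singular value.  ``ar`` additionally replaces exact zeros with
    seeded uniform draws from (0, mean(V)/100], which lets optimizers
    move entries off the NNDSVD zero pattern.
    """
    A = _as_array(V)
    n, m = A.shape
    if not 1 <= rank <= min(n, m):
        raise ValueError(f"rank {rank} outside [1, {min(n, m)}]")
    if np.any(A < 0):
        raise ValueError("NNDSVD requires a non-negative matrix")
    U, S, Vt = np.linalg.svd(A, full_matrices=False)
    W = np.zeros((n, rank))
    H = np.zeros((rank, m))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(S[0]) * np.abs(Vt[0, :])
    for j in range(1, rank):
        x, y = U[:, j], Vt[j, :]
        xp, xn = np.maximum(x, 0), np.maximum(-x, 0)
        yp, yn = np.maximum(y, 0), np.maximum(-y, 0)
        xpn, xnn = np.linalg.norm(xp), np.linalg.norm(xn)
        ypn, ynn = np.linalg.norm(yp), np.linalg.norm(yn)
        mp, mn = xpn * ypn, xnn * ynn
        if mp >= mn:  # tie -> positive part, deterministic
            if mp == 0:
                continue
            u, v, sigma = xp / xpn, yp / ypn, mp
        else:
            u, v, sigma = xn / xnn, yn / ynn, mn
        W[:, j] = np.sqrt(S[j] * sigma) * u
        H[j, :] = np.sqrt(S[j] * sigma) * v
    if variant == "ar":
        rng = np.random.default_rng(seed)
        avg = A.mean()
        for M in (W, H):
            zeros = M == 0
            # uniform on (0, avg/100]: flip the half-open side of uniform()
            M[zeros] = avg / 100.0 * (1.0 - rng.uniform(0.0, 1.0, size=int(zeros.sum())))
    elif variant != "plain":
        raise ValueError("variant must be 'plain' or 'ar'")
    return W, H


def nnls_weights(V, H: np.ndarray) -> np.ndarray:
    """Row-wise non-negative least squares: argmin_{w>=0} ||v - wH||_2.

    All-zero rows of H are dropped from the solve and their weights
    restored as zero (with a warning).
    """
    A = _as_array(V)
    H = np.asarray(H, dtype=float)
    if A.shape[1] != H.shape[1]:
        raise ValueError("column dimensions of V and H disagree")
    active = np.linalg.norm(H, axis=1) > 0
    if not np.all(active):
        warnings.warn(
            f"{int(np.sum(~active))} all-zero basis rows excluded from NNLS solve"
        )
    Ht = H[active].T
    W = np.zeros((A.shape[0], H.shape[0]))
    for i in range(A.shape[0]):
        if np.any(A[i] != 0):
            W[i, active] = _scipy_nnls(Ht, A[i])[0]
    return W


@dataclass
class NMFResults:
    """Fitted factorization V ~ WH with diagnostics.

    ``H`` rows are the codes (sparse non-negative mark patterns), ``W``
    the per-locus code weights.  ``objective_trace`` records the
    penalized objective per outer iteration and is non-increasing;
    ``reconstruction_error`` is the final unpenalized ||V - WH||_F.
    """

    W: np.ndarray
    H: np.ndarray
    rank: int
    reconstruction_error: float
    n_iter: int
    init_method: str
    mode: str = "absolute"
    row_ids: list[str] = field(default_factory=list)
    col_ids: list[str] = field(default_factory=list)
    code_labels: list[str] = field(default_factory=list)
    objective_trace: np.ndarray | None = None
    converged: bool = True
    l1_h: float = 0.0
    class_partition: object | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        if np.any(self.W < 0) or np.any(self.H < 0):
            raise ValueError("factor matrices must be non-negative")
        if not self.row_ids:
            self.row_ids = [f"locus_{i + 1}" for i in range(self.W.shape[0])]
        if not self.col_ids:
            self.col_ids = [f"col_{j + 1}" for j in range(self.H.shape[1])]
        if not self.code_labels:
            self.code_labels = [f"code_{j + 1}" for j in range(self.H.shape[0])]

    @property
    def h_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.H, index=self.code_labels, columns=self.col_ids)

    @property
    def w_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.W, index=self.row_ids, columns=self.code_labels)

    def sparsity_h(self) -> float:
        return matrix_sparsity(self.H, axis="rows")

    def sparsity_w(self) -> float:
        return matrix_sparsity(self.W, axis="rows")

    def assignments(self) -> pd.DataFrame:
        from .postprocess import assign_codes

        return assign_codes(self)

    def summary(self) -> str:
        """Plain-text summary: fit statistics and the top marks per code."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                sw = f"{self.sparsity_w():.3f}"
            except ValueError:  # rank 1: single-entry weight rows
                sw = "n/a"
            try:
                sh = f"{self.sparsity_h():.3f}"
            except ValueError:
                sh = "n/a"
        lines = [
            "Sparse NMF of chromatin signal",
            "=" * 46,
            f"mode:                 {self.mode}",
            f"loci x columns:       {self.W.shape[0]} x {self.H.shape[1]}",
            f"rank (codes):         {self.rank}",
            f"initialization:       {self.init_method}",
            f"l1 penalty on H:      {self.l1_h:g}",
            f"iterations:           {self.n_iter}"
            + ("" if self.converged else "  (max_iter reached)"),
            f"reconstruction error: {self.reconstruction_error:.6g}",
            f"mean Hoyer sparsity:  H {sh} | W {sw}",
            "-" * 46,
        ]
        for label, row in zip(self.code_labels, self.H):
            order = np.argsort(row)[::-1]
            top = [
                f"{self.col_ids[k]}={row[k]:.3f}"
                for k in order[:3]
                if row[k] > 0
            ]
            lines.append(f"{label}: " + (", ".join(top) if top else "(empty)"))
        return "\n".join(lines)

    def save(self, prefix: str | os.PathLike) -> list[str]:
        """Write H, W and hard assignments as TSV next to ``prefix``."""
        from .postprocess import assign_codes

        prefix = str(prefix)
        paths = [f"{prefix}.H.tsv", f"{prefix}.W.tsv", f"{prefix}.assign.tsv"]
        self.h_frame.to_csv(paths[0], sep="\t", index_label="code", float_format="%.17g")
        self.w_frame.to_csv(paths[1], sep="\t", index_label="locus", float_format="%.17g")
        assign_codes(self).to_csv(paths[2], sep="\t", index=False, float_format="%.17g")
        return paths


class SparseNMF:
    """Sparse NMF model of a scaled locus x mark signal matrix.

    Parameters
    ----------
    V : SignalMatrix, DataFrame or ndarray
        Non-negative input; a :class:`~epicode.signal.SignalMatrix` must
        carry ``scaled=True`` (use :func:`epicode.signal.scale_matrix`).
    rank : int
        Number of codes c, the method's single main parameter.
    init : {'nndsvd', 'nndsvdar', 'random'}
        Initialization; the default is deterministic NNDSVD.
    l1_h : float
        Weight of the l1 sparsity penalty on H (0.1 by default on
        sigmoid-scaled data).
    max_iter, tol : int, float
        Outer-iteration cap and relative objective-change stopping rule.
    """

    def __init__(
        self,
        V,
        rank: int,
        *,
        init: str = "nndsvd",
        l1_h: float = 0.1,
        max_iter: int = 500,
        tol: float = 1e-4,
        mode: str = "absolute",
    ) -> None:
        if isinstance(V, SignalMatrix):
            if not V.scaled:
                raise ValueError("SignalMatrix must be scaled before factorization")
            self.row_ids, self.col_ids = list(V.row_ids), list(V.col_ids)
            A = V.values
        elif isinstance(V, pd.DataFrame):
            self.row_ids = [str(i) for i in V.index]
            self.col_ids = [str(c) for c in V.columns]
            A = V.to_numpy(float)
        else:
            A = np.asarray(V, dtype=float)
            self.row_ids = [f"locus_{i + 1}" for i in range(A.shape[0])]
            self.col_ids = [f"col_{j + 1}" for j in range(A.shape[1])]
        if A.ndim != 2:
            raise ValueError("V must be 2-dimensional")
        if not np.all(np.isfinite(A)):
            raise ValueError("non-finite entries in V")
        if np.any(A < 0):
            raise ValueError("V must be non-negative")
        if not np.any(A > 0):
            raise ValueError("V is entirely zero; nothing to factorize")
        if not 1 <= rank <= min(A.shape):
            raise ValueError(f"rank {rank} outside [1, {min(A.shape)}]")
        if init not in ("nndsvd", "nndsvdar", "random"):
            raise ValueError("init must be 'nndsvd', 'nndsvdar' or 'random'")
        self.V = A
        self.rank = int(rank)
        self.init = init
        self.l1_h = float(l1_h)
        self.max_iter = int(max_iter)
        self.tol = float(tol)
        self.mode = mode

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, rank: int, **kwargs) -> "SparseNMF":
        return cls(df, rank, **kwargs)

    def _initialize(self, seed: int | None) -> tuple[np.ndarray, np.ndarray]:
        if self.init == "nndsvd":
            return nndsvd_init(self.V, self.rank, "plain")
        if self.init == "nndsvdar":
            return nndsvd_init(self.V, self.rank, "ar", seed=seed)
        rng = np.random.default_rng(seed)
        n, m = self.V.shape
        return rng.uniform(size=(n, self.rank)), rng.uniform(size=(self.rank, m))

    def fit(self, seed: int | None = None, refit_w: bool = True) -> NMFResults:
        """Run HALS to convergence and return :class:`NMFResults`.

        With ``refit_w`` (default) the final W is replaced by the exact
        row-wise NNLS solution against the converged H, so the weights
        are optimal given the codes and identical across fitting routes.
        """
        V = self.V
        W, H = self._initialize(seed)
        trace: list[float] = []
        prev = np.inf
        converged = False
        n_iter = 0
        for it in range(1, self.max_iter + 1):
            n_iter = it
            # --- W columns (no penalty) ---
            HHt = H @ H.T
            VHt = V @ H.T
            for j in range(self.rank):
                denom = HHt[j, j]
                if denom < _EPS:
                    continue
                col = np.maximum(0.0, W[:, j] + (VHt[:, j] - W @ HHt[:, j]) / denom)
                norm = np.linalg.norm(col)
                if norm > 1.0:  # projection onto {w >= 0, ||w||_2 <= 1}
                    col /= norm
                W[:, j] = col
            # --- H rows (l1-penalized) ---
            WtW = W.T @ W
            WtV = W.T @ V
            for j in range(self.rank):
                denom = WtW[j, j]
                if denom < _EPS:
                    continue
                H[j, :] = np.maximum(
                    0.0,
                    H[j, :] + (WtV[j, :] - WtW[j, :] @ H) / denom - 0.5 * self.l1_h / denom,
                )
            obj = float(np.linalg.norm(V - W @ H, "fro") ** 2 + self.l1_h * H.sum())
            trace.append(obj)
            if prev - obj <= self.tol * max(prev, _EPS) and np.isfinite(prev):
                converged = True
                break
            prev = obj
        if refit_w:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                W = nnls_weights(V, H)
        err = float(np.linalg.norm(V - W @ H, "fro"))
        return NMFResults(
            W=W,
            H=H,
            rank=self.rank,
            reconstruction_error=err,
            n_iter=n_iter,
            init_method=self.init,
            mode=self.mode,
            row_ids=self.row_ids,
            col_ids=self.col_ids,
            objective_trace=np.asarray(trace),
            converged=converged,
            l1_h=self.l1_h,
        )


def nmf(
    V,
    rank: int,
    *,
    init: str = "nndsvd",
    l1_h: float = 0.1,
    max_iter: int = 500,
    tol: float = 1e-4,
    seed: int | None = None,
    mode: str = "absolute",
    refit_w: bool = True,
) -> NMFResults:
    """Functional one-call interface: build a :class:`SparseNMF` and fit it."""
    model = SparseNMF(
        V, rank, init=init, l1_h=l1_h, max_iter=max_iter, tol=tol, mode=mode
    )
    return model.fit(seed=seed, refit_w=refit_w)


def rank_scan(
    V,
    c_values: Sequence[int],
    **nmf_kwargs,
) -> pd.DataFrame:
    """Fit one factorization per candidate rank with identical settings.

    Returns a table of rank, mean Hoyer sparsity of H and W rows,
    unpenalized reconstruction error and iteration count.  No automatic
    rank choice is made; the curves are meant for locating a knee.
    """
    records = []
    for c in c_values:
        res = nmf(V, int(c), **nmf_kwargs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                sw = res.sparsity_w()
            except ValueError:  # rank 1: single-entry weight rows, undefined
                sw = float("nan")
            records.append(
                {
                    "rank": int(c),
                    "sparsity_H": res.sparsity_h(),
                    "sparsity_W": sw,
                    "reconstruction_error": res.reconstruction_error,
                    "n_iter": res.n_iter,
                }
            )
    return pd.DataFrame.from_records(records)
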