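"""Hard code assignment, cross-run code matching and correlation reports.

Loci are hard-labeled with the code of maximal weight (as in K-means
assignment).  Basis matrices from two runs or datasets are aligned by
minimum-total-Euclidean-cost bipartite matching (Hungarian algorithm),
since NMF code order is arbitrary.  Spearman correlation heat-map input
doubles as a multicollinearity report: column pairs with |rho| > 0.8
are flagged as unsafe to include together in one regression model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr

from .nmf import NMFResults

__all__ = [
    "CodeMatching",
    "assign_codes",
    "match_codes",
    "correlation_matrix",
    "multicollinearity_report",
]

UNASSIGNED = "unassigned"


def _w_frame(W) -> pd.DataFrame:
    if isinstance(W, NMFResults):
        return W.w_frame
    if isinstance(W, pd.DataFrame):
        return W
    W = np.asarray(W, dtype=float)
    return pd.DataFrame(
        W,
        index=[f"locus_{i + 1}" for i in range(W.shape[0])],
        columns=[f"code_{j + 1}" for j in range(W.shape[1])],
    )


def _h_frame(H) -> pd.DataFrame:
    if isinstance(H, NMFResults):
        return H.h_frame
    if isinstance(H, pd.DataFrame):
        return H
    H = np.asarray(H, dtype=float)
    return pd.DataFrame(
        H,
        index=[f"code_{j + 1}" for j in range(H.shape[0])],
        columns=[f"col_{j + 1}" for j in range(H.shape[1])],
    )


def assign_codes(W) -> pd.DataFrame:
    """Hard-assign each locus to its highest-weight code.

    Ties break to the lowest code index; an all-zero weight row is
    reported as ``unassigned`` with weight and margin 0.  Returns a
    table with columns locus, code, weight, margin (gap to runner-up).
    """
    wf = _w_frame(W)
    if np.any(wf.to_numpy() < 0):
        raise ValueError("weights must be non-negative")
    records = []
    for locus, row in zip(wf.index, wf.to_numpy(float)):
        if not np.any(row > 0):
            records.append((locus, UNASSIGNED, 0.0, 0.0))
            continue
        j = int(np.argmax(row))  # argmax takes the first maximum: the tie rule
        rest = np.delete(row, j)
        margin = float(row[j] - rest.max()) if rest.size else float(row[j])
        records.append((locus, wf.columns[j], float(row[j]), margin))
    return pd.DataFrame(records, columns=["locus", "code", "weight", "margin"])


@dataclass
class CodeMatching:
    """Minimum-cost pairing of codes from two factorizations."""

    pairs: list[tuple[str, str, float]]
    total_cost: float
    unmatched_a: list[str]
    unmatched_b: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["code_a", "code_b", "cost"])


def match_codes(H_a, H_b, *, normalize: bool = False) -> CodeMatching:
    """Match codes across two basis matrices by Euclidean cost.

    The two H matrices must cover the same column labels (a permuted
    column order is realigned internally).  The Hungarian algorithm
    minimizes the total pairwise Euclidean distance; with unequal ranks
    the smaller side is fully matched and leftovers are reported as
    singletons.  ``normalize`` optionally l2-normalizes rows first, for
    cross-dataset comparisons where absolute scale differs.
    """
    ha, hb = _h_frame(H_a), _h_frame(H_b)
    if set(ha.columns) != set(hb.columns):
        raise ValueError(
            f"column labels differ: {sorted(ha.columns)} vs {sorted(hb.columns)}"
        )
    hb = hb[ha.columns]
    A, B = ha.to_numpy(float), hb.to_numpy(float)
    if normalize:
        def unit(M):
            norms = np.linalg.norm(M, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            return M / norms

        A, B = unit(A), unit(B)
    cost = cdist(A, B, metric="euclidean")
    ri, ci = linear_sum_assignment(cost)
    pairs = [
        (str(ha.index[i]), str(hb.index[j]), float(cost[i, j])) for i, j in zip(ri, ci)
    ]
    return CodeMatching(
        pairs=pairs,
        total_cost=float(cost[ri, ci].sum()),
        unmatched_a=[str(x) for k, x in enumerate(ha.index) if k not in set(ri)],
        unmatched_b=[str(x) for k, x in enumerate(hb.index) if k not in set(ci)],
    )


def correlation_matrix(M, method: str = "spearman") -> pd.DataFrame:
    """Pairwise Spearman rank correlation between columns.

    Applied to the mark columns of V or the code columns of W.  A
    constant column has undefined correlation; its entries are reported
    as 0 with a warning (diagonal stays 1).
    """
    if method != "spearman":
        raise ValueError("only Spearman rank correlation is supported")
    df = M.w_frame if isinstance(M, NMFResults) else (
        M if isinstance(M, pd.DataFrame) else pd.DataFrame(np.asarray(M, dtype=float))
    )
    if df.shape[0] < 3:
        raise ValueError("need >= 3 rows for a rank correlation")
    X = df.to_numpy(float)
    rho = spearmanr(X).statistic if X.shape[1] > 2 else None
    if X.shape[1] == 2:
        rho = np.array([[1.0, spearmanr(X[:, 0], X[:, 1]).statistic]] * 2)
        rho[1, 0] = rho[0, 1]
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    if np.any(np.isnan(rho)):
        warnings.warn("constant column(s): undefined correlations reported as 0")
        rho = np.nan_to_num(rho, nan=0.0)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=df.columns, columns=df.columns)


def multicollinearity_report(corr: pd.DataFrame, threshold: float = 0.8) -> pd.DataFrame:
    """Column pairs whose |Spearman rho| exceeds the rule-of-thumb cutoff."""
    records = []
    cols = list(corr.columns)
    vals = corr.to_numpy(float)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if abs(vals[i, j]) > threshold:
                records.append((cols[i], cols[j], float(vals[i, j])))
    return pd.DataFrame(records, columns=["col_a", "col_b", "rho"])
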