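"""Random-set gene-set enrichment of per-locus code weights.

For a score vector x over N genes (typically one W column mapped to
genes) and a gene set of size m, the random-set statistic compares the
set's mean score to its exact moments under uniform sampling of m genes
without replacement:

    E[Xbar] = mu  (mean of all N scores)
    Var[Xbar] = (sigma^2 / m) * (N - m) / (N - 1)

with sigma^2 the population variance of all scores; z = (Xbar - mu)/sd
and the default p-value is the one-sided upper-tail normal probability
(positive association).  P-values across every (code, set) pair are
jointly Benjamini-Hochberg corrected — the stricter family — while the
output table supports per-collection slicing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .nmf import NMFResults

__all__ = [
    "GeneScoreVector",
    "random_set_test",
    "bh_fdr",
    "read_gmt",
    "enrich_all",
]


@dataclass
class GeneScoreVector:
    """Unique gene identifiers with one real-valued score each."""

    gene_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.gene_ids) != self.scores.size:
            raise ValueError("gene_ids/scores length mismatch")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")
        if self.scores.size < 2:
            raise ValueError("need >= 2 scored genes")


def random_set_test(
    scores: GeneScoreVector,
    gene_set: list[str] | set[str],
    *,
    two_sided: bool = False,
) -> tuple[float, float]:
    """Z statistic and p-value for one gene set under the random-set null.

    Only genes present in the score vector count toward the set size m;
    m = 0 or m = N is rejected.  If every score is identical the
    statistic is degenerate and (0, 0.5) is returned with a warning.
    """
    idx = {g: i for i, g in enumerate(scores.gene_ids)}
    members = sorted({g for g in gene_set if g in idx})
    m, N = len(members), scores.scores.size
    if m == 0:
        raise ValueError("gene set has no overlap with scored genes")
    if m >= N:
        raise ValueError("gene set covers every scored gene; test undefined")
    x = scores.scores
    mu = float(x.mean())
    var = float(x.var(ddof=0))
    if var == 0.0:
        warnings.warn("all scores equal: degenerate random-set statistic")
        return 0.0, 0.5
    xbar = float(np.mean([x[idx[g]] for g in members]))
    sd = np.sqrt(var / m * (N - m) / (N - 1))
    z = (xbar - mu) / sd
    p = 2.0 * norm.sf(abs(z)) if two_sided else float(norm.sf(z))
    return float(z), float(min(p, 1.0))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file: set id, description, tab-separated members."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            sets[fields[0]] = [g for g in fields[2:] if g]
    if not sets:
        raise ValueError(f"no gene sets parsed from {path}")
    return sets


def _gene_scores(
    row_ids: list[str], values: np.ndarray, gene_map: dict[str, str] | None
) -> GeneScoreVector:
    # loci mapping to the same gene are averaged
    agg: dict[str, list[float]] = {}
    for locus, v in zip(row_ids, values):
        gene = gene_map.get(locus) if gene_map is not None else locus
        if gene is None:
            continue
        agg.setdefault(gene, []).append(float(v))
    genes = list(agg)
    return GeneScoreVector(genes, np.array([np.mean(agg[g]) for g in genes]))


def enrich_all(
    factorization: NMFResults | pd.DataFrame,
    gene_sets: dict[str, list[str]] | str,
    gene_map: dict[str, str] | None = None,
    *,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Random-set enrichment of every code against every gene set.

    ``factorization`` supplies the per-locus weight columns (an
    :class:`NMFResults` or a loci x codes DataFrame); ``gene_sets`` is a
    GMT path or a preparsed dict; ``gene_map`` maps locus names to gene
    ids (identity if omitted).  Returns one record per (code, set) with
    set size after intersection, z, p and jointly BH-corrected q; sets
    without overlap are skipped with a warning.
    """
    if isinstance(gene_sets, str):
        gene_sets = read_gmt(gene_sets)
    if not gene_sets:
        raise ValueError("empty gene-set collection")
    wf = factorization.w_frame if isinstance(factorization, NMFResults) else factorization
    records = []
    for code in wf.columns:
        scores = _gene_scores(
            [str(i) for i in wf.index], wf[code].to_numpy(float), gene_map
        )
        for set_id, members in gene_sets.items():
            try:
                z, p = random_set_test(scores, members, two_sided=two_sided)
            except ValueError:
                warnings.warn(f"set {set_id!r}: no overlap with scored genes, skipped")
                continue
            m = len(set(members) & set(scores.gene_ids))
            records.append((str(code), set_id, m, z, p))
    if not records:
        raise ValueError("no testable (code, set) pairs")
    table = pd.DataFrame(records, columns=["code", "set", "set_size", "z", "p"])
    table["q"] = bh_fdr(table["p"].to_numpy())
    return table
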