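"""Pairwise Spearman correlation matrices with silent genes zeroed.

Correlations are rank-based (Spearman's rho, average ranks for ties).
Genes flagged as silent keep their position in the matrix but every entry
touching them — including the diagonal — is exactly 0, so any window that
contains a silent gene is penalized rather than the gene being dropped.
Constant expression profiles, for which rank correlation is undefined,
are likewise assigned 0 with every partner: a flat profile carries no
co-expression evidence.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats


@dataclasses.dataclass
class CorrelationMatrix:
    """Symmetric Spearman rho matrix over an ordered gene list."""

    gene_ids: list[str]
    rho: np.ndarray
    silent_mask: np.ndarray  # boolean, True where the gene is silent

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        self.silent_mask = np.asarray(self.silent_mask, dtype=bool)
        n = len(self.gene_ids)
        if self.rho.shape != (n, n):
            raise ValueError(f"rho shape {self.rho.shape} does not match {n} genes")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    def value(self, a: str, b: str) -> float:
        try:
            return float(self.rho[self._index[a], self._index[b]])
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in correlation matrix") from None

    def submatrix_indices(self, gene_ids: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._index[g] for g in gene_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in correlation matrix") from None


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation of two vectors (average ranks for ties).

    Returns 0 when either vector is constant, where the statistic is
    otherwise undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def _rank_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise average ranks, standardized; constant rows zeroed.

    Returns (standardized ranks, constant-row mask).  With standardized
    ranks, Spearman rho of two rows is just their dot product / N.
    """
    ranks = stats.rankdata(values, axis=1)
    constant = np.ptp(values, axis=1) == 0
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1)
    sd[sd == 0] = 1.0
    z = centered / sd[:, None]
    z[constant] = 0.0
    return z, constant


def pairwise_spearman(
    expr_values: np.ndarray,
    gene_ids: Sequence[str],
    silent: Iterable[str] = (),
) -> CorrelationMatrix:
    """Spearman correlation matrix of expression rows with silent zeroing.

    ``expr_values`` rows must align with ``gene_ids``.  Every entry whose
    row or column gene is silent (or constant) is exactly 0; the diagonal
    is 1 for ordinary genes.
    """
    expr_values = np.asarray(expr_values, dtype=float)
    gene_ids = list(gene_ids)
    if expr_values.shape[0] != len(gene_ids):
        raise ValueError("row count does not match gene_ids")
    z, constant = _rank_rows(expr_values)
    n_samples = expr_values.shape[1]
    rho = (z @ z.T) / n_samples
    np.clip(rho, -1.0, 1.0, out=rho)
    np.fill_diagonal(rho, 1.0)
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    silent_set = set(silent)
    mask = np.array([g in silent_set for g in gene_ids], dtype=bool)
    rho[mask, :] = 0.0
    rho[:, mask] = 0.0
    return CorrelationMatrix(gene_ids, rho, mask)


def correlation_by_chromosome(
    expr,
    genes,
    silent: Iterable[str] = (),
    scope: str = "per_chromosome",
) -> dict[str, CorrelationMatrix]:
    """Correlation matrices keyed by chromosome (or {"*": genome-wide}).

    Windows never span chromosomes, so per-chromosome matrices hold every
    entry the scoring stages consume while avoiding the full genome-wide
    quadratic cost.  The genome_wide scope exists for diagnostics.
    """
    if scope not in ("per_chromosome", "genome_wide"):
        raise ValueError(f"unknown scope {scope!r}")
    silent_set = set(silent)
    if scope == "genome_wide":
        order = [g.gene_id for g in genes]
        idx = [expr.row_index(g) for g in order]
        return {"*": pairwise_spearman(expr.values[idx], order, silent_set)}
    out: dict[str, CorrelationMatrix] = {}
    by_chrom: dict[str, list[str]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g.gene_id)
    for chrom, ids in by_chrom.items():
        idx = [expr.row_index(g) for g in ids]
        out[chrom] = pairwise_spearman(expr.values[idx], ids, silent_set)
    return out


def export_matrix_tsv(corr: CorrelationMatrix, path: str) -> None:
    """Write the rho matrix as TSV for inspection."""
    import pandas as pd

    pd.DataFrame(corr.rho, index=corr.gene_ids, columns=corr.gene_ids).to_csv(
        path, sep="\t", float_format="%.6g"
    )
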