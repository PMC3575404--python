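"""Position-preserving permutation null and empirical p-values.

The null model keeps the authentic genomic positions of genes and shuffles
their expression profiles (rows of the expression matrix) uniformly at
random across the genome.  Silent status travels with each profile.  The
full window enumeration and ANC computation are repeated on every shuffled
transcriptome, and the null ANCs are pooled across shuffles within each
window-size class.  The empirical p-value of an observed window is the
proportion of pooled null ANCs at its size that are strictly greater than
its observed ANC — unadjusted for multiple testing, since the scores are a
ranking device rather than individual significance claims.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional, Sequence

import numpy as np

from .correlation import pairwise_spearman
from .data_model import ExpressionMatrix, GeneRecord, Neighborhood
from .windows import compute_all_ancs


@dataclasses.dataclass
class NullDistribution:
    """Pooled null ANC values for one window-size class."""

    size_key: int
    anc_values: np.ndarray  # sorted
    n_shuffles: int
    seed: int

    def p_value(self, observed_anc: float, pseudo_count: bool = False) -> float:
        n = self.anc_values.size
        greater = n - int(np.searchsorted(self.anc_values, observed_anc, side="right"))
        if pseudo_count:
            return (greater + 1) / (n + 1)
        return greater / n


def shuffle_profiles(expr: ExpressionMatrix, rng_seed: int) -> ExpressionMatrix:
    """Return a copy of the matrix with rows uniformly permuted across genes.

    Gene ids stay in place; the multiset of expression profiles (and, when
    present, detection-call rows, which travel with their profiles) is
    preserved exactly.  The same seed always yields the same permutation.
    """
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(len(expr.gene_ids))
    detection = expr.detection[perm] if expr.detection is not None else None
    return ExpressionMatrix(
        list(expr.gene_ids), list(expr.sample_ids), expr.values[perm], detection
    )


def build_null_distributions(
    windows: Sequence[Neighborhood],
    expr: ExpressionMatrix,
    genes: Sequence[GeneRecord],
    silent: Iterable[str],
    n_shuffles: int = 10,
    seed: int = 0,
) -> dict[int, NullDistribution]:
    """Pooled null ANC distributions per window-size class.

    For each shuffle, profiles (with their silent flags) are permuted
    genome-wide, per-chromosome correlation matrices are rebuilt with
    silent-gene zeroing applied after the shuffle, and ANCs are recomputed
    on the identical window structure (positions are fixed, so the windows
    are the same gene runs).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    silent_set = set(silent)
    gene_order = [g.gene_id for g in genes]
    row_idx = np.array([expr.row_index(g) for g in gene_order])
    silent_flags = np.array([g in silent_set for g in gene_order], dtype=bool)
    values = expr.values[row_idx]

    chrom_slices: dict[str, slice] = {}
    start = 0
    for i, g in enumerate(genes):
        if i == len(genes) - 1 or genes[i + 1].chrom != g.chrom:
            chrom_slices[g.chrom] = slice(start, i + 1)
            start = i + 1

    # null windows mirror the observed enumeration (scores ignored)
    null_windows = [
        dataclasses.replace(w, anc=None, p_value=None, ss=None, tns=None)
        for w in windows
    ]

    rng = np.random.default_rng(seed)
    pools: dict[int, list[np.ndarray]] = {}
    for _ in range(n_shuffles):
        perm = rng.permutation(len(gene_order))
        shuffled_values = values[perm]
        shuffled_silent = silent_flags[perm]
        corr_by_chrom = {}
        for chrom, sl in chrom_slices.items():
            ids = gene_order[sl]
            silent_here = {g for g, s in zip(ids, shuffled_silent[sl]) if s}
            corr_by_chrom[chrom] = pairwise_spearman(
                shuffled_values[sl], ids, silent_here
            )
        compute_all_ancs(null_windows, corr_by_chrom)
        by_size: dict[int, list[float]] = {}
        for w in null_windows:
            by_size.setdefault(w.size_key, []).append(w.anc)
        for k, vals in by_size.items():
            pools.setdefault(k, []).append(np.asarray(vals))

    out: dict[int, NullDistribution] = {}
    for k, chunks in pools.items():
        vals = np.sort(np.concatenate(chunks))
        out[k] = NullDistribution(k, vals, n_shuffles, seed)
    return out


def empirical_pvalues(
    observed: list[Neighborhood],
    expr: ExpressionMatrix,
    genes: Sequence[GeneRecord],
    silent: Iterable[str],
    n_shuffles: int = 10,
    seed: int = 0,
    pseudo_count: bool = False,
    null_dists: Optional[dict[int, NullDistribution]] = None,
) -> list[Neighborhood]:
    """Set ``p_value`` on every observed window from the permutation null.

    Counting is strictly-greater with no add-one correction by default, so
    an observed ANC above every pooled null value gets p = 0 exactly; pass
    ``pseudo_count=True`` for the (k+1)/(n+1) estimator that guarantees
    p > 0.
    """
    if null_dists is None:
        null_dists = build_null_distributions(
            observed, expr, genes, silent, n_shuffles=n_shuffles, seed=seed
        )
    for w in observed:
        if w.anc is None:
            raise ValueError("observed windows must have anc set before p-values")
        dist = null_dists.get(w.size_key)
        assert dist is not None, (
            f"no null windows at size {w.size_key}: null enumeration must mirror "
            "the observed one"
        )
        w.p_value = dist.p_value(w.anc, pseudo_count=pseudo_count)
    return observed


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (reporting only; never gates the TNS)."""
    from scipy.stats import false_discovery_control

    return false_discovery_control(np.asarray(p_values, dtype=float), method="bh")
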