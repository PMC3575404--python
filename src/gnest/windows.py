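"""Candidate neighborhood enumeration and Average Neighborhood Correlation.

Every run of W consecutive non-redundant genes on a chromosome, for every
requested window size W, is a candidate neighborhood ("window").  Windows
never span chromosomes.  The ANC of a window is the mean of the
W*(W-1)/2 distinct pairwise Spearman correlations among its members; it is
computed incrementally across window sizes — the pair sum of the
(start, W) window extends the pair sum of (start, W-1) by the W-1 pairs
the new member introduces.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .correlation import CorrelationMatrix
from .data_model import GeneRecord, Neighborhood


@dataclasses.dataclass(frozen=True)
class WindowSpec:
    """Requested window-size range, in genes or base pairs."""

    size_mode: str = "gene_count"  # "gene_count" | "bp"
    min_size: int = 2
    max_size: int = 10
    bp_sizes: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.size_mode == "gene_count":
            if not (2 <= self.min_size <= self.max_size):
                raise ValueError("gene_count mode requires 2 <= min_size <= max_size")
        elif self.size_mode == "bp":
            if not self.bp_sizes or any(s < 1 for s in self.bp_sizes):
                raise ValueError("bp mode requires positive bp sizes")
        else:
            raise ValueError(f"unknown size_mode {self.size_mode!r}")


def _by_chromosome(genes: Sequence[GeneRecord]) -> dict[str, list[GeneRecord]]:
    out: dict[str, list[GeneRecord]] = {}
    for g in genes:
        out.setdefault(g.chrom, []).append(g)
    return out


def enumerate_gene_windows(
    genes: Sequence[GeneRecord], spec: WindowSpec
) -> list[Neighborhood]:
    """All windows of min_size..max_size consecutive genes per chromosome.

    A chromosome with n genes contributes exactly max(0, n - W + 1) windows
    of size W; sizes exceeding n are silently skipped.
    """
    if spec.size_mode != "gene_count":
        raise ValueError("enumerate_gene_windows requires a gene_count WindowSpec")
    windows: list[Neighborhood] = []
    for chrom, chrom_genes in _by_chromosome(genes).items():
        n = len(chrom_genes)
        for w in range(spec.min_size, min(spec.max_size, n) + 1):
            for i in range(n - w + 1):
                members = chrom_genes[i : i + w]
                windows.append(
                    Neighborhood(
                        chrom=chrom,
                        member_gene_ids=tuple(g.gene_id for g in members),
                        span_start=min(g.start for g in members),
                        span_end=max(g.end for g in members),
                        size_mode="gene_count",
                        size_key=w,
                        start_index=i,
                    )
                )
    return windows


def enumerate_bp_windows(
    genes: Sequence[GeneRecord], sizes: Sequence[int]
) -> list[Neighborhood]:
    """Base-pair-budget windows: per start gene, the maximal run fitting S.

    For each requested size S and each start gene i, the window is the
    longest run of consecutive genes i..j whose span (min start to max end)
    is <= S, provided it holds at least 2 genes.  A member run that
    satisfies several sizes is emitted once, keyed by the smallest
    satisfying size, with the others recorded in ``extra_size_keys``.
    """
    sizes = sorted(set(int(s) for s in sizes))
    if not sizes:
        return []
    windows: list[Neighborhood] = []
    for chrom, chrom_genes in _by_chromosome(genes).items():
        n = len(chrom_genes)
        seen: dict[tuple[int, int], Neighborhood] = {}
        for s in sizes:
            for i in range(n - 1):
                span_start = chrom_genes[i].start
                span_end = chrom_genes[i].end
                j = i
                while j + 1 < n:
                    cand_end = max(span_end, chrom_genes[j + 1].end)
                    if cand_end - span_start > s:
                        break
                    span_end = cand_end
                    j += 1
                if j == i:
                    continue  # not even 2 genes fit the budget
                key = (i, j)
                if key in seen:
                    prev = seen[key]
                    if s not in prev.extra_size_keys and s != prev.size_key:
                        prev.extra_size_keys = prev.extra_size_keys + (s,)
                    continue
                members = chrom_genes[i : j + 1]
                win = Neighborhood(
                    chrom=chrom,
                    member_gene_ids=tuple(g.gene_id for g in members),
                    span_start=span_start,
                    span_end=span_end,
                    size_mode="bp",
                    size_key=s,
                    start_index=i,
                )
                seen[key] = win
                windows.append(win)
    return windows


def enumerate_windows(genes: Sequence[GeneRecord], spec: WindowSpec) -> list[Neighborhood]:
    if spec.size_mode == "gene_count":
        return enumerate_gene_windows(genes, spec)
    return enumerate_bp_windows(genes, spec.bp_sizes)


def compute_anc(window: Neighborhood, corr: CorrelationMatrix) -> float:
    """Mean of all distinct pairwise correlations among window members."""
    idx = corr.submatrix_indices(window.member_gene_ids)
    sub = corr.rho[np.ix_(idx, idx)]
    w = len(idx)
    pair_sum = (sub.sum() - np.trace(sub)) / 2.0
    return float(pair_sum / (w * (w - 1) / 2))


def compute_all_ancs(
    windows: list[Neighborhood], corr_by_chrom: dict[str, CorrelationMatrix]
) -> list[Neighborhood]:
    """Fill in ``anc`` for every window, reusing pair sums across sizes.

    Windows sharing a chromosome and start index form a nested family;
    the pair sum of the (start, W) window is the pair sum of (start, W-1)
    plus the correlations of the newly appended gene with each earlier
    member.  Values are identical to calling :func:`compute_anc` per
    window.
    """
    # pair-sum cache keyed by (chrom, start_index, member count)
    cache: dict[tuple[str, int, int], float] = {}
    for win in sorted(windows, key=lambda w: (w.chrom, w.start_index, w.size_genes)):
        corr = corr_by_chrom.get(win.chrom) or corr_by_chrom.get("*")
        if corr is None:
            raise KeyError(f"no correlation matrix for chromosome {win.chrom!r}")
        idx = corr.submatrix_indices(win.member_gene_ids)
        w = len(idx)
        prev_key = (win.chrom, win.start_index, w - 1)
        if prev_key in cache:
            new_gene = idx[-1]
            pair_sum = cache[prev_key] + float(corr.rho[new_gene, idx[:-1]].sum())
        else:
            sub = corr.rho[np.ix_(idx, idx)]
            pair_sum = float((sub.sum() - np.trace(sub)) / 2.0)
        cache[(win.chrom, win.start_index, w)] = pair_sum
        win.anc = pair_sum / (w * (w - 1) / 2)
    return windows
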