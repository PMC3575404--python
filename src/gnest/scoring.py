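"""Total Neighborhood Score and result emission.

TNS = SS * ANC when the window's empirical p-value is at most alpha
(inclusive, default 0.05), else exactly 0.  The gate deliberately zeroes
windows whose co-expression is unremarkable against the permutation null;
with silent genes' correlations zeroed as well, no non-expressed gene can
prop up a scored neighborhood.  TNS is a ranking score, not a calibrated
probability.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

from .data_model import GeneRecord, Neighborhood


@dataclasses.dataclass
class ScoredGenome:
    """All scored neighborhoods plus the per-gene best-TNS summary."""

    neighborhoods: list[Neighborhood]
    genes: list[GeneRecord]
    alpha: float = 0.05
    best_tns: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.best_tns is None:
            self.best_tns = best_tns_per_gene(self.neighborhoods, self.genes)


def total_neighborhood_score(
    anc: float, ss: float, p: float, alpha: float = 0.05
) -> float:
    """SS * ANC if p <= alpha (inclusive), else exactly 0."""
    if not (0.0 <= ss <= 1.0):
        raise ValueError(f"ss must be in [0, 1], got {ss}")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p}")
    if not (-1.0 <= anc <= 1.0):
        raise ValueError(f"anc must be in [-1, 1], got {anc}")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return ss * anc if p <= alpha else 0.0


def set_total_scores(
    windows: Sequence[Neighborhood], alpha: float = 0.05
) -> None:
    for w in windows:
        if w.anc is None or w.p_value is None or w.ss is None:
            raise ValueError("anc, p_value and ss must be set before TNS")
        w.tns = total_neighborhood_score(w.anc, w.ss, w.p_value, alpha)


def best_tns_per_gene(
    neighborhoods: Sequence[Neighborhood], genes: Sequence[GeneRecord]
) -> dict[str, float]:
    """Max TNS over all windows containing each gene; 0 when in none.

    This is the per-gene track value: the best score among every
    neighborhood the gene belongs to, regardless of window size.
    """
    best = {g.gene_id: 0.0 for g in genes}
    for w in neighborhoods:
        if w.tns is None:
            raise ValueError("TNS must be set before per-gene summarization")
        for g in w.member_gene_ids:
            if g in best and w.tns > best[g]:
                best[g] = w.tns
    return best


def select_nonredundant(
    neighborhoods: Sequence[Neighborhood], min_tns: float
) -> list[Neighborhood]:
    """Greedy gene-disjoint selection of top-scoring windows above min_tns.

    Repeatedly takes the highest-TNS remaining window (ties: more genes,
    then leftmost by chromosome and span start) and discards every window
    sharing a member gene with it.
    """
    candidates = [w for w in neighborhoods if w.tns is not None and w.tns > min_tns]
    candidates.sort(
        key=lambda w: (-w.tns, -w.size_genes, w.chrom, w.span_start, w.member_gene_ids)
    )
    chosen: list[Neighborhood] = []
    used: set[str] = set()
    for w in candidates:
        if used.isdisjoint(w.member_gene_ids):
            chosen.append(w)
            used.update(w.member_gene_ids)
    return chosen


_REPORT_COLUMNS = [
    "chrom",
    "span_start",
    "span_end",
    "size_mode",
    "size",
    "member_gene_ids",
    "anc",
    "p_value",
    "ss",
    "tns",
]


def write_report(scored: ScoredGenome, path: str) -> None:
    """Full neighborhood report TSV, deterministically ordered."""
    rows = sorted(
        scored.neighborhoods,
        key=lambda w: (w.chrom, w.span_start, w.size_genes, w.member_gene_ids),
    )
    with open(path, "w") as fh:
        fh.write("\t".join(_REPORT_COLUMNS) + "\n")
        for w in rows:
            size = w.size_genes if w.size_mode == "gene_count" else w.size_key
            fh.write(
                f"{w.chrom}\t{w.span_start}\t{w.span_end}\t{w.size_mode}\t{size}\t"
                f"{','.join(w.member_gene_ids)}\t"
                f"{w.anc:.6g}\t{w.p_value:.6g}\t{w.ss:.6g}\t{w.tns:.6g}\n"
            )


def write_custom_track(
    scored: ScoredGenome,
    path: str,
    name: str = "best_TNS",
    description: str = "Best associated Total Neighborhood Score per gene",
) -> None:
    """UCSC bedGraph custom track of each gene's best associated TNS."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}" description="{description}"\n')
        for g in sorted(scored.genes, key=lambda r: (r.chrom, r.start)):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{scored.best_tns[g.gene_id]:.6g}\n")


def write_tns_matrix(scored: ScoredGenome, path: str) -> None:
    """TNS-by-window-size matrix TSV for external heatmap rendering.

    Rows are genes in genome order, columns the window sizes; cell (g, W)
    holds the TNS of the size-W window whose first member is gene g
    (0 when no such window exists), so a heatmap of this matrix shows the
    score landscape across all sizes along each chromosome.
    """
    sizes = sorted({w.size_key for w in scored.neighborhoods})
    by_start: dict[tuple[str, str, int], float] = {}
    for w in scored.neighborhoods:
        by_start[(w.chrom, w.member_gene_ids[0], w.size_key)] = w.tns
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\t" + "\t".join(str(s) for s in sizes) + "\n")
        for g in sorted(scored.genes, key=lambda r: (r.chrom, r.start)):
            vals = [
                by_start.get((g.chrom, g.gene_id, s), 0.0) for s in sizes
            ]
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t"
                + "\t".join(f"{v:.6g}" for v in vals)
                + "\n"
            )
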