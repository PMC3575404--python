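"""Non-redundant gene set construction and silent-gene flagging.

Overlapping transcripts are collapsed to a single representative before
window enumeration: among overlapping transcripts, the one with the highest
expression survives, ties broken by length (longest wins), then by gene id.
Silent genes — those failing a minimum-detection or minimum-expression
criterion — are kept in the gene set but flagged, so that their pairwise
correlations can be zeroed rather than the genes discarded.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .data_model import ExpressionMatrix, GeneRecord


@dataclasses.dataclass(frozen=True)
class SilentPolicy:
    """How to decide a gene is silent.

    detection_calls mode: silent iff fewer than ``min_present_calls`` "P"
    flags across samples (microarray detection-call filtering).
    expression_threshold mode: silent iff the maximum expression over
    samples is strictly below ``min_max_expression`` (e.g. 0.2 RPKM for
    RNA-seq abundance).
    """

    mode: str  # "detection_calls" | "expression_threshold"
    min_present_calls: int = 12
    min_max_expression: float = 0.2

    def __post_init__(self) -> None:
        if self.mode not in ("detection_calls", "expression_threshold"):
            raise ValueError(f"unknown silent policy mode {self.mode!r}")
        if self.min_present_calls < 0 or self.min_max_expression < 0:
            raise ValueError("silent policy thresholds must be non-negative")


def _max_expr(gene: GeneRecord, expr: ExpressionMatrix) -> float:
    return float(expr.row(gene.gene_id).max())


def remove_overlapping_transcripts(
    genes: list[GeneRecord], expr: ExpressionMatrix
) -> list[GeneRecord]:
    """Collapse overlapping transcripts to a non-redundant gene set.

    Overlap groups are the connected components of the pairwise coordinate
    overlap graph (strand is ignored).  Within a group, selection is greedy:
    keep the transcript with the highest maximum expression (ties: longest,
    then lexicographically smallest id), drop everything overlapping it, and
    recurse on the remainder.  The result is idempotent and preserves
    genome order.
    """
    for g in genes:
        expr.row_index(g.gene_id)  # raises if a gene lacks an expression row

    survivors: list[GeneRecord] = []
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in sorted(genes, key=lambda r: (r.chrom, r.start, r.end, r.gene_id)):
        by_chrom.setdefault(g.chrom, []).append(g)

    for chrom_genes in by_chrom.values():
        # sweep: a connected overlap component is a maximal run where each
        # gene starts before the running max end of the genes before it
        component: list[GeneRecord] = []
        comp_end = -1
        for g in chrom_genes:
            if component and g.start >= comp_end:
                survivors.extend(_resolve_component(component, expr))
                component = []
                comp_end = -1
            component.append(g)
            comp_end = max(comp_end, g.end)
        if component:
            survivors.extend(_resolve_component(component, expr))

    survivors.sort(key=lambda r: (r.chrom, r.start, r.end, r.gene_id))
    return survivors


def _resolve_component(
    component: list[GeneRecord], expr: ExpressionMatrix
) -> list[GeneRecord]:
    if len(component) == 1:
        return component
    remaining = list(component)
    kept: list[GeneRecord] = []
    while remaining:
        best = max(
            remaining,
            key=lambda g: (_max_expr(g, expr), g.length, _NegStr(g.gene_id)),
        )
        kept.append(best)
        remaining = [
            g
            for g in remaining
            if g is not best and not (g.start < best.end and best.start < g.end)
        ]
    return kept


class _NegStr:
    """Orders strings descending under max(): smaller id wins ties."""

    __slots__ = ("s",)

    def __init__(self, s: str):
        self.s = s

    def __lt__(self, other: "_NegStr") -> bool:
        return self.s > other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _NegStr) and self.s == other.s


def flag_silent_genes(
    expr: ExpressionMatrix, policy: Optional[SilentPolicy] = None
) -> set[str]:
    """Return the ids of genes deemed silent under the policy.

    Both criteria use strict inequalities: a gene with exactly
    ``min_present_calls`` present calls, or maximum expression exactly at
    ``min_max_expression``, is not silent.
    """
    if policy is None:
        policy = SilentPolicy(mode="expression_threshold")
    if policy.mode == "detection_calls":
        if expr.detection is None:
            raise ValueError("detection_calls policy requires a detection matrix")
        n_present = (expr.detection == "P").sum(axis=1)
        silent = n_present < policy.min_present_calls
    else:
        silent = expr.values.max(axis=1) < policy.min_max_expression
    return {g for g, s in zip(expr.gene_ids, np.asarray(silent)) if s}
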