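"""Per-gene and per-pair annotations: Tau tissue specificity, adjacent-pair
orientation classes, and tandem-duplicate flags from protein alignment hits.

Tau here is the unnormalized tissue-specificity index

    Tau = sum_i (1 - x_i / max_j x_j)

over the N samples of a non-negative expression row: 0 for a gene
expressed equally everywhere, N - 1 for a gene expressed in exactly one
sample.  (The commonly used normalized variant divides by N - 1 and lives
in [0, 1]; this package keeps the 0..N-1 range.)  Tau expects linear-scale
non-negative values such as RPKM; de-log log2 intensities before calling.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Optional, Sequence

import numpy as np

from .data_model import ExpressionMatrix, GeneRecord

CO_ORIENTED = "co_oriented"
DIVERGENT = "divergent"
CONVERGENT = "convergent"

DUPLICATE_EVALUE_THRESHOLD = 1e-7


def tau(expr_row: Sequence[float]) -> float:
    """Unnormalized tissue-specificity index of a non-negative row."""
    x = np.asarray(expr_row, dtype=float)
    if (x < 0).any():
        raise ValueError("tau requires non-negative expression values")
    m = x.max()
    if m == 0:
        raise ValueError("tau is undefined for an all-zero expression row")
    return float(np.sum(1.0 - x / m))


def tau_table(expr: ExpressionMatrix) -> dict[str, float]:
    """Tau for every gene in the matrix."""
    return {g: tau(expr.values[i]) for i, g in enumerate(expr.gene_ids)}


@dataclasses.dataclass(frozen=True)
class OrientationClass:
    pair: tuple[str, str]
    orientation: str  # CO_ORIENTED | DIVERGENT | CONVERGENT


def classify_orientation(a: GeneRecord, b: GeneRecord) -> OrientationClass:
    """Orientation class of two adjacent non-overlapping genes, a before b.

    Same strand -> co-oriented (read-through possible); (-, +) -> divergent
    (head-to-head, potentially a shared bidirectional promoter); (+, -) ->
    convergent (tail-to-tail).
    """
    if a.chrom != b.chrom:
        raise ValueError(f"{a.gene_id} and {b.gene_id} are on different chromosomes")
    if a.start >= b.start:
        raise ValueError(f"{a.gene_id} must precede {b.gene_id}")
    if b.start < a.end:
        raise ValueError(f"{a.gene_id} and {b.gene_id} overlap")
    if a.strand == b.strand:
        cls = CO_ORIENTED
    elif a.strand == "-":
        cls = DIVERGENT
    else:
        cls = CONVERGENT
    return OrientationClass((a.gene_id, b.gene_id), cls)


def classify_adjacent_pairs(genes: Sequence[GeneRecord]) -> list[OrientationClass]:
    """Orientation classes for every adjacent pair of a non-redundant gene list."""
    out = []
    ordered = sorted(genes, key=lambda g: (g.chrom, g.start))
    for a, b in zip(ordered, ordered[1:]):
        if a.chrom == b.chrom:
            out.append(classify_orientation(a, b))
    return out


def read_blast_tabular(path: str) -> list[tuple[str, str, float]]:
    """(query, subject, evalue) triples from 12-column tabular BLAST output.

    Only columns 1, 2 and 11 are consumed.
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise ValueError(f"{path}:{lineno}: expected >= 11 columns")
            hits.append((fields[0], fields[1], float(fields[10])))
    return hits


def flag_duplicates(
    blast_hits: Iterable[tuple[str, str, float]],
    threshold: float = DUPLICATE_EVALUE_THRESHOLD,
    known_genes: Optional[set[str]] = None,
) -> set[frozenset[str]]:
    """Unordered gene pairs whose protein alignment e-value is < threshold.

    A pair is flagged when any hit in either direction beats the threshold;
    self-hits are ignored.  Hits naming genes outside ``known_genes`` (when
    given) are skipped with a warning.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    pairs: set[frozenset[str]] = set()
    for query, subject, evalue in blast_hits:
        if query == subject:
            continue
        if known_genes is not None and (
            query not in known_genes or subject not in known_genes
        ):
            warnings.warn(
                f"BLAST hit references unknown gene(s): {query!r}/{subject!r}; skipped",
                stacklevel=2,
            )
            continue
        if evalue < threshold:
            pairs.add(frozenset((query, subject)))
    return pairs


def drop_duplicate_partners(
    genes: Sequence[GeneRecord],
    duplicates: set[frozenset[str]],
    expr: ExpressionMatrix,
) -> list[GeneRecord]:
    """Remove one member of each duplicate pair (duplicate-free gene set).

    The lower-expressed member of each intact pair is removed (ties:
    shorter, then lexicographically larger id), iterating until no flagged
    pair has both members present.  In a chain A-B, B-C, removing the
    shared gene can satisfy both pairs with a single removal.
    """
    present = {g.gene_id: g for g in genes}

    def removal_key(gid: str) -> tuple:
        g = present[gid]
        return (float(expr.row(gid).max()), g.length, _neg_id(gid))

    while True:
        intact = [p for p in duplicates if all(gid in present for gid in p)]
        if not intact:
            break
        # remove the worst member among all intact pairs; recheck after each
        members = {gid for p in intact for gid in p}
        victim = min(members, key=removal_key)
        del present[victim]
    return [g for g in genes if g.gene_id in present]


def _neg_id(gid: str) -> tuple[int, ...]:
    # larger id sorts smaller, so min() removes the lexicographically larger id on ties
    return tuple(-ord(c) for c in gid)


def write_tau_tsv(taus: dict[str, float], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\ttau\n")
        for g in sorted(taus):
            fh.write(f"{g}\t{taus[g]:.6g}\n")


def write_orientation_tsv(classes: Sequence[OrientationClass], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\torientation\n")
        for oc in classes:
            fh.write(f"{oc.pair[0]}\t{oc.pair[1]}\t{oc.orientation}\n")
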