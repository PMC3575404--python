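"""Cross-species conservation scoring and a marker-anchor block builder.

A neighborhood occupies a span of base pairs on the reference genome.  It
counts as conserved in a comparison species when that whole span lies
inside a single unbroken syntenic block of that species — containment, not
mere overlap, because a span crossing a block boundary is by definition
broken in the other genome.  The Synteny Score (SS) of a neighborhood is
the fraction of comparison species in which it is conserved.

The block builder chains sorted marker anchors greedily: consecutive
anchors join one chain when they share reference and target chromosomes
and the gap on *both* genomes is at most ``max_gap``.  Chains shorter than
``num_mark`` anchors or spanning less than ``min_blk`` on the reference are
discarded.  Anchor orientation never breaks a chain (small local
inversions are tolerated); each block's orientation is the majority
orientation of its anchors.  This is a deliberately simple stand-in for a
full synteny engine — precomputed block files can be supplied instead.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

from .data_model import (
    Neighborhood,
    SyntenyBlock,
    SyntenyBlockSet,
    SyntenyParams,
)


@dataclasses.dataclass(frozen=True)
class MarkerAnchor:
    """One alignment marker between the reference and a target genome."""

    ref_chrom: str
    ref_pos: int
    tgt_chrom: str
    tgt_pos: int
    orientation: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.ref_pos < 0 or self.tgt_pos < 0:
            raise ValueError("anchor positions must be non-negative")
        if self.orientation not in ("+", "-"):
            raise ValueError(f"orientation must be '+' or '-', got {self.orientation!r}")


def is_conserved(
    span: tuple[str, int, int], blocks: SyntenyBlockSet
) -> bool:
    """True iff the span is contained within a single block's reference interval."""
    chrom, start, end = span
    return blocks.containing_block(chrom, start, end) is not None


def synteny_score(
    window: Neighborhood, all_blocks: Sequence[SyntenyBlockSet]
) -> float:
    """Fraction of comparison species conserving the window's span."""
    if not all_blocks:
        raise ValueError("at least one comparison species is required")
    span = (window.chrom, window.span_start, window.span_end)
    conserved = sum(1 for bs in all_blocks if is_conserved(span, bs))
    return conserved / len(all_blocks)


def set_synteny_scores(
    windows: Sequence[Neighborhood], all_blocks: Sequence[SyntenyBlockSet]
) -> None:
    for w in windows:
        w.ss = synteny_score(w, all_blocks)


def build_blocks(
    anchors: Sequence[MarkerAnchor],
    params: SyntenyParams = SyntenyParams(),
    species: str = "target",
) -> SyntenyBlockSet:
    """Chain marker anchors into non-overlapping syntenic blocks.

    After chaining and filtering, chains whose reference intervals overlap
    (possible when interleaved anchors map to different targets) are merged
    so the result satisfies the non-overlap invariant of a block set.
    """
    chains: list[list[MarkerAnchor]] = []
    for a in sorted(anchors, key=lambda m: (m.ref_chrom, m.ref_pos, m.tgt_pos)):
        if chains:
            prev = chains[-1][-1]
            if (
                a.ref_chrom == prev.ref_chrom
                and a.tgt_chrom == prev.tgt_chrom
                and a.ref_pos - prev.ref_pos <= params.max_gap
                and abs(a.tgt_pos - prev.tgt_pos) <= params.max_gap
            ):
                chains[-1].append(a)
                continue
        chains.append([a])

    surviving = [
        c
        for c in chains
        if len(c) >= params.num_mark
        and (c[-1].ref_pos - c[0].ref_pos) >= params.min_blk
    ]

    # merge chains overlapping on the reference so the block set invariant holds
    surviving.sort(key=lambda c: (c[0].ref_chrom, c[0].ref_pos))
    merged: list[list[MarkerAnchor]] = []
    for c in surviving:
        if (
            merged
            and merged[-1][0].ref_chrom == c[0].ref_chrom
            and c[0].ref_pos < max(a.ref_pos for a in merged[-1])
        ):
            merged[-1].extend(c)
        else:
            merged.append(list(c))

    blocks = []
    for chain in merged:
        ref_positions = [a.ref_pos for a in chain]
        # when a merge mixed target chromosomes, the majority target wins
        tgt_counts: dict[str, int] = {}
        for a in chain:
            tgt_counts[a.tgt_chrom] = tgt_counts.get(a.tgt_chrom, 0) + 1
        tgt_chrom = max(sorted(tgt_counts), key=lambda t: tgt_counts[t])
        tgt_positions = [a.tgt_pos for a in chain if a.tgt_chrom == tgt_chrom]
        n_plus = sum(1 for a in chain if a.orientation == "+")
        blocks.append(
            SyntenyBlock(
                ref_chrom=chain[0].ref_chrom,
                ref_start=min(ref_positions),
                ref_end=max(ref_positions),
                tgt_chrom=tgt_chrom,
                tgt_start=min(tgt_positions),
                tgt_end=max(tgt_positions),
                orientation="+" if n_plus * 2 >= len(chain) else "-",
            )
        )
    return SyntenyBlockSet(species, blocks)


def read_marker_anchors(path: str) -> list[MarkerAnchor]:
    """Read a five-column anchor TSV (ref_chrom, ref_pos, tgt_chrom, tgt_pos, orientation)."""
    anchors: list[MarkerAnchor] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("ref_chrom"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(fields)}")
            anchors.append(
                MarkerAnchor(
                    fields[0], int(fields[1]), fields[2], int(fields[3]), fields[4]
                )
            )
    return anchors
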