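"""Truth-labelled synthetic input bundles for end-to-end testing.

The generator emulates the shape of a tissue expression atlas over a small
reference genome: genes at non-overlapping positions along chromosomes,
a genes x samples expression table on a linear non-negative scale,
present/absent detection calls, per-comparison-species synteny-block
tables, and a protein-alignment hit table for duplicate flagging.

Co-expression uses a latent-factor model: each planted cluster's members
share a latent sample profile mixed with independent noise so that the
expected pairwise Spearman correlation approximates the configured target
(for jointly Gaussian scores with Pearson correlation r the Spearman value
is (6/pi)*asin(r/2), within 0.02 of r over the range used here; values are
exponentiated to a linear scale afterwards, which preserves ranks).
Background genes get independent noise profiles.  Synteny blocks are laid
out so a planted cluster's span is contained in one block for exactly its
configured number of conserving species, with a block boundary splitting
the span in every other species; background regions are conserved per
species with a configurable probability.  Everything is deterministic
under the configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import os
from typing import Optional

import numpy as np

from .data_model import (
    ExpressionMatrix,
    GeneRecord,
    SyntenyBlock,
    SyntenyBlockSet,
    write_gene_locations,
    write_synteny_blocks,
)
from .scoring import ScoredGenome

GENE_LENGTH = 10_000
GENE_SPACING = 50_000  # start-to-start distance; genes never overlap


@dataclasses.dataclass(frozen=True)
class PlantedCluster:
    """A run of consecutive genes sharing a latent expression profile."""

    chrom: str
    start_index: int  # position within the chromosome's gene list
    size: int
    target_rho: float = 0.9
    conserved_species: Optional[int] = None  # None => conserved in all species

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("a planted cluster needs at least 2 genes")
        if not (0.0 <= self.target_rho <= 1.0):
            raise ValueError("target_rho must be in [0, 1]")


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic bundle.

    Defaults mirror a small tissue-atlas-shaped experiment: 20 samples,
    tens of genes per chromosome, 9 comparison species, strong planted
    clusters (target Spearman 0.9), and background regions syntenic in
    most species (probability 0.7, matching the fraction of adjacent gene
    pairs conserved across all comparison genomes in real mammalian data).
    """

    n_chromosomes: int = 2
    genes_per_chrom: int = 40
    n_samples: int = 20
    planted_clusters: tuple[PlantedCluster, ...] = ()
    silent_fraction: float = 0.0
    n_species: int = 9
    background_conserved_prob: float = 0.7
    noise_sd: float = 1.0
    n_duplicate_pairs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.silent_fraction, self.background_conserved_prob):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must be in [0, 1]")
        for c in self.planted_clusters:
            if c.start_index + c.size > self.genes_per_chrom:
                raise ValueError(
                    f"cluster at {c.chrom}:{c.start_index}+{c.size} overflows "
                    f"a {self.genes_per_chrom}-gene chromosome"
                )
            if c.conserved_species is not None and not (
                0 <= c.conserved_species <= self.n_species
            ):
                raise ValueError("conserved_species out of range")


@dataclasses.dataclass
class TruthTable:
    """Ground truth matching one generated bundle."""

    cluster_members: list[list[str]]
    cluster_conserved_species: list[int]
    silent_genes: list[str]
    duplicate_pairs: list[tuple[str, str]]

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "cluster_members": self.cluster_members,
                    "cluster_conserved_species": self.cluster_conserved_species,
                    "silent_genes": self.silent_genes,
                    "duplicate_pairs": [list(p) for p in self.duplicate_pairs],
                },
                fh,
                indent=2,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path: str) -> "TruthTable":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            d["cluster_members"],
            d["cluster_conserved_species"],
            d["silent_genes"],
            [tuple(p) for p in d["duplicate_pairs"]],
        )


def _chrom_name(i: int) -> str:
    return f"chr{i + 1}"


def make_genes(config: SimConfig, rng: np.random.Generator) -> list[GeneRecord]:
    """Non-overlapping genes in genome order, alternating-ish strands."""
    genes = []
    for c in range(config.n_chromosomes):
        chrom = _chrom_name(c)
        for i in range(config.genes_per_chrom):
            start = i * GENE_SPACING
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneRecord(f"{chrom}_g{i:03d}", chrom, start, start + GENE_LENGTH, strand)
            )
    return genes


def make_expression(
    config: SimConfig, genes: list[GeneRecord], rng: np.random.Generator
) -> tuple[ExpressionMatrix, list[list[str]], list[str]]:
    """Latent-factor expression with planted clusters and silent genes."""
    n_genes = len(genes)
    n = config.n_samples
    scores = rng.normal(0.0, config.noise_sd, size=(n_genes, n))

    index = {g.gene_id: i for i, g in enumerate(genes)}
    by_chrom: dict[str, list[str]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g.gene_id)

    cluster_members: list[list[str]] = []
    for cluster in config.planted_clusters:
        ids = by_chrom[cluster.chrom][
            cluster.start_index : cluster.start_index + cluster.size
        ]
        cluster_members.append(list(ids))
        latent = rng.normal(0.0, 1.0, size=n)
        r = cluster.target_rho
        for gid in ids:
            i = index[gid]
            noise = rng.normal(0.0, 1.0, size=n)
            # Pearson corr between two members is exactly r by construction
            scores[i] = config.noise_sd * (
                np.sqrt(r) * latent + np.sqrt(1.0 - r) * noise
            )

    # linear non-negative scale; monotone, so Spearman targets survive
    values = np.exp2(scores + 4.0)

    planted = {gid for ids in cluster_members for gid in ids}
    eligible = [g.gene_id for g in genes if g.gene_id not in planted]
    n_silent = int(round(config.silent_fraction * n_genes))
    silent = sorted(rng.choice(eligible, size=min(n_silent, len(eligible)), replace=False))
    detection = np.full((n_genes, n), "P", dtype=object)
    for gid in silent:
        i = index[gid]
        values[i] = rng.uniform(0.0, 0.1, size=n)  # below the 0.2 silence threshold
        detection[i] = "A"

    expr = ExpressionMatrix(
        [g.gene_id for g in genes],
        [f"sample_{j:02d}" for j in range(n)],
        values,
        detection,
    )
    return expr, cluster_members, list(silent)


def make_block_sets(
    config: SimConfig, genes: list[GeneRecord], rng: np.random.Generator
) -> list[SyntenyBlockSet]:
    """Per-species block sets encoding the configured conservation pattern.

    Each chromosome is cut into segments at breakpoints: a mandatory
    breakpoint inside every planted cluster's span for species that do not
    conserve it, and random background breakpoints between genes with
    probability 1 - background_conserved_prob, never inside a conserved
    cluster span.  Segments map to consecutive target coordinates, giving
    non-overlapping blocks by construction.
    """
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    cluster_ranges: dict[str, list[tuple[int, int, int]]] = {}  # chrom -> (lo, hi, n_conserving)
    for cluster in config.planted_clusters:
        k = (
            cluster.conserved_species
            if cluster.conserved_species is not None
            else config.n_species
        )
        cluster_ranges.setdefault(cluster.chrom, []).append(
            (cluster.start_index, cluster.start_index + cluster.size - 1, k)
        )

    block_sets = []
    for s in range(config.n_species):
        species = f"species_{s + 1:02d}"
        blocks: list[SyntenyBlock] = []
        for chrom, chrom_genes in by_chrom.items():
            n = len(chrom_genes)
            protected = set()  # inter-gene gaps that must stay unbroken
            forced = set()  # gaps that must break
            for lo, hi, k in cluster_ranges.get(chrom, []):
                gaps = range(lo, hi)  # gap i sits between gene i and i+1
                if s < k:
                    protected.update(gaps)
                else:
                    forced.update(gaps)  # break every within-cluster adjacency
            cuts = []
            for gap in range(n - 1):
                if gap in forced:
                    cuts.append(gap)
                elif gap not in protected and rng.random() > config.background_conserved_prob:
                    cuts.append(gap)
            seg_start_gene = 0
            tgt_offset = 0
            for cut in cuts + [n - 1]:
                seg_genes = chrom_genes[seg_start_gene : cut + 1]
                ref_start = max(0, seg_genes[0].start - GENE_SPACING // 4)
                ref_end = seg_genes[-1].end + GENE_SPACING // 4
                length = ref_end - ref_start
                blocks.append(
                    SyntenyBlock(
                        chrom,
                        ref_start,
                        ref_end,
                        f"t{chrom}",
                        tgt_offset,
                        tgt_offset + length,
                        "+" if rng.random() < 0.9 else "-",
                    )
                )
                tgt_offset += length + 10_000
                seg_start_gene = cut + 1
        block_sets.append(SyntenyBlockSet(species, blocks))
    return block_sets


def make_blast_hits(
    config: SimConfig, genes: list[GeneRecord], rng: np.random.Generator
) -> list[tuple[str, str, float]]:
    """Synthetic protein-alignment hits marking adjacent duplicate pairs."""
    hits = []
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    pairs_made = 0
    for chrom_genes in by_chrom.values():
        for a, b in zip(chrom_genes, chrom_genes[1:]):
            if pairs_made >= config.n_duplicate_pairs:
                break
            hits.append((a.gene_id, b.gene_id, float(10.0 ** rng.uniform(-50, -8))))
            pairs_made += 1
    return hits


def generate_dataset(
    config: SimConfig, out_dir: Optional[str] = None
) -> tuple[dict, TruthTable]:
    """Generate one complete input bundle; optionally write it to disk.

    Returns (bundle, truth).  The bundle dict holds the in-memory objects
    (genes, expr, block_sets, blast_hits); when ``out_dir`` is given the
    same content is written as the plain-text files the pipeline reads
    (genes.bed, expression.tsv, detection.tsv, blocks/<species>.tsv,
    blast_hits.tsv, truth.json), byte-identical for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    genes = make_genes(config, rng)
    expr, cluster_members, silent = make_expression(config, genes, rng)
    block_sets = make_block_sets(config, genes, rng)
    blast_hits = make_blast_hits(config, genes, rng)

    truth = TruthTable(
        cluster_members=cluster_members,
        cluster_conserved_species=[
            c.conserved_species if c.conserved_species is not None else config.n_species
            for c in config.planted_clusters
        ],
        silent_genes=silent,
        duplicate_pairs=[(a, b) for a, b, _ in blast_hits],
    )
    bundle = {
        "genes": genes,
        "expr": expr,
        "block_sets": block_sets,
        "blast_hits": blast_hits,
    }

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_gene_locations(genes, os.path.join(out_dir, "genes.bed"))
        _write_expression(expr, out_dir)
        blocks_dir = os.path.join(out_dir, "blocks")
        os.makedirs(blocks_dir, exist_ok=True)
        for bs in block_sets:
            write_synteny_blocks(bs, os.path.join(blocks_dir, f"{bs.species}.tsv"))
        with open(os.path.join(out_dir, "blast_hits.tsv"), "w") as fh:
            for q, t, e in blast_hits:
                dummy = "\t".join(["0"] * 8)
                fh.write(f"{q}\t{t}\t{dummy}\t{e:.3g}\t0\n")
        truth.to_json(os.path.join(out_dir, "truth.json"))
    return bundle, truth


def _write_expression(expr: ExpressionMatrix, out_dir: str) -> None:
    header = "gene_id\t" + "\t".join(expr.sample_ids) + "\n"
    with open(os.path.join(out_dir, "expression.tsv"), "w") as fh:
        fh.write(header)
        for gid, row in zip(expr.gene_ids, expr.values):
            fh.write(gid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
    if expr.detection is not None:
        with open(os.path.join(out_dir, "detection.tsv"), "w") as fh:
            fh.write(header)
            for gid, row in zip(expr.gene_ids, expr.detection):
                fh.write(gid + "\t" + "\t".join(row) + "\n")


def recovery_report(
    truth: TruthTable, scored: ScoredGenome, min_tns: float
) -> dict:
    """Planted-cluster recovery and background false positives.

    A cluster is recovered when some window with TNS > min_tns shares at
    least half its members with the cluster.  Background false positives
    are windows above the threshold containing no planted gene at all.
    """
    planted = {g for members in truth.cluster_members for g in members}
    recovered = []
    for members in truth.cluster_members:
        member_set = set(members)
        hit = any(
            w.tns is not None
            and w.tns > min_tns
            and len(member_set & set(w.member_gene_ids)) >= 0.5 * len(member_set)
            for w in scored.neighborhoods
        )
        recovered.append(hit)
    fp = sum(
        1
        for w in scored.neighborhoods
        if w.tns is not None
        and w.tns > min_tns
        and not planted & set(w.member_gene_ids)
    )
    return {
        "clusters_recovered": recovered,
        "n_recovered": sum(recovered),
        "n_clusters": len(recovered),
        "background_false_positives": fp,
    }
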