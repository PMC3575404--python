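import numpy as np
import pytest

from gnest.data_model import ExpressionMatrix, GeneRecord, SyntenyBlock, SyntenyBlockSet


@pytest.fixture
def four_genes():
    return [
        GeneRecord("geneA", "chr1", 0, 10_000, "+"),
        GeneRecord("geneB", "chr1", 50_000, 60_000, "+"),
        GeneRecord("geneC", "chr1", 100_000, 110_000, "-"),
        GeneRecord("geneD", "chr1", 150_000, 160_000, "+"),
    ]


@pytest.fixture
def small_expr(four_genes):
    rng = np.random.default_rng(7)
    return ExpressionMatrix(
        [g.gene_id for g in four_genes],
        [f"s{i}" for i in range(6)],
        rng.uniform(1.0, 100.0, size=(4, 6)),
    )


def make_block_set(species, intervals, chrom="chr1"):
    """Block set from (ref_start, ref_end) pairs on one reference chromosome."""
    blocks = [
        SyntenyBlock(chrom, s, e, "tchr1", 10 * s, 10 * e, "+")
        for s, e in intervals
    ]
    return SyntenyBlockSet(species, blocks)
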