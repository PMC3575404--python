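import itertools

import numpy as np
import pytest

from gnest.correlation import pairwise_spearman
from gnest.data_model import GeneRecord
from gnest.windows import (
    WindowSpec,
    compute_all_ancs,
    compute_anc,
    enumerate_bp_windows,
    enumerate_gene_windows,
)


def genes_on(chrom, n, spacing=50_000, length=10_000, start0=0):
    return [
        GeneRecord(f"{chrom}_g{i:02d}", chrom, start0 + i * spacing,
                   start0 + i * spacing + length, "+")
        for i in range(n)
    ]


def brute_force_gene_windows(genes, min_size, max_size):
    """Oracle: all consecutive runs of each size, per chromosome."""
    out = set()
    by_chrom = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom_genes in by_chrom.values():
        for w in range(min_size, max_size + 1):
            for i in range(len(chrom_genes) - w + 1):
                out.add(tuple(g.gene_id for g in chrom_genes[i : i + w]))
    return out


class TestEnumerateGeneWindows:
    def test_abcd_example(self):
        genes = genes_on("chr1", 4)
        wins = enumerate_gene_windows(genes, WindowSpec("gene_count", 2, 4))
        members = {w.member_gene_ids for w in wins}
        g = [x.gene_id for x in genes]
        assert members == {
            (g[0], g[1]), (g[0], g[1], g[2]), (g[0], g[1], g[2], g[3]),
            (g[1], g[2]), (g[1], g[2], g[3]), (g[2], g[3]),
        }

    def test_count_formula(self):
        genes = genes_on("chr1", 5)
        wins = enumerate_gene_windows(genes, WindowSpec("gene_count", 2, 2))
        assert len(wins) == 4

    def test_sizes_clipped_at_chromosome_length(self):
        genes = genes_on("chr1", 3)
        wins = enumerate_gene_windows(genes, WindowSpec("gene_count", 2, 5))
        assert {w.member_gene_ids for w in wins} == brute_force_gene_windows(genes, 2, 3)

    def test_windows_never_span_chromosomes(self):
        genes = genes_on("chr1", 3) + genes_on("chr2", 3)
        wins = enumerate_gene_windows(genes, WindowSpec("gene_count", 2, 6))
        for w in wins:
            assert len({gid.split("_")[0] for gid in w.member_gene_ids}) == 1

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(2, 31))
            lo = int(rng.integers(2, 5))
            hi = int(rng.integers(lo, 11))
            genes = genes_on("chr1", n)
            wins = enumerate_gene_windows(genes, WindowSpec("gene_count", lo, hi))
            assert {w.member_gene_ids for w in wins} == brute_force_gene_windows(genes, lo, hi)
            expected_count = sum(max(0, n - w + 1) for w in range(lo, hi + 1))
            assert len(wins) == expected_count

    def test_span_covers_member_extent(self):
        genes = genes_on("chr1", 3)
        (win,) = enumerate_gene_windows(genes, WindowSpec("gene_count", 3, 3))
        assert win.span_start == genes[0].start
        assert win.span_end == genes[2].end


class TestEnumerateBpWindows:
    def test_budget_excludes_distant_gene(self):
        genes = [
            GeneRecord("g1", "chr1", 0, 10_000, "+"),
            GeneRecord("g2", "chr1", 20_000, 30_000, "+"),
            GeneRecord("g3", "chr1", 1_000_000, 1_010_000, "+"),
        ]
        wins = enumerate_bp_windows(genes, [100_000])
        assert {w.member_gene_ids for w in wins} == {("g1", "g2")}

    def test_too_small_budget_gives_nothing(self):
        genes = genes_on("chr1", 4)  # any 2-gene span is 60 kb
        assert enumerate_bp_windows(genes, [10_000]) == []

    def test_single_gene_chromosome_contributes_nothing(self):
        genes = genes_on("chr1", 1)
        assert enumerate_bp_windows(genes, [10**9]) == []

    def test_duplicate_runs_scored_once_with_all_sizes(self):
        genes = genes_on("chr1", 3)  # full span 110 kb
        wins = enumerate_bp_windows(genes, [200_000, 500_000])
        full = [w for w in wins if len(w.member_gene_ids) == 3]
        assert len(full) == 1
        assert set((full[0].size_key, *full[0].extra_size_keys)) == {200_000, 500_000}

    def test_maximal_run_within_budget(self):
        genes = genes_on("chr1", 5)  # spans: 2 genes 60k, 3 genes 110k, ...
        wins = enumerate_bp_windows(genes, [120_000])
        sizes = {w.member_gene_ids for w in wins}
        # each start takes the longest run <= 120 kb: 3 genes from starts 0..2
        ids = [g.gene_id for g in genes]
        assert tuple(ids[0:3]) in sizes
        assert tuple(ids[0:2]) not in sizes  # not maximal from start 0


def corr_for(genes, rho_map):
    """CorrelationMatrix with prescribed off-diagonal entries."""
    ids = [g.gene_id for g in genes]
    n = len(ids)
    rho = np.eye(n)
    for (a, b), v in rho_map.items():
        i, j = ids.index(a), ids.index(b)
        rho[i, j] = rho[j, i] = v
    from gnest.correlation import CorrelationMatrix

    return CorrelationMatrix(ids, rho, np.zeros(n, dtype=bool))


class TestAnc:
    def test_three_gene_mean(self):
        genes = genes_on("chr1", 3)
        ids = [g.gene_id for g in genes]
        corr = corr_for(
            genes,
            {(ids[0], ids[1]): 0.6, (ids[1], ids[2]): 0.3, (ids[0], ids[2]): 0.9},
        )
        (win,) = enumerate_gene_windows(genes, WindowSpec("gene_count", 3, 3))
        assert compute_anc(win, corr) == pytest.approx(0.6)

    def test_pair_window_is_single_rho(self):
        genes = genes_on("chr1", 2)
        ids = [g.gene_id for g in genes]
        corr = corr_for(genes, {(ids[0], ids[1]): 0.42})
        (win,) = enumerate_gene_windows(genes, WindowSpec("gene_count", 2, 2))
        assert compute_anc(win, corr) == pytest.approx(0.42)

    def test_missing_member_is_error(self):
        genes = genes_on("chr1", 2)
        corr = corr_for(genes_on("chr2", 2), {})
        (win,) = enumerate_gene_windows(genes, WindowSpec("gene_count", 2, 2))
        with pytest.raises(KeyError):
            compute_anc(win, corr)

    def test_incremental_matches_brute_force(self):
        """200 random instances: incremental ANC equals the all-pairs mean to 1e-12."""
        rng = np.random.default_rng(23)
        for _ in range(200):
            n = int(rng.integers(3, 31))
            genes = genes_on("chr1", n)
            values = rng.normal(size=(n, 6))
            corr = pairwise_spearman(values, [g.gene_id for g in genes])
            hi = int(rng.integers(2, 11))
            wins = enumerate_gene_windows(genes, WindowSpec("gene_count", 2, hi))
            compute_all_ancs(wins, {"chr1": corr})
            for w in wins:
                pairs = list(itertools.combinations(w.member_gene_ids, 2))
                brute = np.mean([corr.value(a, b) for a, b in pairs])
                assert w.anc == pytest.approx(brute, abs=1e-12)
                lo_b = min(corr.value(a, b) for a, b in pairs)
                hi_b = max(corr.value(a, b) for a, b in pairs)
                assert lo_b - 1e-12 <= w.anc <= hi_b + 1e-12

    def test_identical_profiles_anc_one(self):
        genes = genes_on("chr1", 4)
        values = np.tile(np.array([1.0, 3.0, 2.0, 5.0, 4.0]), (4, 1))
        corr = pairwise_spearman(values, [g.gene_id for g in genes])
        wins = enumerate_gene_windows(genes, WindowSpec("gene_count", 2, 4))
        compute_all_ancs(wins, {"chr1": corr})
        assert all(w.anc == pytest.approx(1.0) for w in wins)

    def test_all_silent_chromosome_anc_zero(self):
        genes = genes_on("chr1", 4)
        rng = np.random.default_rng(1)
        corr = pairwise_spearman(
            rng.normal(size=(4, 6)),
            [g.gene_id for g in genes],
            silent={g.gene_id for g in genes},
        )
        wins = enumerate_gene_windows(genes, WindowSpec("gene_count", 2, 4))
        compute_all_ancs(wins, {"chr1": corr})
        assert all(w.anc == 0.0 for w in wins)
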