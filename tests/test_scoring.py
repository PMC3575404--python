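import numpy as np
import pytest

from gnest.data_model import GeneRecord, Neighborhood
from gnest.scoring import (
    ScoredGenome,
    best_tns_per_gene,
    select_nonredundant,
    total_neighborhood_score,
    write_custom_track,
    write_report,
    write_tns_matrix,
)


def window(members, chrom="chr1", start=0, end=10_000, start_index=0, **scores):
    w = Neighborhood(
        chrom=chrom,
        member_gene_ids=tuple(members),
        span_start=start,
        span_end=end,
        size_mode="gene_count",
        size_key=len(members),
        start_index=start_index,
    )
    for k, v in scores.items():
        setattr(w, k, v)
    return w


class TestTotalNeighborhoodScore:
    def test_product_when_significant(self):
        assert total_neighborhood_score(0.5, 0.78, 0.01) == pytest.approx(0.39)

    def test_gated_to_zero_above_alpha(self):
        assert total_neighborhood_score(0.9, 1.0, 0.06) == 0.0

    def test_gate_is_inclusive_at_alpha(self):
        assert total_neighborhood_score(0.9, 1.0, 0.05) == pytest.approx(0.9)

    def test_magnitude_bounded_by_ss(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            anc = float(rng.uniform(-1, 1))
            ss = float(rng.uniform(0, 1))
            p = float(rng.uniform(0, 1))
            tns = total_neighborhood_score(anc, ss, p)
            assert abs(tns) <= ss
            if p > 0.05:
                assert tns == 0.0

    @pytest.mark.parametrize(
        "anc,ss,p", [(2.0, 0.5, 0.01), (0.5, 1.5, 0.01), (0.5, 0.5, -0.1)]
    )
    def test_out_of_range_inputs_rejected(self, anc, ss, p):
        with pytest.raises(ValueError):
            total_neighborhood_score(anc, ss, p)


class TestBestTnsPerGene:
    def test_maximum_over_containing_windows(self):
        genes = [GeneRecord("A", "chr1", 0, 10, "+"), GeneRecord("B", "chr1", 20, 30, "+")]
        wins = [
            window(["A", "B"], tns=0.0),
            window(["A", "B"], tns=0.3),
            window(["A", "B"], tns=0.41),
        ]
        best = best_tns_per_gene(wins, genes)
        assert best == {"A": 0.41, "B": 0.41}

    def test_gene_in_no_window_gets_zero(self):
        genes = [GeneRecord("A", "chr1", 0, 10, "+"), GeneRecord("Z", "chr9", 0, 10, "+")]
        best = best_tns_per_gene([window(["A", "B"], tns=0.5)], genes)
        assert best["Z"] == 0.0

    def test_every_best_value_attained_by_a_window(self):
        rng = np.random.default_rng(3)
        genes = [GeneRecord(f"g{i}", "chr1", i * 100, i * 100 + 50, "+") for i in range(10)]
        wins = [
            window([f"g{i}", f"g{i+1}"], start_index=i, tns=float(rng.uniform(0, 1)))
            for i in range(9)
        ]
        best = best_tns_per_gene(wins, genes)
        tns_values = {w.tns for w in wins} | {0.0}
        assert set(best.values()) <= tns_values


class TestSelectNonredundant:
    def test_overlapping_keeps_higher(self):
        wins = [window(["A", "B"], tns=0.5), window(["B", "C"], tns=0.4)]
        sel = select_nonredundant(wins, 0.0)
        assert [w.tns for w in sel] == [0.5]

    def test_disjoint_keeps_both(self):
        wins = [window(["A", "B"], tns=0.5), window(["C", "D"], tns=0.4)]
        assert len(select_nonredundant(wins, 0.0)) == 2

    def test_all_below_threshold_empty(self):
        wins = [window(["A", "B"], tns=0.1)]
        assert select_nonredundant(wins, 0.3) == []

    def test_result_pairwise_gene_disjoint(self):
        rng = np.random.default_rng(8)
        wins = []
        for i in range(30):
            start = int(rng.integers(0, 40))
            size = int(rng.integers(2, 5))
            wins.append(
                window(
                    [f"g{j}" for j in range(start, start + size)],
                    start_index=start,
                    tns=float(rng.uniform(0, 1)),
                )
            )
        sel = select_nonredundant(wins, 0.2)
        seen: set[str] = set()
        for w in sel:
            assert seen.isdisjoint(w.member_gene_ids)
            seen.update(w.member_gene_ids)


class TestWriters:
    @staticmethod
    def scored_genome():
        genes = [
            GeneRecord("A", "chr1", 0, 10_000, "+"),
            GeneRecord("B", "chr1", 20_000, 30_000, "-"),
            GeneRecord("C", "chr1", 40_000, 50_000, "+"),
        ]
        wins = [
            window(["A", "B"], end=30_000, anc=0.8, p_value=0.01, ss=0.5, tns=0.4),
            window(["B", "C"], start=20_000, end=50_000, start_index=1,
                   anc=0.1, p_value=0.5, ss=1.0, tns=0.0),
            window(["A", "B", "C"], end=50_000, anc=0.3, p_value=0.04, ss=1.0, tns=0.3),
        ]
        return ScoredGenome(neighborhoods=wins, genes=genes)

    def test_report_rows_and_determinism(self, tmp_path):
        scored = self.scored_genome()
        p1, p2 = tmp_path / "r1.tsv", tmp_path / "r2.tsv"
        write_report(scored, str(p1))
        write_report(scored, str(p2))
        lines = p1.read_text().splitlines()
        assert len(lines) == 1 + len(scored.neighborhoods)
        assert lines[0].split("\t")[:3] == ["chrom", "span_start", "span_end"]
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_genome_header_only(self, tmp_path):
        scored = ScoredGenome(neighborhoods=[], genes=[])
        path = tmp_path / "empty.tsv"
        write_report(scored, str(path))
        assert len(path.read_text().splitlines()) == 1

    def test_bedgraph_values_are_best_tns(self, tmp_path):
        scored = self.scored_genome()
        path = tmp_path / "track.bedGraph"
        write_custom_track(scored, str(path))
        lines = path.read_text().splitlines()
        assert lines[0].startswith("track type=bedGraph")
        values = {l.split("\t")[0:1][0]: float(l.split("\t")[3]) for l in lines[1:]}
        # gene A: best of {0.4, 0.3}; gene C: best of {0.0, 0.3}
        data = [l.split("\t") for l in lines[1:]]
        assert float(data[0][3]) == pytest.approx(0.4)
        assert float(data[2][3]) == pytest.approx(0.3)

    def test_tns_matrix_dimensions(self, tmp_path):
        scored = self.scored_genome()
        path = tmp_path / "matrix.tsv"
        write_tns_matrix(scored, str(path))
        lines = path.read_text().splitlines()
        sizes = lines[0].split("\t")[2:]
        assert len(lines) == 1 + len(scored.genes)
        assert sizes == ["2", "3"]
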