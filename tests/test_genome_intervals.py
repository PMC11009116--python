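import numpy as np
import pytest

from crekit import genome_intervals as gi
from crekit.genome_intervals import BinGrid, IntervalError
from crekit.screen_io import GenomicInterval
from crekit.strand_bias import GeneModel

from conftest import make_guide


def iv(start, end, chrom="chr1", name=None):
    return GenomicInterval(chrom, start, end, name=name)


class TestBinGrid:
    def test_worked_examples(self):
        grid = BinGrid()
        bins = grid.bins_overlapping(iv(850, 1153))
        assert [(b.start, b.end) for b in bins] == [
            (800, 900), (900, 1000), (1000, 1100), (1100, 1200)
        ]
        assert [(b.start, b.end) for b in grid.bins_overlapping(iv(100, 200))] == [
            (100, 200)
        ]
        assert [(b.start, b.end) for b in grid.bins_overlapping(iv(199, 201))] == [
            (100, 200), (200, 300)
        ]

    def test_every_bin_truly_overlaps(self):
        grid = BinGrid(bin_size=37)
        rng = np.random.default_rng(0)
        for _ in range(200):
            s = int(rng.integers(0, 5000))
            e = s + int(rng.integers(1, 400))
            interval = iv(s, e)
            bins = grid.bins_overlapping(interval)
            assert all(b.overlaps(interval) for b in bins)
            # and no neighbouring bin outside the returned range overlaps
            covered = sum(min(e, b.end) - max(s, b.start) for b in bins)
            assert covered == e - s

    def test_library_upstream_anchor(self):
        grid = BinGrid(anchor="library_upstream", anchor_positions={"chr1": 250})
        bins = grid.bins_overlapping(iv(250, 450))
        assert [(b.start, b.end) for b in bins] == [(250, 350), (350, 450)]
        with pytest.raises(KeyError):
            grid.bins_overlapping(iv(0, 10, chrom="chr2"))

    def test_validation(self):
        with pytest.raises(IntervalError):
            BinGrid(bin_size=0)
        with pytest.raises(IntervalError):
            BinGrid(anchor="midpoint")


class TestFootprint:
    def test_widths(self):
        g = make_guide(pam_start=1000)
        assert (gi.expand_footprint(g, "cas9").start,
                gi.expand_footprint(g, "cas9").end) == (990, 1013)
        fp = gi.expand_footprint(g, "dcas9_krab")
        assert (fp.start, fp.end) == (850, 1153)

    def test_clamped_at_zero(self):
        g = make_guide(pam_start=5)
        fp = gi.expand_footprint(g, "dcas9_krab")
        assert fp.start == 0

    def test_unknown_modality(self):
        with pytest.raises(IntervalError):
            gi.expand_footprint(make_guide(), "base_editor")


def _brute_force_coverage(intervals):
    bases = set()
    for v in intervals:
        for p in range(v.start, v.end):
            bases.add((v.chrom, p))
    return bases


class TestMergeAndJaccard:
    def test_merge_gap_semantics(self):
        merged, bp = gi.merge_intervals([iv(0, 100), iv(101, 200)], max_gap=1)
        assert [(m.start, m.end) for m in merged] == [(0, 200)]
        assert bp == 200
        merged, bp = gi.merge_intervals([iv(0, 100), iv(102, 200)], max_gap=1)
        assert len(merged) == 2 and bp == 198

    def test_merge_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            ivs = [
                iv(s, s + int(rng.integers(1, 30)), chrom=f"chr{rng.integers(1, 3)}")
                for s in rng.integers(0, 300, size=12)
            ]
            merged, bp = gi.merge_intervals(ivs, max_gap=0)
            assert bp == len(_brute_force_coverage(ivs))
            keys = [(m.chrom, m.start) for m in merged]
            assert keys == sorted(keys)
            for a, b in zip(merged, merged[1:]):
                if a.chrom == b.chrom:
                    assert b.start > a.end  # disjoint after merging

    def test_jaccard(self):
        a = [iv(0, 100)]
        assert gi.jaccard_similarity(a, a) == 1.0
        assert gi.jaccard_similarity(a, [iv(200, 300)]) == 0.0
        assert gi.jaccard_similarity([], []) == 0.0
        assert gi.jaccard_similarity([iv(0, 100)], [iv(50, 150)]) == pytest.approx(
            50 / 150
        )

    def test_jaccard_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = [iv(s, s + int(rng.integers(1, 40))) for s in rng.integers(0, 200, 6)]
            b = [iv(s, s + int(rng.integers(1, 40))) for s in rng.integers(0, 200, 6)]
            ca, cb = _brute_force_coverage(a), _brute_force_coverage(b)
            expected = len(ca & cb) / len(ca | cb)
            assert gi.jaccard_similarity(a, b) == pytest.approx(expected)

    def test_genome_fraction(self):
        assert gi.genome_fraction(3_088_269_832) == pytest.approx(1.0)
        assert gi.genome_fraction(308_826_983) == pytest.approx(0.1, rel=1e-6)


class TestTileAndAssign:
    def test_multi_bin_intervals_contribute_to_each(self):
        grid = BinGrid()
        assignment = gi.tile_and_assign([iv(150, 350, name="a"), iv(160, 180, name="b")], grid)
        assert assignment[("chr1", 100, 200)] == ["a", "b"]
        assert assignment[("chr1", 200, 300)] == ["a"]
        assert assignment[("chr1", 300, 400)] == ["a"]


class TestOverlapEnrichment:
    @staticmethod
    def _universe_with_table(n_hit_feat, n_hit_only, n_nohit_feat, n_nohit_only):
        universe, hits, features = [], [], []
        pos = 0
        for count, is_hit, has_feat in [
            (n_hit_feat, True, True),
            (n_hit_only, True, False),
            (n_nohit_feat, False, True),
            (n_nohit_only, False, False),
        ]:
            for _ in range(count):
                region = iv(pos, pos + 5)
                universe.append(region)
                if is_hit:
                    hits.append(region)
                if has_feat:
                    features.append(region)
                pos += 10
        return features, hits, universe

    def test_worked_odds_ratio(self):
        features, hits, universe = self._universe_with_table(20, 80, 5, 95)
        odds, p, table = gi.overlap_enrichment(features, hits, universe)
        assert table == [[20, 80], [5, 95]]
        assert odds == pytest.approx((20 * 95) / (80 * 5))  # 4.75
        assert 0 < p < 1

    def test_hits_equal_universe_gives_infinite_or(self):
        features, hits, universe = self._universe_with_table(20, 80, 0, 0)
        odds, _, _ = gi.overlap_enrichment(features, hits, universe)
        assert odds == float("inf")

    def test_degenerate_inputs_raise(self):
        features, hits, universe = self._universe_with_table(20, 80, 5, 95)
        with pytest.raises(IntervalError, match="universe"):
            gi.overlap_enrichment(features, hits, [])
        with pytest.raises(IntervalError, match="features"):
            gi.overlap_enrichment([iv(10**6, 10**6 + 5)], hits, universe)


class TestSameTad:
    gene = GeneModel("g", "chr1", "+", tss=5000, tes=9000)
    tads = [iv(0, 10_000), iv(20_000, 30_000)]

    def test_same_different_excluded(self):
        assert gi.same_tad(iv(2000, 2100), self.gene, self.tads) == "same"
        assert gi.same_tad(iv(21_000, 21_100), self.gene, self.tads) == "different"
        assert gi.same_tad(iv(15_000, 15_100), self.gene, self.tads) == "cre_not_in_tad"

    def test_overlapping_tads_rejected(self):
        with pytest.raises(IntervalError, match="overlapping"):
            gi.same_tad(iv(100, 200), self.gene, [iv(0, 10_000), iv(9000, 20_000)])
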