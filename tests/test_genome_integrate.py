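"""Interval algebra and the candidate-gene evidence filter.

The independent oracle for all interval geometry is a per-base boolean scan
over a 100 kb toy genome (conftest helpers).
"""

import numpy as np
import pytest

from epimark import genome_integrate as gi
from epimark.genome_integrate import GenomicInterval

from conftest import coverage_mask, mask_to_intervals, random_track


def iv(start, end, chrom="chr1", name="."):
    return GenomicInterval(chrom, start, end, name)


class TestGenomicInterval:
    def test_rejects_degenerate(self):
        with pytest.raises(ValueError):
            iv(20, 10)
        with pytest.raises(ValueError):
            iv(5, 5)
        with pytest.raises(ValueError):
            iv(-1, 5)

    def test_gap_and_overlap(self):
        assert iv(10, 20).overlaps(iv(19, 30))
        assert not iv(10, 20).overlaps(iv(20, 30))  # half-open adjacency
        assert iv(10, 20).gap_to(iv(25, 30)) == 5
        assert iv(10, 20).gap_to(iv(15, 30)) == 0


class TestIntersectTracks:
    def test_basic_overlap(self):
        out = gi.intersect_tracks([iv(10, 20)], [iv(15, 30)])
        assert [(o.start, o.end) for o in out] == [(15, 20)]

    def test_half_open_adjacency_is_empty(self):
        assert gi.intersect_tracks([iv(10, 20)], [iv(20, 30)]) == []

    def test_empty_inputs(self):
        assert gi.intersect_tracks([], [iv(0, 5)]) == []
        assert gi.intersect_tracks([iv(0, 5)], []) == []

    def test_matches_per_base_oracle_on_random_tracks(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            a = random_track(rng, n=200, max_len=1_000)
            b = random_track(rng, n=200, max_len=1_000)
            got = [(o.start, o.end) for o in gi.intersect_tracks(a, b)]
            expected = mask_to_intervals(coverage_mask(a) & coverage_mask(b))
            assert got == expected

    def test_commutative_and_idempotent(self):
        rng = np.random.default_rng(7)
        a = random_track(rng, n=30)
        b = random_track(rng, n=30)
        ab = [(o.start, o.end) for o in gi.intersect_tracks(a, b)]
        ba = [(o.start, o.end) for o in gi.intersect_tracks(b, a)]
        assert ab == ba
        aa = [(o.start, o.end) for o in gi.intersect_tracks(a, a)]
        merged = [(o.start, o.end) for o in gi.merge_track(a)]
        assert aa == merged

    def test_output_length_bounded_by_inputs(self):
        rng = np.random.default_rng(8)
        a, b = random_track(rng, n=40), random_track(rng, n=40)
        out_len = sum(o.length for o in gi.intersect_tracks(a, b))
        len_a = int(coverage_mask(a).sum())
        len_b = int(coverage_mask(b).sum())
        assert out_len <= min(len_a, len_b)


class TestEnhancers:
    def test_disjoint_marks_give_no_enhancer(self):
        assert gi.enhancers([iv(0, 100)], [iv(200, 300)]) == []

    def test_identical_tracks_merge(self):
        track = [iv(10, 20), iv(15, 40)]
        out = gi.enhancers(track, track)
        assert [(o.start, o.end) for o in out] == [(10, 40)]


class TestPromoterCgiMap:
    def test_overlap_within_window(self):
        tss = [iv(10_000, 10_001, name="g1")]
        cgi = [iv(9_500, 10_500, name="cgi1")]
        assert "g1" in gi.promoter_cgi_map(tss, cgi, window=2_000)

    def test_distant_cgi_not_mapped(self):
        tss = [iv(10_000, 10_001, name="g1")]
        cgi = [iv(50_000, 51_000)]
        assert gi.promoter_cgi_map(tss, cgi, window=2_000) == {}

    def test_duplicate_gene_id_rejected(self):
        tss = [iv(1_000, 1_001, name="g1"), iv(9_000, 9_001, name="g1")]
        with pytest.raises(ValueError, match="duplicate"):
            gi.promoter_cgi_map(tss, [], window=100)

    def test_matches_brute_force_distance_check(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            tss = [
                iv(int(p), int(p) + 1, name=f"g{i}")
                for i, p in enumerate(rng.integers(2_000, 98_000, size=15))
            ]
            cgi = random_track(rng, n=25, max_len=2_000)
            window = int(rng.integers(500, 5_000))
            got = gi.promoter_cgi_map(tss, cgi, window=window)
            for t in tss:
                lo, hi = max(0, t.start - window), t.start + window
                expected = [c for c in cgi if c.start < hi and lo < c.end]
                if expected:
                    assert set((c.start, c.end) for c in got[t.name]) == set(
                        (c.start, c.end) for c in expected
                    )
                else:
                    assert t.name not in got


class TestCandidateGenes:
    """Evidence filter on a hand-built two-gene locus plus fixture-driven cases."""

    def _manifest(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "probe_id": ["p1", "p2"],
                "chrom": ["chr1", "chr1"],
                "pos": [10_000, 50_000],
                "gene": ["gA", "gB"],
            }
        )

    def test_full_evidence_qualifies(self):
        promoters = {"gA": [iv(9_000, 11_000, name="CGI_gA")]}
        tf = [iv(11_500, 11_800)]
        enh = [iv(11_400, 12_000)]
        out = gi.candidate_genes({"p1": -0.3}, self._manifest(), tf, enh, promoters)
        assert [c.gene for c in out] == ["gA"]
        assert out[0].rank_key == pytest.approx(-0.3)

    def test_peak_outside_enhancer_excluded(self):
        promoters = {"gA": [iv(9_000, 11_000)]}
        out = gi.candidate_genes(
            {"p1": -0.3}, self._manifest(), [iv(11_500, 11_800)], [iv(30_000, 31_000)], promoters
        )
        assert out == []

    def test_no_differential_probes_gives_empty(self):
        promoters = {"gA": [iv(9_000, 11_000)]}
        assert gi.candidate_genes({}, self._manifest(), [iv(11_500, 11_800)],
                                  [iv(11_400, 12_000)], promoters) == []

    def test_probe_within_flank_of_island_counts(self):
        # probe at 10 000 sits 1 000 bases left of the island: inside the flank
        promoters = {"gA": [iv(11_000, 12_000)]}
        out = gi.candidate_genes(
            {"p1": -0.3}, self._manifest(), [iv(12_100, 12_300)], [iv(12_000, 12_400)],
            promoters, flank=5_000,
        )
        assert [c.gene for c in out] == ["gA"]
        out = gi.candidate_genes(
            {"p1": -0.3}, self._manifest(), [iv(12_100, 12_300)], [iv(12_000, 12_400)],
            promoters, flank=500,
        )
        assert out == []

    def test_unknown_probe_rejected(self):
        with pytest.raises(ValueError, match="ghost"):
            gi.candidate_genes({"ghost": -0.5}, self._manifest(), [], [], {})

    def test_monotone_in_evidence(self):
        # adding intervals to any track never removes a candidate
        promoters = {"gA": [iv(9_000, 11_000)]}
        tf, enh = [iv(11_500, 11_800)], [iv(11_400, 12_000)]
        base = {c.gene for c in gi.candidate_genes({"p1": -0.3}, self._manifest(), tf, enh, promoters)}
        more = {
            c.gene
            for c in gi.candidate_genes(
                {"p1": -0.3},
                self._manifest(),
                tf + [iv(70_000, 70_100)],
                enh + [iv(60_000, 61_000)],
                promoters,
            )
        }
        assert base <= more

    def test_ranked_by_most_negative_delta_then_gene(self):
        import pandas as pd

        manifest = pd.DataFrame(
            {
                "probe_id": ["p1", "p2"],
                "chrom": ["chr1", "chr1"],
                "pos": [10_000, 50_000],
                "gene": ["gA", "gB"],
            }
        )
        promoters = {
            "gA": [iv(9_000, 11_000)],
            "gB": [iv(49_000, 51_000)],
        }
        tf = [iv(11_500, 11_800), iv(51_500, 51_800)]
        enh = [iv(11_400, 12_000), iv(51_400, 52_000)]
        out = gi.candidate_genes({"p1": -0.3, "p2": -0.5}, manifest, tf, enh, promoters)
        assert [c.gene for c in out] == ["gB", "gA"]


class TestBedRoundTrip:
    def test_write_then_read_identical(self, tmp_path):
        track = [iv(0, 10, name="a"), iv(100, 250, name="b"), iv(5, 8, chrom="chr2", name="c")]
        path = tmp_path / "t.bed"
        gi.write_bed(track, path)
        back = gi.read_bed(path)
        assert [(x.chrom, x.start, x.end, x.name) for x in back] == [
            (x.chrom, x.start, x.end, x.name) for x in track
        ]
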