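import json

import numpy as np
import pytest
from Bio import SeqIO

from oracles import quad_tail, write_sam
from readbait.extension import (
    AnchorPoint,
    FragmentCandidate,
    collect_fragments,
    estimate_extension,
    extract_span_sequence,
    fragments_to_tsv,
    score_fragments,
)
from readbait.powerlaw import MembershipModel, PowerLawFit


def _anchor(center=10_000, span=(9_925, 10_073), strand="unknown"):
    return AnchorPoint("chrT", center, span, strand)


class TestCollectFragments:
    def test_empty_alignments_yield_empty_list(self, tmp_path):
        sam = tmp_path / "empty.sam"
        write_sam(sam, "chrT", 1_000_000, [])
        assert collect_fragments(sam, _anchor(), window=5000) == []

    def test_mates_merge_to_outermost_template(self, tmp_path):
        sam = tmp_path / "pair.sam"
        write_sam(
            sam,
            "chrT",
            1_000_000,
            [
                {"qname": "p1", "flag": 99, "pos": 9_800, "cigar": "150M",
                 "mpos": 10_050, "tlen": 400},
                {"qname": "p1", "flag": 147, "pos": 10_050, "cigar": "150M",
                 "mpos": 9_800, "tlen": -400},
            ],
        )
        frags = collect_fragments(sam, _anchor(), window=5000)
        assert len(frags) == 1
        f = frags[0]
        assert (f.start, f.end) == (9_800, 10_199)
        assert f.center == 9_999
        assert f.distance_x == 1

    def test_secondary_and_supplementary_excluded(self, tmp_path):
        sam = tmp_path / "sec.sam"
        write_sam(
            sam,
            "chrT",
            1_000_000,
            [
                {"qname": "r", "flag": 0, "pos": 9_900, "cigar": "100M"},
                {"qname": "r2", "flag": 256, "pos": 9_900, "cigar": "100M"},
                {"qname": "r3", "flag": 2048, "pos": 9_900, "cigar": "100M"},
            ],
        )
        frags = collect_fragments(sam, _anchor(), window=5000)
        assert [f.name for f in frags] == ["r"]

    def test_missing_chromosome_errors(self, tmp_path):
        sam = tmp_path / "wrong.sam"
        write_sam(sam, "chrOther", 1_000_000, [])
        with pytest.raises(ValueError, match="absent"):
            collect_fragments(sam, _anchor(), window=100)

    def test_window_filters_by_center_distance(self, tmp_path):
        sam = tmp_path / "win.sam"
        write_sam(
            sam,
            "chrT",
            1_000_000,
            [
                {"qname": "near", "flag": 0, "pos": 9_950, "cigar": "100M"},
                {"qname": "far", "flag": 0, "pos": 40_000, "cigar": "100M"},
            ],
        )
        frags = collect_fragments(sam, _anchor(), window=1000)
        assert [f.name for f in frags] == ["near"]

    def test_bed_and_sam_routes_agree(self, locus):
        anchor = locus.anchor
        from_sam = collect_fragments(locus.fragments_sam, anchor, window=10_000)
        from_bed = collect_fragments(locus.fragments_bed, anchor, window=10_000)
        assert sorted((f.start, f.end) for f in from_sam) == sorted(
            (f.start, f.end) for f in from_bed
        )


class TestScoreFragments:
    def test_retention_at_published_distances(self, published_model):
        near = FragmentCandidate("chrT", 9_500, 9_600, distance_x=1117)
        far = FragmentCandidate("chrT", 4_000, 4_100, distance_x=5000)
        scored = score_fragments([near, far], published_model)
        by_dist = {f.distance_x: f for f in scored}
        assert by_dist[1117].retained  # tail ~0.54 > 0.3
        assert not by_dist[5000].retained  # tail ~0.13 < 0.3
        assert by_dist[5000].probability == pytest.approx(
            quad_tail(0.594, 1, 6932, 5000), abs=1e-9
        )

    def test_zero_distance_clamps_to_xmin(self, published_model):
        frag = FragmentCandidate("chrT", 9_950, 10_050, distance_x=0)
        (scored,) = score_fragments([frag], published_model)
        assert scored.probability == 1.0 and scored.retained

    def test_extreme_threshold_drops_everything_beyond_xmin(self, published_fit):
        # at threshold 1-eps only distances at or below x_min (tail = 1) survive
        model = MembershipModel(published_fit, threshold=1 - 1e-9)
        frags = [
            FragmentCandidate("chrT", 1, 10, distance_x=d) for d in (0, 1, 50, 700)
        ]
        scored = score_fragments(frags, model)
        assert [f.retained for f in scored] == [True, True, False, False]

    def test_equal_distances_get_equal_probability(self, published_model):
        left = FragmentCandidate("chrT", 8_000, 8_100, distance_x=500)
        right = FragmentCandidate("chrT", 11_900, 12_000, distance_x=500)
        sl, sr = score_fragments([left, right], published_model)
        assert sl.probability == sr.probability


class TestEstimateExtension:
    def test_no_retained_fragments_returns_model_span(self):
        anchor = _anchor()
        est = estimate_extension(anchor, [])
        assert est.span == anchor.model_span
        assert est.total_extension == 0
        assert est.full_length == 149

    def test_interval_arithmetic_by_hand(self):
        anchor = _anchor()
        frags = [
            FragmentCandidate("chrT", 9_000, 9_150, retained=True, probability=0.9),
            FragmentCandidate("chrT", 10_200, 10_336, retained=True, probability=0.8),
        ]
        est = estimate_extension(anchor, frags)
        assert est.span == (9_000, 10_336)
        assert est.ext_left == 925
        assert est.ext_right == 263
        assert est.full_length == 1337
        assert est.full_length == 149 + est.total_extension

    @pytest.mark.parametrize(
        "strand,exp5,exp3,resolved",
        [("+", 925, 263, True), ("-", 263, 925, True), ("unknown", 925, 263, False)],
    )
    def test_strand_resolves_five_and_three_prime(self, strand, exp5, exp3, resolved):
        anchor = _anchor(strand=strand)
        frags = [
            FragmentCandidate("chrT", 9_000, 9_150, retained=True),
            FragmentCandidate("chrT", 10_200, 10_336, retained=True),
        ]
        est = estimate_extension(anchor, frags)
        assert (est.ext_5p, est.ext_3p, est.strand_resolved) == (exp5, exp3, resolved)

    def test_span_always_contains_model_span(self):
        rng = np.random.default_rng(1)
        anchor = _anchor()
        for _ in range(50):
            frags = []
            for _ in range(rng.integers(0, 20)):
                start = int(rng.integers(5_000, 15_000))
                frags.append(
                    FragmentCandidate(
                        "chrT", start, start + int(rng.integers(1, 500)),
                        retained=bool(rng.random() < 0.5),
                    )
                )
            est = estimate_extension(anchor, frags)
            assert est.span[0] <= anchor.model_span[0]
            assert est.span[1] >= anchor.model_span[1]
            assert est.ext_left >= 0 and est.ext_right >= 0
            assert est.full_length >= 149

    def test_threshold_monotonicity_shrinks_retained_set(self, published_fit):
        rng = np.random.default_rng(2)
        anchor = _anchor()
        frags = []
        for i in range(30):
            start = int(rng.integers(4_000, 16_000))
            f = FragmentCandidate("chrT", start, start + 150, name=f"f{i}")
            f.distance_x = abs(f.center - anchor.center)
            frags.append(f)
        lo = score_fragments(frags, MembershipModel(published_fit, threshold=0.2))
        hi = score_fragments(frags, MembershipModel(published_fit, threshold=0.6))
        kept_lo = {f.name for f in lo if f.retained}
        kept_hi = {f.name for f in hi if f.retained}
        assert kept_hi <= kept_lo
        est_lo = estimate_extension(anchor, lo)
        est_hi = estimate_extension(anchor, hi)
        assert est_hi.full_length <= est_lo.full_length

    def test_matches_exhaustive_recomputation(self, published_model):
        """Dual route: per-fragment closed-form tail + hand span merge."""
        rng = np.random.default_rng(3)
        anchor = _anchor()
        frags = []
        for i in range(20):
            start = int(rng.integers(4_000, 16_000))
            f = FragmentCandidate("chrT", start, start + int(rng.integers(50, 400)),
                                  name=f"f{i}")
            f.distance_x = abs(f.center - anchor.center)
            frags.append(f)
        scored = score_fragments(frags, published_model)
        est = estimate_extension(anchor, scored)

        a, lo, hi = 0.594, 1.0, 6932.0
        expected_kept = set()
        starts, ends = [anchor.model_span[0]], [anchor.model_span[1]]
        for f in frags:
            x = max(f.distance_x, lo)
            tail = (hi ** (1 - a) - x ** (1 - a)) / (hi ** (1 - a) - lo ** (1 - a))
            if tail > 0.3:
                expected_kept.add(f.name)
                starts.append(f.start)
                ends.append(f.end)
        assert {f.name for f in est.retained} == expected_kept
        assert est.span == (min(starts), max(ends))


class TestSpanSequence:
    def test_forward_and_reverse_extraction(self, tmp_path):
        fasta = tmp_path / "g.fa"
        fasta.write_text(">chrT\nACGTTTAAAC\n")
        frag = FragmentCandidate("chrT", 1, 4, retained=True)
        anchor = AnchorPoint("chrT", 2, (2, 3), "+")
        est = estimate_extension(anchor, [frag])
        rec = extract_span_sequence(fasta, est)
        assert str(rec.seq) == "ACGT"
        assert rec.id == "chrT:1-4(+)"
        anchor_m = AnchorPoint("chrT", 2, (2, 3), "-")
        est_m = estimate_extension(anchor_m, [frag])
        assert str(extract_span_sequence(fasta, est_m).seq) == "ACGT"  # palindrome

    def test_span_beyond_chromosome_errors(self, tmp_path):
        fasta = tmp_path / "g.fa"
        fasta.write_text(">chrT\nACGTTT\n")
        anchor = AnchorPoint("chrT", 3, (2, 5))
        frag = FragmentCandidate("chrT", 2, 50, retained=True)
        with pytest.raises(ValueError, match="outside"):
            extract_span_sequence(fasta, estimate_extension(anchor, [frag]))

    def test_planted_locus_returns_exact_genomic_subsequence(self, locus, published_model):
        anchor = locus.anchor
        frags = collect_fragments(locus.fragments_sam, anchor, window=10_000)
        est = estimate_extension(anchor, score_fragments(frags, published_model))
        rec = extract_span_sequence(locus.genome_fasta, est)
        genome = str(next(SeqIO.parse(str(locus.genome_fasta), "fasta")).seq)
        assert str(rec.seq) == genome[est.span[0] - 1 : est.span[1]]


def test_fragments_tsv_and_estimate_json_outputs(tmp_path, published_model):
    anchor = _anchor()
    frag = FragmentCandidate("chrT", 9_000, 9_150, name="f0")
    frag.distance_x = abs(frag.center - anchor.center)
    scored = score_fragments([frag], published_model)
    est = estimate_extension(anchor, scored)
    fragments_to_tsv(scored, tmp_path / "frags.tsv")
    est.to_json(tmp_path / "est.json")
    lines = (tmp_path / "frags.tsv").read_text().splitlines()
    assert lines[0].startswith("chrom\t") and len(lines) == 2
    blob = json.loads((tmp_path / "est.json").read_text())
    assert blob["full_length"] == est.full_length
    assert blob["n_retained"] == len(est.retained)
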