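"""Split pairing, boundary snapping, chimeric sequences, seed verification."""
import numpy as np
import pytest

from exofuse.detect import (
    FUSION_EXONS,
    FULL_TRANSCRIPT,
    aggregate_candidates,
    build_fusion_sequence,
    pair_split_segments,
    snap_to_boundary,
    verify_seed,
)
from exofuse.preprocess import UniqueRead
from exofuse.util import revcomp

from .helpers import junction_reads, make_boundary, make_record


def split_pair(
    dist=None,
    chrom_b="chrB",
    span_a=(0, 40),
    span_b=(40, 76),
    read_len=76,
    b_start=None,
):
    a = make_record(query_id="q", query_length=read_len, query_start=span_a[0],
                    query_end=span_a[1], chrom="chrA", target_start=10_000,
                    target_end=10_000 + (span_a[1] - span_a[0]))
    if dist is not None:
        chrom_b = "chrA"
        b_start = a.target_end + dist
    elif b_start is None:
        b_start = 5_000
    b = make_record(query_id="q", query_length=read_len, query_start=span_b[0],
                    query_end=span_b[1], chrom=chrom_b, target_start=b_start,
                    target_end=b_start + (span_b[1] - span_b[0]))
    return [a, b]


class TestPairSplitSegments:
    def test_interchromosomal_pair_accepted(self):
        (sc,) = pair_split_segments(split_pair())
        assert sc.query_gap == 0
        assert sc.segment_head.chrom == "chrA" and sc.segment_tail.chrom == "chrB"

    def test_same_chrom_below_50kbp_rejected(self):
        assert pair_split_segments(split_pair(dist=40_000)) == []

    @pytest.mark.parametrize("dist,expected", [(49_999, 0), (50_001, 1)])
    def test_distance_threshold_flip(self, dist, expected):
        assert len(pair_split_segments(split_pair(dist=dist))) == expected

    @pytest.mark.parametrize("anchor,expected", [(19, 0), (20, 1)])
    def test_anchor_threshold_flip(self, anchor, expected):
        recs = split_pair(span_a=(0, anchor), span_b=(anchor, 76), read_len=76)
        assert len(pair_split_segments(recs)) == expected

    @pytest.mark.parametrize("cover,expected", [(49, 0), (51, 1)])
    def test_coverage_threshold_flip(self, cover, expected):
        # two abutting segments jointly covering `cover`% of a 100 bp read
        recs = split_pair(span_a=(0, 25), span_b=(25, cover), read_len=100)
        assert len(pair_split_segments(recs)) == expected

    @pytest.mark.parametrize("gap,expected", [(10, 1), (11, 0), (-10, 1), (-11, 0)])
    def test_query_gap_threshold_flip(self, gap, expected):
        recs = split_pair(span_a=(0, 44), span_b=(44 + gap, 100), read_len=100)
        assert len(pair_split_segments(recs)) == expected

    def test_fifteen_bp_gap_rejected(self):
        recs = split_pair(span_a=(0, 30), span_b=(45, 100), read_len=100)
        assert pair_split_segments(recs) == []


class TestSnapToBoundary:
    def simple_split(self, toy_genome, toy_annotation, head_end_shift=0, tail_start_shift=0):
        """Records emulating a split ALPHA(exon1 end) -> DELTA(exon2 start)."""
        head = make_record(query_id="q", query_length=100, query_start=0, query_end=50,
                           chrom="chrA", target_start=1150,
                           target_end=1200 + head_end_shift)
        tail = make_record(query_id="q", query_length=100, query_start=50, query_end=100,
                           chrom="chrB", target_start=6000 + tail_start_shift,
                           target_end=6050)
        from exofuse.detect import SplitCandidate

        return SplitCandidate("q", head, tail, 0)

    def test_exact_boundaries_offsets_zero(self, toy_genome, toy_annotation):
        boundary, segs = snap_to_boundary(self.simple_split(toy_genome, toy_annotation),
                                          toy_annotation)
        assert boundary.head_gene == "ALPHA" and boundary.tail_gene == "DELTA"
        assert boundary.head_breakpoint == 1200 and boundary.tail_breakpoint == 6000
        assert (boundary.head_offset, boundary.tail_offset) == (0, 0)

    def test_small_offsets_absorbed(self, toy_genome, toy_annotation):
        sc = self.simple_split(toy_genome, toy_annotation, head_end_shift=-4)
        boundary, _ = snap_to_boundary(sc, toy_annotation)
        assert boundary.head_offset == 4 and boundary.head_breakpoint == 1200

    @pytest.mark.parametrize("shift,snapped", [(-6, True), (-7, False), (6, True), (7, False)])
    def test_offset_threshold_flip(self, toy_genome, toy_annotation, shift, snapped):
        sc = self.simple_split(toy_genome, toy_annotation, head_end_shift=shift)
        assert (snap_to_boundary(sc, toy_annotation) is not None) is snapped

    def test_intra_gene_split_rejected(self, toy_annotation):
        from exofuse.detect import SplitCandidate

        head = make_record(query_id="q", query_start=0, query_end=50, chrom="chrA",
                           target_start=1150, target_end=1200)
        tail = make_record(query_id="q", query_start=50, query_end=100, chrom="chrA",
                           target_start=2000, target_end=2050)
        assert snap_to_boundary(SplitCandidate("q", head, tail, 0), toy_annotation) is None

    def test_unannotated_locus_returns_none(self, toy_annotation):
        from exofuse.detect import SplitCandidate

        head = make_record(query_id="q", query_start=0, query_end=50, chrom="chrA",
                           target_start=50_000, target_end=50_050)
        tail = make_record(query_id="q", query_start=50, query_end=100, chrom="chrB",
                           target_start=6_000, target_end=6_050)
        assert snap_to_boundary(SplitCandidate("q", head, tail, 0), toy_annotation) is None


class TestBuildFusionSequence:
    def test_fusion_exons_concatenation(self, toy_genome, toy_annotation):
        b = make_boundary(toy_annotation, "NM_A1", 0, "NM_D1", 1)
        seq, junction = build_fusion_sequence(b, toy_genome, toy_annotation, FUSION_EXONS)
        assert junction == 200 and len(seq) == 200 + 180
        assert seq[:200] == toy_genome.fetch("chrA", 1000, 1200)
        assert seq[200:] == toy_genome.fetch("chrB", 6000, 6180)

    def test_minus_strand_head_in_transcription_order(self, toy_genome, toy_annotation):
        # oracle: the head portion must equal a prefix of the independently
        # spliced head transcript sequence
        b = make_boundary(toy_annotation, "NM_G1", 0, "NM_D1", 0)
        t = toy_annotation.transcripts["NM_G1"]
        spliced = t.spliced_sequence(toy_genome)
        seq, junction = build_fusion_sequence(b, toy_genome, toy_annotation, FULL_TRANSCRIPT)
        assert seq[:junction] == spliced[:junction]
        assert junction == 200  # GAMMA exon (141000,141200) is transcription-first
        assert seq[:200] == revcomp(toy_genome.fetch("chrA", 141_000, 141_200))

    def test_full_transcript_head_prefix(self, toy_genome, toy_annotation):
        b = make_boundary(toy_annotation, "NM_A1", 1, "NM_D1", 0)
        seq, junction = build_fusion_sequence(b, toy_genome, toy_annotation, FULL_TRANSCRIPT)
        expected_head = toy_genome.fetch("chrA", 1000, 1200) + toy_genome.fetch("chrA", 2000, 2300)
        assert junction == 500 and seq[:500] == expected_head
        tail = toy_annotation.transcripts["NM_D1"].spliced_sequence(toy_genome)
        assert seq[500:] == tail


@pytest.fixture(scope="module")
def fusion(toy_genome, toy_annotation):
    b = make_boundary(toy_annotation, "NM_A1", 1, "NM_E1", 0)
    return build_fusion_sequence(b, toy_genome, toy_annotation, FUSION_EXONS)


class TestVerifySeed:
    def test_centered_window_accepted(self, fusion):
        seq, junction = fusion
        read = UniqueRead(seq[junction - 25 : junction + 25], 1, ["r"])
        seed = verify_seed(read, seq, junction)
        assert seed is not None
        assert (seed.head_overhang, seed.tail_overhang) == (25, 25)
        assert seed.realignment.identity_fraction == 1.0

    def test_reverse_complement_read_accepted(self, fusion):
        seq, junction = fusion
        read = UniqueRead(revcomp(seq[junction - 30 : junction + 30]), 1, ["r"])
        assert verify_seed(read, seq, junction) is not None

    def test_short_tail_side_rejected(self, fusion):
        seq, junction = fusion
        read = UniqueRead(seq[junction - 57 : junction + 19], 1, ["r"])
        assert verify_seed(read, seq, junction) is None

    @pytest.mark.parametrize("n_mismatch,accepted", [(5, True), (6, False)])
    def test_identity_threshold_flip(self, fusion, n_mismatch, accepted):
        # 100 bp junction read at identity 0.95 (5 mismatches) vs 0.94 (6)
        seq, junction = fusion
        read = list(seq[junction - 50 : junction + 50])
        for i in range(n_mismatch):
            pos = 12 + 14 * i  # interior, well-separated mismatches
            read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
        result = verify_seed(UniqueRead("".join(read), 1, ["r"]), seq, junction)
        assert (result is not None) is accepted
        if result is not None:
            assert result.realignment.identity_fraction == pytest.approx(0.95)


class TestAggregate:
    def test_distinct_reads_one_boundary(self, toy_annotation):
        b = make_boundary(toy_annotation, "NM_A1", 0, "NM_D1", 0)
        seeds = [
            _seed(f"SEQ{i}" + "ACGT" * 10) for i in range(3)
        ]
        (cand,) = aggregate_candidates([(b, s) for s in seeds])
        assert cand.n_seeds == 3

    def test_distinct_tail_breakpoints_stay_separate(self, toy_annotation):
        b1 = make_boundary(toy_annotation, "NM_A1", 0, "NM_D1", 0)
        b2 = make_boundary(toy_annotation, "NM_A1", 0, "NM_D1", 1)
        out = aggregate_candidates([(b1, _seed("A" * 40 + "C")), (b2, _seed("C" * 40 + "G"))])
        assert len(out) == 2

    def test_identical_breakpoints_via_isoforms_merge(self, toy_annotation):
        # NM_A1 and NM_A2 share exon 1: same genomic breakpoint via two isoforms
        b1 = make_boundary(toy_annotation, "NM_A1", 0, "NM_D1", 0)
        b2 = make_boundary(toy_annotation, "NM_A2", 0, "NM_D1", 0)
        assert b1.head_breakpoint == b2.head_breakpoint
        (cand,) = aggregate_candidates([(b1, _seed("A" * 41)), (b2, _seed("G" * 41))])
        assert cand.n_seeds == 2
        assert cand.alt_isoforms  # the losing isoform pair is listed

    def test_duplicate_sequences_counted_once(self, toy_annotation):
        b = make_boundary(toy_annotation, "NM_A1", 0, "NM_D1", 0)
        (cand,) = aggregate_candidates([(b, _seed("T" * 41)), (b, _seed("T" * 41))])
        assert cand.n_seeds == 1


def _seed(sequence):
    from exofuse.align import LocalAlignmentResult
    from exofuse.detect import SeedRead

    fake = LocalAlignmentResult(
        score=len(sequence), matches=len(sequence), mismatches=0,
        query_start=0, query_end=len(sequence), target_start=0,
        target_end=len(sequence), blocks=((0, 0, len(sequence)),),
    )
    return SeedRead(sequence=sequence, count=1, realignment=fake,
                    head_overhang=20, tail_overhang=20)
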