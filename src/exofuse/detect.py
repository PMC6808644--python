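"""Fusion detection: split-read pairing, exon-boundary snapping, chimeric
sequence construction, and seed-read verification by realignment.

A fusion candidate starts as a *split read*: one read whose two local
alignments land on loci more than 50 kbp apart (or on different
chromosomes), each anchor at least 20 bp, together covering more than half
the read, contiguous on the read within +/-10 bp.  The split's internal
breakpoints must fall within 6 bp of annotated exon edges — the method only
reports fusions of intact exons — and the read must realign across the
junction of the reconstructed chimeric sequence with >= 20 bp on both sides
at >= 95% identity to count as a seed read.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .align import AlignmentRecord, LocalAlignmentResult, local_align
from .annotation import (
    HEAD_3PRIME,
    TAIL_5PRIME,
    Annotation,
    GenomeRef,
    nearest_exon_boundary,
)
from .preprocess import UniqueRead
from .util import interval_union_length, revcomp

FUSION_EXONS = "fusion_exons"
FULL_TRANSCRIPT = "full_transcript"


@dataclass
class SplitCandidate:
    """Two alignments of one read to distant loci, in query order.

    ``segment_head`` is the 5'-query segment in the read's forward frame; the
    definitive head/tail orientation is fixed later by boundary snapping,
    which also considers the reverse-complement reading of the pair.
    """

    query_id: str
    segment_head: AlignmentRecord
    segment_tail: AlignmentRecord
    query_gap: int  # signed bp between the two query intervals


@dataclass(frozen=True)
class FusionBoundary:
    """A head-gene exon end joined to a tail-gene exon start.

    Breakpoints are reported snapped to the annotated exon boundary (pre-snap
    offsets, each <= 6 bp, are retained); the head breakpoint is a
    transcription-3' exon edge of the head transcript and the tail breakpoint
    a transcription-5' edge of the tail transcript.
    """

    head_gene: str
    tail_gene: str
    head_transcript: str
    tail_transcript: str
    head_exon_index: int  # genomic-order index within the transcript
    tail_exon_index: int
    head_chrom: str
    tail_chrom: str
    head_breakpoint: int
    tail_breakpoint: int
    head_strand: str
    tail_strand: str
    head_offset: int
    tail_offset: int

    @property
    def genomic_key(self) -> Tuple[str, str, str, int, str, int]:
        return (
            self.head_gene,
            self.tail_gene,
            self.head_chrom,
            self.head_breakpoint,
            self.tail_chrom,
            self.tail_breakpoint,
        )


@dataclass
class SeedRead:
    """A split read that realigns across the junction at seed stringency."""

    sequence: str
    count: int
    realignment: LocalAlignmentResult
    head_overhang: int
    tail_overhang: int
    query_id: str = ""
    member_ids: Tuple[str, ...] = ()
    split_records: Tuple[AlignmentRecord, AlignmentRecord] = ()


@dataclass
class SupportRead:
    """A junction-crossing read whose shorter side is below seed length."""

    sequence: str
    count: int
    realignment: LocalAlignmentResult
    head_overhang: int
    tail_overhang: int
    query_id: str = ""


@dataclass
class FusionCandidate:
    boundary: FusionBoundary
    seeds: List[SeedRead]
    supports: List[SupportRead] = field(default_factory=list)
    filter_audit: List[Tuple[str, str, str]] = field(default_factory=list)
    alt_isoforms: Set[Tuple[str, str]] = field(default_factory=set)

    @property
    def n_seeds(self) -> int:
        return len(self.seeds)

    @property
    def candidate_id(self) -> str:
        b = self.boundary
        return (
            f"{b.head_gene}--{b.tail_gene}@"
            f"{b.head_chrom}:{b.head_breakpoint}:{b.head_strand}/"
            f"{b.tail_chrom}:{b.tail_breakpoint}:{b.tail_strand}"
        )


# ---------------------------------------------------------------------------
# Split-read pairing


def _genomic_distance(a: AlignmentRecord, b: AlignmentRecord) -> Optional[int]:
    """bp between the nearest ends of the two target intervals; None if on
    different chromosomes."""
    if a.chrom != b.chrom:
        return None
    gap = max(a.target_start, b.target_start) - min(a.target_end, b.target_end)
    return max(gap, 0)


def pair_split_segments(
    records: Sequence[AlignmentRecord],
    min_anchor: int = 20,
    min_cover: float = 0.5,
    max_query_gap: int = 10,
    min_genomic_gap: int = 50_000,
) -> List[SplitCandidate]:
    """All qualifying split pairs among one query's alignment records.

    A pair qualifies iff the loci are on different chromosomes or more than
    ``min_genomic_gap`` apart; both aligned query spans are >= ``min_anchor``;
    the union of the query spans covers more than ``min_cover`` of the read;
    and the gap/overlap between the query intervals is within
    +/-``max_query_gap``.
    """
    out: List[SplitCandidate] = []
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            a, b = records[i], records[j]
            dist = _genomic_distance(a, b)
            if dist is not None and dist <= min_genomic_gap:
                continue
            if a.query_span < min_anchor or b.query_span < min_anchor:
                continue
            read_len = a.query_length
            covered = interval_union_length(
                [(a.query_start, a.query_end), (b.query_start, b.query_end)]
            )
            if covered <= min_cover * read_len:
                continue
            first, second = (a, b) if (a.query_start, a.query_end) <= (
                b.query_start,
                b.query_end,
            ) else (b, a)
            gap = second.query_start - first.query_end
            if abs(gap) > max_query_gap:
                continue
            out.append(
                SplitCandidate(
                    query_id=a.query_id,
                    segment_head=first,
                    segment_tail=second,
                    query_gap=gap,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Boundary snapping


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _snap_side(
    seg: AlignmentRecord,
    eff_strand: str,
    role: str,
    annotation: Annotation,
    max_offset: int,
):
    """Snap one segment's junction-proximal end to an exon boundary."""
    candidates = [
        t
        for t in annotation.transcripts_overlapping(seg.chrom, seg.target_start, seg.target_end)
        if t.strand == eff_strand
    ]
    if not candidates:
        return None
    if role == HEAD_3PRIME:
        pos = seg.target_end if eff_strand == "+" else seg.target_start
    else:
        pos = seg.target_start if eff_strand == "+" else seg.target_end
    hit = nearest_exon_boundary(candidates, pos, role)
    if hit is None or hit[1] > max_offset:
        return None
    boundary, offset = hit
    transcript = annotation.transcripts[boundary.transcript_id]
    return transcript, boundary, offset


def _try_orientation(
    head_seg: AlignmentRecord,
    tail_seg: AlignmentRecord,
    flipped: bool,
    annotation: Annotation,
    max_offset: int,
) -> Optional[FusionBoundary]:
    hs = _flip(head_seg.strand) if flipped else head_seg.strand
    ts = _flip(tail_seg.strand) if flipped else tail_seg.strand
    head = _snap_side(head_seg, hs, HEAD_3PRIME, annotation, max_offset)
    if head is None:
        return None
    tail = _snap_side(tail_seg, ts, TAIL_5PRIME, annotation, max_offset)
    if tail is None:
        return None
    head_t, head_b, head_off = head
    tail_t, tail_b, tail_off = tail
    if head_t.gene_symbol == tail_t.gene_symbol:
        return None  # intra-gene splits are not fusions
    return FusionBoundary(
        head_gene=head_t.gene_symbol,
        tail_gene=tail_t.gene_symbol,
        head_transcript=head_t.transcript_id,
        tail_transcript=tail_t.transcript_id,
        head_exon_index=head_b.exon_index,
        tail_exon_index=tail_b.exon_index,
        head_chrom=head_t.chrom,
        tail_chrom=tail_t.chrom,
        head_breakpoint=head_b.genomic_position,
        tail_breakpoint=tail_b.genomic_position,
        head_strand=head_t.strand,
        tail_strand=tail_t.strand,
        head_offset=head_off,
        tail_offset=tail_off,
    )


def snap_to_boundary(
    sc: SplitCandidate, annotation: Annotation, max_offset: int = 6
) -> Optional[Tuple[FusionBoundary, Tuple[AlignmentRecord, AlignmentRecord]]]:
    """Snap a split pair to exon boundaries, fixing head/tail orientation.

    Both readings are considered: the read as stored (5'-query segment =
    head) and its reverse complement (segments swapped, strands flipped); the
    reading consistent with 5'->3' transcription on both sides wins.  Returns
    the boundary plus the (head, tail) segments in the winning orientation,
    or None when neither reading is annotation-consistent.
    """
    as_is = _try_orientation(sc.segment_head, sc.segment_tail, False, annotation, max_offset)
    rc = _try_orientation(sc.segment_tail, sc.segment_head, True, annotation, max_offset)
    options = []
    if as_is is not None:
        options.append((as_is, (sc.segment_head, sc.segment_tail)))
    if rc is not None:
        options.append((rc, (sc.segment_tail, sc.segment_head)))
    if not options:
        return None
    options.sort(key=lambda o: (o[0].head_offset + o[0].tail_offset, o[0].head_gene, o[0].tail_gene))
    return options[0]


# ---------------------------------------------------------------------------
# Chimeric sequence construction


def _head_portion(boundary: FusionBoundary, genome: GenomeRef, annotation: Annotation,
                  scope: str) -> str:
    t = annotation.transcripts[boundary.head_transcript]
    tx_exons = t.exons_in_tx_order()
    tx_idx = (
        boundary.head_exon_index
        if t.strand == "+"
        else len(t.exons) - 1 - boundary.head_exon_index
    )
    chosen = tx_exons[: tx_idx + 1] if scope == FULL_TRANSCRIPT else [tx_exons[tx_idx]]
    parts = []
    for s, e in chosen:
        seq = genome.fetch(t.chrom, s, e)
        parts.append(seq if t.strand == "+" else revcomp(seq))
    return "".join(parts)


def _tail_portion(boundary: FusionBoundary, genome: GenomeRef, annotation: Annotation,
                  scope: str) -> str:
    t = annotation.transcripts[boundary.tail_transcript]
    tx_exons = t.exons_in_tx_order()
    tx_idx = (
        boundary.tail_exon_index
        if t.strand == "+"
        else len(t.exons) - 1 - boundary.tail_exon_index
    )
    chosen = tx_exons[tx_idx:] if scope == FULL_TRANSCRIPT else [tx_exons[tx_idx]]
    parts = []
    for s, e in chosen:
        seq = genome.fetch(t.chrom, s, e)
        parts.append(seq if t.strand == "+" else revcomp(seq))
    return "".join(parts)


def build_fusion_sequence(
    boundary: FusionBoundary,
    genome: GenomeRef,
    annotation: Annotation,
    scope: str = FUSION_EXONS,
) -> Tuple[str, int]:
    """Synthetic chimeric sequence for a boundary, plus the junction offset.

    ``fusion_exons`` concatenates just the two fusion exons (each spliced in
    transcription orientation); ``full_transcript`` joins the head
    transcript's spliced sequence 5' of the junction with the tail
    transcript's spliced sequence 3' of it.
    """
    if scope not in (FUSION_EXONS, FULL_TRANSCRIPT):
        raise ValueError(f"unknown scope {scope!r}")
    head = _head_portion(boundary, genome, annotation, scope)
    tail = _tail_portion(boundary, genome, annotation, scope)
    return head + tail, len(head)


# ---------------------------------------------------------------------------
# Seed verification


def _junction_crossing(
    result: LocalAlignmentResult, junction: int
) -> Tuple[int, int]:
    """(head overhang, tail overhang) of an alignment across the junction."""
    head_ov = max(junction - result.target_start, 0)
    tail_ov = max(result.target_end - junction, 0)
    return head_ov, tail_ov


def verify_seed(
    read: UniqueRead,
    fusion_seq: str,
    junction: int,
    word_size: int = 20,
    min_anchor: int = 20,
    min_identity: float = 0.95,
) -> Optional[SeedRead]:
    """Realign a read to the combined-fusion-exon sequence at seed stringency.

    The read (or its reverse complement) must align across the junction with
    >= ``min_anchor`` bases on each side at identity >= ``min_identity``.
    """
    best = None
    for seq in (read.sequence, revcomp(read.sequence)):
        result = local_align(seq, fusion_seq, word_size)
        if result is None:
            continue
        head_ov, tail_ov = _junction_crossing(result, junction)
        if head_ov < min_anchor or tail_ov < min_anchor:
            continue
        if result.identity_fraction < min_identity:
            continue
        if best is None or result.score > best[0].score:
            best = (result, head_ov, tail_ov)
    if best is None:
        return None
    result, head_ov, tail_ov = best
    return SeedRead(
        sequence=read.sequence,
        count=read.count,
        realignment=result,
        head_overhang=head_ov,
        tail_overhang=tail_ov,
        member_ids=tuple(read.member_ids),
    )


# ---------------------------------------------------------------------------
# Aggregation


def aggregate_candidates(
    verified: Iterable[Tuple[FusionBoundary, SeedRead]]
) -> List[FusionCandidate]:
    """Group verified seeds by identical genomic breakpoints.

    One candidate per distinct (head gene, tail gene, head breakpoint, tail
    breakpoint); isoform-ambiguous snaps sharing the same genomic breakpoints
    merge, keeping the smallest-offset boundary as representative and listing
    the alternatives.  Seed multiplicity counts distinct unique (collapsed)
    read sequences.
    """
    groups: Dict[Tuple, List[Tuple[FusionBoundary, SeedRead]]] = {}
    for boundary, seed in verified:
        groups.setdefault(boundary.genomic_key, []).append((boundary, seed))
    out = []
    for key in sorted(groups):
        items = groups[key]
        boundaries = sorted(
            {b for b, _ in items},
            key=lambda b: (b.head_offset + b.tail_offset, b.head_transcript, b.tail_transcript),
        )
        rep = boundaries[0]
        seen: Set[str] = set()
        seeds = []
        for _, seed in items:
            if seed.sequence in seen:
                continue
            seen.add(seed.sequence)
            seeds.append(seed)
        seeds.sort(key=lambda s: (-s.count, s.sequence))
        out.append(
            FusionCandidate(
                boundary=rep,
                seeds=seeds,
                alt_isoforms={
                    (b.head_transcript, b.tail_transcript) for b in boundaries[1:]
                },
            )
        )
    out.sort(key=lambda c: (-c.n_seeds, c.boundary.head_gene, c.boundary.tail_gene))
    return out


# ---------------------------------------------------------------------------
# Detection driver


def detect_fusions(
    unique_reads: Sequence[UniqueRead],
    alignments_by_query: Dict[str, List[AlignmentRecord]],
    genome: GenomeRef,
    annotation: Annotation,
    min_anchor: int = 20,
    min_cover: float = 0.5,
    max_query_gap: int = 10,
    min_genomic_gap: int = 50_000,
    max_boundary_offset: int = 6,
    verify_word_size: int = 20,
    verify_min_identity: float = 0.95,
) -> Tuple[List[FusionCandidate], Dict[str, int]]:
    """Run split pairing -> boundary snapping -> seed verification -> grouping.

    ``alignments_by_query`` must already be restricted to candidate reads
    (2-11 alignments); unique reads are matched to queries by their id.
    """
    read_lookup: Dict[str, UniqueRead] = {}
    for i, u in enumerate(unique_reads):
        read_lookup[unique_read_id(i, u)] = u

    n_split = n_boundary = n_verified = 0
    fusion_seq_cache: Dict[Tuple, Tuple[str, int]] = {}
    verified: List[Tuple[FusionBoundary, SeedRead]] = []
    for query_id in sorted(alignments_by_query):
        records = alignments_by_query[query_id]
        read = read_lookup.get(query_id)
        if read is None:
            continue
        for sc in pair_split_segments(
            records, min_anchor, min_cover, max_query_gap, min_genomic_gap
        ):
            n_split += 1
            snapped = snap_to_boundary(sc, annotation, max_boundary_offset)
            if snapped is None:
                continue
            boundary, (head_seg, tail_seg) = snapped
            n_boundary += 1
            cache_key = boundary.genomic_key
            if cache_key not in fusion_seq_cache:
                fusion_seq_cache[cache_key] = build_fusion_sequence(
                    boundary, genome, annotation, FUSION_EXONS
                )
            fusion_seq, junction = fusion_seq_cache[cache_key]
            seed = verify_seed(
                read, fusion_seq, junction, verify_word_size, min_anchor, verify_min_identity
            )
            if seed is None:
                continue
            seed.query_id = query_id
            seed.split_records = (head_seg, tail_seg)
            n_verified += 1
            verified.append((boundary, seed))
    candidates = aggregate_candidates(verified)
    counts = {
        "split_pairs": n_split,
        "boundary_snapped": n_boundary,
        "verified_seeds": n_verified,
        "aggregated_candidates": len(candidates),
    }
    return candidates, counts


def unique_read_id(rank: int, unique: UniqueRead) -> str:
    """Collapsed-read query id in the ``rank-count`` dialect."""
    return f"{rank + 1}-{unique.count}"
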