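"""Independent oracles and small builders used by the tests.

The Smith-Waterman oracle here is a plain-Python Gotoh DP kept deliberately
separate from the package's alignment path; it exists to cross-check scores,
not to share code with them.
"""
from __future__ import annotations

from typing import List, Optional, Tuple

from exofuse.align import AlignmentRecord

NEG = -1e18


def sw_oracle_score(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = -5,
    gap_extend: int = -2,
) -> float:
    """Unanchored local-alignment score by brute-force affine-gap DP."""
    n, m = len(a), len(b)
    best = 0.0
    M_prev = [0.0] * (m + 1)
    X_prev = [NEG] * (m + 1)
    Y_prev = [NEG] * (m + 1)
    for i in range(1, n + 1):
        M_cur = [0.0] * (m + 1)
        X_cur = [NEG] * (m + 1)
        Y_cur = [NEG] * (m + 1)
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            diag = max(M_prev[j - 1], X_prev[j - 1], Y_prev[j - 1]) + s
            M_cur[j] = diag if diag > 0 else 0.0
            X_cur[j] = max(M_prev[j] + gap_open, Y_prev[j] + gap_open, X_prev[j] + gap_extend)
            Y_cur[j] = max(M_cur[j - 1] + gap_open, X_cur[j - 1] + gap_open,
                           Y_cur[j - 1] + gap_extend)
            if M_cur[j] > best:
                best = M_cur[j]
        M_prev, X_prev, Y_prev = M_cur, X_cur, Y_cur
    return best


def shared_word_exists(a: str, b: str, word_size: int) -> bool:
    words = {a[i : i + word_size] for i in range(len(a) - word_size + 1)}
    return any(b[i : i + word_size] in words for i in range(len(b) - word_size + 1))


def find_all(haystack: str, needle: str) -> List[int]:
    """Exhaustive substring search (the genome_align locus oracle)."""
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def make_record(
    query_id: str = "q",
    query_length: int = 100,
    strand: str = "+",
    query_start: int = 0,
    query_end: int = 50,
    chrom: str = "chrA",
    target_start: int = 1000,
    target_end: int = 1050,
    matches: Optional[int] = None,
    mismatches: int = 0,
    target_length: int = 1_000_000,
) -> AlignmentRecord:
    """AlignmentRecord stub with a single block and consistent fields."""
    span = query_end - query_start
    if matches is None:
        matches = span - mismatches
    return AlignmentRecord(
        query_id=query_id,
        query_length=query_length,
        strand=strand,
        query_start=query_start,
        query_end=query_end,
        chrom=chrom,
        target_length=target_length,
        target_start=target_start,
        target_end=target_end,
        matches=matches,
        mismatches=mismatches,
        block_sizes=(span,),
        q_starts=(query_start if strand == "+" else query_length - query_end,),
        t_starts=(target_start,),
        score=float(matches - 2 * mismatches),
    )


def make_boundary(annotation, head_tx: str, head_tx_exon: int, tail_tx: str, tail_tx_exon: int):
    """FusionBoundary at exact exon edges, from transcription-order exon
    indices (independent recomputation of breakpoints from the annotation)."""
    from exofuse.detect import FusionBoundary

    ht = annotation.transcripts[head_tx]
    tt = annotation.transcripts[tail_tx]
    hg = ht.genomic_to_tx_index(head_tx_exon)
    tg = tt.genomic_to_tx_index(tail_tx_exon)
    head_exon = ht.exons[hg]
    tail_exon = tt.exons[tg]
    return FusionBoundary(
        head_gene=ht.gene_symbol,
        tail_gene=tt.gene_symbol,
        head_transcript=head_tx,
        tail_transcript=tail_tx,
        head_exon_index=hg,
        tail_exon_index=tg,
        head_chrom=ht.chrom,
        tail_chrom=tt.chrom,
        head_breakpoint=head_exon[1] if ht.strand == "+" else head_exon[0],
        tail_breakpoint=tail_exon[0] if tt.strand == "+" else tail_exon[1],
        head_strand=ht.strand,
        tail_strand=tt.strand,
        head_offset=0,
        tail_offset=0,
    )


def junction_reads(genome, annotation, boundary, head_side_lengths, read_len=100, rc=False):
    """Error-free reads crossing the fusion junction, one per requested
    head-side overhang, drawn from the full chimeric transcript."""
    from exofuse.detect import FULL_TRANSCRIPT, build_fusion_sequence
    from exofuse.preprocess import SequencedRead
    from exofuse.util import revcomp

    seq, junction = build_fusion_sequence(boundary, genome, annotation, FULL_TRANSCRIPT)
    reads = []
    for i, head_side in enumerate(head_side_lengths):
        start = junction - head_side
        if start < 0 or start + read_len > len(seq):
            raise ValueError(f"cannot draw read with head side {head_side}")
        s = seq[start : start + read_len]
        if rc:
            s = revcomp(s)
        reads.append(SequencedRead(f"jr{i}-{head_side}", s, [40] * read_len))
    return reads
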