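"""Local alignments with PSL semantics and a native genome aligner.

The pipeline's alignment interchange is the UCSC PSL dialect (21 tab-separated
columns, 0-based half-open).  Any producer of :class:`AlignmentRecord`
collections is accepted — externally generated PSL files or the native
:func:`genome_align` below, a seed-and-extend aligner built on an exact-k-mer
index with Smith–Waterman extension, so the whole pipeline runs without
third-party binaries.

Coordinate conventions follow PSL: ``query_start``/``query_end`` are always on
the forward-oriented query, even for '-' strand records; the per-block
``q_starts`` list is kept in PSL-native form (reversed-query coordinates for
'-' strand records) so reading and writing PSL is lossless.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from Bio import Align

from .annotation import GenomeRef
from .util import revcomp

# Scoring used for all Smith-Waterman extensions/realignments: match +1,
# mismatch -2, gap open -5 (first gap base), gap extend -2.  Thresholds, not
# scores, are the pipeline's contract; these approximate BLAST defaults.
MATCH = 1
MISMATCH = -2
GAP_OPEN = -5
GAP_EXTEND = -2


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


_ALIGNER = _make_aligner()


def _make_extension_aligner() -> Align.PairwiseAligner:
    # Stricter scheme for genome seed extension: a local alignment's end
    # should not drift past a chimeric junction on chance matches.  Under
    # +1/-2 scoring a spurious 7 bp extension carrying two mismatches still
    # gains score (~1% per junction side); -3 mismatches and -8/-3 gaps make
    # net-positive spurious extensions beyond the 6 bp boundary-offset
    # tolerance rare, keeping breakpoint estimates snappable.
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH
    aligner.mismatch_score = -3
    aligner.open_gap_score = -8
    aligner.extend_gap_score = -3
    return aligner


_EXT_ALIGNER = _make_extension_aligner()


@dataclass
class AlignmentRecord:
    """One local alignment of a read segment to the genome (PSL semantics)."""

    query_id: str
    query_length: int
    strand: str
    query_start: int  # forward-query coordinates, 0-based half-open
    query_end: int
    chrom: str
    target_length: int
    target_start: int
    target_end: int
    matches: int
    mismatches: int
    block_sizes: Tuple[int, ...]
    q_starts: Tuple[int, ...]  # PSL-native: reversed-query coords on '-' strand
    t_starts: Tuple[int, ...]
    score: Optional[float] = field(default=None, compare=False)

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    @property
    def identity(self) -> float:
        return self.matches / self.query_span if self.query_span else 0.0


@dataclass
class LocalAlignmentResult:
    """Optimal word-anchored local alignment of a query against a target."""

    score: float
    matches: int
    mismatches: int
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    blocks: Tuple[Tuple[int, int, int], ...]  # (q_start, t_start, length)

    @property
    def identity_fraction(self) -> float:
        span = self.query_end - self.query_start
        return self.matches / span if span else 0.0


# ---------------------------------------------------------------------------
# PSL I/O


def parse_psl(path: os.PathLike | str) -> List[AlignmentRecord]:
    """Parse PSL or PSLX, with or without the 5-line header.

    For '-' strand records PSL stores qStart/qEnd already in forward-query
    coordinates (qStart' = qSize - qEnd of the reversed query), which is the
    normalization this package uses internally; the block-level qStarts stay
    PSL-native.
    """
    records: List[AlignmentRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(("psLayout", "match", "-----", " ")):
                continue
            fields = line.split("\t")
            if len(fields) < 21:
                raise ValueError(f"{path}:{ln}: PSL needs >=21 columns, got {len(fields)}")
            try:
                block_count = int(fields[17])
                block_sizes = tuple(int(x) for x in fields[18].split(",") if x != "")
                q_starts = tuple(int(x) for x in fields[19].split(",") if x != "")
                t_starts = tuple(int(x) for x in fields[20].split(",") if x != "")
                if not (len(block_sizes) == len(q_starts) == len(t_starts) == block_count):
                    raise ValueError("block list lengths disagree with blockCount")
                rec = AlignmentRecord(
                    query_id=fields[9],
                    query_length=int(fields[10]),
                    strand=fields[8],
                    query_start=int(fields[11]),
                    query_end=int(fields[12]),
                    chrom=fields[13],
                    target_length=int(fields[14]),
                    target_start=int(fields[15]),
                    target_end=int(fields[16]),
                    matches=int(fields[0]),
                    mismatches=int(fields[1]),
                    block_sizes=block_sizes,
                    q_starts=q_starts,
                    t_starts=t_starts,
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed PSL line: {exc}") from None
            records.append(rec)
    return records


def write_psl(records: Iterable[AlignmentRecord], path: os.PathLike | str) -> None:
    with open(path, "w") as fh:
        for r in records:
            gaps_q = _gap_stats(r.q_starts, r.block_sizes)
            gaps_t = _gap_stats(r.t_starts, r.block_sizes)
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        r.matches,
                        r.mismatches,
                        0,
                        0,
                        gaps_q[0],
                        gaps_q[1],
                        gaps_t[0],
                        gaps_t[1],
                        r.strand,
                        r.query_id,
                        r.query_length,
                        r.query_start,
                        r.query_end,
                        r.chrom,
                        r.target_length,
                        r.target_start,
                        r.target_end,
                        len(r.block_sizes),
                        "".join(f"{b}," for b in r.block_sizes),
                        "".join(f"{q}," for q in r.q_starts),
                        "".join(f"{t}," for t in r.t_starts),
                    ]
                )
                + "\n"
            )


def _gap_stats(starts: Sequence[int], sizes: Sequence[int]) -> Tuple[int, int]:
    n_insert = base_insert = 0
    for i in range(1, len(starts)):
        gap = starts[i] - (starts[i - 1] + sizes[i - 1])
        if gap > 0:
            n_insert += 1
            base_insert += gap
    return n_insert, base_insert


# ---------------------------------------------------------------------------
# Word-anchored local alignment (pairwise BLAST-style)


def _has_shared_word(query: str, target: str, word_size: int) -> bool:
    if len(query) < word_size or len(target) < word_size:
        return False
    words = {query[i : i + word_size] for i in range(len(query) - word_size + 1)}
    for i in range(len(target) - word_size + 1):
        if target[i : i + word_size] in words:
            return True
    return False


def _alignment_to_blocks(alignment) -> Tuple[Tuple[Tuple[int, int, int], ...], int, int]:
    """(blocks, matches, mismatches) from a Bio.Align alignment (query first)."""
    q_blocks, t_blocks = alignment.aligned
    query = str(alignment.sequences[0])
    target = str(alignment.sequences[1])
    blocks = []
    matches = mismatches = 0
    for (qs, qe), (ts, te) in zip(q_blocks, t_blocks):
        blocks.append((int(qs), int(ts), int(qe - qs)))
        for a, b in zip(query[qs:qe], target[ts:te]):
            if a == b:
                matches += 1
            else:
                mismatches += 1
    return tuple(blocks), matches, mismatches


def local_align(query: str, target: str, word_size: int) -> Optional[LocalAlignmentResult]:
    """Optimal local alignment, gated on a shared exact word of ``word_size``.

    Returns None unless query and target share at least one exact word of the
    given size; otherwise the optimal Smith-Waterman local alignment under the
    module scoring scheme.  ``identity_fraction`` is matches over the aligned
    query span.
    """
    if not query or not target:
        raise ValueError("local_align requires non-empty sequences")
    if not _has_shared_word(query, target, word_size):
        return None
    alignments = _ALIGNER.align(query, target)
    aln = alignments[0]
    blocks, matches, mismatches = _alignment_to_blocks(aln)
    if not blocks:
        return None
    return LocalAlignmentResult(
        score=float(aln.score),
        matches=matches,
        mismatches=mismatches,
        query_start=blocks[0][0],
        query_end=blocks[-1][0] + blocks[-1][2],
        target_start=blocks[0][1],
        target_end=blocks[-1][1] + blocks[-1][2],
        blocks=blocks,
    )


# ---------------------------------------------------------------------------
# Native genome aligner


_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _encode_kmers(seq: str, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """(kmer values, valid mask) for every window start of ``seq``."""
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    m = n - k + 1
    vals = np.zeros(m, dtype=np.uint64)
    bad = np.zeros(m, dtype=bool)
    for j in range(k):
        c = codes[j : m + j]
        vals = (vals << np.uint64(2)) | (c & np.uint8(3)).astype(np.uint64)
        bad |= c == 4
    return vals, ~bad


class GenomeIndex:
    """Sorted exact-k-mer index over a genome for seed lookup."""

    def __init__(self, genome: GenomeRef, seed_length: int = 20, max_kmer_hits: int = 64):
        self.genome = genome
        self.k = seed_length
        self.max_kmer_hits = max_kmer_hits
        self.chrom_names: List[str] = []
        self.chrom_offsets: List[int] = []  # global start per chromosome
        self.chrom_lengths: List[int] = []
        kmer_parts, pos_parts = [], []
        off = 0
        for name in genome.sequences:
            seq = genome.sequences[name]
            vals, valid = _encode_kmers(seq, self.k)
            if vals.size:
                kmer_parts.append(vals[valid])
                pos_parts.append(np.nonzero(valid)[0].astype(np.int64) + off)
            self.chrom_names.append(name)
            self.chrom_offsets.append(off)
            self.chrom_lengths.append(len(seq))
            off += len(seq)
        if kmer_parts:
            kmers = np.concatenate(kmer_parts)
            pos = np.concatenate(pos_parts)
        else:
            kmers = np.empty(0, dtype=np.uint64)
            pos = np.empty(0, dtype=np.int64)
        order = np.argsort(kmers, kind="stable")
        self._kmers = kmers[order]
        self._pos = pos[order]
        self._offsets_arr = np.array(self.chrom_offsets + [off], dtype=np.int64)

    def locate(self, global_pos: int) -> Tuple[int, int]:
        """(chromosome index, chromosome-local position)."""
        ci = int(np.searchsorted(self._offsets_arr, global_pos, side="right")) - 1
        return ci, global_pos - self.chrom_offsets[ci]

    def seed_hits(self, seq: str) -> Tuple[np.ndarray, np.ndarray]:
        """(query positions, global target positions) of exact seed matches."""
        vals, valid = _encode_kmers(seq, self.k)
        if not vals.size:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        qpos_all = np.nonzero(valid)[0]
        vals = vals[valid]
        lo = np.searchsorted(self._kmers, vals, side="left")
        hi = np.searchsorted(self._kmers, vals, side="right")
        counts = hi - lo
        keep = (counts > 0) & (counts <= self.max_kmer_hits)
        q_out, t_out = [], []
        for q, l, h in zip(qpos_all[keep], lo[keep], hi[keep]):
            t = self._pos[l:h]
            q_out.append(np.full(t.size, q, dtype=np.int64))
            t_out.append(t)
        if not q_out:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        return np.concatenate(q_out), np.concatenate(t_out)


def _cluster_seeds(
    qpos: np.ndarray, tpos: np.ndarray, read_len: int, band: int = 8
) -> List[Tuple[int, int, int, int, int]]:
    """Group seed hits into diagonal clusters.

    Returns (n_hits, t_min_projected, t_max_projected, diag_lo, diag_hi) per
    cluster, where the projected interval is the read footprint implied by the
    cluster's seeds.
    """
    if qpos.size == 0:
        return []
    diag = tpos - qpos
    order = np.lexsort((tpos, diag))
    clusters = []
    cur = None
    for idx in order:
        d, q, t = int(diag[idx]), int(qpos[idx]), int(tpos[idx])
        if (
            cur is not None
            and d - cur["diag_hi"] <= band
            and t - cur["t_last"] <= read_len + band
        ):
            cur["n"] += 1
            cur["diag_hi"] = max(cur["diag_hi"], d)
            cur["t_last"] = max(cur["t_last"], t)
            cur["proj_lo"] = min(cur["proj_lo"], t - q)
            cur["proj_hi"] = max(cur["proj_hi"], t + (read_len - q))
        else:
            if cur is not None:
                clusters.append(cur)
            cur = {
                "n": 1,
                "diag_lo": d,
                "diag_hi": d,
                "t_last": t,
                "proj_lo": t - q,
                "proj_hi": t + (read_len - q),
            }
    clusters.append(cur)
    return [
        (c["n"], c["proj_lo"], c["proj_hi"], c["diag_lo"], c["diag_hi"]) for c in clusters
    ]


def _record_from_window(
    oriented_seq: str,
    strand: str,
    query_id: str,
    read_len: int,
    index: GenomeIndex,
    chrom_idx: int,
    win_start: int,
    win_end: int,
) -> Optional[AlignmentRecord]:
    chrom = index.chrom_names[chrom_idx]
    target = index.genome.sequences[chrom][win_start:win_end]
    if not target:
        return None
    alignments = _EXT_ALIGNER.align(oriented_seq, target)
    aln = alignments[0]
    blocks, matches, mismatches = _alignment_to_blocks(aln)
    if not blocks:
        return None
    q_lo = blocks[0][0]
    q_hi = blocks[-1][0] + blocks[-1][2]
    t_lo = blocks[0][1] + win_start
    t_hi = blocks[-1][1] + blocks[-1][2] + win_start
    if strand == "+":
        query_start, query_end = q_lo, q_hi
    else:
        # oriented_seq is the reverse complement; normalize to forward query
        query_start, query_end = read_len - q_hi, read_len - q_lo
    return AlignmentRecord(
        query_id=query_id,
        query_length=read_len,
        strand=strand,
        query_start=query_start,
        query_end=query_end,
        chrom=chrom,
        target_length=index.chrom_lengths[chrom_idx],
        target_start=t_lo,
        target_end=t_hi,
        matches=matches,
        mismatches=mismatches,
        block_sizes=tuple(b[2] for b in blocks),
        q_starts=tuple(b[0] for b in blocks),
        t_starts=tuple(b[1] + win_start for b in blocks),
        score=float(aln.score),
    )


def genome_align(
    sequence: str,
    index: GenomeIndex,
    query_id: str = "query",
    max_reported: int = 5,
    max_clusters: int = 24,
    window_pad: int = 12,
) -> List[AlignmentRecord]:
    """Seed-and-extend local alignment of a read against the indexed genome.

    Both orientations are scanned; exact seed matches of the index's seed
    length anchor diagonal clusters which are extended by Smith-Waterman over
    a padded window.  Up to ``max_reported`` best records per orientation are
    returned, distinct loci only, sorted by score (ties by chrom, start).
    """
    read_len = len(sequence)
    if read_len < index.k:
        return []
    out: List[AlignmentRecord] = []
    for strand in "+-":
        oriented = sequence if strand == "+" else revcomp(sequence)
        qpos, tpos = index.seed_hits(oriented)
        if qpos.size == 0:
            continue
        clusters = _cluster_seeds(qpos, tpos, read_len)
        clusters.sort(key=lambda c: (-c[0], c[1]))
        records: List[AlignmentRecord] = []
        for n_hits, proj_lo, proj_hi, _dlo, _dhi in clusters[:max_clusters]:
            ci, local_lo = index.locate(max(proj_lo, 0))
            chrom_len = index.chrom_lengths[ci]
            chrom_off = index.chrom_offsets[ci]
            win_start = max(proj_lo - chrom_off - window_pad, 0)
            win_end = min(proj_hi - chrom_off + window_pad, chrom_len)
            if win_end <= win_start:
                continue
            rec = _record_from_window(
                oriented, strand, query_id, read_len, index, ci, win_start, win_end
            )
            if rec is not None and rec.query_span >= index.k:
                records.append(rec)
        # distinct loci: drop records mostly overlapping a better-scoring one
        records.sort(key=lambda r: (-(r.score or 0), r.chrom, r.target_start))
        kept: List[AlignmentRecord] = []
        for rec in records:
            dup = False
            for other in kept:
                if rec.chrom == other.chrom:
                    ov = min(rec.target_end, other.target_end) - max(
                        rec.target_start, other.target_start
                    )
                    span = min(rec.target_end - rec.target_start,
                               other.target_end - other.target_start)
                    if span > 0 and ov > 0.5 * span:
                        dup = True
                        break
            if not dup:
                kept.append(rec)
            if len(kept) >= max_reported:
                break
        out.extend(kept)
    out.sort(key=lambda r: (-(r.score or 0), r.chrom, r.target_start, r.strand))
    return out


# ---------------------------------------------------------------------------
# Candidate-read pre-selection


def select_candidate_reads(
    alignments_by_query: Dict[str, List[AlignmentRecord]],
    candidate_min: int = 2,
    candidate_max: int = 11,
) -> Dict[str, List[AlignmentRecord]]:
    """Keep queries whose alignment count n satisfies min <= n <= max.

    A single alignment cannot form a split; too many indicates repetitive
    ambiguity.  Both orientations are pooled.
    """
    return {
        q: recs
        for q, recs in alignments_by_query.items()
        if candidate_min <= len(recs) <= candidate_max
    }


def subtract_concordant(
    alignments_by_query: Dict[str, List[AlignmentRecord]],
    min_cover: float = 0.95,
    min_identity: float = 0.98,
) -> Dict[str, List[AlignmentRecord]]:
    """Drop reads explained by a single full-length concordant alignment.

    Reproduces the transcriptome/genome pre-mapping subtraction: a read with
    exactly one reported locus covering >= ``min_cover`` of its length at
    >= ``min_identity`` identity is a regular (non-chimeric) read.
    """
    out = {}
    for q, recs in alignments_by_query.items():
        if len(recs) == 1:
            r = recs[0]
            if r.query_span >= min_cover * r.query_length and r.identity >= min_identity:
                continue
        out[q] = recs
    return out
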