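"""Read preprocessing: 3'-quality trimming, homopolymer-artifact removal,
and collapsing identical sequences into unique reads with multiplicities.

Paired-end mates are deliberately decoupled: both FASTQ streams are pooled
into one and every mate is treated as an independent single read, because the
junction evidence the detector needs is a single read spanning the fusion
point, not a concordant pair.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple


@dataclass
class SequencedRead:
    read_id: str
    sequence: str
    qualities: List[int]
    mate: Optional[int] = None  # 1, 2 or None

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"{self.read_id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )


@dataclass
class UniqueRead:
    sequence: str
    count: int
    member_ids: List[str]

    def __post_init__(self):
        if self.count != len(self.member_ids) or self.count < 1:
            raise ValueError("count must equal number of member ids and be >= 1")


def quality_trim(
    read: SequencedRead, qual_threshold: int = 10, min_length: int = 38
) -> Optional[SequencedRead]:
    """Trim low-quality bases from the 3' end; drop reads shorter than
    ``min_length`` after trimming.

    Bases are removed from the 3' end while the terminal base quality is below
    ``qual_threshold`` (trimming is terminal-only; internal low-quality bases
    are untouched).  Surviving reads of length >= ``min_length`` are kept.
    """
    end = len(read.sequence)
    while end > 0 and read.qualities[end - 1] < qual_threshold:
        end -= 1
    if end < min_length:
        return None
    if end == len(read.sequence):
        return read
    return SequencedRead(read.read_id, read.sequence[:end], read.qualities[:end], read.mate)


def artifact_filter(read: SequencedRead, max_other: int = 3) -> bool:
    """Keep/discard flag for homopolymer artifacts.

    A read is an artifact (returns False) when all bases except at most
    ``max_other`` are one identical nucleotide.
    """
    if not read.sequence:
        raise ValueError("empty sequence")
    counts: Dict[str, int] = {}
    for base in read.sequence:
        counts[base] = counts.get(base, 0) + 1
    dominant = max(counts.values())
    return (len(read.sequence) - dominant) > max_other


def collapse(reads: Iterable[SequencedRead]) -> List[UniqueRead]:
    """Collapse identical sequences into unique reads with counts.

    Collapse is on the literal sequence string; a read and its reverse
    complement stay distinct (strand handling happens at alignment).  Output
    is ordered by descending count, ties broken by sequence, so the ranking
    is deterministic.
    """
    groups: Dict[str, List[str]] = {}
    for r in reads:
        groups.setdefault(r.sequence, []).append(r.read_id)
    out = [UniqueRead(seq, len(ids), ids) for seq, ids in groups.items()]
    out.sort(key=lambda u: (-u.count, u.sequence))
    return out


# ---------------------------------------------------------------------------
# FASTQ / FASTA I/O


def read_fastq(path: os.PathLike | str, phred_offset: int = 33, mate: Optional[int] = None
               ) -> Iterator[SequencedRead]:
    """Iterate 4-line FASTQ records (Sanger Phred+33 by default)."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise ValueError(f"{path}: malformed FASTQ header {header!r}")
            seq = fh.readline().rstrip("\n").upper()
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not plus.startswith("+"):
                raise ValueError(f"{path}: malformed FASTQ separator for {header!r}")
            yield SequencedRead(
                read_id=header[1:].split()[0],
                sequence=seq,
                qualities=[ord(c) - phred_offset for c in qual],
                mate=mate,
            )


def write_fastq(reads: Iterable[SequencedRead], path: os.PathLike | str,
                phred_offset: int = 33) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + phred_offset) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def write_collapsed_fasta(unique_reads: Iterable[UniqueRead], path: os.PathLike | str) -> None:
    """FASTA with ``rank-count`` headers (fastx_collapser dialect)."""
    with open(path, "w") as fh:
        for rank, u in enumerate(unique_reads, 1):
            fh.write(f">{rank}-{u.count}\n{u.sequence}\n")


def write_collapsed_tsv(unique_reads: Iterable[UniqueRead], path: os.PathLike | str) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tcount\tsequence\tmember_ids\n")
        for rank, u in enumerate(unique_reads, 1):
            fh.write(f"{rank}\t{u.count}\t{u.sequence}\t{','.join(u.member_ids)}\n")


# ---------------------------------------------------------------------------
# Driver


def preprocess_reads(
    reads: Iterable[SequencedRead],
    qual_threshold: int = 10,
    min_length: int = 38,
) -> Tuple[List[UniqueRead], Dict[str, int]]:
    """Trim, artifact-filter, and collapse a pooled read stream.

    Returns the unique reads plus per-stage counts for the run summary.
    """
    n_input = n_trimmed = n_clean = 0
    survivors: List[SequencedRead] = []
    for r in reads:
        n_input += 1
        t = quality_trim(r, qual_threshold, min_length)
        if t is None:
            continue
        n_trimmed += 1
        if not artifact_filter(t):
            continue
        n_clean += 1
        survivors.append(t)
    unique = collapse(survivors)
    counts = {
        "input_reads": n_input,
        "after_quality_trim": n_trimmed,
        "after_artifact_filter": n_clean,
        "unique_reads": len(unique),
    }
    return unique, counts
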