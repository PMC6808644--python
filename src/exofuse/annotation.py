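"""Genome and transcriptome models plus the auxiliary filter lists.

The transcriptome is the UCSC refGene flat-file dialect: one transcript per
line with comma-terminated exonStarts/exonEnds lists, 0-based half-open
coordinates, and the gene symbol in the ``name2`` column.  All coordinates in
this package are 0-based half-open throughout.

Besides parsing, this module answers the coordinate queries the detector
needs: projecting a genomic position into transcript (spliced) coordinates,
finding the nearest eligible exon boundary for a putative fusion junction,
deciding whether an ordered gene pair is a read-through configuration, and
testing repeat overlap.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .util import revcomp

HEAD_3PRIME = "head_3prime"
TAIL_5PRIME = "tail_5prime"


# ---------------------------------------------------------------------------
# Genome


class GenomeRef:
    """In-memory reference genome: chromosome name -> uppercase sequence."""

    def __init__(self, sequences: Dict[str, str]):
        self.sequences = {name: seq.upper() for name, seq in sequences.items()}
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} has empty sequence")

    @classmethod
    def from_fasta(cls, path: os.PathLike | str) -> "GenomeRef":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.sequences[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome bounds (len {len(seq)})"
            )
        return seq[start:end]

    def write_fasta(self, path: os.PathLike | str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Transcript model


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript's exon structure on the genome.

    ``exons`` are non-overlapping genomic intervals sorted ascending by start,
    regardless of strand; transcription order is reversed for minus-strand
    transcripts.
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.transcript_id}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.transcript_id}: empty exon ({s},{e})")
            if s < prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exons_in_tx_order(self) -> List[Tuple[int, int]]:
        """Exons ordered 5'->3' in transcription direction."""
        return list(self.exons) if self.strand == "+" else list(self.exons[::-1])

    def genomic_to_tx_index(self, tx_order_index: int) -> int:
        """Convert a transcription-order exon index to the genomic-order index."""
        if self.strand == "+":
            return tx_order_index
        return len(self.exons) - 1 - tx_order_index

    def spliced_sequence(self, genome: GenomeRef) -> str:
        parts = [genome.fetch(self.chrom, s, e) for s, e in self.exons]
        seq = "".join(parts)
        return seq if self.strand == "+" else revcomp(seq)


@dataclass(frozen=True)
class ExonBoundary:
    """One exon edge, annotated with its junction role eligibility.

    ``is_donor_side`` is True when this edge is a transcription-3' exon end,
    i.e. it can serve as the head gene's junction point.
    """

    transcript_id: str
    exon_index: int  # 0-based in genomic order
    side: str  # "start" | "end"
    genomic_position: int
    is_donor_side: bool


# ---------------------------------------------------------------------------
# Auxiliary filter lists


class AuxiliaryLists:
    """Repeat intervals, paralog pairs, pseudogenes and the fusion blacklist."""

    def __init__(
        self,
        repeat_intervals: Optional[Dict[str, Iterable[Tuple[int, int]]]] = None,
        paralog_pairs: Optional[Iterable[Tuple[str, str]]] = None,
        pseudogenes: Optional[Iterable[str]] = None,
        blacklist: Optional[Iterable[Tuple[str, str]]] = None,
    ):
        self.repeat_trees: Dict[str, IntervalTree] = {}
        for chrom, ivs in (repeat_intervals or {}).items():
            tree = IntervalTree()
            for s, e in ivs:
                if e > s:
                    tree.addi(s, e)
            self.repeat_trees[chrom] = tree
        self.paralog_pairs = {frozenset(p) for p in (paralog_pairs or [])}
        self.pseudogenes = set(pseudogenes or [])
        self.blacklist = {tuple(p) for p in (blacklist or [])}

    # -- loaders ----------------------------------------------------------
    @classmethod
    def load(
        cls,
        repeats_bed: Optional[str] = None,
        paralogs_tsv: Optional[str] = None,
        pseudogenes_txt: Optional[str] = None,
        blacklist_tsv: Optional[str] = None,
    ) -> "AuxiliaryLists":
        repeats: Dict[str, List[Tuple[int, int]]] = {}
        if repeats_bed:
            with open(repeats_bed) as fh:
                for ln, line in enumerate(fh, 1):
                    line = line.strip()
                    if not line or line.startswith(("#", "track", "browser")):
                        continue
                    parts = line.split("\t")
                    if len(parts) < 3:
                        raise ValueError(f"{repeats_bed}:{ln}: BED needs >=3 columns")
                    repeats.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
        paralogs = []
        if paralogs_tsv:
            with open(paralogs_tsv) as fh:
                for line in fh:
                    parts = line.split()
                    if len(parts) >= 2:
                        paralogs.append((parts[0], parts[1]))
        pseudo = []
        if pseudogenes_txt:
            with open(pseudogenes_txt) as fh:
                pseudo = [line.strip() for line in fh if line.strip()]
        black = []
        if blacklist_tsv:
            with open(blacklist_tsv) as fh:
                for line in fh:
                    parts = line.split()
                    if len(parts) >= 2:
                        black.append((parts[0], parts[1]))
        return cls(repeats, paralogs, pseudo, black)

    # -- queries ----------------------------------------------------------
    def is_paralog_pair(self, gene_a: str, gene_b: str) -> bool:
        return frozenset((gene_a, gene_b)) in self.paralog_pairs

    def in_blacklist(self, head: str, tail: str) -> bool:
        return (head, tail) in self.blacklist

    def repeat_overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self.repeat_trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))


def overlaps_repeat(chrom: str, interval: Tuple[int, int], aux: AuxiliaryLists) -> bool:
    """True iff the half-open interval intersects any repeat by >= 1 bp."""
    return aux.repeat_overlaps(chrom, interval[0], interval[1])


# ---------------------------------------------------------------------------
# Annotation collection


class Annotation:
    """Indexed collection of transcripts with per-chromosome interval trees."""

    def __init__(self, transcripts: Sequence[TranscriptModel]):
        self.transcripts: Dict[str, TranscriptModel] = {}
        self.by_gene: Dict[str, List[TranscriptModel]] = {}
        self._trees: Dict[str, IntervalTree] = {}
        for t in transcripts:
            if t.transcript_id in self.transcripts:
                raise ValueError(f"duplicate transcript id {t.transcript_id}")
            self.transcripts[t.transcript_id] = t
            self.by_gene.setdefault(t.gene_symbol, []).append(t)
            self._trees.setdefault(t.chrom, IntervalTree()).addi(
                t.tx_start, t.tx_end, t.transcript_id
            )
        self._gene_spans: Dict[str, Tuple[str, str, int, int]] = {}
        for gene, ts in self.by_gene.items():
            chroms = {t.chrom for t in ts}
            strands = {t.strand for t in ts}
            if len(chroms) > 1 or len(strands) > 1:
                raise ValueError(f"gene {gene}: isoforms disagree on chrom/strand")
            self._gene_spans[gene] = (
                ts[0].chrom,
                ts[0].strand,
                min(t.tx_start for t in ts),
                max(t.tx_end for t in ts),
            )
        self._genes_by_chrom: Dict[str, List[str]] = {}
        for gene, (chrom, _s, start, _e) in self._gene_spans.items():
            self._genes_by_chrom.setdefault(chrom, []).append(gene)
        for chrom in self._genes_by_chrom:
            self._genes_by_chrom[chrom].sort(key=lambda g: self._gene_spans[g][2])

    @property
    def genes(self) -> List[str]:
        return sorted(self.by_gene)

    def gene_span(self, gene: str) -> Tuple[str, str, int, int]:
        """(chrom, strand, start, end) union span of the gene's isoforms."""
        return self._gene_spans[gene]

    def transcripts_overlapping(self, chrom: str, start: int, end: int) -> List[TranscriptModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = tree.overlap(start, end)
        return sorted((self.transcripts[iv.data] for iv in hits), key=lambda t: t.transcript_id)

    def validate_against(self, genome: GenomeRef) -> None:
        for t in self.transcripts.values():
            if t.chrom not in genome.sequences:
                raise ValueError(f"{t.transcript_id}: chromosome {t.chrom} missing from genome")
            if t.tx_end > len(genome.sequences[t.chrom]):
                raise ValueError(f"{t.transcript_id}: exons extend past end of {t.chrom}")


# ---------------------------------------------------------------------------
# refGene parsing / writing


def parse_refgene(path: os.PathLike | str) -> List[TranscriptModel]:
    """Parse a refGene flat file, with or without the leading ``bin`` column.

    The dialect is auto-detected per line by column count (16 columns with the
    bin field, 15 without; truncated files with only the first 13 fields after
    ``bin`` removal are also accepted as long as name2 is present).
    """
    models: List[TranscriptModel] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 16:
                fields = fields[1:]  # drop bin
            if len(fields) < 13:
                raise ValueError(f"{path}:{ln}: expected >=15 refGene columns, got {len(fields) + 1}")
            try:
                name, chrom, strand = fields[0], fields[1], fields[2]
                exon_count = int(fields[7])
                starts = [int(x) for x in fields[8].split(",") if x != ""]
                ends = [int(x) for x in fields[9].split(",") if x != ""]
                name2 = fields[11]
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{ln}: malformed refGene line: {exc}") from None
            if len(starts) != exon_count or len(ends) != exon_count:
                raise ValueError(
                    f"{path}:{ln}: exonCount={exon_count} but lists have "
                    f"{len(starts)}/{len(ends)} entries"
                )
            models.append(
                TranscriptModel(
                    transcript_id=name,
                    gene_symbol=name2,
                    chrom=chrom,
                    strand=strand,
                    exons=tuple(zip(starts, ends)),
                )
            )
    return models


def write_refgene(transcripts: Iterable[TranscriptModel], path: os.PathLike | str) -> None:
    """Write transcripts back to the 15-column (bin-less) refGene dialect."""
    with open(path, "w") as fh:
        for t in transcripts:
            starts = "".join(f"{s}," for s, _ in t.exons)
            ends = "".join(f"{e}," for _, e in t.exons)
            frames = "-1," * len(t.exons)
            fh.write(
                "\t".join(
                    [
                        t.transcript_id,
                        t.chrom,
                        t.strand,
                        str(t.tx_start),
                        str(t.tx_end),
                        str(t.tx_start),
                        str(t.tx_start),
                        str(len(t.exons)),
                        starts,
                        ends,
                        "0",
                        t.gene_symbol,
                        "unk",
                        "unk",
                        frames,
                    ]
                )
                + "\n"
            )


def load_annotation(refgene_path, genome_path) -> Tuple[GenomeRef, Annotation]:
    """Load a genome FASTA plus refGene annotation and cross-validate them."""
    genome = GenomeRef.from_fasta(genome_path)
    annotation = Annotation(parse_refgene(refgene_path))
    annotation.validate_against(genome)
    return genome, annotation


# ---------------------------------------------------------------------------
# Coordinate and adjacency queries


def transcript_coordinate(t: TranscriptModel, genomic_pos: int) -> Optional[int]:
    """Spliced-transcript offset of a genomic position, or None if intronic.

    The offset counts exonic bases 5' of the position in transcription
    direction, so minus-strand transcripts count from the genomic tx_end side.
    """
    offset_from_left = 0
    inside = None
    for s, e in t.exons:
        if s <= genomic_pos < e:
            inside = offset_from_left + (genomic_pos - s)
            break
        offset_from_left += e - s
    if inside is None:
        return None
    if t.strand == "+":
        return inside
    return t.exonic_length - 1 - inside


def _eligible_boundaries(t: TranscriptModel, role: str) -> List[ExonBoundary]:
    out = []
    donor_side_is_end = t.strand == "+"
    for i, (s, e) in enumerate(t.exons):
        if role == HEAD_3PRIME:
            # transcription-3' edge of each exon
            pos, side = (e, "end") if donor_side_is_end else (s, "start")
            out.append(ExonBoundary(t.transcript_id, i, side, pos, True))
        elif role == TAIL_5PRIME:
            pos, side = (s, "start") if donor_side_is_end else (e, "end")
            out.append(ExonBoundary(t.transcript_id, i, side, pos, False))
        else:
            raise ValueError(f"unknown role {role!r}")
    return out


def nearest_exon_boundary(
    transcripts: Sequence[TranscriptModel], genomic_pos: int, role: str
) -> Optional[Tuple[ExonBoundary, int]]:
    """Nearest eligible exon boundary to ``genomic_pos`` among ``transcripts``.

    Returns (boundary, unsigned offset) minimizing the distance; ties are
    broken by smaller offset, then greater total exonic length of the
    transcript, then lexicographic transcript id.
    """
    best = None
    for t in transcripts:
        for b in _eligible_boundaries(t, role):
            off = abs(genomic_pos - b.genomic_position)
            key = (off, -t.exonic_length, t.transcript_id, b.exon_index)
            if best is None or key < best[0]:
                best = (key, b, off)
    if best is None:
        return None
    return best[1], best[2]


def are_read_through(gene_a: str, gene_b: str, annotation: Annotation) -> bool:
    """True iff ``gene_a`` -> ``gene_b`` is a read-through configuration.

    Requires same chromosome, same strand, ``gene_a`` transcriptionally
    upstream of ``gene_b``, and no third annotated gene lying entirely in the
    gap between the two gene spans (overlapping pairs count as consecutive).
    """
    span_a = annotation.gene_span(gene_a)  # raises KeyError on unknown symbol
    span_b = annotation.gene_span(gene_b)
    if gene_a == gene_b:
        return False
    chrom_a, strand_a, start_a, end_a = span_a
    chrom_b, strand_b, start_b, end_b = span_b
    if chrom_a != chrom_b or strand_a != strand_b:
        return False
    if strand_a == "+":
        upstream = start_a < start_b or (start_a == start_b and end_a < end_b)
    else:
        upstream = end_a > end_b or (end_a == end_b and start_a > start_b)
    if not upstream:
        return False
    gap_lo = min(end_a, end_b)
    gap_hi = max(start_a, start_b)
    if gap_lo >= gap_hi:
        return True  # overlapping genes: still consecutive
    for gene_c in annotation._genes_by_chrom.get(chrom_a, []):
        if gene_c in (gene_a, gene_b):
            continue
        _, _, start_c, end_c = annotation.gene_span(gene_c)
        if start_c >= gap_lo and end_c <= gap_hi:
            return False
    return True
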