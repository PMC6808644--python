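"""Synthetic fixtures, fusion truth sets, paired-end read simulation, and
precision/recall scoring.

The fixture generator builds a fully synthetic genome and annotation —
multi-exon genes on both strands separated by large intergenic gaps, with
optional planted repeats, sequence paralogs, forced same-strand adjacent
gene pairs, and pseudogene labels — so every pipeline stage is testable
without any external reference data.

Fusion truths join the spliced 5' portion of a randomly chosen head
transcript to the 3' portion of a tail transcript at exact exon boundaries,
avoiding same-gene and adjacent-gene (read-through-like) pairs.  Reads are
drawn as uniform random paired-end fragments over the chimeric transcript,
with a Normal inner insert, until both a mean per-base depth target and a
95% positional-coverage requirement are met.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .annotation import Annotation, AuxiliaryLists, GenomeRef, TranscriptModel, are_read_through
from .detect import FusionCandidate
from .preprocess import SequencedRead
from .util import revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimParams:
    """Read-simulation settings.

    ``depth`` is the mean per-base coverage over the fusion transcript;
    ``insert_mean``/``insert_sd`` parameterize the inner mate distance (the
    gap between the 3' end of mate 1 and the 5' end of mate 2), Normal and
    truncated at zero.  No sequencing errors are simulated by default;
    ``error_rate`` adds uniform per-base substitutions for robustness tests.
    """

    n_fusions: int = 50
    read_length: int = 100
    depth: float = 50.0
    insert_mean: float = 100.0
    insert_sd: float = 10.0
    min_transcript_coverage: float = 0.95
    error_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.read_length <= 0 or self.depth <= 0 or self.n_fusions <= 0:
            raise ValueError("n_fusions, read_length and depth must be positive")
        if not (0 < self.min_transcript_coverage <= 1):
            raise ValueError("min_transcript_coverage must be in (0,1]")


@dataclass
class SimulatedFusionTruth:
    """One generated fusion case with its chimeric transcript."""

    case_id: str
    head_gene: str
    tail_gene: str
    head_transcript: str
    tail_transcript: str
    head_exon_index: int  # genomic-order index
    tail_exon_index: int
    head_chrom: str
    tail_chrom: str
    head_breakpoint: int
    tail_breakpoint: int
    fusion_sequence: str
    junction_offset: int
    n_read_pairs: int = 0


@dataclass
class EvaluationResult:
    tp: int
    fp: int
    fn: int
    n_reversed: int = 0
    detail: List[Dict[str, str]] = field(default_factory=list)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) > 0 else math.nan

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) > 0 else math.nan

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        if math.isnan(p) or math.isnan(r) or (p + r) == 0:
            return math.nan
        return 2 * p * r / (p + r)

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "EvaluationResult":
        return cls(tp=tp, fp=fp, fn=fn)


# ---------------------------------------------------------------------------
# Fixture generation


def _random_bases(rng: np.random.Generator, n: int) -> bytearray:
    return bytearray(_BASES[rng.integers(0, 4, n)].tobytes())


def _mutate(seq: bytes, rate: float, rng: np.random.Generator) -> bytes:
    arr = np.frombuffer(bytes(seq), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes()


def make_fixture(
    n_genes: int,
    exons_per_gene_range: Tuple[int, int] = (2, 8),
    rng_seed: int = 0,
    planted: Optional[Dict[str, int]] = None,
    n_chroms: int = 2,
    exon_len_range: Tuple[int, int] = (60, 300),
    intron_len_range: Tuple[int, int] = (200, 2000),
    min_intergenic: int = 60_000,
    extra_intergenic: int = 20_000,
    repeat_length: int = 300,
    repeat_copies: int = 8,
    paralog_divergence: float = 0.02,
) -> Tuple[GenomeRef, Annotation, AuxiliaryLists]:
    """Build a synthetic genome, annotation, and auxiliary lists.

    Genes have 2-8 exons (60-300 bp) separated by 200-2,000 bp introns;
    neighboring genes sit >= 60 kbp apart so genuine inter-gene splits clear
    the 50 kbp genomic-distance rule.  ``planted`` may request ``repeats``
    (repeat families copied into intergenic space and recorded as repeat
    intervals), ``paralog_pairs`` (gene pairs with ~98%-identical exonic
    sequence, listed as paralogs), ``adjacent_pairs`` (consecutive gene pairs
    forced onto the same strand — read-through decoy geometry), and
    ``pseudogenes`` (gene symbols labeled as pseudogenes).  Deterministic
    under ``rng_seed``.
    """
    plant = {"repeats": 0, "paralog_pairs": 0, "adjacent_pairs": 0, "pseudogenes": 0}
    plant.update(planted or {})
    if n_genes < 4:
        raise ValueError("need at least 4 genes")
    lo_e, hi_e = exons_per_gene_range
    lo_x, hi_x = exon_len_range
    lo_i, hi_i = intron_len_range
    rng = np.random.default_rng(rng_seed)

    # gene structural plans
    plans = []
    for g in range(n_genes):
        n_ex = int(rng.integers(lo_e, hi_e + 1))
        exon_lens = [int(x) for x in rng.integers(lo_x, hi_x + 1, n_ex)]
        intron_lens = [int(x) for x in rng.integers(lo_i, hi_i + 1, max(n_ex - 1, 0))]
        strand = "+" if rng.random() < 0.5 else "-"
        plans.append({"exon_lens": exon_lens, "intron_lens": intron_lens, "strand": strand})

    # paralog planting: the second gene of each pair copies the first's structure
    n_para = plant["paralog_pairs"]
    special = rng.choice(n_genes, size=min(2 * n_para, n_genes), replace=False)
    paralog_idx_pairs = [
        (int(special[2 * i]), int(special[2 * i + 1])) for i in range(n_para)
    ]
    for a, b in paralog_idx_pairs:
        plans[b] = {
            "exon_lens": list(plans[a]["exon_lens"]),
            "intron_lens": list(plans[a]["intron_lens"]),
            "strand": plans[a]["strand"],
        }

    # adjacency planting: force consecutive layout pairs onto one strand
    taken = {i for pair in paralog_idx_pairs for i in pair}
    adjacent_idx_pairs = []
    i = 0
    while len(adjacent_idx_pairs) < plant["adjacent_pairs"] and i + 1 < n_genes:
        if i not in taken and (i + 1) not in taken:
            plans[i + 1]["strand"] = plans[i]["strand"]
            adjacent_idx_pairs.append((i, i + 1))
            taken.update((i, i + 1))
            i += 2
        else:
            i += 1

    # layout genes across chromosomes in index order
    per_chrom = math.ceil(n_genes / n_chroms)
    chrom_seqs: Dict[str, bytearray] = {}
    transcripts: List[TranscriptModel] = []
    gene_coords: List[Tuple[str, List[Tuple[int, int]]]] = []  # chrom, exons
    gene_gaps: Dict[str, List[Tuple[int, int]]] = {}  # intergenic space per chrom
    g = 0
    for c in range(n_chroms):
        chrom = f"chr{c + 1}"
        cursor = 1000
        coords_here = []
        gaps_here = []
        genes_here = range(g, min(g + per_chrom, n_genes))
        for gi in genes_here:
            plan = plans[gi]
            exons = []
            pos = cursor
            for k, xl in enumerate(plan["exon_lens"]):
                exons.append((pos, pos + xl))
                pos += xl
                if k < len(plan["intron_lens"]):
                    pos += plan["intron_lens"][k]
            coords_here.append((gi, exons))
            gap = min_intergenic + int(rng.integers(0, extra_intergenic + 1))
            gaps_here.append((pos + 1000, pos + gap - 1000))
            cursor = pos + gap
        total_len = cursor + 1000
        chrom_seqs[chrom] = _random_bases(rng, total_len)
        for gi, exons in coords_here:
            transcripts.append(
                TranscriptModel(
                    transcript_id=f"NM_{gi:05d}",
                    gene_symbol=f"GENE{gi:04d}",
                    chrom=chrom,
                    strand=plans[gi]["strand"],
                    exons=tuple(exons),
                )
            )
            gene_coords.append((chrom, exons))
        gene_gaps[chrom] = gaps_here
        g += per_chrom

    gene_coords_by_idx = {int(t.transcript_id[3:]): t for t in transcripts}

    # paralog sequence copying (mutated exon copies)
    paralog_symbol_pairs = []
    for a, b in paralog_idx_pairs:
        ta, tb = gene_coords_by_idx[a], gene_coords_by_idx[b]
        for (sa, ea), (sb, eb) in zip(ta.exons, tb.exons):
            src = bytes(chrom_seqs[ta.chrom][sa:ea])
            chrom_seqs[tb.chrom][sb:eb] = _mutate(src, paralog_divergence, rng)
        paralog_symbol_pairs.append((ta.gene_symbol, tb.gene_symbol))

    # repeat planting in intergenic space
    repeat_intervals: Dict[str, List[Tuple[int, int]]] = {}
    if plant["repeats"] > 0:
        for fam in range(plant["repeats"]):
            motif = bytes(_random_bases(rng, repeat_length))
            placed = 0
            chroms = sorted(gene_gaps)
            attempts = 0
            while placed < repeat_copies and attempts < 1000:
                attempts += 1
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                gaps = gene_gaps[chrom]
                lo, hi = gaps[int(rng.integers(0, len(gaps)))]
                if hi - lo < repeat_length + 2:
                    continue
                start = int(rng.integers(lo, hi - repeat_length))
                chrom_seqs[chrom][start : start + repeat_length] = motif
                repeat_intervals.setdefault(chrom, []).append((start, start + repeat_length))
                placed += 1

    # pseudogene labels
    free = [i for i in range(n_genes) if i not in taken]
    n_pseudo = min(plant["pseudogenes"], len(free))
    pseudo_syms = [f"GENE{free[i]:04d}" for i in range(n_pseudo)]

    genome = GenomeRef({c: bytes(s).decode("ascii") for c, s in chrom_seqs.items()})
    annotation = Annotation(transcripts)
    annotation.validate_against(genome)
    aux = AuxiliaryLists(
        repeat_intervals=repeat_intervals,
        paralog_pairs=paralog_symbol_pairs,
        pseudogenes=pseudo_syms,
    )
    return genome, annotation, aux


# ---------------------------------------------------------------------------
# Truth-set generation


def _portion_sequences(
    t: TranscriptModel, genome: GenomeRef, tx_exon_idx: int, side: str
) -> str:
    tx_exons = t.exons_in_tx_order()
    chosen = tx_exons[: tx_exon_idx + 1] if side == "head" else tx_exons[tx_exon_idx:]
    parts = []
    for s, e in chosen:
        seq = genome.fetch(t.chrom, s, e)
        parts.append(seq if t.strand == "+" else revcomp(seq))
    return "".join(parts)


def generate_truth_set(
    annotation: Annotation,
    genome: GenomeRef,
    n_fusions: int,
    rng_seed: int = 0,
    min_length: Optional[int] = None,
) -> List[SimulatedFusionTruth]:
    """Uniformly random fusion truths at exact exon boundaries.

    Head junctions fall at a transcription-3' exon end and tail junctions at
    a transcription-5' exon start; same-gene pairs and adjacent gene pairs
    (in either order, to exclude read-through-like geometry) are rejected.
    ``min_length`` optionally rejects chimeras shorter than the given length
    (e.g. the read length) for which no read could be drawn.
    """
    rng = np.random.default_rng(rng_seed)
    genes = annotation.genes
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    truths: List[SimulatedFusionTruth] = []
    attempts = 0
    max_attempts = 200 * n_fusions + 1000
    while len(truths) < n_fusions:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("could not find enough valid non-adjacent gene pairs")
        ia, ib = rng.choice(len(genes), size=2, replace=False)
        head_gene, tail_gene = genes[int(ia)], genes[int(ib)]
        if are_read_through(head_gene, tail_gene, annotation) or are_read_through(
            tail_gene, head_gene, annotation
        ):
            continue
        head_iso = annotation.by_gene[head_gene]
        tail_iso = annotation.by_gene[tail_gene]
        head_t = head_iso[int(rng.integers(0, len(head_iso)))]
        tail_t = tail_iso[int(rng.integers(0, len(tail_iso)))]
        head_tx_idx = int(rng.integers(0, head_t.n_exons))
        tail_tx_idx = int(rng.integers(0, tail_t.n_exons))
        head_part = _portion_sequences(head_t, genome, head_tx_idx, "head")
        tail_part = _portion_sequences(tail_t, genome, tail_tx_idx, "tail")
        seq = head_part + tail_part
        if min_length is not None and len(seq) < min_length:
            continue
        head_gidx = head_t.genomic_to_tx_index(head_tx_idx)
        tail_gidx = tail_t.genomic_to_tx_index(tail_tx_idx)
        head_exon = head_t.exons[head_gidx]
        tail_exon = tail_t.exons[tail_gidx]
        head_bp = head_exon[1] if head_t.strand == "+" else head_exon[0]
        tail_bp = tail_exon[0] if tail_t.strand == "+" else tail_exon[1]
        truths.append(
            SimulatedFusionTruth(
                case_id=f"F{len(truths):04d}",
                head_gene=head_gene,
                tail_gene=tail_gene,
                head_transcript=head_t.transcript_id,
                tail_transcript=tail_t.transcript_id,
                head_exon_index=head_gidx,
                tail_exon_index=tail_gidx,
                head_chrom=head_t.chrom,
                tail_chrom=tail_t.chrom,
                head_breakpoint=head_bp,
                tail_breakpoint=tail_bp,
                fusion_sequence=seq,
                junction_offset=len(head_part),
            )
        )
    return truths


# ---------------------------------------------------------------------------
# Read simulation


def simulate_reads(
    truth: SimulatedFusionTruth,
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[Tuple[SequencedRead, SequencedRead]], Dict[str, float]]:
    """Paired-end reads over one fusion transcript.

    Fragment length is 2 x read_length + inner insert (Normal, truncated at
    0); fragments longer than the transcript are clamped to it (overlapping
    mates).  Mate 1 is the fragment's 5' ``read_length`` bases, mate 2 the
    reverse complement of its 3' ``read_length`` bases, all at Q40.  Pairs
    are emitted until the mean read depth reaches ``params.depth`` and at
    least ``min_transcript_coverage`` of the transcript is covered.
    """
    seq = truth.fusion_sequence
    length = len(seq)
    rl = params.read_length
    if length < rl:
        raise ValueError(
            f"{truth.case_id}: fusion sequence ({length} bp) shorter than read length ({rl} bp)"
        )
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    coverage = np.zeros(length, dtype=np.int64)
    pairs: List[Tuple[SequencedRead, SequencedRead]] = []
    inserts: List[float] = []
    quals = [40] * rl
    target_bases = params.depth * length
    needed_cov = params.min_transcript_coverage * length
    total_bases = 0
    max_pairs = int(20 * params.depth * length / (2 * rl)) + 1000  # runaway guard
    while total_bases < target_bases or (coverage > 0).sum() < needed_cov:
        if len(pairs) > max_pairs:
            raise RuntimeError(
                f"{truth.case_id}: coverage target unreachable after {len(pairs)} pairs"
            )
        insert = max(rng.normal(params.insert_mean, params.insert_sd), 0.0)
        frag_len = int(round(2 * rl + insert))
        if frag_len > length:
            # transcript shorter than a typical fragment: shrink the insert
            # (uniform over what fits) or, below 2 read lengths, overlap mates
            if length >= 2 * rl:
                insert = float(rng.integers(0, length - 2 * rl + 1))
                frag_len = 2 * rl + int(insert)
            else:
                insert = 0.0
                frag_len = length
        inserts.append(insert)
        start = int(rng.integers(0, length - frag_len + 1))
        m1_seq = seq[start : start + rl]
        m2_seq = revcomp(seq[start + frag_len - rl : start + frag_len])
        if params.error_rate > 0:
            m1_seq = _mutate(m1_seq.encode(), params.error_rate, rng).decode()
            m2_seq = _mutate(m2_seq.encode(), params.error_rate, rng).decode()
        i = len(pairs)
        pairs.append(
            (
                SequencedRead(f"{truth.case_id}|p{i}/1", m1_seq, list(quals), mate=1),
                SequencedRead(f"{truth.case_id}|p{i}/2", m2_seq, list(quals), mate=2),
            )
        )
        coverage[start : start + rl] += 1
        coverage[start + frag_len - rl : start + frag_len] += 1
        total_bases += 2 * rl
    truth.n_read_pairs = len(pairs)
    stats = {
        "n_pairs": len(pairs),
        "mean_depth": float(coverage.mean()),
        "fraction_covered": float((coverage > 0).mean()),
        "insert_mean": float(np.mean(inserts)),
        "insert_sd": float(np.std(inserts, ddof=1)) if len(inserts) > 1 else 0.0,
    }
    return pairs, stats


def simulate_truth_reads(
    truths: Sequence[SimulatedFusionTruth],
    params: SimParams,
) -> Tuple[List[SequencedRead], Dict[str, float]]:
    """Pooled single-read stream for a whole truth set (mates decoupled)."""
    reads: List[SequencedRead] = []
    all_inserts_mean = []
    rng = np.random.default_rng(params.rng_seed)
    for truth in truths:
        pairs, stats = simulate_reads(truth, params, rng)
        for m1, m2 in pairs:
            reads.append(m1)
            reads.append(m2)
        all_inserts_mean.append(stats["insert_mean"])
    return reads, {"n_reads": len(reads)}


# ---------------------------------------------------------------------------
# Evaluation


def _matches_truth(cand: FusionCandidate, truth: SimulatedFusionTruth, tol: int) -> bool:
    b = cand.boundary
    return (
        b.head_gene == truth.head_gene
        and b.tail_gene == truth.tail_gene
        and b.head_chrom == truth.head_chrom
        and b.tail_chrom == truth.tail_chrom
        and abs(b.head_breakpoint - truth.head_breakpoint) <= tol
        and abs(b.tail_breakpoint - truth.tail_breakpoint) <= tol
    )


def _matches_reversed(cand: FusionCandidate, truth: SimulatedFusionTruth, tol: int) -> bool:
    b = cand.boundary
    return (
        b.head_gene == truth.tail_gene
        and b.tail_gene == truth.head_gene
        and b.head_chrom == truth.tail_chrom
        and b.tail_chrom == truth.head_chrom
        and abs(b.head_breakpoint - truth.tail_breakpoint) <= tol
        and abs(b.tail_breakpoint - truth.head_breakpoint) <= tol
    )


def evaluate(
    predicted: Sequence[FusionCandidate],
    truths: Sequence[SimulatedFusionTruth],
    tolerance_bp: int = 0,
) -> EvaluationResult:
    """Score predictions against a truth set.

    A prediction matches a truth iff the ordered gene pair is equal and both
    breakpoints agree within ``tolerance_bp``.  Direction-reversed matches
    are reported separately and credited to neither TP nor FP; truths found
    only in reversed direction still count as FN.  Precision is undefined
    (NaN) when there are no positive predictions.
    """
    matched_truths: Set[str] = set()
    reversed_truths: Set[str] = set()
    fp = 0
    n_reversed = 0
    detail: List[Dict[str, str]] = []
    for cand in predicted:
        hit = next((t for t in truths if _matches_truth(cand, t, tolerance_bp)), None)
        if hit is not None:
            matched_truths.add(hit.case_id)
            detail.append({"candidate": cand.candidate_id, "status": "TP", "truth": hit.case_id})
            continue
        rev = next((t for t in truths if _matches_reversed(cand, t, tolerance_bp)), None)
        if rev is not None:
            n_reversed += 1
            reversed_truths.add(rev.case_id)
            detail.append(
                {"candidate": cand.candidate_id, "status": "reversed", "truth": rev.case_id}
            )
            continue
        fp += 1
        detail.append({"candidate": cand.candidate_id, "status": "FP", "truth": ""})
    tp = len(matched_truths)
    fn = len(truths) - tp
    for t in truths:
        if t.case_id not in matched_truths:
            detail.append({"candidate": "", "status": "FN", "truth": t.case_id})
    return EvaluationResult(tp=tp, fp=fp, fn=fn, n_reversed=n_reversed, detail=detail)


# ---------------------------------------------------------------------------
# Truth-table I/O

_TRUTH_COLUMNS = [
    "case_id", "head_gene", "tail_gene", "head_transcript", "tail_transcript",
    "head_exon_index", "tail_exon_index", "head_chrom", "tail_chrom",
    "head_breakpoint", "tail_breakpoint", "junction_offset", "n_read_pairs",
    "fusion_sequence",
]


def write_truth_table(truths: Sequence[SimulatedFusionTruth], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TRUTH_COLUMNS) + "\n")
        for t in truths:
            fh.write("\t".join(str(getattr(t, c)) for c in _TRUTH_COLUMNS) + "\n")


def read_truth_table(path) -> List[SimulatedFusionTruth]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TRUTH_COLUMNS:
            raise ValueError(f"{path}: unexpected truth-table columns")
        for line in fh:
            vals = dict(zip(header, line.rstrip("\n").split("\t")))
            out.append(
                SimulatedFusionTruth(
                    case_id=vals["case_id"],
                    head_gene=vals["head_gene"],
                    tail_gene=vals["tail_gene"],
                    head_transcript=vals["head_transcript"],
                    tail_transcript=vals["tail_transcript"],
                    head_exon_index=int(vals["head_exon_index"]),
                    tail_exon_index=int(vals["tail_exon_index"]),
                    head_chrom=vals["head_chrom"],
                    tail_chrom=vals["tail_chrom"],
                    head_breakpoint=int(vals["head_breakpoint"]),
                    tail_breakpoint=int(vals["tail_breakpoint"]),
                    fusion_sequence=vals["fusion_sequence"],
                    junction_offset=int(vals["junction_offset"]),
                    n_read_pairs=int(vals["n_read_pairs"]),
                )
            )
    return out
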