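"""False-positive filter cascade with a per-candidate audit trail.

The cascade removes, in order: read-through transcripts between consecutive
same-strand genes and blacklisted gene pairs; junction flanks homologous to
either partner's natural genomic continuation (splice-slippage artifacts);
candidates anchored in repeats, paralog pairs, or pseudogenes; seeds with
ambiguous genome-wide multi-mapping; and finally candidates left with fewer
than the minimum number of seed reads.  Filters may drop seeds but never
modify a candidate's boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Dict, List, Optional, Sequence, Tuple

from .align import GenomeIndex, genome_align, local_align
from .annotation import Annotation, AuxiliaryLists, GenomeRef, are_read_through
from .detect import FUSION_EXONS, FusionCandidate, build_fusion_sequence
from .util import interval_union_length, revcomp

DEFAULT_ORDER = ("read_through", "blacklist", "homology", "regions", "multimap", "min_seeds")


@dataclass
class FilterConfig:
    """Thresholds and toggles for the cascade.

    ``flank_len`` (bp) is the window either side of the junction examined by
    the homology filter, ``homology_word`` its exact-word anchor size, and
    ``homology_window`` how far (bp) into each gene's natural continuation
    the search extends.  ``multimap_identity`` is the (strict) identity above
    which an alternative full-coverage locus makes a seed ambiguous.
    """

    flank_len: int = 14
    homology_word: int = 10
    homology_window: int = 1000
    multimap_identity: float = 0.95
    min_seeds: int = 2
    enable_read_through: bool = True
    enable_blacklist: bool = True
    enable_homology: bool = True
    enable_regions: bool = True
    enable_multimap: bool = True
    enable_min_seeds: bool = True

    def __post_init__(self):
        if self.flank_len <= 0 or self.homology_word <= 0 or self.homology_window <= 0:
            raise ValueError("all thresholds must be positive")
        if self.min_seeds < 1:
            raise ValueError("min_seeds must be >= 1")

    def enabled(self, name: str) -> bool:
        return getattr(self, f"enable_{name}")

    @classmethod
    def from_file(cls, path) -> "FilterConfig":
        """Read a flat ``key=value`` config file."""
        values: Dict[str, object] = {}
        known = {f.name: f.type for f in dc_fields(cls)}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{ln}: expected key=value")
                key, _, raw = line.partition("=")
                key, raw = key.strip(), raw.strip()
                if key not in known:
                    raise ValueError(f"{path}:{ln}: unknown key {key!r}")
                if key.startswith("enable_"):
                    values[key] = raw.lower() in ("1", "true", "yes", "on")
                elif key == "multimap_identity":
                    values[key] = float(raw)
                else:
                    values[key] = int(raw)
        return cls(**values)

    def to_dict(self) -> Dict[str, object]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


# ---------------------------------------------------------------------------
# Individual filters


def filter_read_through_and_blacklist(
    candidates: Sequence[FusionCandidate],
    annotation: Annotation,
    aux: AuxiliaryLists,
    cfg: Optional[FilterConfig] = None,
) -> List[FusionCandidate]:
    """Remove read-through (consecutive same-strand) and blacklisted pairs."""
    cfg = cfg or FilterConfig()
    out = []
    for cand in candidates:
        head, tail = cand.boundary.head_gene, cand.boundary.tail_gene
        if cfg.enabled("read_through") and are_read_through(head, tail, annotation):
            cand.filter_audit.append(("read_through", "fail", f"{head} upstream-adjacent to {tail}"))
            continue
        if cfg.enabled("read_through"):
            cand.filter_audit.append(("read_through", "pass", ""))
        if cfg.enabled("blacklist") and aux.in_blacklist(head, tail):
            cand.filter_audit.append(("blacklist", "fail", f"({head},{tail}) blacklisted"))
            continue
        if cfg.enabled("blacklist"):
            cand.filter_audit.append(("blacklist", "pass", ""))
        out.append(cand)
    return out


def _continuations(
    cand: FusionCandidate, genome: GenomeRef, window: int
) -> Tuple[str, str]:
    """(head downstream, tail upstream) natural genomic continuations, in
    transcription orientation, ``window`` bp past each breakpoint."""
    b = cand.boundary
    head_len = len(genome.sequences[b.head_chrom])
    tail_len = len(genome.sequences[b.tail_chrom])
    if b.head_strand == "+":
        head_down = genome.fetch(b.head_chrom, b.head_breakpoint,
                                 min(b.head_breakpoint + window, head_len))
    else:
        head_down = revcomp(
            genome.fetch(b.head_chrom, max(b.head_breakpoint - window, 0), b.head_breakpoint)
        )
    if b.tail_strand == "+":
        tail_up = genome.fetch(b.tail_chrom, max(b.tail_breakpoint - window, 0),
                               b.tail_breakpoint)
    else:
        tail_up = revcomp(
            genome.fetch(b.tail_chrom, b.tail_breakpoint,
                         min(b.tail_breakpoint + window, tail_len))
        )
    return head_down, tail_up


def filter_homology(
    cand: FusionCandidate,
    genome: GenomeRef,
    annotation: Annotation,
    cfg: FilterConfig,
) -> Tuple[bool, str]:
    """Fail when a junction flank is homologous to the partner continuation.

    Takes the ``flank_len`` bases immediately 5' and 3' of the junction in
    the combined-fusion-exon sequence.  The candidate fails if the tail-side
    flank matches the head gene's natural downstream continuation, or the
    head-side flank matches the tail gene's natural upstream continuation
    (shared exact ``homology_word``-mer anchor extended to at least that many
    matching bases) — the signature of a mis-called splice rather than a
    genuine fusion.
    """
    fusion_seq, junction = build_fusion_sequence(cand.boundary, genome, annotation, FUSION_EXONS)
    head_flank = fusion_seq[max(junction - cfg.flank_len, 0) : junction]
    tail_flank = fusion_seq[junction : junction + cfg.flank_len]
    note = ""
    if len(head_flank) < cfg.flank_len or len(tail_flank) < cfg.flank_len:
        note = "short_flank;"
    head_down, tail_up = _continuations(cand, genome, cfg.homology_window)
    for flank, continuation, label in (
        (tail_flank, head_down, "tail_flank~head_downstream"),
        (head_flank, tail_up, "head_flank~tail_upstream"),
    ):
        if len(flank) < cfg.homology_word or len(continuation) < cfg.homology_word:
            continue
        hit = local_align(flank, continuation, cfg.homology_word)
        if hit is not None and hit.matches >= cfg.homology_word:
            return False, note + label
    return True, note


def filter_regions(
    cand: FusionCandidate, aux: AuxiliaryLists, annotation: Annotation
) -> Tuple[bool, str]:
    """Repeat / paralog / pseudogene filter.

    Paralog pairs (either order) and pseudogene partners fail outright;
    seeds whose aligned segments overlap a repeat interval are dropped, and
    the candidate fails when no seed survives.
    """
    b = cand.boundary
    if aux.is_paralog_pair(b.head_gene, b.tail_gene):
        return False, f"paralog pair ({b.head_gene},{b.tail_gene})"
    if b.head_gene in aux.pseudogenes or b.tail_gene in aux.pseudogenes:
        bad = b.head_gene if b.head_gene in aux.pseudogenes else b.tail_gene
        return False, f"pseudogene {bad}"
    dropped = 0
    kept = []
    for seed in cand.seeds:
        in_repeat = False
        for rec in seed.split_records:
            if aux.repeat_overlaps(rec.chrom, rec.target_start, rec.target_end):
                in_repeat = True
                break
        if in_repeat:
            dropped += 1
        else:
            kept.append(seed)
    cand.seeds = kept
    if not kept:
        return False, f"all {dropped} seeds in repeat regions"
    return True, f"{dropped} seeds dropped (repeats)" if dropped else ""


def _partner_spans(cand: FusionCandidate, annotation: Annotation):
    b = cand.boundary
    spans = []
    for gene in (b.head_gene, b.tail_gene):
        chrom, _strand, start, end = annotation.gene_span(gene)
        spans.append((chrom, start, end))
    return spans


def filter_multimap(
    cand: FusionCandidate,
    index: GenomeIndex,
    annotation: Annotation,
    cfg: FilterConfig,
) -> Tuple[bool, str]:
    """Drop seeds with an ambiguous full-coverage alignment elsewhere.

    Each seed is realigned genome-wide; an alignment outside both partner
    gene spans, covering at least the seed's combined split coverage at
    identity strictly above ``multimap_identity``, marks the seed ambiguous.
    The candidate fails when no seed survives.
    """
    spans = _partner_spans(cand, annotation)
    kept, dropped = [], 0
    for seed in cand.seeds:
        combined = interval_union_length(
            [(r.query_start, r.query_end) for r in seed.split_records]
        ) if seed.split_records else len(seed.sequence)
        ambiguous = False
        for rec in genome_align(seed.sequence, index, query_id=seed.query_id or "seed",
                                max_reported=10):
            inside_partner = any(
                rec.chrom == chrom and rec.target_start < end and rec.target_end > start
                for chrom, start, end in spans
            )
            if inside_partner:
                continue
            if rec.query_span >= combined and rec.identity > cfg.multimap_identity:
                ambiguous = True
                break
        if ambiguous:
            dropped += 1
        else:
            kept.append(seed)
    cand.seeds = kept
    if not kept:
        return False, f"all {dropped} seeds multi-mapping"
    return True, f"{dropped} seeds dropped (multimap)" if dropped else ""


def filter_min_seeds(cand: FusionCandidate, cfg: FilterConfig) -> Tuple[bool, str]:
    """Require at least ``min_seeds`` surviving seed reads."""
    ok = cand.n_seeds >= cfg.min_seeds
    return ok, f"{cand.n_seeds} seeds (min {cfg.min_seeds})"


# ---------------------------------------------------------------------------
# Cascade driver


def run_cascade(
    candidates: Sequence[FusionCandidate],
    genome: GenomeRef,
    annotation: Annotation,
    aux: AuxiliaryLists,
    cfg: Optional[FilterConfig] = None,
    genome_index: Optional[GenomeIndex] = None,
    order: Sequence[str] = DEFAULT_ORDER,
) -> Tuple[List[FusionCandidate], List[Dict[str, str]]]:
    """Apply the enabled filters in ``order``, recording a full audit.

    Every candidate's audit lists the outcome of each filter applied up to
    and including the first failure.  Returns the survivors sorted by
    (descending seed count, head gene, tail gene) plus a flat audit table.
    """
    cfg = cfg or FilterConfig()
    if genome_index is None and cfg.enable_multimap and "multimap" in order:
        genome_index = GenomeIndex(genome)
    survivors: List[FusionCandidate] = []
    audit_rows: List[Dict[str, str]] = []

    for cand in candidates:
        alive = True
        for name in order:
            if not cfg.enabled(name):
                continue
            if name == "read_through":
                ok = not are_read_through(
                    cand.boundary.head_gene, cand.boundary.tail_gene, annotation
                )
                detail = "" if ok else (
                    f"{cand.boundary.head_gene} upstream-adjacent to {cand.boundary.tail_gene}"
                )
            elif name == "blacklist":
                ok = not aux.in_blacklist(cand.boundary.head_gene, cand.boundary.tail_gene)
                detail = "" if ok else "blacklisted pair"
            elif name == "homology":
                ok, detail = filter_homology(cand, genome, annotation, cfg)
            elif name == "regions":
                ok, detail = filter_regions(cand, aux, annotation)
            elif name == "multimap":
                ok, detail = filter_multimap(cand, genome_index, annotation, cfg)
            elif name == "min_seeds":
                ok, detail = filter_min_seeds(cand, cfg)
            else:
                raise ValueError(f"unknown filter {name!r}")
            outcome = "pass" if ok else "fail"
            cand.filter_audit.append((name, outcome, detail))
            audit_rows.append(
                {
                    "candidate": cand.candidate_id,
                    "filter": name,
                    "outcome": outcome,
                    "detail": detail,
                }
            )
            if not ok:
                alive = False
                break
        if alive:
            survivors.append(cand)
    survivors.sort(key=lambda c: (-c.n_seeds, c.boundary.head_gene, c.boundary.tail_gene))
    return survivors, audit_rows
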