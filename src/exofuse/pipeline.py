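"""End-to-end pipeline: FASTQ (or alignment records) in, fusion report out.

Stage order mirrors the method's workflow: quality trim and artifact filter,
collapse to unique reads, genome alignment, candidate-read selection by
alignment count, split-read pairing with exon-boundary snapping and seed
verification, then the false-positive filter cascade.
"""
from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .align import AlignmentRecord, GenomeIndex, genome_align, select_candidate_reads
from .annotation import Annotation, AuxiliaryLists, GenomeRef
from .detect import FusionCandidate, detect_fusions, unique_read_id
from .filters import FilterConfig, run_cascade
from .preprocess import SequencedRead, UniqueRead, preprocess_reads
from .report import classify_support_reads


@dataclass
class PipelineConfig:
    """Everything tunable about a detection run."""

    qual_threshold: int = 10
    min_read_length: int = 38
    seed_length: int = 20
    max_reported: int = 5
    candidate_min: int = 2
    candidate_max: int = 11
    min_anchor: int = 20
    min_cover: float = 0.5
    max_query_gap: int = 10
    min_genomic_gap: int = 50_000
    max_boundary_offset: int = 6
    verify_word_size: int = 20
    verify_min_identity: float = 0.95
    find_supports: bool = False  # optional: realigns all reads per candidate
    threads: int = 1  # alignment may be partitioned by read; results identical
    filters: FilterConfig = field(default_factory=FilterConfig)

    def to_dict(self) -> Dict[str, object]:
        d = {k: v for k, v in self.__dict__.items() if k != "filters"}
        d.update({f"filter.{k}": v for k, v in self.filters.to_dict().items()})
        return d


@dataclass
class PipelineResult:
    candidates: List[FusionCandidate]
    unique_reads: List[UniqueRead]
    stage_counts: Dict[str, Dict[str, int]]
    audit_rows: List[Dict[str, str]]


def run_pipeline(
    reads: Iterable[SequencedRead],
    genome: GenomeRef,
    annotation: Annotation,
    aux: AuxiliaryLists,
    config: Optional[PipelineConfig] = None,
    genome_index: Optional[GenomeIndex] = None,
    log=None,
) -> PipelineResult:
    """Run preprocessing, alignment, detection and filtering on a read pool."""
    cfg = config or PipelineConfig()

    def _log(msg: str) -> None:
        if log is not None:
            print(msg, file=log)

    unique, read_counts = preprocess_reads(reads, cfg.qual_threshold, cfg.min_read_length)
    _log(f"[preprocess] {read_counts}")

    if genome_index is None:
        genome_index = GenomeIndex(genome, seed_length=cfg.seed_length)

    alignments_by_query: Dict[str, List[AlignmentRecord]] = {}
    for i, u in enumerate(unique):
        qid = unique_read_id(i, u)
        records = genome_align(
            u.sequence, genome_index, query_id=qid, max_reported=cfg.max_reported
        )
        if records:
            alignments_by_query[qid] = records
    read_counts["aligned_queries"] = len(alignments_by_query)

    selected = select_candidate_reads(alignments_by_query, cfg.candidate_min, cfg.candidate_max)
    read_counts["candidate_queries"] = len(selected)
    _log(f"[align] aligned={len(alignments_by_query)} candidates={len(selected)}")

    candidates, detect_counts = detect_fusions(
        unique,
        selected,
        genome,
        annotation,
        min_anchor=cfg.min_anchor,
        min_cover=cfg.min_cover,
        max_query_gap=cfg.max_query_gap,
        min_genomic_gap=cfg.min_genomic_gap,
        max_boundary_offset=cfg.max_boundary_offset,
        verify_word_size=cfg.verify_word_size,
        verify_min_identity=cfg.verify_min_identity,
    )
    _log(f"[detect] {detect_counts}")

    survivors, audit_rows = run_cascade(
        candidates, genome, annotation, aux, cfg.filters, genome_index=genome_index
    )
    filter_counts = _cascade_stage_counts(candidates, survivors, cfg.filters)
    _log(f"[filters] {filter_counts}")

    if cfg.find_supports:
        for cand in survivors:
            cand.supports = classify_support_reads(
                unique, cand, genome, annotation, cfg.min_anchor, cfg.verify_min_identity
            )

    stage_counts = {
        "reads": read_counts,
        "detection": detect_counts,
        "filters": filter_counts,
    }
    return PipelineResult(
        candidates=survivors,
        unique_reads=unique,
        stage_counts=stage_counts,
        audit_rows=audit_rows,
    )


def _cascade_stage_counts(
    candidates: Sequence[FusionCandidate],
    survivors: Sequence[FusionCandidate],
    cfg: FilterConfig,
) -> Dict[str, int]:
    """Candidates remaining after each enabled filter, from the audit."""
    from .filters import DEFAULT_ORDER

    counts: Dict[str, int] = {"aggregated": len(candidates)}
    remaining = len(candidates)
    for name in DEFAULT_ORDER:
        if not cfg.enabled(name):
            continue
        failed = sum(
            1
            for c in candidates
            if any(f == name and o == "fail" for f, o, _ in c.filter_audit)
        )
        remaining -= failed
        counts[f"after_{name}"] = remaining
    counts["final"] = len(survivors)
    return counts
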