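"""Curative outputs: support-read classification, tiling alignment views,
coverage profiles with boundary-change detection, and the report files."""
from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .align import local_align
from .annotation import Annotation, GenomeRef, TranscriptModel
from .detect import (
    FULL_TRANSCRIPT,
    FusionCandidate,
    SupportRead,
    build_fusion_sequence,
    _junction_crossing,
)
from .preprocess import UniqueRead
from .util import revcomp


def classify_support_reads(
    unique_reads: Sequence[UniqueRead],
    candidate: FusionCandidate,
    genome: GenomeRef,
    annotation: Annotation,
    min_anchor: int = 20,
    min_identity: float = 0.95,
    word_size: int = 20,
) -> List[SupportRead]:
    """Find support reads by realigning all reads to the chimeric transcript.

    A read crossing the junction with one side >= ``min_anchor`` aligned
    bases and the other side shorter (but >= 1 bp), at identity >=
    ``min_identity``, is a support read — corroborating but not primary
    evidence.  Reads meeting the seed condition on both sides are never
    double-counted as supports.
    """
    fusion_seq, junction = build_fusion_sequence(
        candidate.boundary, genome, annotation, FULL_TRANSCRIPT
    )
    seed_seqs = {s.sequence for s in candidate.seeds}
    supports: List[SupportRead] = []
    for u in unique_reads:
        if u.sequence in seed_seqs:
            continue
        best = None
        for seq in (u.sequence, revcomp(u.sequence)):
            result = local_align(seq, fusion_seq, word_size)
            if result is None or result.identity_fraction < min_identity:
                continue
            head_ov, tail_ov = _junction_crossing(result, junction)
            if min(head_ov, tail_ov) < 1:
                continue
            if best is None or result.score > best[0].score:
                best = (result, head_ov, tail_ov)
        if best is None:
            continue
        result, head_ov, tail_ov = best
        if min(head_ov, tail_ov) >= min_anchor:
            continue  # seed-grade evidence, not a support
        if max(head_ov, tail_ov) < min_anchor:
            continue
        supports.append(
            SupportRead(
                sequence=u.sequence,
                count=u.count,
                realignment=result,
                head_overhang=head_ov,
                tail_overhang=tail_ov,
            )
        )
    supports.sort(key=lambda s: (s.realignment.target_start, s.sequence))
    return supports


# ---------------------------------------------------------------------------
# Coverage profiles


@dataclass
class CoverageProfile:
    """Per-base read depth over a transcript's spliced coordinates."""

    transcript_id: str
    depth: np.ndarray
    exon_boundary_offsets: List[int]  # internal boundaries, transcript coords
    boundary_change_ratio: List[Optional[float]]  # mean after / mean before
    flagged: List[bool]


def coverage_profile(
    alignments: Iterable[Tuple[int, int]],
    t: TranscriptModel,
    window: int = 30,
    ratio_high: float = 2.0,
    ratio_low: float = 0.5,
) -> CoverageProfile:
    """Accumulate depth from transcript-coordinate intervals and score each
    internal exon boundary for an abrupt depth change.

    The change ratio at a boundary is the mean depth over ``window`` bp after
    it divided by the mean over ``window`` bp before; ratios > ``ratio_high``
    or < ``ratio_low`` are flagged (the fusion signature).  Ratios are None
    when undefined (no coverage on either side).
    """
    n = t.exonic_length
    depth = np.zeros(n, dtype=np.int64)
    for s, e in alignments:
        s, e = max(s, 0), min(e, n)
        if e > s:
            depth[s:e] += 1
    exon_lens = [e - s for s, e in t.exons_in_tx_order()]
    boundaries = list(np.cumsum(exon_lens)[:-1])
    ratios: List[Optional[float]] = []
    flagged: List[bool] = []
    for b in boundaries:
        before = depth[max(b - window, 0) : b]
        after = depth[b : min(b + window, n)]
        mb = float(before.mean()) if before.size else 0.0
        ma = float(after.mean()) if after.size else 0.0
        if mb == 0.0 and ma == 0.0:
            ratios.append(None)
            flagged.append(False)
            continue
        ratio = float("inf") if mb == 0.0 else ma / mb
        ratios.append(ratio)
        flagged.append(ratio > ratio_high or ratio < ratio_low)
    return CoverageProfile(
        transcript_id=t.transcript_id,
        depth=depth,
        exon_boundary_offsets=[int(b) for b in boundaries],
        boundary_change_ratio=ratios,
        flagged=flagged,
    )


# ---------------------------------------------------------------------------
# Fusion alignment view


def _render_row(read_seq: str, realignment, fusion_seq: str, width: int) -> str:
    """One fixed-width row: the read laid out at its aligned target offset,
    mismatching bases lowercased, gapped columns as '-'."""
    row = [" "] * width
    for q_start, t_start, length in realignment.blocks:
        for k in range(length):
            tpos = t_start + k
            if 0 <= tpos < width:
                base = read_seq[q_start + k]
                row[tpos] = base.lower() if base != fusion_seq[tpos] else base
    return "".join(row).rstrip()


def fusion_alignment_view(
    candidate: FusionCandidate,
    genome: GenomeRef,
    annotation: Annotation,
) -> str:
    """Text rendering of seed/support reads tiled on the fusion sequence.

    A progressive tiling of staggered read starts across the junction marker
    is the signature of a genuine fusion.
    """
    from .detect import FUSION_EXONS

    fusion_seq, junction = build_fusion_sequence(
        candidate.boundary, genome, annotation, FUSION_EXONS
    )
    width = len(fusion_seq)
    lines = [candidate.candidate_id]
    marker = " " * junction + "|" + f" <- junction ({junction})"
    lines.append(marker)
    lines.append(fusion_seq)
    rows = []
    for seed in candidate.seeds:
        seq = seed.sequence
        # realignment may be of the reverse complement; detect by block match
        q0, t0, l0 = seed.realignment.blocks[0]
        if seq[q0 : q0 + l0] != fusion_seq[t0 : t0 + l0]:
            seq = revcomp(seq)
        rows.append(("seed", seed.realignment.target_start, seq, seed.realignment))
    for sup in candidate.supports:
        seq = sup.sequence
        q0, t0, l0 = sup.realignment.blocks[0]
        if seq[q0 : q0 + l0] != fusion_seq[t0 : t0 + l0]:
            seq = revcomp(seq)
        rows.append(("support", sup.realignment.target_start, seq, sup.realignment))
    rows.sort(key=lambda r: (r[0] != "seed", r[1]))
    for kind, _start, seq, realignment in rows:
        lines.append(_render_row(seq, realignment, fusion_seq, width) + f"  [{kind}]")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Report files


_REPORT_COLUMNS = [
    "head_gene", "tail_gene", "head_locus", "tail_locus",
    "head_exon", "tail_exon", "n_seeds", "n_supports", "alt_isoforms", "filter_audit",
]


def candidate_table_rows(candidates: Sequence[FusionCandidate]) -> List[Dict[str, str]]:
    rows = []
    for c in candidates:
        b = c.boundary
        rows.append(
            {
                "head_gene": b.head_gene,
                "tail_gene": b.tail_gene,
                "head_locus": f"{b.head_chrom}:{b.head_breakpoint}:{b.head_strand}",
                "tail_locus": f"{b.tail_chrom}:{b.tail_breakpoint}:{b.tail_strand}",
                "head_exon": str(b.head_exon_index),
                "tail_exon": str(b.tail_exon_index),
                "n_seeds": str(c.n_seeds),
                "n_supports": str(len(c.supports)),
                "alt_isoforms": ";".join(sorted(f"{h}|{t}" for h, t in c.alt_isoforms)),
                "filter_audit": ";".join(f"{n}:{o}" for n, o, _ in c.filter_audit),
            }
        )
    return rows


def write_outputs(
    candidates: Sequence[FusionCandidate],
    out_dir: os.PathLike | str,
    genome: Optional[GenomeRef] = None,
    annotation: Optional[Annotation] = None,
    stage_counts: Optional[Dict[str, Dict[str, int]]] = None,
    config: Optional[Dict[str, object]] = None,
    audit_rows: Optional[Sequence[Dict[str, str]]] = None,
) -> Dict[str, str]:
    """Write the main TSV report, breakpoint BED, alignment views, audit
    table, JSON run summary, and config log.  Deterministic for fixed inputs."""
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)

    report_path = os.path.join(out_dir, "fusions.tsv")
    with open(report_path, "w") as fh:
        fh.write("\t".join(_REPORT_COLUMNS) + "\n")
        for row in candidate_table_rows(candidates):
            fh.write("\t".join(row[c] for c in _REPORT_COLUMNS) + "\n")

    bed_path = os.path.join(out_dir, "breakpoints.bed")
    with open(bed_path, "w") as fh:
        for c in candidates:
            b = c.boundary
            name = f"{b.head_gene}--{b.tail_gene}"
            fh.write(f"{b.head_chrom}\t{max(b.head_breakpoint - 1, 0)}\t{b.head_breakpoint + 1}"
                     f"\t{name}|head\t{c.n_seeds}\t{b.head_strand}\n")
            fh.write(f"{b.tail_chrom}\t{max(b.tail_breakpoint - 1, 0)}\t{b.tail_breakpoint + 1}"
                     f"\t{name}|tail\t{c.n_seeds}\t{b.tail_strand}\n")

    paths = {"report": report_path, "bed": bed_path}

    if genome is not None and annotation is not None:
        views_dir = os.path.join(out_dir, "views")
        os.makedirs(views_dir, exist_ok=True)
        for i, c in enumerate(candidates):
            view_path = os.path.join(views_dir, f"candidate_{i:03d}.txt")
            with open(view_path, "w") as fh:
                fh.write(fusion_alignment_view(c, genome, annotation))
        paths["views"] = views_dir

    if audit_rows is not None:
        audit_path = os.path.join(out_dir, "filter_audit.tsv")
        with open(audit_path, "w") as fh:
            fh.write("candidate\tfilter\toutcome\tdetail\n")
            for row in audit_rows:
                fh.write(f"{row['candidate']}\t{row['filter']}\t{row['outcome']}\t{row['detail']}\n")
        paths["audit"] = audit_path

    summary = {"n_final_candidates": len(candidates)}
    if stage_counts is not None:
        summary["stage_counts"] = stage_counts
    summary_path = os.path.join(out_dir, "summary.json")
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["summary"] = summary_path

    if config is not None:
        config_path = os.path.join(out_dir, "config.log")
        with open(config_path, "w") as fh:
            for key in sorted(config):
                fh.write(f"{key}={config[key]}\n")
        paths["config"] = config_path
    return paths
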