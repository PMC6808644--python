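"""Shared fixtures: a hand-built toy annotation plus simulator-generated
worlds reused across test modules (session-scoped; everything is seeded)."""
from __future__ import annotations

import numpy as np
import pytest

import exofuse as ef
from exofuse.annotation import Annotation, GenomeRef, TranscriptModel


def random_genome(lengths: dict, seed: int) -> GenomeRef:
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return GenomeRef(
        {name: bases[rng.integers(0, 4, n)].tobytes().decode() for name, n in lengths.items()}
    )


TOY_TRANSCRIPTS = [
    # ALPHA: two isoforms on chrA '+'
    TranscriptModel("NM_A1", "ALPHA", "chrA", "+", ((1000, 1200), (2000, 2300), (3000, 3200))),
    TranscriptModel("NM_A2", "ALPHA", "chrA", "+", ((1000, 1200), (2000, 2300))),
    TranscriptModel("NM_B1", "BETA", "chrA", "+", ((80_000, 80_200), (81_000, 81_300))),
    TranscriptModel("NM_Z1", "ZETA", "chrA", "+", ((120_000, 120_200), (121_000, 121_100))),
    TranscriptModel("NM_G1", "GAMMA", "chrA", "-", ((140_000, 140_150), (141_000, 141_200))),
    TranscriptModel("NM_D1", "DELTA", "chrB", "+", ((5_000, 5_240), (6_000, 6_180))),
    TranscriptModel("NM_E1", "EPSILON", "chrB", "-", ((70_000, 70_200), (71_000, 71_150))),
]


@pytest.fixture(scope="session")
def toy_genome() -> GenomeRef:
    return random_genome({"chrA": 200_000, "chrB": 150_000}, seed=42)


@pytest.fixture(scope="session")
def toy_annotation() -> Annotation:
    return Annotation(TOY_TRANSCRIPTS)


@pytest.fixture(scope="session")
def small_world():
    """A 12-gene fixture with 4 simulated fusions, pipeline already run."""
    genome, annotation, aux = ef.make_fixture(12, rng_seed=7)
    truths = ef.generate_truth_set(annotation, genome, 4, rng_seed=8, min_length=100)
    params = ef.SimParams(n_fusions=4, read_length=100, depth=50, rng_seed=9)
    reads, _ = ef.simulate_truth_reads(truths, params)
    result = ef.run_pipeline(reads, genome, annotation, aux)
    return {
        "genome": genome,
        "annotation": annotation,
        "aux": aux,
        "truths": truths,
        "reads": reads,
        "result": result,
    }


@pytest.fixture(scope="session")
def cascade_world():
    """A fixture with one true fusion and four planted decoys.

    Decoys: a read-through pair (consecutive same-strand genes), a
    paralog-listed pair, a pair whose seeds all fall in a planted repeat,
    and a single-seed artifact.  Returns the inputs plus a ``detect``
    callable producing fresh pre-cascade candidates (the cascade mutates
    candidates, so property tests need fresh copies).
    """
    from intervaltree import IntervalTree

    from exofuse.align import GenomeIndex, genome_align, select_candidate_reads
    from exofuse.detect import detect_fusions, unique_read_id
    from exofuse.preprocess import preprocess_reads
    from exofuse.annotation import are_read_through
    from .helpers import junction_reads, make_boundary

    genome, annotation, aux = ef.make_fixture(
        16, rng_seed=5, planted={"adjacent_pairs": 1}
    )
    tx = lambda i: f"NM_{i:05d}"
    gene = lambda i: f"GENE{i:04d}"

    # read-through decoy: the planted adjacent same-strand pair, head upstream
    rt_head, rt_tail = (0, 1) if are_read_through(gene(0), gene(1), annotation) else (1, 0)
    assert are_read_through(gene(rt_head), gene(rt_tail), annotation)

    cases = {
        "true": ((4, 10), [30, 45, 55]),
        "read_through": ((rt_head, rt_tail), [30, 50]),
        "paralog": ((6, 12), [28, 48]),
        "repeat": ((2, 14), [26, 41, 52]),
        "single_seed": ((5, 9), [35]),
    }
    reads = []
    boundaries = {}
    for name, ((hi, ti), head_sides) in cases.items():
        boundary = make_boundary(annotation, tx(hi), 0, tx(ti), 0)
        boundaries[name] = boundary
        reads.extend(junction_reads(genome, annotation, boundary, head_sides))

    # paralog decoy: listed pair (list-based filter; sequences untouched)
    b = boundaries["paralog"]
    aux.paralog_pairs.add(frozenset((b.head_gene, b.tail_gene)))
    # repeat decoy: the head fusion exon lies inside a repeat interval
    b = boundaries["repeat"]
    head_t = annotation.transcripts[b.head_transcript]
    s, e = head_t.exons[b.head_exon_index]
    aux.repeat_trees.setdefault(b.head_chrom, IntervalTree()).addi(s - 10, e + 10)

    unique, _ = preprocess_reads(reads)
    index = GenomeIndex(genome)
    aligned = {}
    for i, u in enumerate(unique):
        qid = unique_read_id(i, u)
        recs = genome_align(u.sequence, index, query_id=qid)
        if recs:
            aligned[qid] = recs
    selected = select_candidate_reads(aligned)

    def detect():
        cands, _ = detect_fusions(unique, selected, genome, annotation)
        return cands

    return {
        "genome": genome,
        "annotation": annotation,
        "aux": aux,
        "index": index,
        "boundaries": boundaries,
        "detect": detect,
    }
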