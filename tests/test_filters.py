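"""The false-positive filter cascade and its audit trail."""
import numpy as np
import pytest
from intervaltree import IntervalTree

from exofuse.align import GenomeIndex, LocalAlignmentResult
from exofuse.annotation import Annotation, AuxiliaryLists, GenomeRef, TranscriptModel
from exofuse.detect import FusionCandidate, SeedRead
from exofuse.filters import (
    FilterConfig,
    filter_homology,
    filter_min_seeds,
    filter_multimap,
    filter_read_through_and_blacklist,
    filter_regions,
    run_cascade,
)

from .conftest import random_genome
from .helpers import make_boundary, make_record


def make_seed(sequence="A" * 100, split_records=None, query_id="s"):
    fake = LocalAlignmentResult(
        score=len(sequence), matches=len(sequence), mismatches=0,
        query_start=0, query_end=len(sequence), target_start=0,
        target_end=len(sequence), blocks=((0, 0, len(sequence)),),
    )
    return SeedRead(sequence=sequence, count=1, realignment=fake, head_overhang=50,
                    tail_overhang=50, query_id=query_id,
                    split_records=tuple(split_records or ()))


def make_candidate(boundary, seeds):
    return FusionCandidate(boundary=boundary, seeds=list(seeds))


class TestConfig:
    def test_defaults_valid(self):
        cfg = FilterConfig()
        assert cfg.min_seeds == 2 and cfg.flank_len == 14 and cfg.homology_word == 10

    def test_min_seeds_lower_bound(self):
        with pytest.raises(ValueError):
            FilterConfig(min_seeds=0)

    def test_from_file(self, tmp_path):
        p = tmp_path / "f.cfg"
        p.write_text("min_seeds = 3\nenable_homology = off\nmultimap_identity = 0.9\n")
        cfg = FilterConfig.from_file(p)
        assert cfg.min_seeds == 3 and not cfg.enable_homology
        assert cfg.multimap_identity == 0.9

    def test_from_file_unknown_key(self, tmp_path):
        p = tmp_path / "f.cfg"
        p.write_text("bogus = 1\n")
        with pytest.raises(ValueError, match="bogus"):
            FilterConfig.from_file(p)


class TestReadThroughAndBlacklist:
    def test_consecutive_same_strand_removed(self, toy_annotation):
        cand = make_candidate(make_boundary(toy_annotation, "NM_A1", 0, "NM_B1", 0),
                              [make_seed(), make_seed("C" * 100)])
        out = filter_read_through_and_blacklist([cand], toy_annotation, AuxiliaryLists())
        assert out == []
        assert cand.filter_audit[0][:2] == ("read_through", "fail")

    def test_blacklisted_pair_removed(self, toy_annotation):
        aux = AuxiliaryLists(blacklist=[("ALPHA", "DELTA")])
        cand = make_candidate(make_boundary(toy_annotation, "NM_A1", 0, "NM_D1", 0),
                              [make_seed()])
        assert filter_read_through_and_blacklist([cand], toy_annotation, aux) == []

    def test_interchromosomal_never_read_through(self, toy_annotation):
        cand = make_candidate(make_boundary(toy_annotation, "NM_A1", 0, "NM_D1", 0),
                              [make_seed()])
        out = filter_read_through_and_blacklist([cand], toy_annotation, AuxiliaryLists())
        assert out == [cand]


class TestHomology:
    """Crafted genomes where flank/continuation homology is fully known."""

    def build(self, patch=None):
        genome = random_genome({"chrH": 10_000, "chrT": 10_000}, seed=77)
        if patch:
            for chrom, start, repl in patch:
                s = genome.sequences[chrom]
                genome.sequences[chrom] = s[:start] + repl + s[start + len(repl):]
        ann = Annotation([
            TranscriptModel("NM_H", "HEAD", "chrH", "+", ((1000, 1100), (2000, 2100))),
            TranscriptModel("NM_T", "TAIL", "chrT", "+", ((5000, 5100), (6000, 6100))),
        ])
        cand = make_candidate(make_boundary(ann, "NM_H", 1, "NM_T", 0), [make_seed()])
        return genome, ann, cand

    @staticmethod
    def shared_10mer(flank, continuation):
        words = {flank[i : i + 10] for i in range(len(flank) - 9)}
        return any(continuation[i : i + 10] in words for i in range(len(continuation) - 9))

    def test_tail_flank_equal_to_head_intron_fails(self):
        genome, ann, cand = self.build()
        tail_flank = genome.fetch("chrT", 5000, 5014)
        genome2, ann2, cand2 = self.build(patch=[("chrH", 2100, tail_flank)])
        ok, detail = filter_homology(cand2, genome2, ann2, FilterConfig())
        assert not ok and "tail_flank" in detail

    def test_head_flank_in_tail_upstream_fails(self):
        genome, ann, cand = self.build()
        head_flank = genome.fetch("chrH", 2086, 2100)
        genome2, ann2, cand2 = self.build(patch=[("chrT", 4950, head_flank)])
        ok, detail = filter_homology(cand2, genome2, ann2, FilterConfig())
        assert not ok and "head_flank" in detail

    def test_agrees_with_exhaustive_word_intersection(self):
        # random flanks: the decision must equal the 10-mer set-intersection oracle
        genome, ann, cand = self.build()
        head_down = genome.fetch("chrH", 2100, 3100)
        tail_up = genome.fetch("chrT", 4000, 5000)
        head_flank = genome.fetch("chrH", 2086, 2100)
        tail_flank = genome.fetch("chrT", 5000, 5014)
        expected = not (
            self.shared_10mer(tail_flank, head_down) or self.shared_10mer(head_flank, tail_up)
        )
        ok, _ = filter_homology(cand, genome, ann, FilterConfig())
        assert ok is expected

    def test_nine_mer_only_passes(self):
        genome, ann, cand = self.build()
        tail9 = genome.fetch("chrT", 5000, 5009)
        # plant the 9-mer followed by a base differing from the flank's 10th
        tenth = genome.fetch("chrT", 5009, 5010)
        other = {"A": "C", "C": "G", "G": "T", "T": "A"}[tenth]
        genome2, ann2, cand2 = self.build(patch=[("chrH", 2100, tail9 + other)])
        head_down = genome2.fetch("chrH", 2100, 3100)
        tail_up = genome2.fetch("chrT", 4000, 5000)
        head_flank = genome2.fetch("chrH", 2086, 2100)
        tail_flank = genome2.fetch("chrT", 5000, 5014)
        if not (self.shared_10mer(tail_flank, head_down) or self.shared_10mer(head_flank, tail_up)):
            ok, _ = filter_homology(cand2, genome2, ann2, FilterConfig())
            assert ok


class TestRegions:
    def candidate(self, toy_annotation, seeds):
        return make_candidate(make_boundary(toy_annotation, "NM_A1", 0, "NM_D1", 0), seeds)

    def test_pseudogene_partner_fails(self, toy_annotation):
        aux = AuxiliaryLists(pseudogenes=["ALPHA"])
        ok, detail = filter_regions(self.candidate(toy_annotation, [make_seed()]),
                                    aux, toy_annotation)
        assert not ok and "pseudogene" in detail

    @pytest.mark.parametrize("pair", [("ALPHA", "DELTA"), ("DELTA", "ALPHA")])
    def test_paralog_pair_fails_either_order(self, toy_annotation, pair):
        aux = AuxiliaryLists(paralog_pairs=[pair])
        ok, detail = filter_regions(self.candidate(toy_annotation, [make_seed()]),
                                    aux, toy_annotation)
        assert not ok and "paralog" in detail

    def test_repeat_seed_dropped_candidate_survives(self, toy_annotation):
        # interval-overlap oracle: exactly the seed whose segment intersects
        # the repeat interval must be dropped
        aux = AuxiliaryLists(repeat_intervals={"chrA": [(1100, 1300)]})
        in_repeat = make_seed("G" * 100, [make_record(chrom="chrA", target_start=1150,
                                                      target_end=1200)])
        clean1 = make_seed("C" * 100, [make_record(chrom="chrA", target_start=2200,
                                                   target_end=2300)])
        clean2 = make_seed("T" * 100, [make_record(chrom="chrB", target_start=6000,
                                                   target_end=6060)])
        cand = self.candidate(toy_annotation, [in_repeat, clean1, clean2])
        ok, _ = filter_regions(cand, aux, toy_annotation)
        assert ok and cand.n_seeds == 2
        assert all(s.sequence != "G" * 100 for s in cand.seeds)

    def test_all_seeds_in_repeats_fails(self, toy_annotation):
        aux = AuxiliaryLists(repeat_intervals={"chrA": [(1000, 1300)]})
        cand = self.candidate(
            toy_annotation,
            [make_seed("G" * 100, [make_record(chrom="chrA", target_start=1150,
                                               target_end=1200)])],
        )
        ok, _ = filter_regions(cand, aux, toy_annotation)
        assert not ok and cand.n_seeds == 0


class TestMultimap:
    def build(self, planted=None):
        genome = random_genome({"chrM": 120_000}, seed=88)
        ann = Annotation([
            TranscriptModel("NM_MA", "MA", "chrM", "+", ((1000, 1100), (2000, 2100))),
            TranscriptModel("NM_MB", "MB", "chrM", "+", ((80_000, 80_100), (81_000, 81_100))),
        ])
        seed_seq = genome.fetch("chrM", 1060, 1100) + genome.fetch("chrM", 80_000, 80_060)
        if planted is not None:
            pos, mutate = planted
            copy = seed_seq
            if mutate:
                arr = list(copy)
                for i in range(0, 40, 4):  # 10 mismatches clustered in the head part
                    arr[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[i]]
                copy = "".join(arr)
            s = genome.sequences["chrM"]
            genome.sequences["chrM"] = s[:pos] + copy + s[pos + 100:]
        seed = make_seed(seed_seq, [
            make_record(chrom="chrM", query_start=0, query_end=40,
                        target_start=1060, target_end=1100),
            make_record(chrom="chrM", query_start=40, query_end=100,
                        target_start=80_000, target_end=80_060),
        ])
        cand = make_candidate(make_boundary(ann, "NM_MA", 0, "NM_MB", 0), [seed])
        return genome, ann, cand

    def test_exact_third_locus_copy_drops_seed(self):
        genome, ann, cand = self.build(planted=(50_000, False))
        ok, detail = filter_multimap(cand, GenomeIndex(genome), ann, FilterConfig())
        assert not ok and "multi-mapping" in detail

    def test_degraded_copy_kept(self):
        genome, ann, cand = self.build(planted=(50_000, True))
        ok, _ = filter_multimap(cand, GenomeIndex(genome), ann, FilterConfig())
        assert ok and cand.n_seeds == 1

    def test_copy_inside_partner_gene_kept(self):
        genome, ann, cand = self.build(planted=(1500, False))  # inside MA's span
        ok, _ = filter_multimap(cand, GenomeIndex(genome), ann, FilterConfig())
        assert ok and cand.n_seeds == 1

    def test_no_alternative_locus_kept(self):
        genome, ann, cand = self.build()
        ok, _ = filter_multimap(cand, GenomeIndex(genome), ann, FilterConfig())
        assert ok


class TestMinSeeds:
    @pytest.mark.parametrize("n,expected", [(0, False), (1, False), (2, True)])
    def test_threshold(self, toy_annotation, n, expected):
        cand = make_candidate(
            make_boundary(toy_annotation, "NM_A1", 0, "NM_D1", 0),
            [make_seed(b * 100) for b in "ACGT"[:n]],
        )
        ok, _ = filter_min_seeds(cand, FilterConfig())
        assert ok is expected


class TestCascade:
    def test_ground_truth_fixture(self, cascade_world):
        w = cascade_world
        candidates = w["detect"]()
        assert len(candidates) == 5  # true fusion + four decoys all detected
        survivors, audit = run_cascade(
            candidates, w["genome"], w["annotation"], w["aux"],
            genome_index=w["index"],
        )
        assert len(survivors) == 1
        b_true = w["boundaries"]["true"]
        assert survivors[0].boundary.genomic_key == b_true.genomic_key

        def first_fail(pair_name):
            b = w["boundaries"][pair_name]
            cand = next(c for c in candidates
                        if (c.boundary.head_gene, c.boundary.tail_gene)
                        == (b.head_gene, b.tail_gene))
            fails = [(f, d) for f, o, d in cand.filter_audit if o == "fail"]
            assert len(fails) == 1
            return fails[0]

        name, _ = first_fail("read_through")
        assert name == "read_through"
        name, detail = first_fail("paralog")
        assert name == "regions" and "paralog" in detail
        name, detail = first_fail("repeat")
        assert name == "regions" and "repeat" in detail
        name, _ = first_fail("single_seed")
        assert name == "min_seeds"

    def test_empty_input(self, toy_genome, toy_annotation):
        survivors, audit = run_cascade([], toy_genome, toy_annotation, AuxiliaryLists(),
                                       genome_index=GenomeIndex(toy_genome))
        assert survivors == [] and audit == []

    def test_all_filters_off_passthrough(self, cascade_world):
        w = cascade_world
        cfg = FilterConfig(**{f"enable_{n}": False for n in
                              ("read_through", "blacklist", "homology", "regions",
                               "multimap", "min_seeds")})
        candidates = w["detect"]()
        survivors, audit = run_cascade(candidates, w["genome"], w["annotation"], w["aux"],
                                       cfg, genome_index=w["index"])
        assert len(survivors) == len(candidates) and audit == []

    def test_final_set_invariant_under_filter_order(self, cascade_world):
        w = cascade_world
        orders = [
            ("read_through", "blacklist", "homology", "regions", "multimap", "min_seeds"),
            ("blacklist", "multimap", "regions", "homology", "read_through", "min_seeds"),
            ("regions", "read_through", "homology", "blacklist", "multimap", "min_seeds"),
        ]
        results = []
        for order in orders:
            survivors, _ = run_cascade(w["detect"](), w["genome"], w["annotation"],
                                       w["aux"], genome_index=w["index"], order=order)
            results.append({c.boundary.genomic_key for c in survivors})
        assert results[0] == results[1] == results[2]

    def test_stricter_config_yields_subset(self, cascade_world):
        w = cascade_world
        lax, _ = run_cascade(w["detect"](), w["genome"], w["annotation"], w["aux"],
                             FilterConfig(min_seeds=1), genome_index=w["index"])
        strict, _ = run_cascade(w["detect"](), w["genome"], w["annotation"], w["aux"],
                                FilterConfig(min_seeds=3), genome_index=w["index"])
        lax_keys = {c.boundary.genomic_key for c in lax}
        strict_keys = {c.boundary.genomic_key for c in strict}
        assert strict_keys <= lax_keys

    def test_boundaries_never_modified(self, cascade_world):
        w = cascade_world
        candidates = w["detect"]()
        before = [c.boundary for c in candidates]
        run_cascade(candidates, w["genome"], w["annotation"], w["aux"],
                    genome_index=w["index"])
        assert [c.boundary for c in candidates] == before
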