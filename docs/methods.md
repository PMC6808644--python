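# Methods

This note documents the models, parameters, and numerical choices behind
exofuse, and what the synthetic benchmarks do and do not demonstrate.

## Detection model

The caller targets one specific event class: chimeric transcripts formed by
joining **intact exons** of two genes. The head and tail genes are named by
transcription direction (5′ partner → 3′ partner), and the two exons
flanking the junction are the *fusion exons*. The primary evidence unit is
the split read: a single read whose two local alignments land on loci more
than 50 kbp apart or on different chromosomes. Mid-exon breakpoints are out
of model by design; in practice most recurrent, clinically relevant fusions
join intact exons, and the conservative definition is what keeps the
false-positive rate low.

A split pair must satisfy, in order:

| rule | default | comparison |
| --- | --- | --- |
| genomic separation (nearest interval ends) | > 50,000 bp | strict |
| aligned anchor per side | ≥ 20 bp | inclusive |
| read coverage by both spans together | > 50 % | strict |
| gap/overlap between the read's two spans | within ±10 bp | inclusive |
| distance of each breakpoint to an exon edge | ≤ 6 bp | inclusive |
| seed realignment identity | ≥ 0.95 | inclusive |
| seed overhang on each side of the junction | ≥ 20 bp | inclusive |
| seeds per reported candidate | ≥ 2 | inclusive |

The ±10 bp contiguity is evaluated on the read's own coordinates (the read
is its own transcript-coordinate proxy). Head/tail orientation is resolved
by trying both readings of the split (as stored, and segment-swapped with
strands complemented) and keeping the one consistent with 5′→3′
transcription on both sides; ambiguous ties go to the smaller summed
boundary offset. Breakpoints are reported snapped to the exon edge — the
downstream chimeric sequence is built from intact exons — with the pre-snap
offsets retained in the record. Intra-gene splits are rejected: the method
defines fusions as inter-gene events. Seed multiplicity counts distinct
collapsed read sequences, so PCR duplicates cannot inflate support.

Isoform ambiguity: boundary snaps through different isoforms that give
identical genomic breakpoints are merged into one candidate; the
representative transcript pair is the smallest-offset one and the
alternatives are listed in an auxiliary column.

## Alignment machinery

Optimal local alignment is delegated to Biopython's `PairwiseAligner`
(C implementation). Two scoring schemes are used:

* `local_align` (seed verification, homology filter): match +1, mismatch
  −2, gap −5 to open (first gap base) and −2 to extend, gated on a shared
  exact word (20 bp for seed verification, 10 bp for the homology filter).
  Thresholds (identity, overhangs, word sizes), not scores, are the
  contract; the scheme approximates BLAST-like defaults.
* `genome_align` extension: match +1, mismatch −3, gaps −8/−3. The
  stricter scheme exists because alignment *ends* define breakpoint
  estimates: under the laxer scheme a chance extension past a chimeric
  junction of ≥ 7 bp carrying two mismatches still gains score (~1 % per
  junction side), which pushes the estimate beyond the 6 bp snapping
  tolerance and silently loses true fusions. With −3/−8/−3 such spurious
  extensions are ~30× rarer; genuine matches are unaffected on error-free
  data and barely affected at realistic error rates.

`genome_align` is a seed-and-extend aligner over a sorted exact-20-mer
index (2-bit encoded, numpy `searchsorted`): seed hits are grouped into
diagonal clusters (band 8 bp), each cluster is extended by Smith–Waterman
over a padded window, near-duplicate loci are collapsed, and up to 5 best
records per orientation are returned. K-mers occurring more than 64 times
in the genome are skipped as repeat noise, mirroring common seed-skipping
heuristics. Any external producer of PSL records can replace it; PSL
coordinates follow the UCSC convention (0-based half-open; `query_start/
query_end` always forward-query; per-block `qStarts` kept PSL-native, i.e.
reversed-query for '−' strand records, so round-trips are lossless).

## Filter cascade

Applied in order: read-through, blacklist, homology, regions (repeats /
paralogs / pseudogenes), multi-mapping, minimum seeds. The order only
affects audit attribution — the final set is order-invariant (asserted by a
property test) because seed-dropping decisions are mutually independent.

* **Read-through**: consecutive same-strand gene pairs with the head
  transcriptionally upstream are co-transcription/intergenic-splicing
  (CoTIS) artifacts, not rearrangements. "Consecutive" means no third
  annotated gene lies entirely in the gap between the two gene spans
  (union of isoform spans); overlapping gene pairs count as consecutive,
  and no base-pair distance cap is imposed. This may discard genuine
  fusions arising from small deletions — a known cost of the filter.
* **Homology**: the 14 bp flanks either side of the junction are compared
  against 1 kb of each partner's natural genomic continuation past its
  breakpoint (head: downstream in transcription direction; tail:
  upstream). A shared exact 10-mer anchor fails the candidate — the
  signature of a mis-called splice rather than a true junction. The 1 kb
  window is a package choice: splice-slippage artifacts live immediately
  past the breakpoint, and an unbounded search would add cost without
  catching a different artifact class. With random sequence the chance of
  a spurious shared 10-mer is ~1–2 % per candidate, so the filter
  occasionally removes a true fusion; this is inherent to the method.
* **Regions**: paralog pairs (unordered lookup) and pseudogene partners
  fail outright; seeds whose genomic segments overlap a repeat interval by
  ≥ 1 bp are dropped first, and the candidate fails only if no seed
  survives. Any-overlap (rather than containment) is used because a
  partial repeat anchor is exactly the failure mode being filtered.
* **Multi-mapping**: each seed is realigned genome-wide; an alignment
  outside both partner gene spans covering at least the seed's combined
  split coverage at identity strictly > 0.95 marks it ambiguous. Hits
  inside either partner don't count — a seed legitimately matches both.
* **Minimum seeds**: ≥ 2 distinct unique-read seeds. On real data this is
  the single most effective filter.

Filters may drop seeds but never alter a boundary. Every applied filter
appends (name, outcome, detail) to the candidate's audit, and removed
candidates record exactly one failure — the first.

## Simulator

`make_fixture` generates a fully synthetic genome: genes of 2–8 exons
(60–300 bp) separated by 200–2,000 bp introns, neighboring genes ≥ 60 kbp
apart (so genuine inter-gene splits clear the 50 kbp rule), strands
random, optional planted repeat families (identical 300 bp copies in
intergenic space), sequence paralogs (~98 % exonic identity), forced
same-strand adjacent pairs (read-through decoy geometry), and pseudogene
labels. Everything is a pure function of the seed.

`generate_truth_set` joins the spliced 5′ portion of a random head
transcript to the 3′ portion of a random tail transcript at exact exon
boundaries, uniformly over genes, then isoforms, then exons; same-gene and
adjacent-gene pairs (either order) are excluded.

`simulate_reads` draws fragments uniformly over the chimeric transcript:
fragment = 2 × read length + inner insert, insert ~ Normal(100 bp, 10 bp)
truncated at 0 ("insert" means the inner mate distance — with 100 bp reads
a 100 bp *fragment* would make mates fully overlap, which is implausible).
Mate 1 is the fragment's 5′ read; mate 2 the reverse complement of its 3′
read; all bases Q40. Pairs are emitted until mean per-base depth reaches
the target **and** ≥ 95 % of transcript positions are covered. For
transcripts shorter than a typical fragment the insert is shrunk (uniform
over what fits), and below two read lengths the mates overlap over the
whole transcript; without this the 95 % coverage demand is unreachable for
transcripts slightly longer than two read lengths. An optional uniform
per-base substitution rate (default 0) supports robustness tests.

What the simulator does *not* model: sequencing errors and quality decay
(by default), expression imbalance between partners, coverage biases,
polymorphisms, and intronic/intergenic background transcription. Passing
the synthetic benchmark therefore demonstrates the pipeline's logic —
split discovery, orientation resolution, snapping, filtering — under clean
conditions, not performance on real libraries, where precision is known to
degrade substantially.

## Evaluation

A prediction matches a truth case iff the ordered (head, tail) gene pair is
identical and both breakpoints agree within a tolerance (default 0 bp,
i.e. exact exon edges). Direction-reversed matches are counted and
reported separately but credited to neither TP nor FP; the truth involved
still counts as missed. Precision is reported as NaN (never 0) when there
are no positive predictions. F1 is the harmonic mean of precision and
recall.

## Benchmark scale and observed behaviour

The acceptance benchmark runs 100 genes / 50 fusions / 100 bp / 50×
(~30,000 reads, ~7.5 Mb genome), chosen so a complete run plus the test
suite finishes in minutes on one CPU while every pipeline stage is
exercised at realistic per-gene geometry. At this scale the pipeline
recovers 48–50 of 50 truths with no false positives across seeds. The two
residual miss classes are structural, not incidental: the homology
filter's chance-10-mer false kills (above), and short chimeras (~250–400
bp) where the insert geometry can satisfy the 95 % coverage rule while no
emitted read crosses the junction with 20 bp on both sides — no seed reads
exist, so no caller under this evidence model could report the case.

## Numerical and degenerate-input conventions

* Coordinates are 0-based half-open everywhere; refGene txStart/exonStarts
  and txEnd/exonEnds are adopted verbatim. Minus-strand transcript
  coordinates count from the genomic `tx_end` side.
* Boundary-snap ties break by (smaller offset, larger transcript exonic
  length, lexicographic transcript id); alignment ranking ties break by
  (chromosome, start) for determinism.
* `quality_trim` keeps reads of trimmed length ≥ 38 (tool `-l` semantics);
  an N base does not by itself discard a read; collapse is on the literal
  sequence (reverse complements stay distinct until alignment).
* Coverage-profile boundary ratios use 30 bp windows and flag ratios > 2
  or < 0.5; a ratio over a zero-depth upstream window is +inf (flagged),
  and undefined (None) when both windows are empty.
* Support-read search realigns against the full chimeric transcript
  (seeds are verified against the fusion-exon pair only); the shorter side
  of a support read may be as small as 1 bp. The search is optional and
  off by default since it realigns the whole library.
* `--threads` partitions alignment by read; results are independent of the
  partitioning (the default implementation is sequential, which satisfies
  the contract trivially).

## Known limitations

* Mid-exon breakpoints and fusions supported only by discordant mate
  pairs (no junction-spanning read) are undetectable by construction.
* The homology criterion ("flank shares a 10-mer with the partner's
  continuation") is an interpretation of a qualitative rule; it is
  isolated behind `FilterConfig` (`flank_len`, `homology_word`,
  `homology_window`).
* The native aligner is exact-seed based: a junction segment containing an
  error inside every 20-mer window would be missed; the external-PSL entry
  point exists for sensitive third-party aligners.
* Annotation handling assumes one chromosome and strand per gene symbol.
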