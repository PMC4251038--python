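# Methods

## Read cleaning

Reads pass through a fixed per-read pipeline: adapter trim → quality end trim
→ drop if any `N` remains → drop if shorter than `min_length`. Counters
satisfy `n_raw = n_cleaned + n_dropped_n + n_dropped_short` by construction.

* **Quality trimming** scans from both ends and removes terminal bases while
  their Phred score is below `q_cutoff` (default **Q20**); interior bases are
  never touched. This plain end-scan was chosen over partial-sum schemes
  (as used by Cutadapt/BWA) because it is deterministic, trivially auditable
  and idempotent; the function is a single seam that can be swapped out.
* **Adapter trimming** is off by default (no adapter is assumed). When an
  adapter is configured, a valid placement is a full internal match or an
  adapter-prefix overlap of at least `min_overlap` (default 3) bases at the
  read's 3′ end, with mismatch fraction ≤ `max_error_rate` (default 0.1) of
  the matched length; the leftmost valid placement and everything 3′ of it is
  removed. Defaults follow common adapter-trimmer conventions.
* `min_length` defaults to 1, i.e. only reads that trim to nothing are
  dropped, and they are counted separately rather than as cleaned reads.
* Paired-end files are processed independently; mate consistency is
  deliberately not enforced (two-run comparisons of paired data are run once
  per mate file).
* Quality encoding: Phred+33 by default, configurable; no autodetection.

## Deduplication (identical + inclusive reads)

Definitions: two reads are **identical** when they match 100% and have equal
length; an **inclusive** read is an exact sub-sequence of a longer read. Only
the longest read is kept as the unique read; its copy count accumulates every
read it absorbs. The **redundancy rate** is
`100 · redundant / unique` and may exceed 100%.

Engine: distinct sequences are processed in descending length order (ties:
lexicographic) and inserted into an incremental joined-text index; each
candidate is resolved with one leftmost substring search over the survivors.
Because survivors are inserted longest-first, the leftmost hit is the longest
container with lexicographic tie-breaking — a deterministic crediting rule
(the definitions alone do not fix which of several containers receives the
copies, so reproducibility requires committing to one). Transitivity
guarantees searching survivors only is sufficient: if a sequence is contained
in a removed sequence it is also contained in that sequence's container.

Bookkeeping: copies of a sequence absorbed by containment all count as
inclusive-removed; duplicate copies of surviving sequences count as
identical-removed. This keeps `n_input = n_unique + n_identical_removed +
n_inclusive_removed` exact. For fixed-length read sets no proper substring
can exist, so identical-only and full deduplication coincide.

Strand handling: by default identity and containment are tested on the
forward strand only, because the definitions are stated purely on sequences.
A `both_strands` mode additionally folds reverse-complement duplicates and
containments, approximating what a strand-aware self-alignment would report.
The default is the documented behaviour; all shipped statistics use it.

The engine is validated against an exhaustive O(n²) pairwise substring-scan
oracle (tests/oracles.py) on hundreds of randomized instances, plus
substring-freeness, conservation and idempotence invariants.

## Reference coverage

Only SAM columns FLAG, RNAME, POS and CIGAR are consumed. CIGAR ops `M`, `=`
and `X` cover reference bases; `D` and `N` advance the reference cursor
without covering (a committed interpretation of "bases mapped": a deletion
is not a mapped base); `I/S/H/P` consume no reference. Records flagged
unmapped (0x4), secondary (0x100) or supplementary (0x800) are excluded from
both depth and the mapped-read count, so each read contributes one primary
placement — this avoids double-counting multi-mapped reads, whose original
treatment is not documented. An alignment naming a scaffold absent from the
header is a hard error, not a silent unmapped record.

Per scaffold and genome-wide:

* breadth (%) = 100 · covered bases / length (genome breadth is therefore the
  length-weighted mean of scaffold breadths),
* depth = mapped bases / length,
* evenness = population SD of scaffold breadths / mean scaffold breadth,
  computed over **all** scaffolds including uncovered ones.

The summary additionally reports the SD and mean of per-scaffold mean depths.
Note these two depth rows' ratio is *not* the evenness statistic — evenness
is defined on breadths. (Published summary tables in this problem domain have
printed evenness values consistent with neither convention; this package
implements the breadth-based definition exactly as stated and exposes the
depth SD/mean pair alongside it so either ratio can be formed.)

Histograms over scaffolds: breadth bins are `{0}, (0,10], …, (90,100]` in
percent; depth bins are `{0}, (0,1], (1,2], (2,4], (4,10], (10,∞)` — open
below, closed above, with a dedicated zero bin. The depth edges reflect the
4-fold / 10-fold thresholds conventionally highlighted in coverage reports
and are configurable. Bin assignment uses integer arithmetic
(`⌈10·covered/length⌉`), so boundary values like exactly 40% land in `(30,40]`
without floating-point surprises.

The internal aligner reports each read at every exact full-length
forward-strand occurrence (first occurrence primary, later ones secondary,
misses unmapped). It exists so the toolkit and its tests run without an
external aligner; real analyses should supply a SAM from a production
aligner. Depth accumulation is validated against a naive per-base oracle.

## Two-run comparison

Each run is cleaned and deduplicated independently. A unique sequence
*overlaps* the other run when it is identical to, a substring of, or a
superstring of one of the other run's unique sequences — exact containment,
not mismatch-tolerant alignment. This convention makes the entire derived
ledger exact integer arithmetic: "total overlapping reads" is the cleaned-read
mass (sum of copy counts) carried by the overlapping uniques, and every
derived row follows by subtraction and the redundancy-rate formula within
each stratum. All ten columns of the published benchmark ledger reproduce
to the printed decimals under these identities (see tests/test_acceptance.py).

The combined unique-overlap count merges both runs' overlapping sets and
collapses cross-run identical/inclusive sequences. For fixed-length runs the
three unique-overlap counts (run 1, run 2, merged) are necessarily equal; for
variable-length runs the merged count can exceed either side's, because
containment can run in both directions between the runs (a constructed
instance asserting this is in the test suite).

## Synthetic data generator

`make_paper_synthetic` emulates a classic validation construction: 10
artificial chromosomes of 150 bp clipped at disjoint loci of a source genome,
10 read templates of 75–100 bp clipped from each chromosome, each emitted
10× at constant Q40 — 1,000 reads whose dedup truth (100 uniques × count 10,
redundancy 900.0%) and coverage truth (the recorded clip windows) are exact.
Defaults are fixed to this construction and are not tuning knobs.

* The source genome defaults to a seeded random 5-kb sequence so the fixture
  never requires a download; any user FASTA can be substituted.
* Clip windows within a chromosome are drawn with strictly increasing starts
  *and* ends (a staircase). Ten independent 75–100-bp windows in 150 bp would
  almost surely nest, making "redraw until substring-free" non-terminating;
  the staircase keeps positions and lengths random while making interval
  nesting impossible. A global pairwise substring-free check (with redraw)
  remains as the guard against chance sequence-level containment.
* The two-run fixture splits the reads interleaved, so each half holds 5
  copies of every template and overlap is complete by construction; a block
  split would instead exercise partial overlap.
* Reads carry constant Q40 qualities and no sequencing errors; the generator
  emulates dataset *structure* (copy numbers, containment, placement), not
  error profiles. Passing fixture tests therefore demonstrates correctness of
  the combinatorial statistics, not robustness to base-calling noise — the
  workflows are exact-match by definition, so noisy duplicates count as
  distinct.

`random_instance` generates property-test instances with a planted
containment fraction: base templates are redrawn until pairwise
substring-free, planted sequences are proper substrings of exactly one base
template, so the expected unique set and counters are known at generation
time and independently re-derivable by the brute-force oracle.

## Numerical and formatting conventions

* Rates and ratios are held at full float precision internally; reports
  round redundancy-style rates to one decimal and coverage percentages/depths
  to two, matching the conventions of the workflows' standard reports.
* Standard deviations are population SDs (divide by N).
* Unique-sequence tables are sorted by count desc, length desc, then sequence,
  and ids assigned after sorting — output is byte-reproducible.
* The per-base depth track omits zero-depth positions unless `--emit-zeros`
  is set, bounding file size on sparse coverage.
* Zero-denominator cases: redundancy rate with zero uniques raises an error;
  stratum rates with an empty stratum report 0.0; evenness of a fully
  uncovered genome is NaN.
* Problem sizes in the test suite (reads ≤ 200, ≤ 500 randomized instances
  per property) were chosen so the exhaustive oracles stay exact and fast;
  the engines themselves handle much larger inputs.

## Known limitations

* Redundancy and overlap are exact-match only; no mismatch tolerance.
* The internal aligner is exact, full-length, forward-strand — it is a
  testing device, not a read mapper.
* BAM/CRAM are not read (SAM text only); SFF conversion is out of scope.
* Gene-model ("expression-like") analysis is the same code path with gene
  sequences supplied as scaffolds; no spliced alignment.
* `--threads` is accepted and validated for interface parity but processing
  is single-threaded; results are by construction thread-count invariant.
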