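# Methods

## Insertion model

The caller targets transposable elements whose integration duplicates the
target site: LTR retrotransposons and TIR DNA transposons, which create
target site duplications (TSDs) of at most ~10 bp (5 bp for the rice
Ty1-copia element Tos17, 8 bp for the Drosophila P-element).  Non-LTR
class I elements, which create no TSD, are outside the model.

On insertion at a site whose pre-insertion sequence spans `[s..e]`
(`e − s + 1 = L`, the TSD length), the mutant chromosome reads

```
... prefix through e | element | suffix from s ...
```

i.e. left TSD copy, element, right TSD copy.  A read crossing the left
junction carries genomic sequence ending with the TSD followed by the
element's 5′ terminus (head); a read crossing the right junction carries
the element's 3′ terminus (tail) followed by the TSD and genomic sequence.
For a reverse-oriented element the roles of the two junctions swap, so the
junction order on the reference encodes orientation.

All coordinates are 1-based inclusive throughout the public surface;
conversions are internal.  Calls are reported against the pre-insertion
(reference) coordinate system: the TSD span `[min(tail, head)..max]` with
the junction positions at its ends, `tsd_len = |head − tail| + 1`, and
direction forward iff `head ≥ tail` (the degenerate `head == tail`, a 1-bp
span, is reported forward by convention; real elements in the model never
produce it, the convention only makes the function total).

## Signature scan

Reads are selected by **exact** occurrence of the element's terminal
signatures — its first and last `k` bases (`k = 17` default, minimum 8).
Both the read and its reverse complement are scanned, which makes detection
read-strand-agnostic and is required to see reverse-oriented insertions.
Exactness is deliberate: a point mutation in a terminus silently hides its
junction (a documented sensitivity limit of this family of methods), but
chance signature hits are essentially eliminated at `k = 17`
(expected ≈ genome size × 4⁻¹⁷).  Signatures reject ambiguous bases; reads
containing `N` simply never match.  A read carrying both signatures yields
both records; duplicate reads are not collapsed, so support counts reflect
raw read evidence.

Flank length filters: basic mode keeps flanks ≥ the TSD length (a flank
must contain a whole TSD to be groupable); extended mode keeps flanks
≥ 20 bp, the default placement-specificity threshold (a 20-mer is unique in
a random 200 kb genome with very high probability, and in real genomes
20 bp is the conventional lower bound for near-unique exact placement).

## Reference-free grouping (basic algorithm)

Head flanks are keyed by their length-`L` suffix, tail flanks by their
length-`L` prefix; keys present on both sides become groups and the longest
flank per side is the representative (ties broken by smallest read id, so
output is invariant to read order).  One-sided keys are discarded — both
junctions must be witnessed.  Representatives are written as a multi-FASTA
sorted by TSD string with headers `{TSD}_{side}` plus a description
carrying flank length and support; the header dialect is this package's own
(deterministic, sortable, usable directly as BLAST query input).

Two distinct insertions share a TSD string with probability `4^-L`
(1/1024 at `L = 5`) per pair, so for the ~10 insertions typical of the
intended use case merging is rare but possible; the reference-guided
algorithm exists to resolve exactly this.  Note that a reverse-oriented
insertion is observed by this route as the reverse complement of the
plus-strand TSD — without a reference the strand cannot be known — so
strand-aware comparisons between the two algorithms canonicalise TSD
strings to `min(s, revcomp(s))`.

## Flank placement (internal exact mapper)

Rather than shelling out to an external aligner, flanks are placed by a
seed-and-verify exact matcher: all plus-strand 13-mers of the reference are
indexed; a query is verified by direct string comparison at each seeded
candidate, on both strands (palindromic queries are deduplicated).  A flank
is accepted only when its **full length matches exactly at exactly one
location genome-wide**; otherwise it is rejected as unmapped or
multi-mapped, with the reason recorded.  This is stricter than a
local-alignment search (no partial or near matches), trading a little
sensitivity near repeats for a deterministic, version-independent contract;
insertions inside perfect repeats are unidentifiable by construction, an
inherited limitation of unique-placement approaches.  The matcher is
cross-checked in the test suite against an independent naive full-genome
scan on every simulated flank.  The junction coordinate is the flank base
adjacent to the element — head: interval end on `+`, interval start on `−`;
tail: mirrored — always reported in plus-strand coordinates.

## Junction pairing and TSD verification (extended algorithm)

Identically placed junctions collapse into clusters (support = read
count).  Head/tail cluster pairs on one chromosome with junction distance
strictly less than the pairing window (default 10 bp, covering every
admissible TSD length; "distance 9 pairs, distance 10 does not") are
candidates.  A candidate is accepted iff the plus-strand-normalised bases
of the head representative over the span, those of the tail
representative, and the reference substring at the span are all identical;
that substring is the call's TSD.  Representatives are the longest flank
per cluster, mirroring the basic algorithm's selection; one consistent
head/tail pair suffices (`min_support` default 1, configurable).  A
cluster may participate in several candidates; all verified candidates are
emitted, since the chance of a spurious combination also passing TSD
verification is bounded by the `4^-L` coincidence probability.  Candidates
whose span is not covered by a flank, or whose flank bases disagree with
the reference, are rejected with a reason.

Control subtraction (`diff_calls`) declares two calls the same locus when
their TSD spans overlap on the same chromosome, and partitions a
sample/control pair into common, sample-specific and control-specific
sets — the standard parent-vs-derivative workflow for isolating de novo
events.

## Parameter sweep

`run_sweep` re-runs the reference-free route over a `(k, L)` grid and, when
a reference is given, projects each group to a verified locus (both
representatives uniquely placed, junctions within the window, span length
`== L`, reference span equal to the group TSD on either strand).  The
expected profile, reproduced on simulation: flank-record counts inflate as
`k` drops below the element-specific length when the terminus is shared
with other genomic copies, and the verified locus count collapses when `L`
is off by one in either direction, because a real junction's head-flank
suffix and tail-flank prefix only coincide at the true `L`.

## Simulator

`make_genome` draws i.i.d. bases at a given GC content.  Defaults model
the intended study design: 100 bp paired-end reads (fragments normal
300 ± 30 bp, both strands, uniform starts), 30× coverage, read count
`round(coverage × genome_len / read_len)` (fragments halved when paired),
substitution-only errors i.i.d. per base.  `plant_insertions` picks sites
whose ±150 bp context is unique genome-wide (either strand) and ≥ 1 kb
apart — guaranteeing the unique-placement contract can succeed — duplicates
the `L`-bp target site and inserts the element (reverse-complemented for
reverse orientation); exactly `round(frac_reverse × n)` sites are reverse,
shuffled by seed, so a requested orientation mix is always realised.
Truth records live in pre-insertion coordinates, the system calls are
reported in.  `choose_shared_tsd_sites` deliberately finds two sites with
identical TSD strings to exercise the basic algorithm's merge failure mode.
`evaluate` scores calls by exact agreement (chromosome, ordered span, TSD
sequence, orientation), one call per truth record.

What the simulator does *not* model: indels and quality-dependent errors,
PCR duplicates, coverage bias, heterozygous/mosaic insertions, nested or
clustered TEs, and real genomes' repeat structure (contexts are unique by
construction except where a test plants repeats on purpose).  Passing
tests therefore demonstrate algorithmic correctness under the stated model,
not performance on real libraries, where signature mutations, repeats and
coverage gaps reduce sensitivity.

## Problem sizes and numerical choices

The test suite and the acceptance script run the headline
parameter-recovery setting on a 200 kb two-chromosome genome with 12
planted insertions of a 400 bp toy element at 30× (≈ 61 000 reads), the
coincidence scenario on 80 kb with 2 insertions, and the error-robustness
property (0.5 % per-base error) over 20 seeded replicates of a 30 kb
genome with 2 insertions each — sizes chosen so the whole suite completes
in well under a minute while every property is exercised end to end.
All randomness flows through explicit integer seeds (numpy PCG64); fixed
seeds give byte-identical outputs.  Tie-breaks (longest flank, then
smallest read id; sorted group and call order) make every pipeline stage
canonical and read-order-invariant.

## Bundled curated call set

`tifind.fixtures` ships the PCR/sequencing-validated Tos17 insertion loci
of two regenerated rice lines (ttm2: 4 loci; ttm5: 12 loci by this
method's approach, 8 by a comparison detector, 7 confirmed by both; one
detector-specific locus that failed validation), checksummed at load.  It
is used as a fixed oracle for the coordinate conventions: every locus
satisfies `|head − tail| + 1 = 5` with orientation matching the junction
order.

## Known limitations

* Exact signature matching misses junctions whose terminal sequence
  mutated; a mismatch-tolerant scan is a possible extension but is off by
  default by design.
* Unique exact placement discards flanks in duplicated sequence; basic
  mode partially compensates (no placement step) at the cost of possible
  TSD-string merges.
* The whole-genome k-mer index is held in memory; it is sized for the
  package's simulation scale and for small genomes, with a pluggable
  external-aligner adapter as the intended path for large real genomes.
* TSD-less elements (non-LTR retrotransposons) are out of scope.
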