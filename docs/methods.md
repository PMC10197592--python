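# Methods

## Problem setting

A tandem repeat (TR) locus is a reference interval covered by consecutive
copies of a motif (1–60 bp here; the truth-set filter itself admits 2–50 bp).
TR alleles differ from the reference by whole-copy gains (expansions) or
losses (contractions), which a variant caller reports as insertions or
deletions with a shared anchor base. Given a trustworthy indel call set and
the reference it was called against, the package decides per allele whether
it is a TR event, assembles a per-locus truth table with short/long allele
repeat counts, and supports validating that table against a second assembly
and benchmarking TR genotypers against it.

## Motif model

* **Canonical motif.** The representative of a motif class is the
  lexicographically smallest string among all cyclic rotations of the motif
  and of its reverse complement (2·|m| candidates). This identifies motifs
  that describe the same physical tract read in either orientation or from
  any phase. Canonicalization is idempotent and invariant under rotation and
  reverse complement; ties between candidates are resolved by the plain
  minimum (duplicates are harmless).
* **Pure decomposition.** The smallest period d dividing |s| with
  s = m·(|s|/d). When no proper period exists the whole sequence is its own
  motif with count 1 — this is what lets a 5 bp insertion beside three
  identical 5 bp copies pass as a 4-copy repeat.
* **Interrupted decomposition.** All |s|/d chunks must agree at every motif
  position except at most one shared position; the motif is the most common
  chunk. When chunk frequencies tie, the first chunk in left-to-right order
  wins — deterministic and order-stable (the tie-break is not dictated by
  the problem; it can change which rotation gets extended at ties).
  Dinucleotides additionally require ≥ 4/5 of chunks to equal the common
  motif; homopolymers require ≥ 9/10 matching bases and forbid two adjacent
  interrupting bases. These stricter small-motif rules prevent the
  one-variable-position relaxation from swallowing arbitrary AT-rich
  sequence.
* **Reference extension.** Whole adjacent copies only, never a partial
  trailing copy. In interrupted mode (motifs ≥ 3 bp) a copy may differ at
  the variable position, but the first and last counted copy in each
  direction must equal the common motif exactly: far-end inexact copies are
  trimmed, and if the copy nearest the anchor is inexact that direction
  counts zero (copies must stay contiguous with the anchor, so the inexact
  near copy cannot be skipped). This per-direction reading is slightly
  conservative; it prevents over-extending the locus boundary past a
  departure from the common motif. Homopolymer and dinucleotide extension
  uses exact copies only and stops at any interruption.

## The allele classifier

Order of attempts: pure decomposition first (a variant that passes as a
pure repeat is never reported interrupted), then interrupted decompositions
by increasing motif length over the divisors of the variant-sequence length
(including length 1, so interrupted homopolymers reach the homopolymer
categories), then the partial-repeat check, then size-based rejection.

Thresholds are applied to the *larger* of the reference and alternate
alleles: ≥ `min_repeats` (3) total copies spanning ≥ `min_span_bp` (9) bp.
This admits, e.g., a 2-copy deletion from a 6-copy tract (the reference
allele carries the 6 copies). Homopolymer and > 50 bp-motif repeats are
detected by the same machinery but routed to their own categories rather
than the truth set; they are biologically TR-like but excluded from the
benchmark by design.

**Partial repeats.** A variant sequence that is whole copies of a motif plus
a non-empty partial copy at one end (e.g. CAGCAGCA) cannot be a whole-copy
TR event. The classifier labels it `partial_repeat_end` when the whole
copies plus reference extension of that motif would have met the thresholds
— i.e. the category means "a TR event but for the partial copy". Both
leading- and trailing-aligned readings are tried, smallest motif first.
Without reaching thresholds, such alleles fall through to the size
categories like any other decoy.

**Coordinates.** VCF positions are 1-based; all internal loci and emitted
BED are 0-based half-open. The insertion point sits between pos and pos+1
after anchor stripping; a deletion removes [pos, pos+|s|) and its copies
count toward the reference total, with extension running from the flanks
outside the deleted interval. Each REF/ALT pair is first reduced to minimal
representation (common suffix then prefix trimmed, one anchor base kept) so
multi-allelic records decompose per allele; no left-alignment against the
reference is attempted — un-normalized input may mis-classify.

**Sites.** A bi-allelic variant passes only when both alleles pass and
agree on motif string, locus start/end and variable position; exact motif
strings are compared (not canonical forms) since the locus coordinates must
agree anyway. One-passing and both-passing-but-disagreeing sites get their
own categories; with more than two alternate alleles the site is `other`.
After site classification, any two variants whose reference loci share a
base are both discarded (`overlapping_locus`): neither can be trusted as
the locus's genotype. A heterozygous single-alt site keeps the reference
repeat count as its short allele; a site is multi-allelic when both alleles
differ from the reference and from each other (in repeat counts).

## Validation against a target assembly

Coordinate liftover (chain files) is an external prerequisite; only the
position-based logic lives here. Mono-allelic deletions are first rewritten
as 1 bp SNV placeholders (original alleles stored in an INFO tag,
restorable byte-identically) because liftover tools fail on deletions
straddling chain-interval boundaries. Around the lifted position, motif
copies are counted immediately left and right (anchor between pos−1 and
pos) and summed, reusing the locus's interruption mode; the locus passes if
the target count is within ±2 repeats of the short or long allele. The
margin is in repeat units for all motif sizes. Passing is monotone in the
margin. A final check verifies that a forward-and-back liftover returns
every record (matched by ID) to its original position.

## Pure-repeat catalogs

The scanner reports every maximal run of ≥ 2 whole identical copies, once
per smallest period, with the end coordinate trimmed to a whole number of
copies; runs of different motifs may overlap and are all kept (no merging).
Implementation: for each motif length k, maximal stretches with
s[x] = s[x+k]; a run is reported only when its k-mer motif is itself
aperiodic, which makes the smallest-period report unique. This defines
"pure repeat" directly rather than through an external repeat finder's
scoring parameters; on scoring-based catalogs of real genomes, counts can
differ at edge cases. Homopolymers are scannable (`min_motif=1`) but the
CLI default starts at 2 bp, matching common catalog practice. Completeness
of a catalog against a truth BED counts truth loci with zero overlapping
bases (a single shared base counts as covered).

Tool-catalog export writes the 0-based half-open loci in each genotyper's
1-based inclusive convention: ExpansionHunter variant-catalog JSON
(`ReferenceRegion "chr:start+1-end"`, `LocusStructure "(MOTIF)*"`), GangSTR
TSV, HipSTR regions BED. Exports round-trip through the bundled readers
(HipSTR's format does not store the motif sequence, only its length).

## Evaluation

Estimated alleles are paired with truth alleles strictly short↔short,
long↔long — never best-matching permutation — because a benchmark should
penalize a tool that swaps its alleles. Category precedence for a
non-exact estimate: no-call > called-hom-ref > called-het-ref >
wrong-direction > over/under-estimate; "wrong direction" requires both the
estimate and the truth to be strictly non-reference with opposite signs,
while estimates sitting exactly at the reference go to the ref-call
categories.

Quality scores: `Q_CI = exp(−4·ci/size)` with both quantities in the same
unit (repeat units here; the ratio is unit-invariant). The read-fraction
score divides supporting reads by total reads, counts in-repeat reads as
supporting any allele whose size exceeds 80% of the read length (in-repeat
read sizes plateau near the read length), and rescales the raw fraction by
mapping anything above 0.15 to 1 and dividing smaller values by 0.15. The
threshold sweep counts an allele as true positive when strictly accurate
and passing the threshold, true negative when inaccurate and filtered; the
false-negative rate is the fraction of strictly accurate alleles a
threshold filters away. No-calls never pass a threshold and can optionally
be excluded entirely.

Profile-interval matching (EHdn-style): an interval detects a truth
expansion when canonical motifs agree and the midpoints lie within 600 bp
(the window comfortably exceeds typical short-read fragment lengths; a flag
switches to nearest-edge distance, since "within 600 bp" does not name its
anchor points). Sensitivity is binned by total long-allele size,
specificity by motif size. The multi-allelic fraction — the share of
alleles at loci where both alleles differ from the reference and from each
other, a relative mutation-rate proxy — is computed per bin with bins under
20 alleles suppressed, and in size/motif binning modes admits interrupted
alleles only up to 25% interrupted copies.

## Synthetic fixtures

The generator emulates the *shape* of the real inputs: a reference with
planted TR tracts separated by screened random spacers, an indel VCF with
known per-record outcomes, and simulated tool calls. One RNG stream per
seed, consumed in a fixed order, makes every artifact byte-reproducible.
Spacers are rejection-sampled until they contain no repeat run of ≥ 6 bp
themselves and their junction bases cannot extend an adjacent tract (either
as a whole extra copy or by continuing the scanner's periodicity run), so
planted ground truth is exact rather than probable. Decoy indels are
re-rolled until the classifier assigns the intended rejection category
against the assembled reference. Interruption specs vary one motif position
in the *inserted* copies (first and last kept exact); reference tracts stay
pure. Default tract sizes (4–12 copies), decoy counts, and the tool error
model (80% exactly right, 2% no-calls, symmetric over/under errors with
geometric magnitudes, confidence intervals wider for erroneous calls) are
chosen to resemble a well-behaved short-read genotyper on a benchmark
sample. What the fixtures do **not** model: read-level errors, alignment
artifacts, low-complexity flanking sequence, somatic mosaicism — so passing
tests demonstrate the correctness of the algorithms, not robustness to
messy real-world calls.

Test and acceptance problem sizes (hundreds of random alleles, ≤ 5 kb
contigs, 100-locus fixtures, 10⁴-string property checks) were chosen as the
smallest scales at which the brute-force oracles still exercise every code
path; all suites run in seconds.

## Known limitations

* One variable position per motif only; alternating-motif or compound loci
  are out of scope.
* The filter trusts the input's normalization; un-left-aligned indels may
  classify at a shifted locus.
* The pure-repeat scanner intentionally has no mismatch tolerance; it is
  not a drop-in replacement for scoring-based repeat finders on imperfect
  repeats.
* Full-genome runs are supported by the streaming design but not optimized
  (the scanner is O(L·k_max) pure Python).
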