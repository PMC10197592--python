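# trtruth — tandem-repeat truth sets from ins/del variants

Tandem repeats (TRs) — tracts of consecutive copies of a short DNA motif —
mutate by gaining or losing whole motif copies, so TR expansions and
contractions surface in a variant call file as ordinary insertions and
deletions. `trtruth` turns a high-quality indel call set (e.g. one derived
from haploid assemblies) into a per-locus TR *truth set* suitable for
benchmarking TR genotyping tools, and provides the machinery around it:

* **motif algorithmics** — canonical motifs (the alphabetically first string
  over all cyclic rotations of a motif and its reverse complement, so CAG,
  AGC and CTG all normalize to AGC), smallest-period decomposition, and
  interrupted-repeat decomposition where one motif position may vary across
  copies (NGG-style patterns);
* **the TR filter** — classifies every VCF ins/del allele as a TR expansion
  or contraction, or assigns it exactly one rejection category (small indel,
  non-TR ≥ 6 bp, homopolymer, motif > 50 bp, partial repeat at the variant
  end, multi-allelic disagreement, overlapping loci, other);
* **validation** — concordance of truth alleles with an independent
  ("target") assembly of the same genome, within ±2 repeat copies;
* **catalogs** — a pure-repeat scanner over any reference FASTA, span
  filtering, completeness scoring against a truth BED, and export in the
  ExpansionHunter / GangSTR / HipSTR catalog formats;
* **evaluation** — per-allele concordance (short allele with short, long
  with long), error categories, two allele quality scores, quality-threshold
  sweeps, and detection/false-positive matching for profile-style interval
  callers;
* **fixtures** — a seeded generator of toy references with planted TR
  tracts, ground-truth VCFs with decoys, and simulated tool calls, so the
  whole pipeline is testable without downloads.

## The filter in one paragraph

For an allele, strip the shared VCF anchor base to get the *variant
sequence* and find its smallest pure repeat unit (falling back to the whole
sequence). Extend that motif into the reference immediately left and right
of the insertion point (for deletions the deleted bases themselves count as
reference copies). The allele passes if the larger of the two alleles has
≥ 3 total repeats spanning ≥ 9 bp with a 2–50 bp motif. If the pure
decomposition fails, retry allowing one motif position to vary across
copies — with stricter purity rules for dinucleotides (≥ 4/5 exact copies)
and homopolymers (≥ 9/10 matching bases, no two adjacent interruptions),
and requiring the first and last reference copy to match the common motif
exactly. Multi-allelic variants pass only when both alleles agree on motif,
locus coordinates and interruption position; variants whose reference loci
overlap are both discarded.

## Worked example

```python
from trtruth import VariantAllele, classify_allele

contig = "TGACTTAGCATCCGATTGACCTGAACGTATCGGATCTTAC" + "GCG" * 9 + "TTAGACTCAG"
allele = VariantAllele("chr1", 40, contig[39], contig[39] + "GCGGCG", gt=(0, 1))
call = classify_allele(allele, {"chr1": contig})
print(call.motif, call.ref_repeats, call.allele_repeats)
```

prints `GCG 9 11`: the 6 bp insertion contributes 2 GCG copies, the
reference contributes 9 adjacent copies, so the alternate allele is an
11 × GCG repeat spanning 33 bp — a TR expansion that enters the truth set
with locus coordinates covering the 27 bp reference tract. Running
`python examples/02_filter_vcf_to_truth_set.py` shows the same logic over a
whole simulated VCF:

```
"passing_alleles": 6, "passing_loci": 5,
"rejection_categories": {"small_indel_1_5bp": 3, "non_tr_ge_6bp": 3}
```

with a truth table listing each locus's motif, reference repeats, and
short/long allele genotype (a multi-allelic AAG locus comes out as 6/8
copies on a 5-copy reference). The other `examples/*.py` scripts cover
catalog building, target-assembly validation and tool evaluation; each
prints what it computes and what the numbers mean.

There is also a thin CLI: `trtruth filter | catalog | evaluate | simulate`
(see `trtruth --help`).

## Limitations

Input VCFs are assumed normalized (anchored, left-aligned); coordinate
liftover between assemblies is delegated to external chain-file tools (this
package handles the bookkeeping before and after); multi-position
interruption patterns (e.g. alternating-motif loci) are out of scope. See
`docs/methods.md` for the full model description and design choices.
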