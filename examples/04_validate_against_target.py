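"""Validate truth loci against a second ("target") reference assembly.

A truth locus genotyped 7/9 GAA repeats is checked against a target assembly
holding 9 GAA copies at the lifted position: the long allele matches exactly,
so the locus passes the +/-2-repeat concordance test. A second target with
only 3 copies matches neither allele and fails.
"""

from trtruth import check_target_concordance
from trtruth.trfilter import TruthLocus

locus = TruthLocus(
    chrom="chr9", locus_start=1000, locus_end=1021, motif="GAA",
    canonical_motif="AAG", is_pure=True, short_allele_repeats=7,
    long_allele_repeats=9, ref_repeats=7, is_multiallelic=False,
)

flank_l = "TGACTTAGCATCCGATTGAC"
flank_r = "CTGAACGTATCGGATCTTAC"

target_good = {"chr9": flank_l + "GAA" * 9 + flank_r}
lifted_pos = len(flank_l) + 1  # 1-based position at the tract start
res = check_target_concordance(locus, lifted_pos, target_good)
print(f"target with 9 copies: target_repeats={res.target_repeats} "
      f"matched={res.matched_allele} passed={res.passed}")

target_bad = {"chr9": flank_l + "GAA" * 3 + flank_r}
res = check_target_concordance(locus, lifted_pos, target_bad)
print(f"target with 3 copies: target_repeats={res.target_repeats} "
      f"failed_step={res.failed_step}")
# |3-7| and |3-9| both exceed the margin of 2, so the allele_match step fails
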