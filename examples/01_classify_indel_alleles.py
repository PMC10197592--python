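"""Classify single ins/del alleles as tandem-repeat expansions/contractions.

Builds a toy contig holding a 9-copy GCG tract and a 6-copy TC tract, then
asks the filter what a 6 bp insertion and a 4 bp deletion at those tracts
represent. The printed repeat counts include the copies already present in
the reference: an insertion of 2 GCG copies beside 9 reference copies is an
11-repeat allele spanning 33 bp.
"""

from trtruth import VariantAllele, classify_allele

# 40 bp non-repetitive flanks around each tract
contig = (
    "TGACTTAGCATCCGATTGACCTGAACGTATCGGATCTTAC"
    + "GCG" * 9
    + "TTAGACTCAGATCGTATGCCAATGCTTAGCCATGACTTGA"
    + "TC" * 6
    + "ATCGGATCTTACTGACTTAGCATCCGATTGACCTGAACGT"
)
ref = {"chr1": contig}

gcg_start = 40  # 0-based start of the GCG tract
ins = VariantAllele("chr1", gcg_start, contig[gcg_start - 1],
                    contig[gcg_start - 1] + "GCGGCG", gt=(0, 1))
call = classify_allele(ins, ref)
print("insertion +GCGGCG at the GCG tract:")
print(f"  motif={call.motif} reference copies={call.ref_repeats} "
      f"allele copies={call.allele_repeats} "
      f"span={call.allele_repeats * len(call.motif)} bp pure={call.is_pure}")

tc_start = 40 + 27 + 40
dele = VariantAllele("chr1", tc_start, contig[tc_start - 1] + "TCTC",
                     contig[tc_start - 1], gt=(0, 1))
call = classify_allele(dele, ref)
print("deletion of TCTC from the TC tract:")
print(f"  motif={call.motif} reference copies={call.ref_repeats} "
      f"allele copies={call.allele_repeats} (contraction of {-call.delta_repeats} copies)")

# a 4 bp random insertion is not a TR: it gets a rejection category instead
decoy = VariantAllele("chr1", 12, contig[11], contig[11] + "GTCA", gt=(0, 1))
print(f"decoy +GTCA insertion: {classify_allele(decoy, ref)}")
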