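"""Filter a whole VCF down to a TR truth set.

Simulates a reference with five planted TR tracts plus decoy variants,
writes FASTA/VCF to a temp directory, runs the filter, and prints the
category summary: every ins/del allele lands either in the truth set or in
exactly one rejection category.
"""

import json
import tempfile
from pathlib import Path

from trtruth import PlantSpec, filter_vcf, generate_reference, generate_vcf

specs = [
    PlantSpec("CAG", 9, (2,)),             # CAG expansion +2 copies
    PlantSpec("GCG", 7, (3,)),
    PlantSpec("TC", 6, (-2,)),             # TC contraction
    PlantSpec("AAG", 5, (1, 3)),           # multi-allelic: 6/8 copies
    PlantSpec("CGG", 6, (4,), interruption=(0, 0.3)),  # interrupted NGG repeat
]

with tempfile.TemporaryDirectory() as tmp:
    synref = generate_reference(specs, seed=11)
    synvcf = generate_vcf(synref, seed=11)
    fasta = synref.write_fasta(Path(tmp) / "ref.fa")
    vcf = synvcf.write_vcf(Path(tmp) / "variants.vcf")
    result = filter_vcf(vcf, fasta, out_prefix=str(Path(tmp) / "truthset"))

print(json.dumps(result.summary, indent=2))
print()
print(result.truth_df.to_string(index=False))
# the AAG locus shows is_multiallelic=True with short/long = 6/8 repeats;
# decoy indels appear under small_indel_1_5bp / non_tr_ge_6bp
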