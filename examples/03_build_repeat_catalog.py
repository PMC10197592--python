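"""Scan a reference for pure repeats, span-filter, and export tool catalogs.

Prints the loci found at two span thresholds (larger threshold = subset),
scores how many truth loci a thinned catalog misses, and writes an
ExpansionHunter variant-catalog JSON entry to show the 1-based inclusive
coordinate convention.
"""

import json
import tempfile
from pathlib import Path

from trtruth import filter_by_span, missed_fraction, scan_pure_repeats, write_tool_catalogs

contig = (
    "TTAGACTCAGATCGTATGCC" + "CAG" * 8        # 24 bp CAG tract
    + "AATGCTTAGCCATGACTTGA" + "AT" * 5       # 10 bp AT tract
    + "GTCAACTGGATCCTTACGAC" + "TTAGGG" * 3   # 18 bp telomere-like tract
    + "CCGATTGACCTGAACGTATC"
)

catalog9 = scan_pure_repeats({"chr1": contig}, min_motif=2, max_motif=8, min_span_bp=9)
print("loci spanning >= 9 bp:")
for l in catalog9:
    print(f"  [{l.start:4d},{l.end:4d}) {l.motif:>6s} x{l.repeat_count}")

catalog12 = filter_by_span(catalog9, 12)
print(f"span >= 12 bp keeps {len(catalog12)} of {len(catalog9)} loci (nested subset)")

# completeness: drop the AT locus from the catalog and count missed truth loci
truth = [(l.chrom, l.start, l.end) for l in catalog9]
thinned = [(l.chrom, l.start, l.end) for l in catalog9 if l.motif != "AT"]
missed, frac = missed_fraction(truth, thinned)
print(f"thinned catalog misses {missed} truth locus ({frac:.1%})")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "eh.json"
    write_tool_catalogs(catalog9, "expansionhunter", path)
    print("first ExpansionHunter catalog entry:")
    print(json.dumps(json.load(open(path))[0], indent=2))
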