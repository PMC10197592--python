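"""Pure tandem-repeat catalogs: scanning, span filtering, completeness, export.

``scan_pure_repeats`` enumerates every maximal run of >= 2 whole identical
motif copies in a reference sequence, one report per smallest period. Runs of
different motifs may physically overlap and are all reported (no merging).
End coordinates are trimmed so each locus spans an exact multiple of the
motif size.

``missed_fraction`` scores how many truth loci a catalog misses entirely
(zero overlapping bases — ``bedtools subtract -A`` semantics).

``write_tool_catalogs`` exports loci in the repeat-catalog formats consumed
by ExpansionHunter (variant-catalog JSON), GangSTR (TSV) and HipSTR (regions
BED), converting the internal 0-based half-open intervals to each tool's
1-based inclusive convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from .motif import smallest_pure_unit
from .refseq import as_refview

__all__ = [
    "CatalogLocus",
    "scan_pure_repeats",
    "filter_by_span",
    "missed_fraction",
    "write_tool_catalogs",
    "read_tool_catalog",
]

TOOL_FORMATS = ("expansionhunter", "gangstr", "hipstr")


@dataclass(frozen=True)
class CatalogLocus:
    """A pure reference TR interval; 0-based half-open, end trimmed to a whole
    number of motif copies."""

    chrom: str
    start: int
    end: int
    motif: str
    repeat_count: int

    def __post_init__(self) -> None:
        assert self.end - self.start == self.repeat_count * len(self.motif)

    @property
    def span(self) -> int:
        return self.end - self.start


def scan_pure_repeats(
    reference,
    min_motif: int = 1,
    max_motif: int = 60,
    min_span_bp: int = 9,
    chroms: Optional[Sequence[str]] = None,
) -> List[CatalogLocus]:
    """Find all maximal pure repeat runs in a reference.

    ``reference`` may be an indexed FASTA path/handle or an in-memory dict /
    string. For each motif length ``k`` a run is a maximal stretch where
    ``s[x] == s[x+k]``; the run is reported only at its smallest period (an
    ``ACAC`` unit is reported as ``AC``), must contain at least 2 whole
    copies, and is kept when its trimmed span reaches ``min_span_bp``.
    Overlapping runs of different motifs are all reported.
    """
    looks_like_sequence = isinstance(reference, str) and set(reference.upper()) <= set("ACGTN")
    if isinstance(reference, (str, Path)) and not looks_like_sequence:
        import pysam

        reference = pysam.FastaFile(str(reference))
    ref = as_refview(reference)
    out: List[CatalogLocus] = []
    for chrom in chroms if chroms is not None else ref.contigs():
        seq = ref.get(chrom, 0, ref.length(chrom))
        out.extend(_scan_sequence(seq, chrom, min_motif, max_motif, min_span_bp))
    out.sort(key=lambda l: (l.chrom or "", l.start, len(l.motif)))
    return out


def _scan_sequence(
    seq: str, chrom: Optional[str], min_motif: int, max_motif: int, min_span_bp: int
) -> List[CatalogLocus]:
    n = len(seq)
    found: List[CatalogLocus] = []
    for k in range(min_motif, min(max_motif, n // 2) + 1):
        x = 0
        limit = n - k
        while x < limit:
            if seq[x] != seq[x + k] or seq[x] not in "ACGT":
                x += 1
                continue
            run_start = x
            while x < limit and seq[x] == seq[x + k] and seq[x] in "ACGT":
                x += 1
            run_len = x - run_start  # matched lag-k positions
            span = run_len + k
            copies = span // k
            if copies < 2:
                continue
            trimmed = copies * k
            if trimmed < min_span_bp:
                continue
            motif = seq[run_start : run_start + k]
            if len(smallest_pure_unit(motif).motif) != k:
                continue  # reported at its smaller period instead
            found.append(
                CatalogLocus(chrom, run_start, run_start + trimmed, motif, copies)
            )
    return found


def filter_by_span(
    catalog: Iterable[CatalogLocus], min_span_bp: int
) -> List[CatalogLocus]:
    """Keep loci spanning at least ``min_span_bp``; monotone in the threshold."""
    return [l for l in catalog if l.span >= min_span_bp]


def _as_intervals(bed) -> List[Tuple[str, int, int]]:
    if isinstance(bed, (str, Path)):
        out = []
        with open(bed) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                if len(f) < 3:
                    raise ValueError(f"malformed BED line: {line!r}")
                out.append((f[0], int(f[1]), int(f[2])))
        return out
    norm = []
    for item in bed:
        if isinstance(item, CatalogLocus):
            norm.append((item.chrom, item.start, item.end))
        else:
            chrom, start, end = item[0], int(item[1]), int(item[2])
            norm.append((chrom, start, end))
    return norm


def missed_fraction(truth_bed, catalog_bed) -> Tuple[int, float]:
    """Count truth loci with zero overlap with any catalog interval.

    A single shared base is enough to count as covered. Returns
    ``(missed_count, missed_fraction)``; the fraction is 0.0 for an empty
    truth set.
    """
    from intervaltree import IntervalTree

    truth = _as_intervals(truth_bed)
    catalog = _as_intervals(catalog_bed)
    trees: Dict[str, IntervalTree] = {}
    for chrom, start, end in catalog:
        if end > start:
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    missed = 0
    for chrom, start, end in truth:
        tree = trees.get(chrom)
        if tree is None or not tree.overlap(start, end):
            missed += 1
    frac = missed / len(truth) if truth else 0.0
    return missed, frac


def write_tool_catalogs(
    loci: Iterable[CatalogLocus],
    fmt: str,
    path: Union[str, Path],
) -> int:
    """Write loci in a TR-genotyper catalog format; returns loci written.

    Loci with zero repeat copies in the reference cannot be encoded in these
    formats and are skipped. Conventions:

    * ``expansionhunter``: JSON array of ``{LocusId, LocusStructure,
      ReferenceRegion, VariantType}`` with ``ReferenceRegion`` 1-based
      inclusive (``chr:start+1-end``) and structure ``(MOTIF)*``;
    * ``gangstr``: TSV of chrom, 1-based start, 1-based inclusive end,
      motif length, motif;
    * ``hipstr``: regions BED of chrom, 1-based start, 1-based inclusive end,
      motif length, repeat count, locus name.
    """
    if fmt not in TOOL_FORMATS:
        raise ValueError(f"unknown catalog format {fmt!r}; expected one of {TOOL_FORMATS}")
    rows = []
    n_skipped = 0
    for l in loci:
        if l.repeat_count < 1:
            n_skipped += 1
            continue
        rows.append(l)
    if n_skipped:  # pragma: no cover - warning path
        import warnings

        warnings.warn(f"skipped {n_skipped} loci with zero reference repeats")

    path = str(path)
    if fmt == "expansionhunter":
        entries = [
            {
                "LocusId": f"{l.chrom}-{l.start}-{l.end}-{l.motif}",
                "LocusStructure": f"({l.motif})*",
                "ReferenceRegion": f"{l.chrom}:{l.start + 1}-{l.end}",
                "VariantType": "Repeat",
            }
            for l in rows
        ]
        with open(path, "w") as fh:
            json.dump(entries, fh, indent=2)
    elif fmt == "gangstr":
        with open(path, "w") as fh:
            for l in rows:
                fh.write(
                    f"{l.chrom}\t{l.start + 1}\t{l.end}\t{len(l.motif)}\t{l.motif}\n"
                )
    else:  # hipstr
        with open(path, "w") as fh:
            for l in rows:
                name = f"{l.chrom}-{l.start}-{l.end}-{l.motif}"
                fh.write(
                    f"{l.chrom}\t{l.start + 1}\t{l.end}\t{len(l.motif)}\t"
                    f"{l.repeat_count}\t{name}\n"
                )
    return len(rows)


def read_tool_catalog(fmt: str, path: Union[str, Path]) -> List[CatalogLocus]:
    """Parse a catalog written by :func:`write_tool_catalogs` back to loci."""
    if fmt not in TOOL_FORMATS:
        raise ValueError(f"unknown catalog format {fmt!r}")
    loci: List[CatalogLocus] = []
    if fmt == "expansionhunter":
        with open(path) as fh:
            entries = json.load(fh)
        for e in entries:
            chrom, region = e["ReferenceRegion"].split(":")
            start_1, end = (int(v) for v in region.split("-"))
            motif = e["LocusStructure"].strip("()*")
            start = start_1 - 1
            loci.append(CatalogLocus(chrom, start, end, motif, (end - start) // len(motif)))
        return loci
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if not f or not f[0]:
                continue
            chrom, start_1, end = f[0], int(f[1]), int(f[2])
            start = start_1 - 1
            if fmt == "gangstr":
                motif = f[4]
                count = (end - start) // len(motif)
            else:  # hipstr: motif length + count, motif sequence not stored
                motif_len, count = int(f[3]), int(f[4])
                motif = "N" * motif_len  # placeholder; sequence not in format
            loci.append(CatalogLocus(chrom, start, end, motif, count))
    return loci
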