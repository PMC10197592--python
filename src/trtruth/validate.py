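"""Concordance of truth-set TR calls against a second ("target") reference.

Truth loci derived from one assembly can be cross-checked against an
independent assembly of the same genome (e.g. the T2T assembly of the same
cell line): after mapping a locus position into the target assembly, the
number of motif copies found in the target sequence around that position
should match the short or long truth allele to within a small margin
(default +/- 2 repeats).

Coordinate liftover itself (chain files, LiftoverVcf) is an external
prerequisite; this module consumes lifted positions and performs the
bookkeeping around it:

* converting mono-allelic deletions to 1 bp SNV placeholders so that liftover
  tools do not fail on deletions straddling chain-interval boundaries, with a
  lossless round-trip back to the original alleles;
* counting motif copies around the lifted position and applying the margin
  test (:func:`check_target_concordance`);
* verifying that a forward-then-back liftover returns every record to its
  original position (:func:`positions_unchanged_after_roundtrip`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .refseq import as_refview
from .trfilter import TruthLocus, _extend

__all__ = [
    "ConcordanceResult",
    "check_target_concordance",
    "deletions_to_snv_placeholders",
    "restore_snv_placeholders",
    "positions_unchanged_after_roundtrip",
]

PLACEHOLDER_TAG = "OriginalAlleles"


@dataclass(frozen=True)
class ConcordanceResult:
    """Outcome of validating one truth locus against the target reference."""

    locus_id: str
    target_repeats: Optional[int]
    matched_allele: str  # "none" | "short" | "long" | "both"
    passed: bool
    failed_step: Optional[str] = None  # liftover|allele_match|back_liftover|position_changed

    def __post_init__(self) -> None:
        assert self.passed == (self.failed_step is None) == (self.matched_allele != "none")


def check_target_concordance(
    locus: TruthLocus,
    lifted_pos: int,
    target_ref,
    margin: int = 2,
    target_chrom: Optional[str] = None,
) -> ConcordanceResult:
    """Count motif copies around ``lifted_pos`` in the target reference and
    test agreement with the truth alleles.

    ``lifted_pos`` is 1-based; copies are counted immediately left and right
    of the anchor between positions ``lifted_pos - 1`` and ``lifted_pos`` and
    summed, reusing the locus's interruption mode. The check passes when the
    target repeat count is within ``margin`` repeats of the short or long
    truth allele (or both).
    """
    ref = as_refview(target_ref)
    chrom = target_chrom if target_chrom is not None else locus.chrom
    locus_id = f"{locus.chrom}:{locus.locus_start}-{locus.locus_end}"
    if chrom not in ref.contigs() or not 1 <= lifted_pos <= ref.length(chrom):
        return ConcordanceResult(locus_id, None, "none", False, "liftover")
    anchor = lifted_pos - 1  # 0-based offset between lifted_pos-1 and lifted_pos
    left = _extend(ref, chrom, anchor, locus.motif, locus.variable_position, "left")
    right = _extend(ref, chrom, anchor, locus.motif, locus.variable_position, "right")
    target_repeats = left + right
    short_ok = abs(target_repeats - locus.short_allele_repeats) <= margin
    long_ok = abs(target_repeats - locus.long_allele_repeats) <= margin
    if short_ok and long_ok:
        matched = "both"
    elif short_ok:
        matched = "short"
    elif long_ok:
        matched = "long"
    else:
        return ConcordanceResult(locus_id, target_repeats, "none", False, "allele_match")
    return ConcordanceResult(locus_id, target_repeats, matched, True, None)


# ---------------------------------------------------------------------------
# VCF bookkeeping around an external liftover


def _iter_vcf(path):
    import pysam

    return pysam.VariantFile(str(path))


def deletions_to_snv_placeholders(in_vcf: str, out_vcf: str) -> int:
    """Rewrite mono-allelic deletions as 1 bp SNV placeholders.

    Each mono-allelic deletion record becomes an SNV at the same start
    position with an arbitrary alternate base; the original REF/ALT strings
    are stored in the ``OriginalAlleles`` INFO tag so
    :func:`restore_snv_placeholders` can reproduce them byte-identically.
    Insertions and multi-allelic records pass through untouched. Returns the
    number of converted records.
    """
    vcf = _iter_vcf(in_vcf)
    if PLACEHOLDER_TAG not in vcf.header.info:
        vcf.header.info.add(
            PLACEHOLDER_TAG, 1, "String",
            "REF|ALT of the original deletion replaced by this SNV placeholder",
        )
    import pysam

    out = pysam.VariantFile(str(out_vcf), "w", header=vcf.header)
    n = 0
    for rec in vcf:
        alts = rec.alts or ()
        if len(alts) == 1 and len(rec.ref) > len(alts[0]) == 1:
            orig_ref, orig_alt = rec.ref, alts[0]
            placeholder = "A" if orig_ref[0] != "A" else "C"
            rec.info[PLACEHOLDER_TAG] = f"{orig_ref}|{orig_alt}"
            rec.ref = orig_ref[0]
            rec.alts = (placeholder,)
            n += 1
        out.write(rec)
    out.close()
    return n


def restore_snv_placeholders(in_vcf: str, out_vcf: str) -> int:
    """Inverse of :func:`deletions_to_snv_placeholders`."""
    import pysam

    vcf = _iter_vcf(in_vcf)
    out = pysam.VariantFile(str(out_vcf), "w", header=vcf.header)
    n = 0
    for rec in vcf:
        tag = rec.info.get(PLACEHOLDER_TAG)
        if tag:
            orig_ref, orig_alt = tag.split("|")
            rec.ref = orig_ref
            rec.alts = (orig_alt,)
            del rec.info[PLACEHOLDER_TAG]
            n += 1
        out.write(rec)
    out.close()
    return n


def positions_unchanged_after_roundtrip(
    original_vcf: str, roundtrip_vcf: str
) -> List[Tuple[str, Tuple[str, int], Tuple[str, int]]]:
    """Compare record positions before and after a there-and-back liftover.

    Records are matched by their ID field. Returns a list of
    ``(record_id, (chrom, pos) original, (chrom, pos) after round trip)`` for
    every record whose position changed; an empty list means the round-trip
    check passes. Raises on duplicate IDs (the key must be unique).
    """
    def positions(path) -> Dict[str, Tuple[str, int]]:
        seen: Dict[str, Tuple[str, int]] = {}
        for rec in _iter_vcf(path):
            key = rec.id
            if key is None:
                raise ValueError(f"record at {rec.chrom}:{rec.pos} has no ID to match on")
            if key in seen:
                raise ValueError(f"duplicate record ID {key!r}")
            seen[key] = (rec.chrom, rec.pos)
        return seen

    before = positions(original_vcf)
    after = positions(roundtrip_vcf)
    changed = []
    for key, pos in before.items():
        if key in after and after[key] != pos:
            changed.append((key, pos, after[key]))
    return changed
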