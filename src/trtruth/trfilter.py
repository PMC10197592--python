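"""Classify VCF insertion/deletion alleles as tandem-repeat expansions/contractions.

The filter decides, for every ins/del allele, whether it represents a TR
expansion or contraction, and if not assigns it exactly one rejection
category, so that the categories plus the passing alleles partition the input.

The decision procedure per allele:

1. strip the shared VCF anchor base to obtain the *variant sequence*;
2. find its smallest pure repeat unit (falling back to the whole sequence);
3. extend that motif into the reference immediately left and right of the
   insertion point (or outside the deleted interval; the deleted bases
   themselves contribute their copies to the reference count);
4. pass if the larger of the reference/alternate allele has >= 3 repeats
   spanning >= 9 bp with a 2-50 bp motif. Homopolymer and >50 bp-motif
   repeats are detected the same way but routed to their own categories;
5. if the pure decomposition fails the thresholds, retry allowing one motif
   position to vary across repeats (interrupted repeats, e.g. NGG);
6. if the variant sequence is whole copies of a motif plus a partial copy at
   one end, and the whole copies plus reference context would have met the
   thresholds, reject it as ending in a partial repeat;
7. otherwise reject by size (1-5 bp small indel / >= 6 bp non-TR).

Bi-allelic variants pass only when both alternate alleles pass with the same
motif, reference locus coordinates and interruption position. Variants whose
resulting reference loci overlap another variant's locus are discarded in a
final pass (both parties dropped, since the true genotype is then ambiguous).

Coordinates: VCF positions are 1-based; locus intervals are 0-based half-open.
Input is assumed VCF-normalized (left-aligned, anchor-base convention).
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .motif import (
    canonical_motif,
    extend_into_reference,
    interrupted_unit,
    is_valid_dna,
    scan_repeat_copies,
    smallest_pure_unit,
    RepeatDecomposition,
)
from .refseq import RefView, as_refview

__all__ = [
    "FilterConfig",
    "VariantAllele",
    "TandemRepeatCall",
    "RejectionCategory",
    "TruthLocus",
    "SiteClassification",
    "classify_allele",
    "classify_site",
    "minimal_representation",
    "classify_variant",
    "drop_overlapping_loci",
    "filter_vcf",
    "FilterResult",
]


class RejectionCategory(str, Enum):
    """Why an ins/del allele was excluded from the truth set."""

    SMALL_INDEL = "small_indel_1_5bp"
    NON_TR = "non_tr_ge_6bp"
    HOMOPOLYMER_AT = "homopolymer_AT"
    HOMOPOLYMER_CG = "homopolymer_CG"
    MOTIF_GT_50BP = "motif_gt_50bp"
    PARTIAL_REPEAT = "partial_repeat_end"
    MULTIALLELIC_ONE_PASSED = "multiallelic_one_allele_passed"
    MULTIALLELIC_INCONSISTENT = "multiallelic_inconsistent"
    OVERLAPPING_LOCUS = "overlapping_locus"
    OTHER = "other"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the TR filter.

    Defaults are the truth-set criteria: the larger allele must have at least
    ``min_repeats`` repeats spanning at least ``min_span_bp`` base pairs, with
    a motif of ``min_motif``..``max_motif`` bp. ``allow_interruptions``
    triggers the interrupted-repeat retry only when the pure decomposition
    fails, mirroring ``--allow-interruptions only-if-pure-repeats-not-found``.
    """

    min_span_bp: int = 9
    min_repeats: int = 3
    min_motif: int = 2
    max_motif: int = 50
    allow_interruptions: bool = True


@dataclass(frozen=True)
class VariantAllele:
    """One VCF alternate allele with its anchor position and genotype context."""

    chrom: str
    pos: int  # 1-based position of the shared anchor base
    ref: str
    alt: str
    gt: Optional[Tuple[int, ...]] = None

    @property
    def is_insertion(self) -> bool:
        return len(self.alt) > len(self.ref)

    @property
    def is_deletion(self) -> bool:
        return len(self.ref) > len(self.alt)

    @property
    def variant_seq(self) -> str:
        """Inserted or deleted bases after removing the anchor base."""
        longer = self.alt if self.is_insertion else self.ref
        return longer[1:].upper()


@dataclass(frozen=True)
class TandemRepeatCall:
    """The filter's verdict for one passing allele."""

    chrom: str
    locus_start: int  # 0-based half-open reference interval spanning all
    locus_end: int    # adjacent reference repeats
    motif: str
    canonical_motif: str
    is_pure: bool
    variable_position: Optional[int]
    ref_repeats: int
    allele_repeats: int  # total repeats on the alternate allele
    delta_repeats: int   # allele_repeats - ref_repeats
    variant_seq: str

    def __post_init__(self) -> None:
        assert self.allele_repeats == self.ref_repeats + self.delta_repeats
        assert self.locus_end - self.locus_start == self.ref_repeats * len(self.motif)


@dataclass(frozen=True)
class TruthLocus:
    """A validated truth-set record for one variant locus."""

    chrom: str
    locus_start: int
    locus_end: int
    motif: str
    canonical_motif: str
    is_pure: bool
    short_allele_repeats: int
    long_allele_repeats: int
    ref_repeats: int
    is_multiallelic: bool
    variable_position: Optional[int] = None

    def __post_init__(self) -> None:
        assert self.short_allele_repeats <= self.long_allele_repeats


def _extend(
    ref: RefView,
    chrom: Optional[str],
    boundary: int,
    motif: str,
    variable_position: Optional[int],
    direction: str,
) -> int:
    """Window-growing reference extension from a contig boundary offset."""
    m = len(motif)
    clen = ref.length(chrom)
    window = max(150, 8 * m)
    while True:
        if direction == "left":
            start = max(0, boundary - window)
            seq = ref.get(chrom, start, boundary)
            anchor = len(seq)
            hit_edge = start == 0
        else:
            end = min(clen, boundary + window)
            seq = ref.get(chrom, boundary, end)
            anchor = 0
            hit_edge = end == clen
        raw = scan_repeat_copies(seq, anchor, motif, variable_position, direction)
        # refetch a larger window if the scan consumed it entirely
        if len(raw) * m + m <= len(seq) or hit_edge:
            return extend_into_reference(seq, anchor, motif, variable_position, direction)
        window *= 2


def minimal_representation(pos: int, ref: str, alt: str) -> Tuple[int, str, str]:
    """Reduce one REF/ALT pair to its minimal anchored form.

    Multi-allelic records pad every ALT to a shared REF; trimming the common
    suffix, then the common prefix (keeping one anchor base and advancing
    ``pos``), recovers each allele's own ins/del representation. Already
    minimal pairs are returned unchanged. No left-alignment is attempted.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    return pos, ref, alt


def classify_allele(
    allele: VariantAllele,
    reference,
    config: Optional[FilterConfig] = None,
) -> Union[TandemRepeatCall, RejectionCategory]:
    """Classify a single ins/del allele against the reference.

    Returns a :class:`TandemRepeatCall` when the allele passes the TR filter,
    otherwise the :class:`RejectionCategory` it falls into.
    """
    cfg = config or FilterConfig()
    ref = as_refview(reference)
    ra, aa = allele.ref.upper(), allele.alt.upper()
    if not (is_valid_dna(ra) and is_valid_dna(aa)):
        return RejectionCategory.OTHER
    pos, ra, aa = minimal_representation(allele.pos, ra, aa)
    if len(ra) == len(aa) or min(len(ra), len(aa)) != 1 or ra[0] != aa[0]:
        return RejectionCategory.OTHER  # not an anchored simple ins/del
    is_ins = len(aa) > len(ra)
    vs = (aa if is_ins else ra)[1:]
    length = len(vs)
    # 0-based offsets flanking the event: the insertion point sits between
    # pos-1 and pos (0-based), a deletion removes [pos, pos+length)
    left_b = pos
    right_b = pos + (0 if is_ins else length)
    chrom = allele.chrom

    def build(dec: RepeatDecomposition) -> Optional[TandemRepeatCall]:
        m, varpos = dec.motif, dec.variable_position
        ml = len(m)
        left = _extend(ref, chrom, left_b, m, varpos, "left")
        right = _extend(ref, chrom, right_b, m, varpos, "right")
        if is_ins:
            ref_repeats = left + right
            delta = dec.count
        else:
            ref_repeats = left + dec.count + right
            delta = -dec.count
        allele_repeats = ref_repeats + delta
        biggest = max(ref_repeats, allele_repeats)
        if biggest < cfg.min_repeats or biggest * ml < cfg.min_span_bp:
            return None
        return TandemRepeatCall(
            chrom=chrom,
            locus_start=left_b - left * ml,
            locus_end=right_b + right * ml,
            motif=m,
            canonical_motif=canonical_motif(m) if ml <= 60 else "",
            is_pure=dec.is_pure,
            variable_position=varpos,
            ref_repeats=ref_repeats,
            allele_repeats=allele_repeats,
            delta_repeats=delta,
            variant_seq=vs,
        )

    def route(call: TandemRepeatCall) -> Union[TandemRepeatCall, RejectionCategory]:
        ml = len(call.motif)
        if ml == 1:
            if call.motif in ("A", "T"):
                return RejectionCategory.HOMOPOLYMER_AT
            return RejectionCategory.HOMOPOLYMER_CG
        if ml > cfg.max_motif:
            return RejectionCategory.MOTIF_GT_50BP
        if ml < cfg.min_motif:  # pragma: no cover - defaults make this unreachable
            return RejectionCategory.OTHER
        return call

    # pure path first: a variant that passes as a pure repeat is never
    # reported as interrupted
    pure_dec = smallest_pure_unit(vs)
    call = build(pure_dec)
    if call is not None:
        return route(call)

    if cfg.allow_interruptions:
        # shortest candidate motif length first; homopolymers use the
        # 9/10 + no-consecutive-interruption rule, dinucleotides the 4/5 rule
        for d in range(1, length):
            if length % d != 0 or d == len(pure_dec.motif):
                continue
            idec = interrupted_unit(vs, d)
            if idec is None or idec.is_pure:
                continue
            call = build(idec)
            if call is not None:
                return route(call)

    if _ends_in_partial_repeat(ref, chrom, vs, left_b, right_b, cfg):
        return RejectionCategory.PARTIAL_REPEAT
    if length <= 5:
        return RejectionCategory.SMALL_INDEL
    return RejectionCategory.NON_TR


def _ends_in_partial_repeat(
    ref: RefView,
    chrom: Optional[str],
    vs: str,
    left_b: int,
    right_b: int,
    cfg: FilterConfig,
) -> bool:
    """Variant sequence = whole motif copies + a partial copy at one end, where
    the whole copies plus reference extension would have met the thresholds."""
    length = len(vs)
    for d in range(1, min(cfg.max_motif, length - 1) + 1):
        whole, rem = divmod(length, d)
        if rem == 0 or whole < 1:
            continue
        for m in {vs[:d], vs[-d:]}:
            aligned_lead = vs == (m * (whole + 1))[:length]
            aligned_trail = vs == (m * (whole + 1))[-length:]
            if not (aligned_lead or aligned_trail):
                continue
            left = _extend(ref, chrom, left_b, m, None, "left")
            right = _extend(ref, chrom, right_b, m, None, "right")
            total = whole + left + right
            if total >= cfg.min_repeats and total * d >= cfg.min_span_bp:
                return True
    return False


@dataclass
class SiteClassification:
    """Outcome of classifying all called alternate alleles at one VCF site."""

    truth_locus: Optional[TruthLocus]
    allele_results: List[Union[TandemRepeatCall, RejectionCategory]]
    #: final per-allele rejection labels; all ``None`` when the variant passes
    allele_categories: List[Optional[RejectionCategory]]

    @property
    def passed(self) -> bool:
        return self.truth_locus is not None

    @property
    def category(self) -> Optional[RejectionCategory]:
        for c in self.allele_categories:
            if c is not None:
                return c
        return None


def _is_hom_alt(gt: Optional[Tuple[int, ...]]) -> bool:
    return gt is not None and len(gt) >= 2 and len(set(gt)) == 1 and gt[0] not in (0, None)


def classify_site(
    alleles: Sequence[VariantAllele],
    reference,
    config: Optional[FilterConfig] = None,
) -> SiteClassification:
    """Classify the 1-2 called ins/del alleles at one site into a truth locus
    or per-allele rejection categories."""
    if not 1 <= len(alleles) <= 2:
        cats = [RejectionCategory.OTHER] * len(alleles)
        return SiteClassification(None, list(cats), list(cats))
    results = [classify_allele(a, reference, config) for a in alleles]

    if len(alleles) == 1:
        r = results[0]
        if isinstance(r, TandemRepeatCall):
            if _is_hom_alt(alleles[0].gt):
                short = long_ = r.allele_repeats
            else:
                short, long_ = sorted((r.ref_repeats, r.allele_repeats))
            locus = TruthLocus(
                chrom=r.chrom,
                locus_start=r.locus_start,
                locus_end=r.locus_end,
                motif=r.motif,
                canonical_motif=r.canonical_motif,
                is_pure=r.is_pure,
                short_allele_repeats=short,
                long_allele_repeats=long_,
                ref_repeats=r.ref_repeats,
                is_multiallelic=False,
                variable_position=r.variable_position,
            )
            return SiteClassification(locus, results, [None])
        return SiteClassification(None, results, [r])

    r1, r2 = results
    p1 = isinstance(r1, TandemRepeatCall)
    p2 = isinstance(r2, TandemRepeatCall)
    if p1 and p2:
        key = lambda r: (r.motif, r.locus_start, r.locus_end, r.variable_position)
        if key(r1) == key(r2):
            short, long_ = sorted((r1.allele_repeats, r2.allele_repeats))
            locus = TruthLocus(
                chrom=r1.chrom,
                locus_start=r1.locus_start,
                locus_end=r1.locus_end,
                motif=r1.motif,
                canonical_motif=r1.canonical_motif,
                is_pure=r1.is_pure and r2.is_pure,
                short_allele_repeats=short,
                long_allele_repeats=long_,
                ref_repeats=r1.ref_repeats,
                is_multiallelic=short != long_,
                variable_position=r1.variable_position,
            )
            return SiteClassification(locus, results, [None, None])
        cat = RejectionCategory.MULTIALLELIC_INCONSISTENT
        return SiteClassification(None, results, [cat, cat])
    if p1 != p2:
        cat = RejectionCategory.MULTIALLELIC_ONE_PASSED
        return SiteClassification(None, results, [cat, cat])
    return SiteClassification(None, results, [r1, r2])


def classify_variant(
    alleles: Sequence[VariantAllele],
    reference,
    config: Optional[FilterConfig] = None,
) -> Union[TruthLocus, RejectionCategory]:
    """Variant-level verdict: the truth locus, or the (first) rejection label."""
    site = classify_site(alleles, reference, config)
    if site.truth_locus is not None:
        return site.truth_locus
    assert site.category is not None
    return site.category


def drop_overlapping_loci(
    loci: Sequence[TruthLocus],
) -> Tuple[List[TruthLocus], List[TruthLocus]]:
    """Drop every locus whose reference interval overlaps another's.

    When two variants imply overlapping reference TR loci it is unclear which
    one represents the true genotype, so *both* are discarded. Intervals are
    half-open; sharing a single base counts as overlap, abutting does not.
    """
    order = sorted(range(len(loci)), key=lambda i: (loci[i].chrom, loci[i].locus_start, loci[i].locus_end))
    overlapped = [False] * len(loci)
    active: List[Tuple[int, int]] = []  # (end, index) heap per chrom
    current_chrom: Optional[str] = None
    for i in order:
        locus = loci[i]
        if locus.chrom != current_chrom:
            active.clear()
            current_chrom = locus.chrom
        while active and active[0][0] <= locus.locus_start:
            heapq.heappop(active)
        if active:
            overlapped[i] = True
            for _, j in active:
                overlapped[j] = True
        heapq.heappush(active, (locus.locus_end, i))
    kept = [l for i, l in enumerate(loci) if not overlapped[i]]
    dropped = [l for i, l in enumerate(loci) if overlapped[i]]
    return kept, dropped


# ---------------------------------------------------------------------------
# whole-VCF driver


@dataclass
class FilterResult:
    truth_loci: List[TruthLocus]
    truth_df: pd.DataFrame
    summary: Dict
    rejected: List[Tuple[str, int, str, str, RejectionCategory]]  # chrom,pos,ref,alt,category
    output_paths: Dict[str, str] = field(default_factory=dict)


_TRUTH_COLUMNS = [
    "chrom",
    "locus_start",
    "locus_end",
    "motif",
    "canonical_motif",
    "is_pure",
    "ref_repeats",
    "short_allele_repeats",
    "long_allele_repeats",
    "is_multiallelic",
]


def _load_bed_trees(bed_path):
    from intervaltree import IntervalTree

    trees: Dict[str, "IntervalTree"] = {}
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def _contained(trees, chrom: str, start: int, end: int) -> bool:
    tree = trees.get(chrom)
    if tree is None:
        return False
    return any(iv.begin <= start and iv.end >= end for iv in tree.overlap(start, end))


def filter_vcf(
    vcf_path: str,
    reference,
    high_confidence_bed: Optional[str] = None,
    config: Optional[FilterConfig] = None,
    out_prefix: Optional[str] = None,
) -> FilterResult:
    """Run the TR filter over a whole VCF.

    ``reference`` may be an indexed FASTA path, a :class:`pysam.FastaFile`, or
    an in-memory dict of contig sequences. When ``high_confidence_bed`` is
    given only records whose reference footprint is fully contained in a BED
    interval are considered (bedtools ``intersect -f 1`` semantics). When
    ``out_prefix`` is given, writes ``<prefix>.truth.tsv``, ``<prefix>.loci.bed``,
    ``<prefix>.rejected.vcf`` and ``<prefix>.summary.json``.

    Every input ins/del allele lands in exactly one bucket: passing, or one
    rejection category.
    """
    import pysam

    cfg = config or FilterConfig()
    if isinstance(reference, (str, Path)):
        reference = pysam.FastaFile(str(reference))
    ref = as_refview(reference)
    trees = _load_bed_trees(high_confidence_bed) if high_confidence_bed else None

    vcf = pysam.VariantFile(str(vcf_path))
    category_counts: Dict[str, int] = {c.value: 0 for c in RejectionCategory}
    n_pass_alleles = 0
    n_snv_alleles = 0
    n_indel_alleles = 0
    loci: List[TruthLocus] = []
    loci_sites: List[List[VariantAllele]] = []
    rejected: List[Tuple[str, int, str, str, RejectionCategory]] = []

    for rec in vcf:
        if rec.chrom not in ref.contigs():
            raise ValueError(
                f"contig {rec.chrom!r} in VCF is absent from the reference"
            )
        if trees is not None and not _contained(
            trees, rec.chrom, rec.start, rec.start + len(rec.ref)
        ):
            continue
        gt: Optional[Tuple[int, ...]] = None
        if rec.samples:
            sample = rec.samples[0]
            if "GT" in sample and sample["GT"] is not None:
                gt = tuple(a for a in sample["GT"] if a is not None)
                if not gt:
                    gt = None
        alts = rec.alts or ()
        called_idx = sorted({a for a in (gt or range(1, len(alts) + 1)) if a >= 1})
        indel_alleles: List[VariantAllele] = []
        for idx in called_idx:
            if idx > len(alts):
                continue
            alt = alts[idx - 1]
            if alt is None or alt.startswith("<") or len(alt) == len(rec.ref):
                n_snv_alleles += 1
                continue
            indel_alleles.append(
                VariantAllele(rec.chrom, rec.pos, rec.ref, alt, gt=gt)
            )
        if not indel_alleles:
            continue
        n_indel_alleles += len(indel_alleles)
        site = classify_site(indel_alleles, ref, cfg)
        if site.passed:
            n_pass_alleles += len(indel_alleles)
            loci.append(site.truth_locus)
            loci_sites.append(indel_alleles)
        else:
            for allele, cat in zip(indel_alleles, site.allele_categories):
                assert cat is not None
                category_counts[cat.value] += 1
                rejected.append((allele.chrom, allele.pos, allele.ref, allele.alt, cat))

    kept, dropped = drop_overlapping_loci(loci)
    dropped_set = {id(l) for l in dropped}
    for locus, site_alleles in zip(loci, loci_sites):
        if id(locus) in dropped_set:
            n_pass_alleles -= len(site_alleles)
            cat = RejectionCategory.OVERLAPPING_LOCUS
            for allele in site_alleles:
                category_counts[cat.value] += 1
                rejected.append((allele.chrom, allele.pos, allele.ref, allele.alt, cat))

    kept_sorted = sorted(kept, key=lambda l: (l.chrom, l.locus_start))
    truth_df = pd.DataFrame(
        [{k: getattr(l, k) for k in _TRUTH_COLUMNS} for l in kept_sorted],
        columns=_TRUTH_COLUMNS,
    )
    summary = {
        "total_ins_del_alleles": n_indel_alleles,
        "passing_alleles": n_pass_alleles,
        "passing_loci": len(kept_sorted),
        "snv_or_other_alleles": n_snv_alleles,
        "rejection_categories": {k: v for k, v in category_counts.items() if v},
    }
    # partition check: every ins/del allele is accounted exactly once
    assert n_pass_alleles + sum(category_counts.values()) == n_indel_alleles

    result = FilterResult(kept_sorted, truth_df, summary, rejected)
    if out_prefix:
        result.output_paths = _write_outputs(out_prefix, truth_df, kept_sorted, rejected, summary)
    return result


def _write_outputs(prefix, truth_df, loci, rejected, summary) -> Dict[str, str]:
    prefix = str(prefix)
    paths = {
        "truth_tsv": prefix + ".truth.tsv",
        "loci_bed": prefix + ".loci.bed",
        "rejected_vcf": prefix + ".rejected.vcf",
        "summary_json": prefix + ".summary.json",
    }
    truth_df.to_csv(paths["truth_tsv"], sep="\t", index=False)
    with open(paths["loci_bed"], "w") as fh:
        for l in loci:
            delta = l.long_allele_repeats - l.ref_repeats
            fh.write(
                f"{l.chrom}\t{l.locus_start}\t{l.locus_end}\t{l.motif}\t{delta}\t.\n"
            )
    with open(paths["rejected_vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=TR_CATEGORY,Number=1,Type=String,'
            'Description="Reason the ins/del allele failed the TR filter">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref_a, alt_a, cat in sorted(rejected, key=lambda r: (r[0], r[1])):
            fh.write(f"{chrom}\t{pos}\t.\t{ref_a}\t{alt_a}\t.\t.\tTR_CATEGORY={cat.value}\n")
    with open(paths["summary_json"], "w") as fh:
        json.dump(summary, fh, indent=2)
    return paths
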