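"""Per-allele concordance of TR genotyping tools with the truth set.

A tool genotype at a TR locus is a pair of allele-size estimates (in repeat
units) with optional confidence intervals and read-support counts. Estimated
alleles are paired with truth alleles strictly short-with-short and
long-with-long — never by best-matching permutation — and each pairing gets
a *strict accuracy* flag (exact equality) plus a detailed error category:

* ``exact`` — estimate equals truth;
* ``overestimate`` / ``underestimate`` — signed error, same side of the
  reference as the truth (or truth at reference);
* ``wrong_direction`` — the tool called a contraction where the truth is an
  expansion or vice versa (both strictly non-reference, opposite signs);
* ``called_het_ref`` / ``called_hom_ref`` — the estimate sits at the
  reference size while the truth does not (one vs both alleles);
* ``no_call`` — the tool produced no estimate.

Two per-allele quality scores are defined for confidence-interval-reporting
tools: ``Q_CI = exp(-4 * ci_size / allele_size)``, and a read-fraction score
(supporting reads / total reads, with in-repeat reads supporting any allele
above 80% of the read length, rescaled so that any fraction above 0.15 maps
to 1). ``threshold_sweep`` traces accuracy and false-negative rate across
minimum-Q thresholds.

``match_ehdn`` scores ExpansionHunterDenovo-style profile intervals against
truth expansions (same canonical motif within a 600 bp window), and
``multiallelic_fraction`` computes the fraction of alleles at multi-allelic
loci — a relative mutation-rate proxy — across user-chosen bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .motif import canonical_motif

__all__ = [
    "ToolGenotype",
    "AlleleConcordance",
    "EhdnInterval",
    "allele_concordance",
    "q_from_ci",
    "q_from_reads",
    "threshold_sweep",
    "match_ehdn",
    "multiallelic_fraction",
]

CATEGORIES = (
    "exact",
    "overestimate",
    "underestimate",
    "wrong_direction",
    "called_het_ref",
    "called_hom_ref",
    "no_call",
)


@dataclass(frozen=True)
class ToolGenotype:
    """One tool's call at a locus, in repeat units.

    ``read_support`` maps a read class (``spanning``/``flanking``/``inrepeat``)
    to a list of ``(allele_size, read_count)`` pairs.
    """

    locus_id: str
    short_est: Optional[int]
    long_est: Optional[int]
    ci_short: Optional[Tuple[int, int]] = None
    ci_long: Optional[Tuple[int, int]] = None
    read_support: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)
    q: Optional[float] = None

    def __post_init__(self) -> None:
        if self.short_est is not None and self.long_est is not None:
            assert self.short_est <= self.long_est


@dataclass(frozen=True)
class AlleleConcordance:
    """Comparison of one estimated allele with its truth counterpart."""

    which: str  # "short" | "long"
    true_size: int
    est_size: Optional[int]
    category: str
    delta: Optional[int]  # est - true, None for no-call


def _categorize(
    true_size: int, est: Optional[int], other_est: Optional[int], ref_repeats: int
) -> Tuple[str, Optional[int]]:
    if est is None:
        return "no_call", None
    delta = est - true_size
    if delta == 0:
        return "exact", 0
    if est == ref_repeats and true_size != ref_repeats:
        if other_est == ref_repeats:
            return "called_hom_ref", delta
        return "called_het_ref", delta
    est_dir = est - ref_repeats
    true_dir = true_size - ref_repeats
    if est_dir != 0 and true_dir != 0 and (est_dir > 0) != (true_dir > 0):
        return "wrong_direction", delta
    return ("overestimate" if delta > 0 else "underestimate"), delta


def allele_concordance(
    truth,
    call: ToolGenotype,
    ref_repeats: Optional[int] = None,
) -> Tuple[AlleleConcordance, AlleleConcordance]:
    """Pair truth and estimated alleles short-with-short / long-with-long.

    ``truth`` is any object with ``short_allele_repeats``,
    ``long_allele_repeats`` and (when ``ref_repeats`` is not given)
    ``ref_repeats`` attributes, e.g. a :class:`~trtruth.trfilter.TruthLocus`.
    """
    ref = ref_repeats if ref_repeats is not None else truth.ref_repeats
    pairs = (
        ("short", truth.short_allele_repeats, call.short_est, call.long_est),
        ("long", truth.long_allele_repeats, call.long_est, call.short_est),
    )
    out = []
    for which, true_size, est, other in pairs:
        category, delta = _categorize(true_size, est, other, ref)
        out.append(AlleleConcordance(which, true_size, est, category, delta))
    return out[0], out[1]


def q_from_ci(ci_size: float, allele_size: float) -> Optional[float]:
    """Confidence-interval quality score ``exp(-4 * ci_size / allele_size)``.

    Both arguments must share a unit (repeat units or bp — the ratio is
    unit-invariant). ``ci_size == 0`` gives 1.0; ``ci_size == allele_size``
    gives ``e**-4``. Undefined (``None``) for a zero-size allele.
    """
    if allele_size == 0:
        return None
    if ci_size < 0:
        raise ValueError("confidence-interval size must be >= 0")
    return math.exp(-4.0 * ci_size / allele_size)


def q_from_reads(
    read_support: Dict[str, List[Tuple[int, int]]],
    allele_est: int,
    motif_len: int,
    read_length: int = 150,
) -> float:
    """Read-fraction quality score for one estimated allele.

    Supporting reads are those whose paired allele size equals the estimate;
    in-repeat reads additionally support *any* allele whose size in bp
    exceeds 80% of the read length (in-repeat read sizes plateau near the
    read length). The raw fraction supporting/total is rescaled for
    empirical performance: values above 0.15 map to 1, smaller values are
    divided by 0.15. Zero total reads gives 0.
    """
    total = 0
    supporting = 0
    allele_bp = allele_est * motif_len
    inrepeat_supports_all = allele_bp > 0.8 * read_length
    for read_class, pairs in read_support.items():
        for size, count in pairs:
            total += count
            if size == allele_est:
                supporting += count
            elif read_class == "inrepeat" and inrepeat_supports_all:
                supporting += count
    if total == 0:
        return 0.0
    raw = supporting / total
    return 1.0 if raw > 0.15 else raw / 0.15


def threshold_sweep(
    records: Sequence[Tuple[bool, Optional[float]]],
    thresholds: Sequence[float],
    exclude_no_call: bool = False,
) -> pd.DataFrame:
    """Accuracy / false-negative-rate trade-off across minimum-Q thresholds.

    ``records`` holds one ``(is_exact, q)`` pair per allele; ``q is None``
    marks a no-call (it never passes any threshold). At threshold ``t`` an
    allele counts as a true positive when it is strictly accurate and its
    score passes (``q >= t``), and as a true negative when it is inaccurate
    and filtered out (``q < t``); accuracy is (TP + TN) / total. The
    false-negative rate is the fraction of strictly accurate alleles that a
    threshold filters away. With ``exclude_no_call`` the no-call records are
    dropped before computing either statistic.
    """
    recs = [(bool(e), q) for e, q in records]
    if exclude_no_call:
        recs = [(e, q) for e, q in recs if q is not None]
    total = len(recs)
    n_exact = sum(e for e, _ in recs)
    rows = []
    for t in thresholds:
        tp = sum(1 for e, q in recs if e and q is not None and q >= t)
        tn = sum(1 for e, q in recs if not e and (q is None or q < t))
        fn = sum(1 for e, q in recs if e and (q is None or q < t))
        rows.append(
            {
                "threshold": t,
                "accuracy": (tp + tn) / total if total else float("nan"),
                "false_negative_rate": fn / n_exact if n_exact else 0.0,
                "n": total,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EhdnInterval:
    """One genomic interval from an EHdn-style profile output."""

    chrom: str
    start: int
    end: int
    motif: str
    anchored_read_count: int = 0

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


def match_ehdn(
    intervals: Sequence[EhdnInterval],
    truth_expansions: Sequence,
    window_bp: int = 600,
    anchor: str = "midpoint",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Match profile intervals against truth expansions.

    A truth expansion is *detected* when some interval on the same chromosome
    shares its canonical motif and lies within ``window_bp``; an interval
    with no matching truth expansion is a false positive. ``truth_expansions``
    items need ``chrom``, ``canonical_motif``, interval coordinates and a
    ``long_allele_bp`` attribute (total size of the longer allele in bp).
    Distance is measured between midpoints by default, or between nearest
    edges with ``anchor='edges'``.

    Returns ``(truth_df, interval_df)``: per-truth rows with a ``detected``
    flag and ``long_allele_bp`` (for binning sensitivity by allele size), and
    per-interval rows with a ``matched`` flag and ``motif_size`` (for binning
    specificity by motif size).
    """

    def distance(a_lo, a_hi, b_lo, b_hi) -> float:
        if anchor == "midpoint":
            return abs((a_lo + a_hi) / 2 - (b_lo + b_hi) / 2)
        if a_hi < b_lo:
            return b_lo - a_hi
        if b_hi < a_lo:
            return a_lo - b_hi
        return 0.0

    canon_i = [canonical_motif(iv.motif) for iv in intervals]
    detected = []
    for t in truth_expansions:
        t_lo = t.locus_start if hasattr(t, "locus_start") else t.start
        t_hi = t.locus_end if hasattr(t, "locus_end") else t.end
        hit = any(
            iv.chrom == t.chrom
            and cm == t.canonical_motif
            and distance(iv.start, iv.end, t_lo, t_hi) <= window_bp
            for iv, cm in zip(intervals, canon_i)
        )
        detected.append(hit)
    matched = []
    for iv, cm in zip(intervals, canon_i):
        hit = any(
            iv.chrom == t.chrom
            and cm == t.canonical_motif
            and distance(
                iv.start,
                iv.end,
                t.locus_start if hasattr(t, "locus_start") else t.start,
                t.locus_end if hasattr(t, "locus_end") else t.end,
            )
            <= window_bp
            for t in truth_expansions
        )
        matched.append(hit)
    truth_df = pd.DataFrame(
        {
            "chrom": [t.chrom for t in truth_expansions],
            "canonical_motif": [t.canonical_motif for t in truth_expansions],
            "long_allele_bp": [getattr(t, "long_allele_bp", np.nan) for t in truth_expansions],
            "detected": detected,
        }
    )
    interval_df = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "motif": [iv.motif for iv in intervals],
            "motif_size": [len(iv.motif) for iv in intervals],
            "matched": matched,
        }
    )
    return truth_df, interval_df


def multiallelic_fraction(
    alleles: pd.DataFrame,
    by: str,
    bins: Optional[Sequence[float]] = None,
    min_bin_size: int = 20,
    max_interruption: float = 0.25,
) -> pd.DataFrame:
    """Fraction of alleles occurring at multi-allelic loci, per bin.

    ``alleles`` needs columns ``is_multiallelic`` plus the binning column:
    ``allele_size_bp``, ``motif_size`` or ``interruption_fraction``. In the
    size/motif modes, interrupted alleles with more than ``max_interruption``
    of their repeats differing from the common motif are excluded (the
    single-position interruption notion; fraction 0 means pure). Bins holding
    fewer than ``min_bin_size`` alleles are omitted — the fraction estimate is
    a mutation-rate proxy and unstable in small bins.
    """
    valid_modes = ("allele_size_bp", "motif_size", "interruption_fraction")
    if by not in valid_modes:
        raise ValueError(f"by must be one of {valid_modes}")
    df = alleles.copy()
    if by != "interruption_fraction" and "interruption_fraction" in df.columns:
        df = df[df["interruption_fraction"].fillna(0.0) <= max_interruption]
    if bins is not None:
        df = df.assign(_bin=pd.cut(df[by], bins=list(bins)))
    else:
        df = df.assign(_bin=df[by])
    grouped = df.groupby("_bin", observed=True)["is_multiallelic"].agg(["mean", "count"])
    grouped = grouped[grouped["count"] >= min_bin_size]
    return (
        grouped.rename(columns={"mean": "multiallelic_fraction", "count": "n_alleles"})
        .reset_index()
        .rename(columns={"_bin": by})
    )
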