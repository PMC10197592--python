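"""Repeat-motif string algorithmics.

Everything downstream of the tandem-repeat filter rests on a handful of exact
string operations defined here:

* motif canonicalization — the representative of a motif under cyclic rotation
  and reverse complement (``CAT``, ``GAT`` and ``TGA`` all normalize to ``ATC``);
* pure decomposition — the smallest-period factorization of a variant sequence
  into identical repeat units;
* interrupted decomposition — factorization into repeat units that agree at
  every motif position except one shared "variable" position (e.g. an NGG
  pattern), with stricter purity rules for dinucleotides (at least 4/5 of the
  units must equal the most common unit) and homopolymers (at least 9/10
  matching bases and no two consecutive interruptions);
* reference extension — counting whole adjacent motif copies in flanking
  reference sequence, never counting a partial trailing copy.

All sequences are uppercase strings over {A, C, G, T}; anything else raises
:class:`MotifError`. Coordinates are 0-based offsets into plain strings.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import List, Optional

__all__ = [
    "MotifError",
    "RepeatDecomposition",
    "canonical_motif",
    "smallest_pure_unit",
    "interrupted_unit",
    "extend_into_reference",
    "scan_repeat_copies",
    "interruption_fraction",
    "reverse_complement",
    "validate_motif",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID_BASES = frozenset("ACGT")

#: default upper bound on motif length handled by the canonicalizer / types;
#: the truth-set filter itself passes only 2-50 bp motifs but longer units
#: still need to be *categorized*.
MAX_MOTIF_LEN = 60

# fraction of dinucleotide units that must exactly equal the common motif
DINUCLEOTIDE_PURITY = 4 / 5
# fraction of bases in an interrupted homopolymer that must equal the common base
HOMOPOLYMER_PURITY = 9 / 10


class MotifError(ValueError):
    """Raised for sequences that are not plain uppercase A/C/G/T DNA."""


def validate_motif(seq: str, max_len: Optional[int] = MAX_MOTIF_LEN) -> str:
    """Uppercase and validate a motif/sequence; return the normalized string.

    Raises :class:`MotifError` on empty input, characters outside {A,C,G,T}
    (ambiguity codes such as N disqualify a sequence), or length above
    ``max_len`` when a bound is given.
    """
    if not seq:
        raise MotifError("empty sequence")
    seq = seq.upper()
    if not _VALID_BASES.issuperset(seq):
        bad = sorted(set(seq) - _VALID_BASES)
        raise MotifError(f"non-ACGT characters in sequence: {bad}")
    if max_len is not None and len(seq) > max_len:
        raise MotifError(f"motif longer than {max_len} bp")
    return seq


def is_valid_dna(seq: str) -> bool:
    """True if ``seq`` is non-empty uppercase-able A/C/G/T."""
    return bool(seq) and _VALID_BASES.issuperset(seq.upper())


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RepeatDecomposition:
    """Factorization of a sequence into tandem copies of one motif.

    ``motif`` is the repeat unit used downstream (for interrupted repeats this
    is the most common concrete unit, e.g. ``CGG`` for an NGG pattern);
    ``common_motif`` is kept as an explicit alias of the same unit.
    ``variable_position`` is the single 0-based motif position at which units
    may differ, set only for interrupted decompositions.
    """

    motif: str
    count: int
    is_pure: bool
    variable_position: Optional[int] = None
    common_motif: str = ""

    def __post_init__(self) -> None:
        if not self.common_motif:
            object.__setattr__(self, "common_motif", self.motif)
        if self.is_pure and self.variable_position is not None:
            raise ValueError("pure decomposition cannot carry a variable position")

    @property
    def span(self) -> int:
        return self.count * len(self.motif)


def canonical_motif(motif: str) -> str:
    """Canonical form of a motif: the lexicographically smallest string among
    all cyclic rotations of the motif and of its reverse complement.

    Idempotent, and invariant under rotating or reverse-complementing the
    argument. E.g. ``CAT``/``GAT``/``TGA`` -> ``ATC``; ``AC``/``CA``/``GT``/
    ``TG`` -> ``AC``.
    """
    motif = validate_motif(motif)
    rc = reverse_complement(motif)
    n = len(motif)
    doubled, rc_doubled = motif * 2, rc * 2
    candidates = [doubled[i : i + n] for i in range(n)]
    candidates += [rc_doubled[i : i + n] for i in range(n)]
    return min(candidates)


def smallest_pure_unit(seq: str) -> RepeatDecomposition:
    """Smallest-period pure decomposition of ``seq``.

    Returns the shortest motif ``m`` such that ``seq == m * k`` with ``k >= 2``;
    when no smaller period exists the motif is the whole sequence with count 1
    (so the caller can still treat the entire variant sequence as one unit).
    """
    seq = validate_motif(seq, max_len=None)
    n = len(seq)
    for d in range(1, n // 2 + 1):
        if n % d == 0 and seq == seq[:d] * (n // d):
            return RepeatDecomposition(seq[:d], n // d, is_pure=True)
    return RepeatDecomposition(seq, 1, is_pure=True)


def _most_common_unit(units: List[str]) -> str:
    """Most frequent unit; ties broken by first occurrence left-to-right."""
    counts = Counter(units)
    best = max(counts.values())
    for u in units:
        if counts[u] == best:
            return u
    raise AssertionError("unreachable")


def interrupted_unit(seq: str, motif_len: int) -> Optional[RepeatDecomposition]:
    """Decompose ``seq`` into ``motif_len``-bp units allowing one variable position.

    General rule (motif_len >= 3): split into whole units; succeed if the units
    agree at every position except at most one shared position. The motif is
    the most common unit.

    Dinucleotides additionally require at least 4/5 of units to exactly equal
    the most common unit. Homopolymers require at least 9/10 of bases to equal
    the common base and forbid two consecutive interrupting bases.

    Returns ``None`` when ``motif_len`` does not divide ``len(seq)`` or the
    interruption pattern is not of the single-position kind. A decomposition
    with zero interruptions is returned as pure.
    """
    seq = validate_motif(seq, max_len=None)
    if motif_len < 1 or len(seq) % motif_len != 0:
        return None
    n_units = len(seq) // motif_len

    if motif_len == 1:
        common = _most_common_unit(list(seq))
        mismatch_idx = [i for i, b in enumerate(seq) if b != common]
        if not mismatch_idx:
            return RepeatDecomposition(common, n_units, is_pure=True)
        if (len(seq) - len(mismatch_idx)) / len(seq) < HOMOPOLYMER_PURITY:
            return None
        if any(j - i == 1 for i, j in zip(mismatch_idx, mismatch_idx[1:])):
            return None  # interruptions spanning >= 2 bases in a row
        return RepeatDecomposition(
            common, n_units, is_pure=False, variable_position=0, common_motif=common
        )

    units = [seq[i : i + motif_len] for i in range(0, len(seq), motif_len)]
    varying = [
        p for p in range(motif_len) if len({u[p] for u in units}) > 1
    ]
    if len(varying) > 1:
        return None
    common = _most_common_unit(units)
    if not varying:
        return RepeatDecomposition(common, n_units, is_pure=True)
    if motif_len == 2:
        exact = sum(u == common for u in units)
        if exact / n_units < DINUCLEOTIDE_PURITY:
            return None
    return RepeatDecomposition(
        common, n_units, is_pure=False, variable_position=varying[0], common_motif=common
    )


def _unit_matches(unit: str, motif: str, variable_position: Optional[int]) -> bool:
    if unit == motif:
        return True
    if variable_position is None or len(motif) < 3:
        # homopolymer/dinucleotide extension uses pure copies only
        return False
    return all(
        a == b for p, (a, b) in enumerate(zip(unit, motif)) if p != variable_position
    )


def scan_repeat_copies(
    ref_seq: str,
    anchor: int,
    motif: str,
    variable_position: Optional[int] = None,
    direction: str = "right",
) -> List[str]:
    """Maximal run of whole motif copies adjacent to ``anchor``, nearest first.

    ``anchor`` is a 0-based offset: for ``direction='right'`` copies are read
    starting at ``anchor``; for ``'left'`` they end at ``anchor``. Copies match
    exactly, or — in interrupted mode for motifs >= 3 bp — at every position
    except ``variable_position``. Scanning stops at the first non-matching or
    partial copy.
    """
    if not 0 <= anchor <= len(ref_seq):
        raise ValueError("anchor outside reference sequence")
    m = len(motif)
    copies: List[str] = []
    if direction == "right":
        i = anchor
        while i + m <= len(ref_seq):
            unit = ref_seq[i : i + m]
            if not _unit_matches(unit, motif, variable_position):
                break
            copies.append(unit)
            i += m
    elif direction == "left":
        i = anchor
        while i - m >= 0:
            unit = ref_seq[i - m : i]
            if not _unit_matches(unit, motif, variable_position):
                break
            copies.append(unit)
            i -= m
    else:
        raise ValueError(f"direction must be 'left' or 'right', got {direction!r}")
    return copies


def extend_into_reference(
    ref_seq: str,
    anchor: int,
    motif: str,
    variable_position: Optional[int] = None,
    direction: str = "right",
) -> int:
    """Count whole motif copies adjacent to ``anchor`` in one direction.

    In interrupted mode (``variable_position`` set, motif >= 3 bp) the first
    and last counted copy must exactly equal the common motif: far-end inexact
    copies are trimmed, and if the copy nearest the anchor is inexact nothing
    in that direction can be counted (copies must stay contiguous with the
    anchor). Homopolymer and dinucleotide motifs are extended over exact
    copies only and stop at any interruption.
    """
    copies = scan_repeat_copies(ref_seq, anchor, motif, variable_position, direction)
    if variable_position is None or len(motif) < 3:
        return len(copies)
    while copies and copies[-1] != motif:
        copies.pop()
    if copies and copies[0] != motif:
        return 0
    return len(copies)


def interruption_fraction(allele_seq: str, motif_len: int) -> Optional[float]:
    """Fraction of repeat units in ``allele_seq`` differing from the common motif.

    Defined only when ``motif_len`` divides the sequence length and units
    differ from each other at no more than one shared motif position (the
    single-position notion of interruption); otherwise ``None``. A pure repeat
    has fraction 0.0; ``CAGCAGCATCAG`` with motif length 3 gives 0.25.
    """
    allele_seq = validate_motif(allele_seq, max_len=None)
    if motif_len < 1 or len(allele_seq) % motif_len != 0:
        return None
    units = [allele_seq[i : i + motif_len] for i in range(0, len(allele_seq), motif_len)]
    varying = [p for p in range(motif_len) if len({u[p] for u in units}) > 1]
    if len(varying) > 1:
        return None
    common = _most_common_unit(units)
    return sum(u != common for u in units) / len(units)
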