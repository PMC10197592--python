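"""Seeded synthetic fixtures: toy references with planted TR tracts, VCFs of
expansions/contractions plus decoys, and simulated tool-call tables.

Every generator consumes a single :class:`numpy.random.Generator` stream per
seed in a fixed order, so outputs are byte-reproducible across platforms.
Spacer sequence between planted tracts is rejection-sampled until it contains
no repeat run that could be confused with a planted tract (the screen uses
the package's own pure-repeat scanner), and decoy indels are re-rolled until
the classifier assigns them their intended rejection category against the
actual assembled reference — the planted ground truth is therefore exact, not
merely probable.

These fixtures emulate the *shape* of a real benchmark input (an indel VCF
restricted to high-confidence regions, against a reference with TR tracts);
they do not simulate reads, sequencing error, or alignment artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .catalog import scan_pure_repeats
from .motif import canonical_motif, smallest_pure_unit
from .trfilter import (
    FilterConfig,
    RejectionCategory,
    VariantAllele,
    classify_allele,
)

__all__ = [
    "PlantSpec",
    "PlantedLocus",
    "SyntheticReference",
    "SyntheticVcf",
    "ErrorModel",
    "generate_reference",
    "generate_vcf",
    "generate_tool_calls",
    "generate_ehdn_intervals",
    "tool_calls_to_genotypes",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantSpec:
    """One TR tract to plant: reference copies plus 1-2 allele deltas.

    ``allele_deltas`` are signed whole-motif-copy changes (one per alternate
    allele); ``interruption=(variable_position, fraction)`` makes that
    fraction of the *inserted* repeat units differ from the motif at the
    given position. ``flank_len`` is the screened random spacer placed before
    the tract.
    """

    motif: str
    ref_repeat_count: int
    allele_deltas: Tuple[int, ...] = (1,)
    interruption: Optional[Tuple[int, float]] = None
    flank_len: int = 80

    def __post_init__(self) -> None:
        assert 1 <= len(self.allele_deltas) <= 2
        assert all(d != 0 for d in self.allele_deltas)
        max_del = max((-d for d in self.allele_deltas if d < 0), default=0)
        assert max_del <= self.ref_repeat_count, "cannot delete more copies than planted"
        if self.interruption is not None:
            assert all(d >= 3 for d in self.allele_deltas), (
                "interrupted specs must be expansions of >= 3 copies so the "
                "inserted units can keep exact first/last copies"
            )


@dataclass(frozen=True)
class PlantedLocus:
    spec: PlantSpec
    chrom: str
    tract_start: int  # 0-based half-open tract interval in the reference
    tract_end: int


@dataclass
class SyntheticReference:
    sequences: Dict[str, str]
    planted: List[PlantedLocus]

    def write_fasta(self, path: Union[str, Path], line_width: int = 70) -> str:
        path = str(path)
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")
        try:
            import pysam

            pysam.faidx(path)
        except Exception:  # pragma: no cover - index is a convenience
            pass
        return path

    def truth_bed(self) -> List[Tuple[str, int, int, str]]:
        return [
            (p.chrom, p.tract_start, p.tract_end, p.spec.motif) for p in self.planted
        ]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _clean_spacer(
    rng: np.random.Generator,
    n: int,
    prev_motif: str,
    next_motif: str,
    max_tries: int = 400,
) -> str:
    """Random sequence containing no short-TR run of its own and whose junction
    bases cannot continue an adjacent planted tract (neither as a whole extra
    motif copy nor by extending the scanner's periodicity run)."""
    for _ in range(max_tries):
        sp = _random_seq(rng, n)
        if scan_pure_repeats(sp, min_motif=1, max_motif=8, min_span_bp=6):
            continue
        if prev_motif and (sp[0] == prev_motif[0] or sp[0] == prev_motif[-1]):
            continue
        if next_motif and (sp[-1] == next_motif[-1] or sp[-1] == next_motif[0]):
            continue
        if prev_motif and sp.startswith(prev_motif):
            continue
        if next_motif and sp.endswith(next_motif):
            continue
        return sp
    raise RuntimeError("could not generate a clean spacer; spacer too short?")


def generate_reference(
    specs: Sequence[PlantSpec],
    seed: int = 0,
    chrom: str = "chr1",
    tail_len: int = 120,
) -> SyntheticReference:
    """Assemble a single-contig reference with the given tracts planted in
    order, separated by screened random spacers. Deterministic per seed."""
    rng = np.random.default_rng(seed)
    parts: List[str] = []
    planted: List[PlantedLocus] = []
    cursor = 0
    prev_motif = ""
    for spec in specs:
        spacer = _clean_spacer(rng, spec.flank_len, prev_motif, spec.motif)
        parts.append(spacer)
        cursor += len(spacer)
        tract = spec.motif * spec.ref_repeat_count
        parts.append(tract)
        planted.append(
            PlantedLocus(spec, chrom, cursor, cursor + len(tract))
        )
        cursor += len(tract)
        prev_motif = spec.motif
    tail = _clean_spacer(rng, tail_len, prev_motif, "")
    parts.append(tail)
    return SyntheticReference({chrom: "".join(parts)}, planted)


# ---------------------------------------------------------------------------
# VCF generation


@dataclass
class SyntheticVcf:
    records: List[Tuple]  # (chrom, pos, id, ref, alt_string, gt_string)
    expected: pd.DataFrame  # one row per record with the expected outcome
    reference: SyntheticReference

    def write_vcf(self, path: Union[str, Path]) -> str:
        path = str(path)
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for chrom, seq in self.reference.sequences.items():
                fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
            for chrom, pos, rid, ref, alt, gt in sorted(
                self.records, key=lambda r: (r[0], r[1])
            ):
                fh.write(f"{chrom}\t{pos}\t{rid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gt}\n")
        return path


def _interrupt_units(
    rng: np.random.Generator, motif: str, count: int, variable_position: int, fraction: float
) -> str:
    """``count`` repeat units with ~``fraction`` of them varied at one position.

    At least one unit is varied (else the sequence would be pure) and the
    first and last units are kept exact so reference extension rules behave.
    """
    n_vary = max(1, round(count * fraction))
    n_vary = min(n_vary, max(count - 2, 1))
    positions = rng.choice(np.arange(1, count - 1) if count > 2 else [0], size=n_vary, replace=False)
    units = []
    for i in range(count):
        if i in positions:
            alternatives = [b for b in "ACGT" if b != motif[variable_position]]
            b = alternatives[int(rng.integers(0, 3))]
            u = motif[:variable_position] + b + motif[variable_position + 1 :]
        else:
            u = motif
        units.append(u)
    return "".join(units)


def generate_vcf(
    synref: SyntheticReference,
    seed: int = 0,
    n_decoy_snvs: int = 3,
    n_decoy_small_indels: int = 3,
    n_decoy_large_indels: int = 3,
    config: Optional[FilterConfig] = None,
) -> SyntheticVcf:
    """VCF records for every planted tract plus screened decoy variants.

    Expansion alleles insert whole (optionally interrupted) motif copies at
    the tract's left boundary; contractions delete leading copies. Two-delta
    specs become multi-allelic records genotyped 1/2, one-delta specs 0/1.
    Decoys are SNVs, 1-5 bp indels and >= 6 bp non-periodic indels placed in
    spacer sequence, re-rolled until the classifier assigns the intended
    rejection category, which is recorded as the expected outcome.
    """
    cfg = config or FilterConfig()
    rng = np.random.default_rng(seed + 1)
    chrom = synref.planted[0].chrom if synref.planted else next(iter(synref.sequences))
    seq = synref.sequences[chrom]
    records: List[Tuple] = []
    expected_rows: List[Dict] = []
    used: List[Tuple[int, int]] = []  # occupied [start, end) record footprints

    def variant_seq_for(spec: PlantSpec, n_copies: int) -> str:
        if spec.interruption is not None:
            vp, frac = spec.interruption
            return _interrupt_units(rng, spec.motif, n_copies, vp, frac)
        return spec.motif * n_copies

    for i, planted in enumerate(synref.planted):
        spec = planted.spec
        m = spec.motif
        ml = len(m)
        ts = planted.tract_start
        anchor = seq[ts - 1]
        deltas = spec.allele_deltas
        max_del = max((-d for d in deltas if d < 0), default=0)
        ref_allele = anchor + seq[ts : ts + max_del * ml]
        alts = []
        for d in deltas:
            kept = max_del + d  # copies of the REF footprint present on this allele
            if d > 0:
                alt = anchor + variant_seq_for(spec, kept) if max_del else anchor + variant_seq_for(spec, d)
            else:
                alt = anchor + seq[ts : ts + kept * ml]
            alts.append(alt)
        gt = "0/1" if len(deltas) == 1 else "1/2"
        pos = ts  # 1-based anchor position (= 0-based ts - 1, +1)
        rid = f"tr{i}"
        records.append((chrom, pos, rid, ref_allele, ",".join(alts), gt))
        used.append((pos - 1, pos - 1 + len(ref_allele)))
        allele_repeats = sorted(spec.ref_repeat_count + d for d in deltas)
        if len(deltas) == 1:
            short, long_ = sorted((spec.ref_repeat_count, allele_repeats[0]))
            multi = False
        else:
            short, long_ = allele_repeats[0], allele_repeats[-1]
            multi = short != long_
        expected_rows.append(
            {
                "record_id": rid,
                "kind": "planted_tr",
                "chrom": chrom,
                "pos": pos,
                "expected_outcome": "pass",
                "motif": m,
                "canonical_motif": canonical_motif(m),
                "locus_start": ts,
                "locus_end": planted.tract_end,
                "ref_repeats": spec.ref_repeat_count,
                "short_allele_repeats": short,
                "long_allele_repeats": long_,
                "is_multiallelic": multi,
                "is_pure": spec.interruption is None,
            }
        )

    # decoy placement inside spacers, away from tracts and other records
    tract_iv = [(p.tract_start - 8, p.tract_end + 8) for p in synref.planted]

    def free_position(width: int, tries: int = 500) -> int:
        for _ in range(tries):
            pos0 = int(rng.integers(20, len(seq) - width - 20))
            footprint = (pos0, pos0 + width)
            if any(a < footprint[1] and footprint[0] < b for a, b in tract_iv + used):
                continue
            return pos0
        raise RuntimeError("no room for decoys; enlarge flanks")

    def add_decoy(kind: str, want: RejectionCategory, size_range: Tuple[int, int], j: int):
        for _ in range(200):
            size = int(rng.integers(size_range[0], size_range[1] + 1))
            is_del = bool(rng.integers(0, 2))
            width = size + 1 if is_del else 1
            pos0 = free_position(width)
            if is_del:
                ref_a = seq[pos0 : pos0 + size + 1]
                alt_a = ref_a[0]
            else:
                ref_a = seq[pos0]
                alt_a = ref_a + _random_seq(rng, size)
            res = classify_allele(
                VariantAllele(chrom, pos0 + 1, ref_a, alt_a, gt=(0, 1)), synref.sequences, cfg
            )
            if res is want:
                rid = f"{kind}{j}"
                records.append((chrom, pos0 + 1, rid, ref_a, alt_a, "0/1"))
                used.append((pos0, pos0 + len(ref_a)))
                expected_rows.append(
                    {
                        "record_id": rid,
                        "kind": kind,
                        "chrom": chrom,
                        "pos": pos0 + 1,
                        "expected_outcome": want.value,
                    }
                )
                return
        raise RuntimeError(f"could not construct decoy of kind {kind}")

    for j in range(n_decoy_small_indels):
        add_decoy("decoy_small", RejectionCategory.SMALL_INDEL, (1, 5), j)
    for j in range(n_decoy_large_indels):
        add_decoy("decoy_large", RejectionCategory.NON_TR, (6, 12), j)
    for j in range(n_decoy_snvs):
        pos0 = free_position(1)
        ref_b = seq[pos0]
        alt_b = str(rng.choice([b for b in "ACGT" if b != ref_b]))
        rid = f"snv{j}"
        records.append((chrom, pos0 + 1, rid, ref_b, alt_b, "0/1"))
        used.append((pos0, pos0 + 1))
        expected_rows.append(
            {
                "record_id": rid,
                "kind": "decoy_snv",
                "chrom": chrom,
                "pos": pos0 + 1,
                "expected_outcome": "snv",
            }
        )

    expected = pd.DataFrame(expected_rows)
    return SyntheticVcf(records, expected, synref)


# ---------------------------------------------------------------------------
# simulated tool calls


@dataclass(frozen=True)
class ErrorModel:
    """Simple per-allele error model for a simulated TR genotyper.

    Defaults emulate a tool that is exactly right on most alleles with a
    small no-call rate and symmetric over/under-estimation errors whose
    magnitudes are geometric.
    """

    exact_rate: float = 0.8
    nocall_rate: float = 0.02
    over_bias: float = 0.5  # fraction of erroneous calls that overestimate
    error_magnitude_p: float = 0.5  # geometric parameter for |error| in repeats

    def __post_init__(self) -> None:
        assert 0 <= self.exact_rate <= 1 and 0 <= self.nocall_rate <= 1
        assert self.exact_rate + self.nocall_rate <= 1


def generate_tool_calls(
    truth_df: pd.DataFrame,
    error_model: Optional[ErrorModel] = None,
    seed: int = 0,
    read_length: int = 150,
) -> pd.DataFrame:
    """Simulate one tool's genotypes for every truth locus.

    ``truth_df`` needs columns ``chrom``, ``locus_start``, ``locus_end``,
    ``motif``, ``ref_repeats``, ``short_allele_repeats``,
    ``long_allele_repeats``. Returns one row per locus with estimates,
    confidence intervals, a Q_CI-style quality score per allele, and the
    *realized* outcome per allele (exact/overestimate/underestimate/no_call)
    tallied directly by the generator so downstream concordance output can be
    checked against it.
    """
    em = error_model or ErrorModel()
    rng = np.random.default_rng(seed + 2)
    rows = []
    for _, t in truth_df.iterrows():
        ests: List[Optional[int]] = []
        for true_size in (int(t.short_allele_repeats), int(t.long_allele_repeats)):
            u = rng.random()
            if u < em.nocall_rate:
                ests.append(None)
            elif u < em.nocall_rate + em.exact_rate:
                ests.append(true_size)
            else:
                mag = int(rng.geometric(em.error_magnitude_p))
                if rng.random() < em.over_bias:
                    ests.append(true_size + mag)
                else:
                    ests.append(max(0, true_size - mag))
        # enforce short <= long as a real tool's output would, then re-derive
        # the realized outcome of each slot from its final estimate
        if ests[0] is not None and ests[1] is not None and ests[0] > ests[1]:
            ests = [ests[1], ests[0]]
        trues = (int(t.short_allele_repeats), int(t.long_allele_repeats))
        realized = [
            "no_call" if est is None
            else "exact" if est == true
            else "overestimate" if est > true
            else "underestimate"
            for est, true in zip(ests, trues)
        ]
        cis = []
        qs = []
        for est, outcome in zip(ests, realized):
            if est is None:
                cis.append((None, None))
                qs.append(None)
                continue
            width = 0 if outcome == "exact" and rng.random() < 0.7 else int(rng.integers(1, 6))
            cis.append((max(0, est - width), est + width))
            qs.append(float(np.exp(-4.0 * (2 * width) / est)) if est > 0 else None)
        locus_id = f"{t.chrom}:{t.locus_start}-{t.locus_end}"
        rows.append(
            {
                "locus_id": locus_id,
                "motif": t.motif,
                "ref_repeats": int(t.ref_repeats),
                "true_short": int(t.short_allele_repeats),
                "true_long": int(t.long_allele_repeats),
                "short_est": ests[0],
                "long_est": ests[1],
                "ci_short_lo": cis[0][0],
                "ci_short_hi": cis[0][1],
                "ci_long_lo": cis[1][0],
                "ci_long_hi": cis[1][1],
                "q_short": qs[0],
                "q_long": qs[1],
                "realized_short": realized[0],
                "realized_long": realized[1],
            }
        )
    return pd.DataFrame(rows)


def tool_calls_to_genotypes(calls_df: pd.DataFrame):
    """Convert a simulated tool-call table to :class:`ToolGenotype` objects."""
    from .evaluate import ToolGenotype

    out = []
    for _, r in calls_df.iterrows():
        def _opt(v):
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else int(v)

        ci_s = (_opt(r.ci_short_lo), _opt(r.ci_short_hi))
        ci_l = (_opt(r.ci_long_lo), _opt(r.ci_long_hi))
        out.append(
            ToolGenotype(
                locus_id=r.locus_id,
                short_est=_opt(r.short_est),
                long_est=_opt(r.long_est),
                ci_short=None if ci_s[0] is None else ci_s,
                ci_long=None if ci_l[0] is None else ci_l,
            )
        )
    return out


def generate_ehdn_intervals(
    truth_df: pd.DataFrame,
    detect_rate: float = 1.0,
    n_false_positives: int = 0,
    position_jitter_bp: int = 100,
    seed: int = 0,
) -> List:
    """EHdn-profile-style intervals around a subset of truth expansions, plus
    optional false-positive intervals on an unused contig location."""
    from .evaluate import EhdnInterval

    rng = np.random.default_rng(seed + 3)
    intervals = []
    for _, t in truth_df.iterrows():
        if t.long_allele_repeats <= t.ref_repeats:
            continue  # EHdn sees expansions only
        if rng.random() >= detect_rate:
            continue
        jitter = int(rng.integers(-position_jitter_bp, position_jitter_bp + 1))
        start = max(0, int(t.locus_start) + jitter)
        intervals.append(
            EhdnInterval(t.chrom, start, start + max(1, int(t.locus_end - t.locus_start)), t.motif, 5)
        )
    far = 10_000_000
    for j in range(n_false_positives):
        motif = "".join(_BASES[rng.integers(0, 4, size=int(rng.integers(2, 7)))])
        if len(smallest_pure_unit(motif).motif) != len(motif):
            motif = "AGC"  # keep the decoy motif aperiodic
        start = far + 5000 * j
        intervals.append(EhdnInterval("chrFP", start, start + 300, motif, 3))
    return intervals
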