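"""TR filter: allele classification, site logic, overlap handling, VCF driver."""

import json

import pytest

from trtruth.fixtures import PlantSpec, generate_reference, generate_vcf
from trtruth.trfilter import (
    RejectionCategory,
    TandemRepeatCall,
    TruthLocus,
    VariantAllele,
    classify_allele,
    classify_site,
    classify_variant,
    drop_overlapping_loci,
    filter_vcf,
    minimal_representation,
)

from conftest import make_tract_contig, nonrepetitive_seq, random_seq


def ins(chrom, pos, anchor, inserted, gt=(0, 1)):
    return VariantAllele(chrom, pos, anchor, anchor + inserted, gt=gt)


class TestClassifyAlleleWorkedExamples:
    """The five canonical single-allele scenarios of the filter."""

    def test_insertion_next_to_reference_tract(self, rng):
        # +GCGGCG beside 9 reference GCG copies -> 11 total repeats over 33 bp
        seq, ts = make_tract_contig(rng, "GCG", 9)
        call = classify_allele(ins("c", ts, seq[ts - 1], "GCGGCG"), {"c": seq})
        assert isinstance(call, TandemRepeatCall)
        assert call.motif == "GCG" and call.is_pure
        assert call.ref_repeats == 9 and call.allele_repeats == 11
        assert call.allele_repeats * 3 == 33
        assert (call.locus_start, call.locus_end) == (ts, ts + 27)

    def test_deletion_contracts_tc_tract(self, rng):
        # deleting 2 of 6 TC copies -> 4 total repeats on the allele
        seq, ts = make_tract_contig(rng, "TC", 6)
        a = VariantAllele("c", ts, seq[ts - 1] + "TCTC", seq[ts - 1], gt=(0, 1))
        call = classify_allele(a, {"c": seq})
        assert isinstance(call, TandemRepeatCall)
        assert call.motif == "TC"
        assert call.ref_repeats == 6 and call.allele_repeats == 4
        assert call.delta_repeats == -2
        assert (call.locus_start, call.locus_end) == (ts, ts + 12)

    def test_motif_is_whole_variant_sequence(self, rng):
        # +TTGTC has no smaller period; 3 adjacent copies give a 4x allele
        seq, ts = make_tract_contig(rng, "TTGTC", 3)
        call = classify_allele(ins("c", ts, seq[ts - 1], "TTGTC"), {"c": seq})
        assert isinstance(call, TandemRepeatCall)
        assert call.motif == "TTGTC"
        assert call.allele_repeats == 4 and call.ref_repeats == 3

    def test_tr_with_no_adjacent_reference_copies(self, rng):
        # 4 AAG copies in the variant sequence alone pass (12 bp >= 9, 4 >= 3)
        flank_l = nonrepetitive_seq(rng, 40, avoid_motifs=["AAG"])
        flank_r = nonrepetitive_seq(rng, 40, avoid_motifs=["AAG"])
        seq = flank_l + flank_r
        pos = len(flank_l)
        call = classify_allele(ins("c", pos, seq[pos - 1], "AAGAAGAAGAAG"), {"c": seq})
        assert isinstance(call, TandemRepeatCall)
        assert call.motif == "AAG" and call.is_pure
        assert call.ref_repeats == 0 and call.allele_repeats == 4

    def test_interrupted_insertion(self, rng):
        # +CGGCGGAGG (NGG x3) beside 4 reference NGG copies -> 7 x NGG
        ref_tract = "CGGTGGAGGCGG"  # first/last copies exact
        lf = nonrepetitive_seq(rng, 40, avoid_motifs=["CGG"])
        rf = nonrepetitive_seq(rng, 40, avoid_motifs=["CGG"])
        seq = lf + ref_tract + rf
        pos = len(lf) + len(ref_tract)  # insert right of the tract
        call = classify_allele(ins("c", pos, seq[pos - 1], "CGGCGGAGG"), {"c": seq})
        assert isinstance(call, TandemRepeatCall)
        assert not call.is_pure and call.variable_position == 0
        assert call.motif == "CGG"
        assert call.ref_repeats == 4 and call.allele_repeats == 7

    def test_partial_repeat_end_rejected(self, rng):
        # CAGCAGCA > C inside a CAG tract: whole copies + partial copy
        seq, ts = make_tract_contig(rng, "CAG", 10)
        ref_a = seq[ts : ts + 8]  # "CAGCAGCA"
        assert ref_a == "CAGCAGCA"
        a = VariantAllele("c", ts + 1, ref_a, ref_a[0], gt=(0, 1))
        assert classify_allele(a, {"c": seq}) is RejectionCategory.PARTIAL_REPEAT

    def test_small_indel_without_context_rejected(self, rng):
        flank = nonrepetitive_seq(rng, 80, avoid_motifs=["ATT"])
        res = classify_allele(ins("c", 40, flank[39], "ATT"), {"c": flank})
        assert res is RejectionCategory.SMALL_INDEL


class TestClassifyAlleleRouting:
    def test_homopolymer_routed_by_base(self, rng):
        seq, ts = make_tract_contig(rng, "A", 12)
        res = classify_allele(ins("c", ts, seq[ts - 1], "AAAA"), {"c": seq})
        assert res is RejectionCategory.HOMOPOLYMER_AT
        seq, ts = make_tract_contig(rng, "G", 12)
        res = classify_allele(ins("c", ts, seq[ts - 1], "GGGG"), {"c": seq})
        assert res is RejectionCategory.HOMOPOLYMER_CG

    def test_motif_above_50bp_categorized(self, rng):
        motif = random_seq(rng, 55)
        while len(motif) != 55:
            motif = random_seq(rng, 55)
        seq, ts = make_tract_contig(rng, motif, 3, left=60, right=60)
        res = classify_allele(ins("c", ts, seq[ts - 1], motif), {"c": seq})
        assert res is RejectionCategory.MOTIF_GT_50BP

    def test_non_acgt_goes_to_other(self):
        a = VariantAllele("c", 5, "A", "ANNN", gt=(0, 1))
        assert classify_allele(a, "ACGTACGTACGT") is RejectionCategory.OTHER

    def test_pure_path_wins_over_interrupted(self, rng):
        # AAG insertion could be read as interrupted AAN, but the pure
        # decomposition passes first and is reported pure
        seq, ts = make_tract_contig(rng, "AAG", 5)
        call = classify_allele(ins("c", ts, seq[ts - 1], "AAGAAGAAG"), {"c": seq})
        assert isinstance(call, TandemRepeatCall) and call.is_pure

    def test_symmetry_insertion_vs_deletion(self, rng):
        # +k copies and -k copies at one tract: same locus, |delta| equal
        seq, ts = make_tract_contig(rng, "CTG", 8)
        ins_call = classify_allele(ins("c", ts, seq[ts - 1], "CTG" * 2), {"c": seq})
        del_a = VariantAllele("c", ts, seq[ts - 1] + "CTGCTG", seq[ts - 1], gt=(0, 1))
        del_call = classify_allele(del_a, {"c": seq})
        assert isinstance(ins_call, TandemRepeatCall) and isinstance(del_call, TandemRepeatCall)
        assert abs(ins_call.delta_repeats) == abs(del_call.delta_repeats) == 2
        assert (ins_call.locus_start, ins_call.locus_end) == (
            del_call.locus_start,
            del_call.locus_end,
        )

    def test_deletion_thresholds_use_reference_total(self, rng):
        # deleting 2 TC copies from a 6-copy tract: variant has only 2 copies
        # but the reference total (6) meets the thresholds
        seq, ts = make_tract_contig(rng, "TC", 6)
        a = VariantAllele("c", ts, seq[ts - 1] + "TCTC", seq[ts - 1], gt=(0, 1))
        assert isinstance(classify_allele(a, {"c": seq}), TandemRepeatCall)


class TestClassifySite:
    def test_multiallelic_expansion_pair(self, rng):
        # +1 and +3 copies on a 9-copy tract: true genotype 10/12
        seq, ts = make_tract_contig(rng, "GAA", 9)
        anchor = seq[ts - 1]
        alleles = [
            ins("c", ts, anchor, "GAA", gt=(1, 2)),
            ins("c", ts, anchor, "GAAGAAGAA", gt=(1, 2)),
        ]
        locus = classify_variant(alleles, {"c": seq})
        assert isinstance(locus, TruthLocus)
        assert (locus.short_allele_repeats, locus.long_allele_repeats) == (10, 12)
        assert locus.is_multiallelic

    def test_heterozygous_single_allele_keeps_reference_short(self, rng):
        seq, ts = make_tract_contig(rng, "CAG", 7)
        locus = classify_variant(
            [ins("c", ts, seq[ts - 1], "CAGCAG", gt=(0, 1))], {"c": seq}
        )
        assert (locus.short_allele_repeats, locus.long_allele_repeats) == (7, 9)
        assert not locus.is_multiallelic

    def test_homozygous_alt_sets_both_alleles(self, rng):
        seq, ts = make_tract_contig(rng, "CAG", 7)
        locus = classify_variant(
            [ins("c", ts, seq[ts - 1], "CAGCAG", gt=(1, 1))], {"c": seq}
        )
        assert (locus.short_allele_repeats, locus.long_allele_repeats) == (9, 9)

    def test_one_passing_allele_rejects_variant(self, rng):
        seq, ts = make_tract_contig(rng, "GAA", 9)
        anchor = seq[ts - 1]
        alleles = [
            ins("c", ts, anchor, "GAAGAA", gt=(1, 2)),
            ins("c", ts, anchor, "CTTCA", gt=(1, 2)),  # not a GAA repeat
        ]
        site = classify_site(alleles, {"c": seq})
        assert not site.passed
        assert site.allele_categories == [
            RejectionCategory.MULTIALLELIC_ONE_PASSED,
            RejectionCategory.MULTIALLELIC_ONE_PASSED,
        ]

    def test_inconsistent_motifs_reject_variant(self, rng):
        # two passing alleles with different motifs at one anchor
        lf = nonrepetitive_seq(rng, 40, avoid_motifs=["AAG", "ATC"])
        rf = nonrepetitive_seq(rng, 40, avoid_motifs=["AAG", "ATC"])
        seq = lf + rf
        pos = len(lf)
        anchor = seq[pos - 1]
        alleles = [
            ins("c", pos, anchor, "AAG" * 4, gt=(1, 2)),
            ins("c", pos, anchor, "ATC" * 4, gt=(1, 2)),
        ]
        site = classify_site(alleles, {"c": seq})
        assert site.allele_categories == [
            RejectionCategory.MULTIALLELIC_INCONSISTENT,
            RejectionCategory.MULTIALLELIC_INCONSISTENT,
        ]


class TestMinimalRepresentation:
    @pytest.mark.parametrize(
        "pos,ref,alt,expected",
        [
            (10, "A", "AGCG", (10, "A", "AGCG")),  # already minimal
            (10, "ACAGCAG", "ACAG", (10, "ACAG", "A")),  # suffix trimmed first
            (10, "ACAG", "ACAGCAG", (10, "A", "ACAG")),
            (10, "AC", "AT", (11, "C", "T")),  # MNV reduces to an SNV
        ],
    )
    def test_examples(self, pos, ref, alt, expected):
        assert minimal_representation(pos, ref, alt) == expected


class TestDropOverlappingLoci:
    def make(self, chrom, start, end):
        return TruthLocus(
            chrom=chrom, locus_start=start, locus_end=end, motif="CAG",
            canonical_motif="AGC", is_pure=True, short_allele_repeats=3,
            long_allele_repeats=4, ref_repeats=3, is_multiallelic=False,
        )

    def test_disjoint_all_kept(self):
        loci = [self.make("c", 0, 9), self.make("c", 9, 18), self.make("c", 30, 39)]
        kept, dropped = drop_overlapping_loci(loci)
        assert len(kept) == 3 and not dropped

    def test_overlap_drops_both(self):
        loci = [self.make("c", 0, 10), self.make("c", 9, 20), self.make("c", 40, 50)]
        kept, dropped = drop_overlapping_loci(loci)
        assert [l.locus_start for l in kept] == [40]
        assert sorted(l.locus_start for l in dropped) == [0, 9]

    def test_nested_drops_both(self):
        loci = [self.make("c", 0, 30), self.make("c", 10, 20)]
        kept, dropped = drop_overlapping_loci(loci)
        assert not kept and len(dropped) == 2

    def test_same_coords_different_chroms_kept(self):
        loci = [self.make("c1", 0, 10), self.make("c2", 0, 10)]
        kept, _ = drop_overlapping_loci(loci)
        assert len(kept) == 2

    def test_matches_quadratic_oracle(self, rng):
        starts = rng.integers(0, 500, size=40)
        loci = [self.make("c", int(s), int(s) + int(rng.integers(3, 30))) for s in starts]
        kept, dropped = drop_overlapping_loci(loci)
        overl = [
            any(
                a is not b and a.locus_start < b.locus_end and b.locus_start < a.locus_end
                for b in loci
            )
            for a in loci
        ]
        expect_kept = [l for l, o in zip(loci, overl) if not o]
        assert sorted(l.locus_start for l in kept) == sorted(l.locus_start for l in expect_kept)


# ---------------------------------------------------------------------------
# brute-force classifier oracle


def naive_classify(seq, pos, ref_a, alt_a, min_span=9, min_repeats=3):
    """Straight-line re-derivation of the allele verdict for the oracle test.

    Returns ("pass", motif, allele_repeats) or a category string. Written with
    direct string stepping only — no shared helpers with the implementation.
    """
    # minimal representation
    while len(ref_a) > 1 and len(alt_a) > 1 and ref_a[-1] == alt_a[-1]:
        ref_a, alt_a = ref_a[:-1], alt_a[:-1]
    while len(ref_a) > 1 and len(alt_a) > 1 and ref_a[0] == alt_a[0]:
        ref_a, alt_a, pos = ref_a[1:], alt_a[1:], pos + 1
    if len(ref_a) == len(alt_a) or min(len(ref_a), len(alt_a)) != 1 or ref_a[0] != alt_a[0]:
        return ("other",)
    is_ins = len(alt_a) > len(ref_a)
    vs = (alt_a if is_ins else ref_a)[1:]
    L = len(vs)
    lb = pos
    rb = pos + (0 if is_ins else L)

    def count_exact(m, boundary, direction):
        n, k = 0, len(m)
        if direction == "left":
            while boundary - (n + 1) * k >= 0 and seq[boundary - (n + 1) * k : boundary - n * k] == m:
                n += 1
        else:
            while boundary + (n + 1) * k <= len(seq) and seq[boundary + n * k : boundary + (n + 1) * k] == m:
                n += 1
        return n

    def count_interrupted(m, vp, boundary, direction):
        k = len(m)
        copies = []
        n = 0
        while True:
            if direction == "left":
                lo = boundary - (n + 1) * k
                if lo < 0:
                    break
                unit = seq[lo : lo + k]
            else:
                lo = boundary + n * k
                if lo + k > len(seq):
                    break
                unit = seq[lo : lo + k]
            ok = all(a == b for i, (a, b) in enumerate(zip(unit, m)) if i != vp)
            if not ok:
                break
            copies.append(unit)
            n += 1
        while copies and copies[-1] != m:
            copies.pop()
        if copies and copies[0] != m:
            return 0
        return len(copies)

    def verdict(m, n_var, left, right):
        if is_ins:
            ref_r = left + right
            allele_r = ref_r + n_var
        else:
            ref_r = left + n_var + right
            allele_r = ref_r - n_var
        big = max(ref_r, allele_r)
        if big < min_repeats or big * len(m) < min_span:
            return None
        if len(m) == 1:
            return ("homopolymer_AT",) if m in "AT" else ("homopolymer_CG",)
        if len(m) > 50:
            return ("motif_gt_50bp",)
        return ("pass", m, allele_r)

    # pure path
    motif = vs
    for d in range(1, L):
        if L % d == 0 and vs == vs[:d] * (L // d):
            motif = vs[:d]
            break
    n_var = L // len(motif)
    v = verdict(motif, n_var, count_exact(motif, lb, "left"), count_exact(motif, rb, "right"))
    if v:
        return v
    # interrupted path
    for d in [x for x in range(1, L) if L % x == 0 and x != len(motif)]:
        units = [vs[i : i + d] for i in range(0, L, d)]
        common = max(sorted(set(units), key=units.index), key=units.count)
        diffpos = {i for u in units for i in range(d) if u[i] != common[i]}
        if len(diffpos) != 1:
            continue
        vp = diffpos.pop()
        if d == 1:
            bad = [i for i, b in enumerate(vs) if b != common]
            if (L - len(bad)) / L < 0.9 or any(b - a == 1 for a, b in zip(bad, bad[1:])):
                continue
            left, right = count_exact(common, lb, "left"), count_exact(common, rb, "right")
        elif d == 2:
            if sum(u == common for u in units) / len(units) < 0.8:
                continue
            left, right = count_exact(common, lb, "left"), count_exact(common, rb, "right")
        else:
            left = count_interrupted(common, vp, lb, "left")
            right = count_interrupted(common, vp, rb, "right")
        v = verdict(common, len(units), left, right)
        if v:
            return v
    # partial repeat
    for d in range(1, min(50, L - 1) + 1):
        whole, rem = divmod(L, d)
        if rem == 0:
            continue
        for m in {vs[:d], vs[-d:]}:
            if vs != (m * (whole + 1))[:L] and vs != (m * (whole + 1))[-L:]:
                continue
            total = whole + count_exact(m, lb, "left") + count_exact(m, rb, "right")
            if total >= min_repeats and total * d >= min_span:
                return ("partial_repeat_end",)
    return ("small_indel_1_5bp",) if L <= 5 else ("non_tr_ge_6bp",)


def as_tuple(result):
    if isinstance(result, TandemRepeatCall):
        return ("pass", result.motif, result.allele_repeats)
    return (result.value,)


class TestOracleEquivalence:
    def test_random_alleles_match_bruteforce(self, rng):
        motifs = ["A", "AT", "AC", "CAG", "GCG", "AAG", "TTGTC", "ATGCC"]
        n_checked = 0
        for _ in range(300):
            motif = motifs[int(rng.integers(0, len(motifs)))]
            copies = int(rng.integers(0, 9))
            lf = random_seq(rng, int(rng.integers(40, 60)))
            rf = random_seq(rng, int(rng.integers(40, 60)))
            seq = lf + motif * copies + rf
            pos = int(rng.integers(10, len(seq) - 45))
            if rng.random() < 0.5:
                k = int(rng.integers(1, 15))
                if rng.random() < 0.6:
                    varseq = (motif * 6)[:k]
                else:
                    varseq = random_seq(rng, k)
                ref_a, alt_a = seq[pos - 1], seq[pos - 1] + varseq
            else:
                k = int(rng.integers(1, min(15, len(seq) - pos - 30)))
                ref_a, alt_a = seq[pos - 1 : pos + k], seq[pos - 1]
            got = as_tuple(
                classify_allele(VariantAllele("c", pos, ref_a, alt_a, gt=(0, 1)), {"c": seq})
            )
            assert got == naive_classify(seq, pos, ref_a, alt_a), (
                seq, pos, ref_a, alt_a,
            )
            n_checked += 1
        assert n_checked == 300


class TestFilterVcf:
    @pytest.fixture
    def fixture_run(self, tmp_path):
        specs = [
            PlantSpec("CAG", 9, (2,)),
            PlantSpec("GCG", 9, (2,)),
            PlantSpec("TC", 6, (-2,)),
            PlantSpec("AAG", 5, (1, 3)),
            PlantSpec("TTGTC", 3, (1,)),
        ]
        synref = generate_reference(specs, seed=7)
        synvcf = generate_vcf(synref, seed=7, n_decoy_snvs=2,
                              n_decoy_small_indels=3, n_decoy_large_indels=2)
        fasta = synref.write_fasta(tmp_path / "ref.fa")
        vcf = synvcf.write_vcf(tmp_path / "calls.vcf")
        return synref, synvcf, fasta, vcf, tmp_path

    def test_planted_trs_recovered_and_decoys_rejected(self, fixture_run):
        synref, synvcf, fasta, vcf, tmp = fixture_run
        res = filter_vcf(vcf, fasta, out_prefix=str(tmp / "out"))
        assert len(res.truth_loci) == 5
        expected = synvcf.expected
        planted = expected[expected.kind == "planted_tr"].set_index("locus_start")
        for locus in res.truth_loci:
            row = planted.loc[locus.locus_start]
            assert locus.motif == row.motif
            assert locus.locus_end == row.locus_end
            assert locus.ref_repeats == row.ref_repeats
            assert locus.short_allele_repeats == row.short_allele_repeats
            assert locus.long_allele_repeats == row.long_allele_repeats
            assert locus.is_multiallelic == row.is_multiallelic
        cats = res.summary["rejection_categories"]
        assert cats.get("small_indel_1_5bp", 0) == 3
        assert cats.get("non_tr_ge_6bp", 0) == 2

    def test_partition_sums_to_total(self, fixture_run):
        _, _, fasta, vcf, tmp = fixture_run
        res = filter_vcf(vcf, fasta)
        s = res.summary
        assert (
            s["passing_alleles"] + sum(s["rejection_categories"].values())
            == s["total_ins_del_alleles"]
        )

    def test_outputs_written_and_consistent(self, fixture_run):
        _, _, fasta, vcf, tmp = fixture_run
        res = filter_vcf(vcf, fasta, out_prefix=str(tmp / "out"))
        with open(res.output_paths["summary_json"]) as fh:
            assert json.load(fh)["passing_loci"] == len(res.truth_loci)
        bed_lines = open(res.output_paths["loci_bed"]).read().splitlines()
        assert len(bed_lines) == len(res.truth_loci)
        truth_lines = open(res.output_paths["truth_tsv"]).read().splitlines()
        assert len(truth_lines) == len(res.truth_loci) + 1

    def test_high_confidence_bed_restricts(self, fixture_run, tmp_path):
        synref, synvcf, fasta, vcf, tmp = fixture_run
        chrom = synref.planted[0].chrom
        first = synref.planted[0]
        bed = tmp_path / "hc.bed"
        bed.write_text(f"{chrom}\t0\t{first.tract_end + 30}\n")
        res = filter_vcf(vcf, fasta, high_confidence_bed=str(bed))
        assert len(res.truth_loci) == 1
        assert res.truth_loci[0].locus_start == first.tract_start

    def test_empty_vcf(self, tmp_path):
        ref = tmp_path / "r.fa"
        ref.write_text(">c\n" + "ACGTTGCA" * 10 + "\n")
        import pysam

        pysam.faidx(str(ref))
        vcf = tmp_path / "e.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=c,length=80>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        res = filter_vcf(str(vcf), str(ref))
        assert res.truth_df.empty and res.summary["total_ins_del_alleles"] == 0

    def test_contig_mismatch_fatal(self, fixture_run, tmp_path):
        _, _, fasta, vcf, _ = fixture_run
        bad = tmp_path / "bad.vcf"
        lines = open(vcf).read().replace("chr1", "chrZ")
        bad.write_text(lines)
        with pytest.raises(ValueError, match="contig"):
            filter_vcf(str(bad), fasta)

    def test_overlapping_loci_both_dropped(self, rng, tmp_path):
        # two separate VCF variants implying overlapping reference loci:
        # an insertion at each end of one tract extends over the same copies
        seq, ts = make_tract_contig(rng, "CAG", 8, left=60, right=60)
        te = ts + 24
        fasta = tmp_path / "r.fa"
        fasta.write_text(">c\n" + seq + "\n")
        import pysam

        pysam.faidx(str(fasta))
        vcf = tmp_path / "v.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            f"##contig=<ID=c,length={len(seq)}>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n"
            f"c\t{ts}\tv1\t{seq[ts - 1]}\t{seq[ts - 1]}CAGCAG\t.\tPASS\t.\tGT\t0/1\n"
            f"c\t{te}\tv2\t{seq[te - 1]}\t{seq[te - 1]}CAGCAG\t.\tPASS\t.\tGT\t0/1\n"
        )
        res = filter_vcf(str(vcf), str(fasta))
        assert not res.truth_loci
        assert res.summary["rejection_categories"].get("overlapping_locus") == 2
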