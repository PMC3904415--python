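"""MD/CIGAR reference reconstruction and per-read variant extraction."""

import re
from random import Random

import pytest

from paircall import (
    DEL,
    INS,
    SNV,
    AlignedRead,
    Amplicon,
    MdError,
    Variant,
    decode_reference,
    extract_read_variants,
    variant_within_amplicon,
)
from paircall.alignment import UnsupportedCigarError
from paircall.synth import md_tag


def make_read(pos, cigar, md, seq, quals=None, **flags):
    if quals is None:
        quals = (30,) * len(seq)
    return AlignedRead(qname="r", chrom="chr1", pos=pos,
                       cigar=tuple(cigar), md=md, seq=seq,
                       quals=tuple(quals), **flags)


class TestDecodeReference:
    @pytest.mark.parametrize("cigar,md,seq,expected", [
        ([("M", 4)], "4", "ACGT", "ACGT"),            # all-match
        ([("M", 4)], "2A1", "ACGT", "ACAT"),          # read G over ref A
        ([("M", 2), ("D", 1), ("M", 2)], "2^A2", "ACGT", "ACAGT"),
        ([("M", 2), ("I", 1), ("M", 2)], "4", "ACGTT", "ACTT"),
        ([("S", 2), ("M", 3)], "1G1", "TTACG", "AGG"),
    ])
    def test_hand_decoded_examples(self, cigar, md, seq, expected):
        assert decode_reference(tuple(cigar), md, seq) == expected

    @pytest.mark.parametrize("cigar,md,seq", [
        ([("M", 4)], "5", "ACGT"),         # run overruns columns
        ([("M", 4)], "2", "ACGT"),         # run underruns columns
        ([("M", 4)], "2^A2", "ACGT"),      # deletion where CIGAR has none
        ([("M", 2), ("D", 1), ("M", 2)], "5", "ACGT"),  # match over D col
        ([("M", 4)], "A2A", "ACGT"),       # violates the MD grammar
    ])
    def test_inconsistent_md_raises(self, cigar, md, seq):
        with pytest.raises(MdError):
            decode_reference(tuple(cigar), md, seq)

    def test_padding_rejected(self):
        with pytest.raises(UnsupportedCigarError):
            decode_reference((("M", 2), ("P", 1), ("M", 2)), "4", "ACGT")


class TestExtractReadVariants:
    def test_reference_identical_read_yields_nothing(self):
        assert extract_read_variants(
            make_read(100, [("M", 4)], "4", "ACGT")) == set()

    def test_snv_position_and_quality(self):
        out = extract_read_variants(
            make_read(100, [("M", 4)], "2A1", "ACGT",
                      quals=(30, 30, 25, 30)))
        assert out == {Variant("chr1", 102, SNV, "A", "G", quals=(25,))}
        (v,) = out
        assert v.quals == (25,)

    def test_insertion_left_anchored(self):
        out = extract_read_variants(
            make_read(100, [("M", 2), ("I", 1), ("M", 2)], "4", "ACGTT",
                      quals=(30, 30, 18, 30, 30)))
        assert out == {Variant("chr1", 101, INS, "-", "G", quals=(18,))}
        (v,) = out
        assert v.quals == (18,)

    def test_deletion_of_md_denoted_bases(self):
        out = extract_read_variants(
            make_read(100, [("M", 2), ("D", 1), ("M", 2)], "2^A2", "ACGT"))
        assert out == {Variant("chr1", 102, DEL, "A", "-")}

    def test_soft_clips_do_not_shift_coordinates(self):
        out = extract_read_variants(
            make_read(100, [("S", 3), ("M", 4), ("S", 2)], "2A1",
                      "TTTACGTGG"))
        assert out == {
            Variant("chr1", 102, SNV, "A", "G", quals=(30,))}

    def test_multi_base_deletion_is_one_event(self):
        out = extract_read_variants(
            make_read(100, [("M", 2), ("D", 3), ("M", 2)], "2^ACA2",
                      "GGTT"))
        assert out == {Variant("chr1", 102, DEL, "ACA", "-")}

    def test_missing_md_directs_user_to_calmd(self):
        with pytest.raises(MdError, match="calmd"):
            extract_read_variants(make_read(100, [("M", 4)], None, "ACGT"))

    def test_unmapped_read_is_a_contract_violation(self):
        with pytest.raises(ValueError, match="unmapped"):
            extract_read_variants(
                make_read(100, [("M", 4)], "4", "ACGT", is_unmapped=True))


def random_alignment(rng: Random):
    """A random (reference, cigar, read seq) triple plus its MD tag."""
    ref = "".join(rng.choice("ACGT") for _ in range(400))
    pos = rng.randint(0, 100)
    cigar = []
    seq = []
    rp = pos
    if rng.random() < 0.3:
        n = rng.randint(1, 5)
        cigar.append(("S", n))
        seq.extend(rng.choice("ACGT") for _ in range(n))
    n_ops = rng.randint(1, 6)
    for k in range(n_ops):
        op = "M" if k % 2 == 0 else rng.choice("MID")
        n = rng.randint(1, 8)
        if op == "M":
            for _ in range(n):
                base = ref[rp]
                if rng.random() < 0.15:  # mismatch
                    base = rng.choice([b for b in "ACGT" if b != ref[rp]])
                seq.append(base)
                rp += 1
            cigar.append(("M", n))
        elif op == "I":
            seq.extend(rng.choice("ACGT") for _ in range(n))
            cigar.append(("I", n))
        else:
            cigar.append(("D", n))
            rp += n
    if cigar[-1][0] != "M":  # alignments must end on an aligned column
        cigar.append(("M", 2))
        seq.extend(ref[rp:rp + 2])
        rp += 2
    if rng.random() < 0.3:
        n = rng.randint(1, 5)
        cigar.append(("S", n))
        seq.extend(rng.choice("ACGT") for _ in range(n))
    # merge adjacent same-op runs (e.g. M followed by M)
    merged = []
    for op, n in cigar:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    seq = "".join(seq)
    md = md_tag(merged, seq, ref, pos)
    return ref, pos, tuple(merged), seq, md


class TestRandomizedRoundTrips:
    def test_decode_recovers_reference_and_md_round_trips(self):
        rng = Random(20240117)
        for _ in range(300):
            ref, pos, cigar, seq, md = random_alignment(rng)
            decoded = decode_reference(cigar, md, seq)
            span = sum(n for op, n in cigar if op in "MD")
            assert decoded == ref[pos:pos + span]
            # re-encoding the decoded reference reproduces the MD string
            assert md_tag(list(cigar), seq, "N" * pos + decoded, pos) == md

    def test_variant_counts_match_md_and_cigar_structure(self):
        rng = Random(987)
        for _ in range(300):
            ref, pos, cigar, seq, md = random_alignment(rng)
            read = make_read(pos, cigar, md, seq)
            variants = extract_read_variants(read)
            n_snv = sum(1 for v in variants if v.kind == SNV)
            n_ins = sum(1 for v in variants if v.kind == INS)
            n_del = sum(1 for v in variants if v.kind == DEL)
            mismatch_letters = len(re.findall(r"(?<!\^)[A-Z]",
                                              re.sub(r"\^[A-Z]+", "^", md)))
            assert n_snv == mismatch_letters
            assert n_del == md.count("^")
            assert n_ins == sum(1 for op, _ in cigar if op == "I")
            for v in variants:  # Variant invariants hold by construction
                assert v.chrom == "chr1"
                assert pos <= v.pos


class TestVariantWithinAmplicon:
    AMP = Amplicon("chr1", 100, 250, "a")

    @pytest.mark.parametrize("variant,expected", [
        (Variant("chr1", 150, SNV, "A", "G", quals=(1,)), True),
        (Variant("chr1", 99, SNV, "A", "G", quals=(1,)), False),  # primer
        (Variant("chr1", 100, SNV, "A", "G", quals=(1,)), True),
        (Variant("chr1", 249, SNV, "A", "G", quals=(1,)), True),
        (Variant("chr1", 250, SNV, "A", "G", quals=(1,)), False),
        (Variant("chr1", 248, DEL, "AAA", "-"), False),  # runs past end
        (Variant("chr1", 247, DEL, "AAA", "-"), True),
        (Variant("chr1", 248, INS, "-", "T", quals=(1,)), True),
        (Variant("chr1", 249, INS, "-", "T", quals=(1,)), False),  # edge
        (Variant("chr2", 150, SNV, "A", "G", quals=(1,)), False),
    ])
    def test_footprint_rule(self, variant, expected):
        assert variant_within_amplicon(variant, self.AMP) is expected
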