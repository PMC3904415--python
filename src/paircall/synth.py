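"""Synthetic short-insert amplicon datasets with known ground truth.

Emulates the sequencing regime the caller is designed for: every library
molecule is one PCR amplicon whose insert is shorter than the read length,
so both mates of a pair read the entire insert (plus the flanking primer
sequence) in opposite orientations.  Mates share the template content of
their molecule; sequencing errors are injected independently per mate, so a
single-read error can never be pair-concordant by construction.

The generator writes a random reference FASTA, a BED file of insert
intervals, and a coordinate-sorted, indexed BAM with correct CIGAR and MD
tags — and returns an exact truth table of concordant read-pair counts per
planted variant, computed from its own bookkeeping during generation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from random import Random
from typing import Optional

import pysam

from .alignment import DEL, GAP, INS, SNV, Variant
from .calling import CallRecord, Thresholds
from .regions import Amplicon, write_target_regions

logger = logging.getLogger(__name__)

BASES = "ACGT"

_FLAG_MATE1 = 0x1 | 0x2 | 0x20 | 0x40  # paired, proper, mate reverse, first
_FLAG_MATE2 = 0x1 | 0x2 | 0x10 | 0x80  # paired, proper, reverse, second


class FixtureConfigError(ValueError):
    """The fixture configuration is internally inconsistent."""


@dataclass(frozen=True)
class PlantedSpec:
    """A variant to plant, positioned relative to its amplicon's insert.

    ``offset`` is 0-based within the insert; the concrete reference allele
    is resolved against the generated reference.  ``allele_fraction`` is the
    per-pair probability that the molecule carries the alternate allele
    (0.5 emulates a heterozygous germline variant, 1.0 a homozygous one).
    """

    amplicon_index: int
    kind: str
    offset: int
    allele_fraction: float
    alt: Optional[str] = None  # SNV: alt base; INS: inserted bases
    length: int = 1            # DEL: number of deleted reference bases

    def __post_init__(self) -> None:
        if self.kind not in (SNV, INS, DEL):
            raise FixtureConfigError(f"unknown variant kind {self.kind!r}")
        if not 0.0 <= self.allele_fraction <= 1.0:
            raise FixtureConfigError("allele_fraction outside [0, 1]")
        if self.kind == DEL and self.length < 1:
            raise FixtureConfigError("deletion length must be >= 1")


@dataclass(frozen=True)
class QualityProfile:
    """Constant or two-point base-quality model (Phred scale).

    With ``low_fraction`` 0 every base gets ``high``; otherwise each base
    independently gets ``low`` with that probability.
    """

    high: int = 38
    low: int = 12
    low_fraction: float = 0.0

    def sample(self, rng: Random, n: int) -> list[int]:
        if self.low_fraction <= 0.0:
            return [self.high] * n
        return [self.low if rng.random() < self.low_fraction else self.high
                for _ in range(n)]


@dataclass
class FixtureConfig:
    """Study conditions for one synthetic dataset.

    Defaults model a multiplexed amplicon design read on a 150-base
    paired-end chemistry: 100 bp inserts flanked by 20 bp primers, 50
    read-pairs per amplicon, error-free unless stated.  A mate's aligned
    span is the full 140 bp amplicon region, so its overlap fraction with
    the insert is 100/140 ~ 0.71 — pass ``min_overlap`` <= 0.7 when calling
    fixtures of this geometry.
    """

    seed: int = 0
    n_amplicons: int = 3
    insert_length: int = 100
    read_length: int = 150
    primer_length: int = 20
    pairs_per_amplicon: int = 50
    planted: list[PlantedSpec] = field(default_factory=list)
    per_base_error_rate: float = 0.0
    quality: QualityProfile = field(default_factory=QualityProfile)
    chrom: str = "chr1"
    gap: int = 50  # reference bases between consecutive amplicon regions

    def __post_init__(self) -> None:
        if self.insert_length > self.read_length:
            raise FixtureConfigError(
                "insert_length must not exceed read_length (the complete "
                "read-pair overlap regime)")
        if not 0.0 <= self.per_base_error_rate <= 1.0:
            raise FixtureConfigError("per_base_error_rate outside [0, 1]")
        if self.n_amplicons < 1 or self.pairs_per_amplicon < 0:
            raise FixtureConfigError("need >= 1 amplicon, >= 0 pairs")
        region = self.insert_length + 2 * self.primer_length
        for i in range(self.n_amplicons):
            specs = [p for p in self.planted if p.amplicon_index == i]
            ins_total = sum(len(p.alt or "N") for p in specs
                            if p.kind == INS)
            if region + ins_total > self.read_length:
                raise FixtureConfigError(
                    f"amplicon {i}: region ({region} bp) plus planted "
                    f"insertions ({ins_total} bp) exceeds read_length "
                    f"{self.read_length}")
        for p in self.planted:
            if not 0 <= p.amplicon_index < self.n_amplicons:
                raise FixtureConfigError(
                    f"planted amplicon_index {p.amplicon_index} out of "
                    "range")
            end = p.offset + (p.length if p.kind == DEL else 1)
            limit = self.insert_length - 1 if p.kind == INS \
                else self.insert_length
            if p.offset < 0 or end > limit:
                raise FixtureConfigError(
                    f"planted {p.kind} at insert offset {p.offset} falls "
                    "outside the amplicon insert")

    @property
    def region_length(self) -> int:
        return self.insert_length + 2 * self.primer_length


@dataclass(frozen=True)
class TruthEntry:
    """One planted variant with its exact concordant-pair count."""

    amplicon: Amplicon
    variant: Variant
    pair_count: int
    total_pairs: int


@dataclass
class Fixture:
    """Paths and ground truth of one generated dataset."""

    config: FixtureConfig
    reference_path: Path
    regions_path: Path
    bam_path: Path
    reference: str
    amplicons: list[Amplicon]
    truth: list[TruthEntry]


def _resolve_planted(config: FixtureConfig, reference: str,
                     amplicons: list[Amplicon], rng: Random
                     ) -> dict[int, list[tuple[Variant, float]]]:
    """Turn insert-relative specs into concrete Variants, per amplicon."""
    per_amp: dict[int, list[tuple[Variant, float]]] = {
        i: [] for i in range(config.n_amplicons)}
    for spec in config.planted:
        ins_start = amplicons[spec.amplicon_index].start
        pos = ins_start + spec.offset
        if spec.kind == SNV:
            ref_base = reference[pos]
            alt = spec.alt or rng.choice(
                [b for b in BASES if b != ref_base])
            if alt == ref_base:
                raise FixtureConfigError(
                    f"planted SNV alt {alt!r} equals reference base at "
                    f"{pos}")
            v = Variant(config.chrom, pos, SNV, ref_base, alt, quals=(0,))
        elif spec.kind == INS:
            alt = spec.alt or rng.choice(BASES)
            v = Variant(config.chrom, pos, INS, GAP, alt,
                        quals=(0,) * len(alt))
        else:
            ref_bases = reference[pos:pos + spec.length]
            v = Variant(config.chrom, pos, DEL, ref_bases, GAP)
        per_amp[spec.amplicon_index].append((v, spec.allele_fraction))
    for i, entries in per_amp.items():
        entries.sort(key=lambda e: e[0].pos)
        prev_end = -1
        for v, _ in entries:
            start = v.pos
            end = v.pos + (1 if v.kind == INS else len(v.ref))
            if start < prev_end:
                raise FixtureConfigError(
                    f"amplicon {i}: planted variant footprints overlap")
            prev_end = end
    return per_amp


def _build_template(reference: str, reg_start: int, reg_end: int,
                    variants: list[tuple[Variant, bool]]
                    ) -> tuple[str, list[list], dict, dict]:
    """Apply the carried variants to the region, producing the molecule.

    Returns (template sequence, CIGAR runs, SNV column map, alt column
    map).  The SNV column map locates every planted SNV's position in the
    template whether or not the allele was applied (needed for exact truth
    accounting: an error could recreate the alt on a non-carrier pair); the
    alt column map lists the template columns holding an applied variant's
    alternate bases.
    """
    seq: list[str] = []
    runs: list[list] = []

    def add(op: str, n: int) -> None:
        if n <= 0:
            return
        if runs and runs[-1][0] == op:
            runs[-1][1] += n
        else:
            runs.append([op, n])

    snv_col: dict[Variant, int] = {}
    alt_cols: dict[Variant, list[int]] = {}
    cur = reg_start
    for v, applied in variants:
        if v.kind == SNV:
            pre = reference[cur:v.pos]
            seq.extend(pre)
            add("M", len(pre))
            col = len(seq)
            seq.append(v.alt if applied else reference[v.pos])
            add("M", 1)
            snv_col[v] = col
            if applied:
                alt_cols[v] = [col]
            cur = v.pos + 1
        elif v.kind == DEL:
            pre = reference[cur:v.pos]
            seq.extend(pre)
            add("M", len(pre))
            if applied:
                add("D", len(v.ref))
            else:
                seq.extend(reference[v.pos:v.pos + len(v.ref)])
                add("M", len(v.ref))
            cur = v.pos + len(v.ref)
        else:  # INS, anchored left: insert after reference base v.pos
            pre = reference[cur:v.pos + 1]
            seq.extend(pre)
            add("M", len(pre))
            if applied:
                cols = list(range(len(seq), len(seq) + len(v.alt)))
                seq.extend(v.alt)
                add("I", len(v.alt))
                alt_cols[v] = cols
            cur = v.pos + 1
    tail = reference[cur:reg_end]
    seq.extend(tail)
    add("M", len(tail))
    return "".join(seq), runs, snv_col, alt_cols


def md_tag(cigar: list, seq: str, reference: str, ref_start: int) -> str:
    """Build the MD optional field for an alignment against the reference.

    Walks the CIGAR comparing read bases with reference bases; emits match
    run lengths, mismatched reference bases, and '^'-prefixed deleted runs,
    in the standard grammar (a count, possibly 0, between any two
    non-count tokens and at both ends).
    """
    parts: list[str] = []
    match = 0
    rp = ref_start
    rd = 0
    for op, n in cigar:
        if op in "M=X":
            for _ in range(n):
                if seq[rd] == reference[rp]:
                    match += 1
                else:
                    parts.append(str(match))
                    parts.append(reference[rp])
                    match = 0
                rd += 1
                rp += 1
        elif op in "IS":
            rd += n
        elif op == "D":
            parts.append(str(match))
            match = 0
            parts.append("^" + reference[rp:rp + n])
            rp += n
        elif op == "N":
            rp += n
    parts.append(str(match))
    return "".join(parts)


def _edit_distance(cigar: list, seq: str, reference: str,
                   ref_start: int) -> int:
    nm = 0
    rp = ref_start
    rd = 0
    for op, n in cigar:
        if op in "M=X":
            nm += sum(1 for i in range(n)
                      if seq[rd + i] != reference[rp + i])
            rd += n
            rp += n
        elif op == "I":
            nm += n
            rd += n
        elif op == "S":
            rd += n
        elif op == "D":
            nm += n
            rp += n
        elif op == "N":
            rp += n
    return nm


def _inject_errors(seq: list[str], rate: float, rng: Random) -> set[int]:
    """Mutate bases in place at the given per-base rate; return hit sites."""
    hit: set[int] = set()
    if rate <= 0.0:
        return hit
    for i in range(len(seq)):
        if rng.random() < rate:
            seq[i] = rng.choice([b for b in BASES if b != seq[i]])
            hit.add(i)
    return hit


def _layout(config: FixtureConfig, rng: Random
            ) -> tuple[str, list[Amplicon], list[int]]:
    """Draw the reference and lay amplicon regions along it."""
    region_len = config.region_length
    amplicons: list[Amplicon] = []
    region_starts: list[int] = []
    cursor = config.gap
    for i in range(config.n_amplicons):
        region_starts.append(cursor)
        ins_start = cursor + config.primer_length
        amplicons.append(Amplicon(
            config.chrom, ins_start, ins_start + config.insert_length,
            f"amp{i:02d}"))
        cursor += region_len + config.gap
    reference = "".join(rng.choice(BASES) for _ in range(cursor))
    return reference, amplicons, region_starts


def _write_sample_bam(config: FixtureConfig, reference: str,
                      amplicons: list[Amplicon], region_starts: list[int],
                      per_amp: dict, rng: Random, bam_path: Path
                      ) -> list[TruthEntry]:
    """Simulate one sample's read-pairs into a sorted, indexed BAM.

    Returns the exact truth table for this sample.
    """
    region_len = config.region_length
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": config.chrom, "LN": len(reference)}],
    }
    support: dict[tuple[int, Variant], int] = {
        (i, v): 0 for i in per_amp for v, _ in per_amp[i]}

    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
        for i, amplicon in enumerate(amplicons):
            reg_s = region_starts[i]
            reg_e = reg_s + region_len
            planted_here = per_amp[i]
            for j in range(config.pairs_per_amplicon):
                qname = f"{amplicon.name}.pair{j:04d}"
                carried = [(v, rng.random() < af) for v, af in planted_here]
                template, runs, snv_col, alt_cols = _build_template(
                    reference, reg_s, reg_e, carried)
                filler_len = config.read_length - len(template)

                # mate 1 (forward): template then right soft clip
                seq1 = list(template) + [rng.choice(BASES)
                                         for _ in range(filler_len)]
                cigar1 = [list(r) for r in runs]
                if filler_len:
                    cigar1.append(["S", filler_len])
                _inject_errors(seq1, config.per_base_error_rate, rng)
                # mate 2 (reverse-oriented): left soft clip then template
                seq2 = [rng.choice(BASES) for _ in range(filler_len)] \
                    + list(template)
                cigar2 = ([["S", filler_len]] if filler_len else []) \
                    + [list(r) for r in runs]
                _inject_errors(seq2, config.per_base_error_rate, rng)

                # exact concordance bookkeeping
                for v, applied in carried:
                    if v.kind == SNV:
                        col = snv_col[v]
                        if seq1[col] == v.alt and \
                                seq2[filler_len + col] == v.alt:
                            support[(i, v)] += 1
                    elif v.kind == INS:
                        if applied and all(
                                seq1[c] == v.alt[k]
                                and seq2[filler_len + c] == v.alt[k]
                                for k, c in enumerate(alt_cols[v])):
                            support[(i, v)] += 1
                    else:  # DEL: substitution errors cannot unmake it
                        if applied:
                            support[(i, v)] += 1

                for flag, cig in ((_FLAG_MATE1, cigar1),
                                  (_FLAG_MATE2, cigar2)):
                    rec = pysam.AlignedSegment()
                    rec.query_name = qname
                    rec.flag = flag
                    rec.reference_id = 0
                    rec.reference_start = reg_s
                    rec.mapping_quality = 60
                    rec.cigartuples = [
                        ("MIDNSHP=X".index(op), n) for op, n in cig]
                    seq_str = "".join(seq1 if flag == _FLAG_MATE1 else seq2)
                    rec.query_sequence = seq_str
                    rec.query_qualities = config.quality.sample(
                        rng, len(seq_str))
                    rec.next_reference_id = 0
                    rec.next_reference_start = reg_s
                    rec.template_length = (reg_e - reg_s) * \
                        (1 if flag == _FLAG_MATE1 else -1)
                    rec.set_tag("MD", md_tag(cig, seq_str, reference,
                                             reg_s))
                    rec.set_tag("NM", _edit_distance(cig, seq_str,
                                                     reference, reg_s))
                    bam.write(rec)
    pysam.index(str(bam_path))
    return [
        TruthEntry(amplicon=amplicons[i], variant=v,
                   pair_count=support[(i, v)],
                   total_pairs=config.pairs_per_amplicon)
        for i in per_amp for v, _ in per_amp[i]
    ]


def _write_reference(config: FixtureConfig, reference: str,
                     outdir: Path) -> Path:
    reference_path = outdir / "reference.fasta"
    with open(reference_path, "wt", encoding="utf-8") as fasta:
        fasta.write(f">{config.chrom}\n")
        for k in range(0, len(reference), 60):
            fasta.write(reference[k:k + 60] + "\n")
    return reference_path


def generate_fixture(config: FixtureConfig, outdir) -> Fixture:
    """Generate reference, regions, aligned pairs and the exact truth table.

    Both mates of a pair share the molecule's template (reference with the
    pair's drawn alleles applied) and are aligned over the full amplicon
    region; read bases beyond the template (read-through into the adapter)
    are soft-clipped — at the right end of the forward mate and the left
    end of the reverse-oriented mate.  Sequencing errors are independent
    substitutions per mate.  The truth table's concordant count for a
    variant is exact: for SNVs it counts pairs whose *final* base at the
    variant column equals the alternate allele on both mates (so an error
    destroying — or, however unlikely, recreating — the allele is accounted
    for); insertions require the applied allele to survive untouched on
    both mates; deletions are structural and substitution errors cannot
    affect them.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = Random(config.seed)
    reference, amplicons, region_starts = _layout(config, rng)
    per_amp = _resolve_planted(config, reference, amplicons, rng)
    bam_path = outdir / "reads.bam"
    truth = _write_sample_bam(config, reference, amplicons, region_starts,
                              per_amp, rng, bam_path)
    reference_path = _write_reference(config, reference, outdir)
    regions_path = outdir / "regions.bed"
    write_target_regions(amplicons, regions_path)
    logger.info("generated fixture: %d amplicons x %d pairs, %d planted "
                "variants", config.n_amplicons, config.pairs_per_amplicon,
                len(truth))
    return Fixture(config=config, reference_path=reference_path,
                   regions_path=regions_path, bam_path=bam_path,
                   reference=reference, amplicons=amplicons, truth=truth)


@dataclass
class CohortFixture:
    """Several samples' BAMs simulated against one shared reference."""

    config: FixtureConfig
    reference_path: Path
    regions_path: Path
    reference: str
    amplicons: list[Amplicon]
    bam_paths: dict[str, Path]
    truths: dict[str, list[TruthEntry]]


def generate_cohort(config: FixtureConfig, outdir,
                    sample_names: list[str]) -> CohortFixture:
    """Simulate a cohort: one reference and region set, one BAM per sample.

    The reference, amplicons and planted-variant resolution are drawn from
    ``config.seed``; each sample's molecules and errors come from an
    independent stream derived from the seed and the sample index, so the
    same planted alleles segregate independently across samples (as
    germline variants do across unrelated carriers).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = Random(config.seed)
    reference, amplicons, region_starts = _layout(config, rng)
    per_amp = _resolve_planted(config, reference, amplicons, rng)
    reference_path = _write_reference(config, reference, outdir)
    regions_path = outdir / "regions.bed"
    write_target_regions(amplicons, regions_path)
    bam_paths: dict[str, Path] = {}
    truths: dict[str, list[TruthEntry]] = {}
    for idx, sample in enumerate(sample_names):
        sample_rng = Random((config.seed * 1000003 + 7919 * idx + 1)
                            % 2**31)
        bam_path = outdir / f"{sample}.bam"
        truths[sample] = _write_sample_bam(
            config, reference, amplicons, region_starts, per_amp,
            sample_rng, bam_path)
        bam_paths[sample] = bam_path
    return CohortFixture(config=config, reference_path=reference_path,
                         regions_path=regions_path, reference=reference,
                         amplicons=amplicons, bam_paths=bam_paths,
                         truths=truths)


def truth_expected_calls(truth: list[TruthEntry], t: Thresholds,
                         sample: str) -> set[CallRecord]:
    """Apply the caller's threshold arithmetic to the exact truth counts."""
    expected: set[CallRecord] = set()
    for entry in truth:
        if entry.total_pairs == 0 or entry.pair_count == 0:
            continue
        proportion = entry.pair_count / entry.total_pairs
        if entry.pair_count >= t.absthresh and \
                proportion >= t.proportionthresh:
            expected.add(CallRecord(
                sample=sample, variant=entry.variant,
                pair_count=entry.pair_count,
                total_pairs=entry.total_pairs, proportion=proportion,
                amplicon_name=entry.amplicon.name))
    return expected
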