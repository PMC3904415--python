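"""The concordance-calling core: pair mates, intersect their variant sets,
filter by quality and amplicon bounds, tally, and apply read-pair thresholds.

Evidence unit is the read-pair: a variant contributes only when it is seen
identically in *both* mates of a pair, which suppresses sequencing-chemistry
errors (an error would have to recur at the same position with the same
allele on both mates).  Per amplicon, the number of concordant supporting
pairs and the proportion of all assigned pairs are then compared with an
absolute and a proportional threshold.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pysam

from .alignment import DEL, AlignedRead, Variant, extract_read_variants, \
    variant_within_amplicon
from .regions import Amplicon, GenomicInterval, pair_assigned_to_amplicon

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    """Filtering parameters for a calling run.

    absthresh
        Minimum number of concordant read-pairs supporting a variant.
    proportionthresh
        Minimum fraction of the amplicon's assigned read-pairs that must
        concordantly carry the variant.
    qualthresh
        Optional minimum Phred base quality; when set, an SNV or insertion
        counts for a pair only if every supporting base quality in *both*
        mates is at or above it (deletions carry no base qualities and are
        exempt).
    min_overlap
        Fraction of a mate's aligned span that must fall inside the insert
        interval for the pair to be assigned to the amplicon.
    """

    absthresh: int = 2
    proportionthresh: float = 0.15
    qualthresh: Optional[int] = None
    min_overlap: float = 0.9

    def __post_init__(self) -> None:
        if self.absthresh < 0:
            raise ValueError("absthresh must be non-negative")
        if not 0.0 <= self.proportionthresh <= 1.0:
            raise ValueError("proportionthresh must be in [0, 1]")
        if self.qualthresh is not None and self.qualthresh < 0:
            raise ValueError("qualthresh must be non-negative")
        if not 0.0 <= self.min_overlap <= 1.0:
            raise ValueError("min_overlap must be in [0, 1]")


@dataclass
class AmpliconTally:
    """Per-amplicon concordant read-pair counts."""

    amplicon: Amplicon
    counts: dict[Variant, int] = field(default_factory=dict)
    total_pairs: int = 0


@dataclass(frozen=True)
class CallRecord:
    """One emitted call: a variant that passed both read-pair thresholds."""

    sample: str
    variant: Variant
    pair_count: int
    total_pairs: int
    proportion: float
    amplicon_name: str


def _span(read: AlignedRead) -> GenomicInterval:
    return GenomicInterval(read.chrom, read.pos, read.reference_end)


def collect_pairs(
    reads: Iterable[AlignedRead],
    amplicon: Amplicon,
    min_overlap: float,
    stats: Optional[dict] = None,
) -> list[tuple[AlignedRead, AlignedRead]]:
    """Group fetched reads into mate pairs assigned to the amplicon.

    Keeps only groups of exactly two primary, mapped, paired reads on the
    same chromosome whose spans both satisfy the overlap fraction.
    Singletons, secondary/supplementary records and over-full name groups
    are discarded and counted (in ``stats`` when given), never raised.
    """
    if stats is None:
        stats = {}
    groups: dict[str, list[AlignedRead]] = defaultdict(list)
    for read in reads:
        if read.is_secondary_or_supplementary:
            stats["secondary_or_supplementary"] = \
                stats.get("secondary_or_supplementary", 0) + 1
            continue
        if read.is_unmapped or not read.is_paired or not read.mate_mapped:
            stats["unpaired_or_unmapped"] = \
                stats.get("unpaired_or_unmapped", 0) + 1
            continue
        groups[read.qname].append(read)

    pairs: list[tuple[AlignedRead, AlignedRead]] = []
    for qname, members in groups.items():
        if len(members) == 1:
            stats["singletons"] = stats.get("singletons", 0) + 1
            continue
        if len(members) > 2:
            stats["overfull_groups"] = stats.get("overfull_groups", 0) + 1
            logger.debug("read name %s has %d primary records; skipped",
                         qname, len(members))
            continue
        r1, r2 = members
        if r1.chrom != r2.chrom:
            stats["cross_chrom_pairs"] = \
                stats.get("cross_chrom_pairs", 0) + 1
            continue
        if pair_assigned_to_amplicon(_span(r1), _span(r2), amplicon,
                                     min_overlap):
            pairs.append((r1, r2))
        else:
            stats["insufficient_overlap"] = \
                stats.get("insufficient_overlap", 0) + 1
    return pairs


def concordant_variants(
    v1: set[Variant],
    v2: set[Variant],
    qualthresh: Optional[int] = None,
) -> set[Variant]:
    """Variants present identically in both mates, quality-filtered.

    The intersection is by variant identity (chrom, pos, kind, ref, alt).
    With ``qualthresh`` set, an SNV or insertion survives only if every
    supporting base quality in *both* mates' copies meets the threshold;
    deletions are exempt.
    """
    by_id_2 = {v: v for v in v2}
    out: set[Variant] = set()
    for a in v1:
        b = by_id_2.get(a)
        if b is None:
            continue
        if qualthresh is not None and a.kind != DEL:
            if any(q < qualthresh for q in a.quals) or \
                    any(q < qualthresh for q in b.quals):
                continue
        out.add(a)
    return out


def tally_amplicon(
    pairs: list[tuple[AlignedRead, AlignedRead]],
    amplicon: Amplicon,
    qualthresh: Optional[int] = None,
) -> AmpliconTally:
    """Count concordant, in-bounds variants across the amplicon's pairs.

    Each pair increments each of its surviving variants by exactly one;
    ``total_pairs`` counts every assigned pair, including pairs contributing
    no variants.
    """
    tally = AmpliconTally(amplicon=amplicon, total_pairs=len(pairs))
    for r1, r2 in pairs:
        shared = concordant_variants(
            extract_read_variants(r1), extract_read_variants(r2), qualthresh
        )
        for v in shared:
            if variant_within_amplicon(v, amplicon):
                tally.counts[v] = tally.counts.get(v, 0) + 1
    return tally


def apply_thresholds(
    tally: AmpliconTally, t: Thresholds, sample: str
) -> set[CallRecord]:
    """Emit a call for every variant meeting both read-pair thresholds.

    Both thresholds are inclusive; nothing is emitted for an amplicon with
    zero assigned pairs.
    """
    if tally.total_pairs == 0:
        return set()
    out: set[CallRecord] = set()
    for variant, count in tally.counts.items():
        proportion = count / tally.total_pairs
        if count >= t.absthresh and proportion >= t.proportionthresh:
            out.add(CallRecord(
                sample=sample, variant=variant, pair_count=count,
                total_pairs=tally.total_pairs, proportion=proportion,
                amplicon_name=tally.amplicon.name,
            ))
    return out


def call_variants_file(
    alignments: pysam.AlignmentFile,
    amplicons: list[Amplicon],
    t: Thresholds,
    sample: str,
    stats: Optional[dict] = None,
) -> tuple[set[CallRecord], dict[Amplicon, int]]:
    """Run the per-amplicon calling loop over one alignment file.

    Returns the union of call records across amplicons and the per-amplicon
    assigned-pair counts (the coverage report).  A region contig missing
    from the alignment header is warned about and reported with zero pairs.
    A pair satisfying the overlap criterion for several overlapping
    amplicons contributes to each of their tallies; records carry the
    amplicon name, so such duplicates remain distinguishable downstream.
    """
    try:
        alignments.check_index()
    except (ValueError, AttributeError) as exc:
        raise FileNotFoundError(
            f"{alignments.filename!r} has no index; create one with "
            "`samtools index` before calling"
        ) from exc
    if stats is None:
        stats = {}
    calls: set[CallRecord] = set()
    coverage: dict[Amplicon, int] = {}
    known = set(alignments.references)
    for amplicon in amplicons:
        if amplicon.chrom not in known:
            logger.warning(
                "amplicon %s: contig %s absent from alignment header; "
                "reported with 0 pairs", amplicon.name, amplicon.chrom,
            )
            coverage[amplicon] = 0
            continue
        fetched = (
            AlignedRead.from_pysam(rec)
            for rec in alignments.fetch(
                amplicon.chrom, amplicon.start, amplicon.end)
        )
        pairs = collect_pairs(fetched, amplicon, t.min_overlap, stats)
        tally = tally_amplicon(pairs, amplicon, t.qualthresh)
        coverage[amplicon] = tally.total_pairs
        calls |= apply_thresholds(tally, t, sample)
    stats["pairs_assigned"] = sum(coverage.values())
    stats["calls_emitted"] = len(calls)
    return calls, coverage
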