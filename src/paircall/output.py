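"""Tab-delimited writers: annotation-compatible calls and coverage reports.

Call rows use the 1-based inclusive coordinate dialect expected by common
variant-annotation tools (chromosome, start, end, ref, alt); everything
internal stays 0-based half-open, and the conversion lives only here.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

from .alignment import DEL, GAP, INS, SNV, Variant
from .calling import CallRecord
from .regions import Amplicon

CALL_HEADER = (
    "chrom", "start", "end", "ref", "alt",
    "sample", "amplicon", "pair_count", "total_pairs", "proportion",
)

COVERAGE_HEADER = ("amplicon", "chrom", "start", "end", "pairs")


def annotation_coordinates(v: Variant) -> tuple[int, int]:
    """1-based inclusive (start, end) of a variant's annotation-input row.

    SNV: start = end = pos + 1.  Deletion: start = pos + 1,
    end = pos + |ref|.  Insertion: start = end = pos + 1 with ref "-"
    (anchored at the base left of the insertion point).
    """
    start = v.pos + 1
    if v.kind == DEL:
        return start, v.pos + len(v.ref)
    return start, start


def variant_from_row(chrom: str, start: int, end: int,
                     ref: str, alt: str) -> Variant:
    """Invert :func:`annotation_coordinates` back to a Variant identity."""
    if ref == GAP:
        return Variant(chrom, start - 1, INS, GAP, alt,
                       quals=(0,) * len(alt))
    if alt == GAP:
        return Variant(chrom, start - 1, DEL, ref, GAP)
    return Variant(chrom, start - 1, SNV, ref, alt, quals=(0,))


def sort_key(record: CallRecord):
    """Deterministic output order: position, alleles, amplicon, sample.

    Chromosome order is lexicographic over names as given.
    """
    v = record.variant
    return (v.chrom, v.pos, v.ref, v.alt, record.amplicon_name,
            record.sample)


def write_calls(records: Iterable[CallRecord], path) -> None:
    """Write one header row plus one sorted row per call record.

    The proportion is formatted to 4 decimal places for byte-stable output.
    """
    rows = sorted(records, key=sort_key)
    with open(path, "wt", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(CALL_HEADER)
        for r in rows:
            v = r.variant
            start, end = annotation_coordinates(v)
            writer.writerow((
                v.chrom, start, end, v.ref, v.alt,
                r.sample, r.amplicon_name, r.pair_count, r.total_pairs,
                f"{r.proportion:.4f}",
            ))


def write_coverage(coverage: dict[Amplicon, int], coverdir, sample: str
                   ) -> Path:
    """Write ``<sample>.coverage.tsv`` with one row per amplicon.

    Rows follow region-file order (the mapping's insertion order) and
    include zero-count amplicons, so under-covered regions are visible.
    """
    coverdir = Path(coverdir)
    coverdir.mkdir(parents=True, exist_ok=True)
    out = coverdir / f"{sample}.coverage.tsv"
    with open(out, "wt", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(COVERAGE_HEADER)
        for amplicon, pairs in coverage.items():
            writer.writerow((amplicon.name, amplicon.chrom, amplicon.start,
                             amplicon.end, pairs))
    return out
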