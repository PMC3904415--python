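"""Amplicon target regions: BED parsing and read-pair-to-amplicon assignment.

An amplicon's BED record describes the primer-intervening *insert* interval
(0-based, half-open), one record per amplicon.  Read-pairs are assigned to an
amplicon when each mate's aligned reference span overlaps the insert by at
least a user-chosen fraction of the mate's own span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from os import PathLike
from typing import Iterable, Union

logger = logging.getLogger(__name__)

_SKIP_PREFIXES = ("track", "browser", "#")


class RegionFileError(ValueError):
    """A malformed line in the target-region (BED) file."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based, half-open interval on a named contig."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Amplicon:
    """One target region: the insert interval between the two primers.

    ``start``/``end`` are 0-based half-open coordinates of the insert
    (primer-intervening) sequence; ``name`` is a free-text label.
    """

    chrom: str
    start: int
    end: int
    name: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"amplicon {self.name!r}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if not self.name:
            raise ValueError("amplicon name must be non-empty")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


def parse_target_regions(path: Union[str, PathLike]) -> list[Amplicon]:
    """Parse a BED file of amplicon insert intervals.

    Lines starting with ``track``, ``browser`` or ``#`` and blank lines are
    skipped.  Each data line needs at least chrom, start, end; a fourth
    column, when present, is the amplicon name, otherwise the name is
    synthesized as ``chrom:start-end``.  Coordinates are taken verbatim as
    0-based half-open per the BED convention.

    Raises :class:`RegionFileError` (naming the offending line number) for
    non-integer coordinates, start >= end, fewer than three columns, or a
    duplicated (chrom, start, end) triple.  An empty file yields an empty
    list with a logged warning.
    """
    amplicons: list[Amplicon] = []
    seen: set[tuple[str, int, int]] = set()
    with open(path, "rt", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise RegionFileError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated "
                    f"columns, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise RegionFileError(
                    f"{path}: line {lineno}: non-integer coordinates "
                    f"{fields[1]!r}, {fields[2]!r}"
                ) from exc
            if start >= end or start < 0:
                raise RegionFileError(
                    f"{path}: line {lineno}: invalid interval "
                    f"[{start}, {end})"
                )
            name = fields[3] if len(fields) >= 4 and fields[3] else (
                f"{chrom}:{start}-{end}"
            )
            key = (chrom, start, end)
            if key in seen:
                raise RegionFileError(
                    f"{path}: line {lineno}: duplicate region "
                    f"{chrom}:{start}-{end}"
                )
            seen.add(key)
            amplicons.append(Amplicon(chrom, start, end, name))
    if not amplicons:
        logger.warning("region file %s contains no target regions", path)
    return amplicons


def write_target_regions(amplicons: Iterable[Amplicon], path) -> None:
    """Write amplicons back out as 4-column BED (inverse of the parser)."""
    with open(path, "wt", encoding="utf-8") as handle:
        for a in amplicons:
            handle.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.name}\n")


def overlap_fraction(read: GenomicInterval, amplicon: Amplicon) -> float:
    """Fraction of the read's aligned span that lies inside the insert.

    Returns ``|read ∩ insert| / |read|``; 0.0 when the contigs differ or the
    read span is empty.  The denominator is deliberately the read's span, not
    the amplicon length: the criterion is how much of the *read* is on
    target.
    """
    if read.chrom != amplicon.chrom or len(read) == 0:
        return 0.0
    inter = min(read.end, amplicon.end) - max(read.start, amplicon.start)
    if inter <= 0:
        return 0.0
    return inter / len(read)


def pair_assigned_to_amplicon(
    read1: GenomicInterval,
    read2: GenomicInterval,
    amplicon: Amplicon,
    min_fraction: float,
) -> bool:
    """True iff *both* mates individually satisfy the overlap fraction.

    Both mates must cover the insert for the pair to be concordance-checked,
    so assignment is the conjunction of the per-mate tests.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError(f"min_fraction {min_fraction} outside [0, 1]")
    return (
        overlap_fraction(read1, amplicon) >= min_fraction
        and overlap_fraction(read2, amplicon) >= min_fraction
    )
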