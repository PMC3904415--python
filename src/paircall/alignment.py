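"""Per-read variant extraction from CIGAR + MD, without a reference file.

The MD optional field encodes, for the aligned columns of one read, the run
lengths of matches, the reference base at each mismatch, and the reference
bases of each deletion.  Together with the CIGAR string this is enough to
reconstruct the reference sequence under the alignment, so the variants a
read implies (SNVs, small insertions and deletions) can be derived from the
alignment file alone.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

import pysam

# Variant kinds
SNV = "SNV"
INS = "INS"
DEL = "DEL"

GAP = "-"

_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")
_MD_GRAMMAR = re.compile(r"^\d+((([A-Za-z])|(\^[A-Za-z]+))\d+)*$")

# CIGAR ops that consume read bases / reference bases
_CONSUMES_READ = frozenset("MIS=X")
_CONSUMES_REF = frozenset("MDN=X")
_ALIGNED = frozenset("M=X")  # columns covered by MD match/mismatch runs

_PYSAM_OPS = "MIDNSHP=X"


class MdError(ValueError):
    """MD string missing, malformed, or inconsistent with the CIGAR."""


class UnsupportedCigarError(ValueError):
    """CIGAR contains an operation this caller does not model (P)."""


@dataclass(frozen=True)
class Variant:
    """A normalized SNV, insertion or deletion implied by one read.

    ``pos`` is 0-based: for an SNV the substituted reference base, for a
    deletion the first deleted reference base, and for an insertion the
    reference base immediately *left* of the insertion point.  ``quals``
    carries the Phred qualities of the read bases forming the alternate
    allele (one per SNV base, one per inserted base, empty for deletions);
    it is excluded from identity, so tallying compares only
    (chrom, pos, kind, ref, alt).
    """

    chrom: str
    pos: int
    kind: str
    ref: str
    alt: str
    quals: tuple[int, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.kind == SNV:
            ok = (len(self.ref) == 1 and len(self.alt) == 1
                  and self.ref != self.alt and len(self.quals) == 1)
        elif self.kind == INS:
            ok = self.ref == GAP and len(self.alt) >= 1 \
                and len(self.quals) == len(self.alt)
        elif self.kind == DEL:
            ok = self.alt == GAP and len(self.ref) >= 1 and not self.quals
        else:
            ok = False
        if not ok:
            raise ValueError(f"ill-formed variant {self!r}")

    @property
    def ref_span(self) -> int:
        """Number of reference bases the variant's footprint occupies."""
        return 0 if self.kind == INS else len(self.ref)


@dataclass(frozen=True)
class AlignedRead:
    """The per-read facts needed for variant extraction.

    ``cigar`` is a tuple of (operation letter, length) pairs; ``pos`` is the
    0-based leftmost mapped reference position.
    """

    qname: str
    chrom: str
    pos: int
    cigar: tuple[tuple[str, int], ...]
    md: Optional[str]
    seq: str
    quals: tuple[int, ...]
    is_paired: bool = True
    mate_mapped: bool = True
    is_unmapped: bool = False
    is_secondary_or_supplementary: bool = False
    is_reverse: bool = False

    def __post_init__(self) -> None:
        read_len = sum(n for op, n in self.cigar if op in _CONSUMES_READ)
        if read_len != len(self.seq):
            raise ValueError(
                f"read {self.qname}: CIGAR consumes {read_len} read bases "
                f"but SEQ has {len(self.seq)}"
            )
        if len(self.quals) != len(self.seq):
            raise ValueError(f"read {self.qname}: QUAL/SEQ length mismatch")
        if self.pos < 0:
            raise ValueError(f"read {self.qname}: negative position")

    @property
    def reference_end(self) -> int:
        """0-based exclusive end of the aligned reference span."""
        return self.pos + sum(n for op, n in self.cigar if op in _CONSUMES_REF)

    @classmethod
    def from_pysam(cls, rec: pysam.AlignedSegment) -> "AlignedRead":
        cigar = tuple(
            (_PYSAM_OPS[op], n) for op, n in (rec.cigartuples or ())
        )
        md = rec.get_tag("MD") if rec.has_tag("MD") else None
        quals = tuple(rec.query_qualities) if rec.query_qualities is not None \
            else (0,) * len(rec.query_sequence or "")
        return cls(
            qname=rec.query_name,
            chrom=rec.reference_name or "",
            pos=rec.reference_start,
            cigar=cigar,
            md=md,
            seq=rec.query_sequence or "",
            quals=quals,
            is_paired=rec.is_paired,
            mate_mapped=not rec.mate_is_unmapped if rec.is_paired else False,
            is_unmapped=rec.is_unmapped,
            is_secondary_or_supplementary=rec.is_secondary
            or rec.is_supplementary,
            is_reverse=rec.is_reverse,
        )


def _md_tokens(md: str) -> list:
    """Tokenize an MD string into ints (match runs), '^'-strings (deletions)
    and single letters (mismatched reference bases)."""
    if not _MD_GRAMMAR.match(md):
        raise MdError(f"MD string {md!r} does not conform to the MD grammar")
    tokens = []
    for m in _MD_TOKEN.finditer(md):
        num, dele, mism = m.groups()
        if num is not None:
            tokens.append(int(num))
        elif dele is not None:
            tokens.append(dele)
        else:
            tokens.append(mism)
    return tokens


def decode_reference(
    cigar: tuple[tuple[str, int], ...], md: str, seq: str
) -> str:
    """Reconstruct the reference bases under the alignment from the MD field.

    Returns the reference bases of the M/=/X and D columns in reference
    order: match runs copy the read base, mismatch letters copy the MD
    letter, '^'-prefixed runs contribute the deleted reference bases.
    Inserted and soft-clipped read bases contribute nothing.

    Raises :class:`MdError` when the MD run lengths do not tile the aligned
    columns of the CIGAR.
    """
    # Lay out the aligned columns the MD string must tile: for each M/=/X
    # column the read base, for each D column a placeholder.
    columns: list[Optional[str]] = []
    read_idx = 0
    for op, n in cigar:
        if op in _ALIGNED:
            columns.extend(seq[read_idx:read_idx + n])
            read_idx += n
        elif op in "IS":
            read_idx += n
        elif op == "D":
            columns.extend([None] * n)
        elif op in "HN":
            pass
        elif op == "P":
            raise UnsupportedCigarError("padding (P) operations unsupported")
        else:
            raise UnsupportedCigarError(f"unknown CIGAR operation {op!r}")

    ref: list[str] = []
    col = 0
    for token in _md_tokens(md):
        if isinstance(token, int):
            for _ in range(token):
                if col >= len(columns) or columns[col] is None:
                    raise MdError(
                        f"MD {md!r} match run overruns aligned columns of "
                        f"CIGAR {cigar!r}"
                    )
                ref.append(columns[col])
                col += 1
        elif token.startswith("^"):
            for base in token[1:]:
                if col >= len(columns) or columns[col] is not None:
                    raise MdError(
                        f"MD {md!r} deletion run misaligned with CIGAR "
                        f"{cigar!r}"
                    )
                ref.append(base.upper())
                col += 1
        else:
            if col >= len(columns) or columns[col] is None:
                raise MdError(
                    f"MD {md!r} mismatch letter misaligned with CIGAR "
                    f"{cigar!r}"
                )
            ref.append(token.upper())
            col += 1
    if col != len(columns):
        raise MdError(
            f"MD {md!r} covers {col} columns but CIGAR {cigar!r} has "
            f"{len(columns)}"
        )
    return "".join(ref)


def extract_read_variants(read: AlignedRead) -> set[Variant]:
    """The set of variants (with supporting base qualities) one read implies.

    Walks the CIGAR with a reference cursor (starting at ``read.pos``) and a
    read cursor.  Mismatching M/=/X columns yield SNVs; each I run yields one
    insertion anchored at the reference base to its left; each D run yields
    one deletion of the MD-denoted reference bases.  Soft/hard clips advance
    only the read cursor (or neither); N advances only the reference cursor.
    """
    if read.is_unmapped:
        raise ValueError(f"read {read.qname} is unmapped")
    if not read.cigar:
        raise ValueError(f"read {read.qname} has no CIGAR")
    if read.md is None:
        raise MdError(
            f"read {read.qname} has no MD tag; regenerate it with a calmd "
            "utility (e.g. `samtools calmd`) before calling"
        )
    decoded = decode_reference(read.cigar, read.md, read.seq)

    variants: set[Variant] = set()
    ref_pos = read.pos
    read_idx = 0
    dec_idx = 0  # cursor over decoded reference (M/=/X and D columns)
    for op, n in read.cigar:
        if op in _ALIGNED:
            for _ in range(n):
                rb = read.seq[read_idx]
                refb = decoded[dec_idx]
                if rb != refb:
                    variants.add(Variant(
                        chrom=read.chrom, pos=ref_pos, kind=SNV,
                        ref=refb, alt=rb,
                        quals=(read.quals[read_idx],),
                    ))
                ref_pos += 1
                read_idx += 1
                dec_idx += 1
        elif op == "I":
            variants.add(Variant(
                chrom=read.chrom, pos=ref_pos - 1, kind=INS,
                ref=GAP, alt=read.seq[read_idx:read_idx + n],
                quals=tuple(read.quals[read_idx:read_idx + n]),
            ))
            read_idx += n
        elif op == "D":
            variants.add(Variant(
                chrom=read.chrom, pos=ref_pos, kind=DEL,
                ref=decoded[dec_idx:dec_idx + n], alt=GAP,
            ))
            ref_pos += n
            dec_idx += n
        elif op == "S":
            read_idx += n
        elif op == "N":
            ref_pos += n
        elif op == "H":
            pass
        else:
            raise UnsupportedCigarError(f"CIGAR operation {op!r} unsupported")
    return variants


def variant_within_amplicon(v: Variant, a) -> bool:
    """True iff the variant's reference footprint lies inside the insert.

    SNVs and deletions need their whole footprint in [start, end); an
    insertion anchor must be strictly interior so that both flanking insert
    bases are in bounds.  Positions in the primer regions are thereby
    clipped from calling.
    """
    if v.chrom != a.chrom:
        return False
    if v.kind == INS:
        return a.start <= v.pos < a.end - 1
    return a.start <= v.pos and v.pos + len(v.ref) <= a.end
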