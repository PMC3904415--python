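"""Naive brute-force reference caller, used only as an independent oracle.

Deliberately avoids the package's MD decoder and CIGAR walker: per-read
variants are re-derived from pysam's ``get_aligned_pairs(with_seq=True)``
(which consumes the MD tag through htslib's own machinery), and pairing,
overlap, bounds, tallying and thresholds are re-implemented here with plain
arithmetic over small in-memory lists.  Keep this module independent of
``paircall`` internals.
"""

from __future__ import annotations

from collections import defaultdict

import pysam

# Variant identity tuples: (chrom, pos0, kind, ref, alt)


def read_variants(rec: pysam.AlignedSegment) -> dict[tuple, tuple]:
    """Map variant identity -> supporting base qualities, for one read."""
    chrom = rec.reference_name
    seq = rec.query_sequence
    quals = rec.query_qualities
    qstart, qend = rec.query_alignment_start, rec.query_alignment_end
    # drop soft-clipped columns (query index outside the aligned window)
    pairs = [
        (q, r, b) for q, r, b in rec.get_aligned_pairs(with_seq=True)
        if not (q is not None and (q < qstart or q >= qend))
    ]
    variants: dict[tuple, tuple] = {}
    last_ref = rec.reference_start - 1
    i = 0
    while i < len(pairs):
        q, r, b = pairs[i]
        if q is not None and r is not None:
            if b is not None and seq[q].upper() != b.upper():
                variants[(chrom, r, "SNV", b.upper(), seq[q].upper())] = \
                    (quals[q],)
            last_ref = r
            i += 1
        elif r is None:  # insertion run (query-only columns)
            j = i
            while j < len(pairs) and pairs[j][1] is None:
                j += 1
            qidx = [pairs[k][0] for k in range(i, j)]
            alt = "".join(seq[k] for k in qidx).upper()
            variants[(chrom, last_ref, "INS", "-", alt)] = \
                tuple(quals[k] for k in qidx)
            i = j
        else:  # deletion run (reference-only columns)
            j = i
            while j < len(pairs) and pairs[j][0] is None:
                j += 1
            ref_bases = "".join(
                (pairs[k][2] or "N") for k in range(i, j)).upper()
            variants[(chrom, pairs[i][1], "DEL", ref_bases, "-")] = ()
            last_ref = pairs[j - 1][1]
            i = j
    return variants


def call(bam_path, amplicons, absthresh, proportionthresh,
         qualthresh=None, min_overlap=0.9):
    """Enumerate pairs naively and call variants; returns (calls, coverage).

    ``calls`` is a set of (identity, amplicon name, pair count, total
    pairs); ``coverage`` maps amplicon name -> assigned pair count.
    """
    calls = set()
    coverage: dict[str, int] = {}
    with pysam.AlignmentFile(str(bam_path)) as bam:
        contigs = set(bam.references)
        for amp in amplicons:
            if amp.chrom not in contigs:
                coverage[amp.name] = 0
                continue
            groups = defaultdict(list)
            for rec in bam.fetch(amp.chrom, amp.start, amp.end):
                if rec.is_secondary or rec.is_supplementary \
                        or rec.is_unmapped or not rec.is_paired \
                        or rec.mate_is_unmapped:
                    continue
                groups[rec.query_name].append(rec)
            pairs = []
            for recs in groups.values():
                if len(recs) != 2:
                    continue
                a, b = recs
                if a.reference_name != b.reference_name:
                    continue
                assigned = True
                for rec in (a, b):
                    span = rec.reference_end - rec.reference_start
                    inter = min(rec.reference_end, amp.end) - \
                        max(rec.reference_start, amp.start)
                    frac = inter / span if span > 0 and inter > 0 else 0.0
                    if frac < min_overlap:
                        assigned = False
                if assigned:
                    pairs.append((a, b))
            total = len(pairs)
            coverage[amp.name] = total
            counts: dict[tuple, int] = defaultdict(int)
            for a, b in pairs:
                va, vb = read_variants(a), read_variants(b)
                for ident in set(va) & set(vb):
                    _, pos, kind, ref, _ = ident
                    if qualthresh is not None and kind != "DEL":
                        if any(q < qualthresh for q in va[ident]) or \
                                any(q < qualthresh for q in vb[ident]):
                            continue
                    if kind == "INS":
                        if not (amp.start <= pos < amp.end - 1):
                            continue
                    elif not (amp.start <= pos
                              and pos + len(ref) <= amp.end):
                        continue
                    counts[ident] += 1
            for ident, c in counts.items():
                if total and c >= absthresh \
                        and c / total >= proportionthresh:
                    calls.add((ident, amp.name, c, total))
    return calls, coverage
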