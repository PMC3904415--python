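"""Reconstruct the reference from a read's MD tag and extract its variants.

No reference FASTA is needed: the CIGAR relates read bases to reference
positions and the MD field supplies the reference bases at mismatches and
deletions.  The read below aligns at chr1:1000 with a mismatch (read G
over reference A), a 1 bp insertion and a 2 bp deletion.
"""

from paircall import AlignedRead, decode_reference, extract_read_variants

read = AlignedRead(
    qname="demo_read",
    chrom="chr1",
    pos=1000,
    cigar=(("M", 5), ("I", 1), ("M", 3), ("D", 2), ("M", 4)),
    md="2A5^CT4",
    seq="ACGTTGACCTTTT",
    quals=(30, 30, 25, 30, 30, 18, 30, 30, 30, 30, 30, 30, 30),
)

reference = decode_reference(read.cigar, read.md, read.seq)
print(f"reference under the alignment (M and D columns): {reference}")

print("variants implied by the read:")
for v in sorted(extract_read_variants(read), key=lambda v: v.pos):
    print(f"  {v.kind:3s} at {v.chrom}:{v.pos}  {v.ref}>{v.alt}"
          f"  base qualities {list(v.quals)}")
print("positions are 0-based; the insertion is anchored at the reference "
      "base to its left; qualities are those of the alternate bases.")
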