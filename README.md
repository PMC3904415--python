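# paircall

Variant calling for short-insert, PCR-amplicon massively parallel
sequencing in which both reads of a pair completely overlap the
primer-intervening (insert) sequence.

## The problem and who this is for

Highly multiplexed PCR target-enrichment produces libraries of uniform,
short amplicons. When the insert is shorter than the read length, the two
mates of a paired-end read cover the same insert in opposite orientations,
so every insert position is sequenced twice — once per mate — from the
same physical molecule. Sequencing-chemistry errors strike the two mates
independently, so an error almost never recurs at the same position with
the same allele on both. Requiring **read-pair concordance** before a base
difference may contribute any evidence is therefore a very stringent error
filter, without the pitfalls of merging mates into a consensus read or
trimming primers by error-prone sequence matching.

`paircall` is for groups running amplicon panels (mutation screening,
gene-panel testing) who want accurate SNV and small-indel calls directly
from mapped BAM files plus the panel's design coordinates.

## Method

For each amplicon (a BED record giving the insert interval), read-pairs
are fetched from a coordinate-indexed BAM. A pair is assigned to the
amplicon when each mate's aligned span overlaps the insert by at least a
fraction *f* (`--overlap`, default 0.9). For each mate, the implied
variants are derived by walking the CIGAR string while reconstructing the
reference from the MD tag — no reference FASTA is required. Per pair, only
the **intersection** of the two mates' variant sets survives
(optionally further requiring base quality ≥ *q* in *both* mates,
`--qualthresh`); variants whose footprint leaves the insert interval are
clipped away by coordinates, removing primer-derived positions. Per
amplicon, a variant seen concordantly in *k* of *n* assigned pairs is
reported when

&nbsp;&nbsp;&nbsp;&nbsp;*k* ≥ `absthresh`  and  *k*/*n* ≥ `proportionthresh`

(defaults 2 and 0.15). Heterozygous germline variants appear at *k*/*n*
near 0.5, homozygous ones near 1.0. A per-amplicon read-pair coverage
report identifies regions needing further screening.

## Worked example

`examples/simulate_and_call.py` simulates one sample (two amplicons,
50 read-pairs each, 1% per-base error) with a planted heterozygous SNV
and a homozygous 2 bp deletion, then calls:

```
planted truth (concordant pairs / total):
  SNV at chr1:100 C>G  23/50
  DEL at chr1:320 TC>-  50/50

calls (1-based annotation coordinates):
  chr1:101-101 C>G  pairs=23/50  proportion=0.4600  amplicon=amp00
  chr1:321-322 TC>-  pairs=50/50  proportion=1.0000  amplicon=amp01

read-pair coverage per amplicon:
  amp00  chr1:70-170  50 pairs
  amp01  chr1:260-360  50 pairs
```

The heterozygous SNV is supported by 23 of 50 pairs (proportion 0.46,
consistent with one of two alleles); the homozygous deletion by all 50.
The 1% single-read errors produce no calls: none recurred on both mates.
See also `examples/decode_read_variants.py` (MD/CIGAR reference
reconstruction) and `examples/run_cli_cohort.py` (three-sample CLI run).

## Command line

```bash
paircall --primers panel.bed --log logfile.txt --out variant_calls.tsv \
         --proportionthresh 0.15 --absthresh 2 --qualthresh 20 \
         --coverdir coverage_dir sampleX.bam sampleY.bam sampleZ.bam
```

writes one combined call file (columns: chrom, start, end, ref, alt in
1-based inclusive annotation-input convention, then sample, amplicon,
pair_count, total_pairs, proportion) and one
`<sample>.coverage.tsv` per input BAM. Exit status: 0 success, 1 usage
error, 2 runtime error.

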