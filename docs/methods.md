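# Methods

## Model and assumptions

The caller targets the *complete read-pair overlap* regime of amplicon
sequencing: library inserts are shorter than the read length, so both
mates of a pair read the entire insert from the same template molecule.
Under this model:

- The two mates agree on every true allele of the molecule (including
  PCR-polymerase misincorporations, which occur before sequencing and are
  copied into both mates).
- Sequencing-chemistry errors are independent between mates; a
  concordant false signal requires the same substitution at the same
  position on both mates of one pair, probability ≈ (e/3)² per site per
  pair at per-base error rate e (~10⁻⁵ at e = 1%).
- Residual concordant noise (polymerase error in early PCR cycles) is
  suppressed by the read-pair count and proportion thresholds: germline
  alleles appear in ≈50% or 100% of pairs, early-cycle artifacts in far
  fewer.

The unit of evidence is therefore the read-pair, not the read. Evidence
never crosses pairs except through the final tally.

## Procedure

1. **Region file.** Each BED record is the insert (primer-intervening)
   interval of one amplicon, 0-based half-open; one record per amplicon.
2. **Pair assignment.** Reads fetched over the insert are grouped by
   query name; only groups of exactly two primary, mapped, paired records
   on one contig survive. Each mate's aligned reference span must overlap
   the insert by ≥ `min_overlap` of the *mate's own span* (both mates
   individually — a pair that cannot be concordance-checked across the
   insert is useless). A pair may satisfy this for several overlapping
   amplicons and then contributes to each tally independently; records
   carry the amplicon name so downstream consumers can reconcile.
3. **Per-read variants.** The reference under the alignment is
   reconstructed from the MD tag (match runs copy the read base, mismatch
   letters and `^`-runs copy MD letters) and walked in lockstep with the
   CIGAR. Mismatching aligned columns yield SNVs; each `I` run yields one
   insertion anchored at the reference base to its left; each `D` run
   yields one deletion event. Reads without MD are rejected with a
   pointer to `samtools calmd` rather than silently re-deriving from a
   reference, preserving the BAM-only property. `N` advances the
   reference only; `P` is rejected loudly (neither occurs in amplicon
   data).
4. **Concordance.** Per pair, the identity-intersection (chrom, pos,
   kind, ref, alt) of the mates' variant sets; with `qualthresh` set,
   every supporting base of an SNV or insertion must meet it in *both*
   mates (strictest reading of multi-base alleles; deletions carry no
   base qualities and are exempt).
5. **Bounds filter.** A surviving variant's reference footprint must lie
   inside the insert interval (insertion anchors strictly interior), so
   primer-region positions are clipped by coordinates, never by sequence
   matching.
6. **Thresholds.** With k concordant pairs of n assigned: call iff
   k ≥ `absthresh` and k/n ≥ `proportionthresh`, both inclusive. The
   denominator is *all* assigned pairs, including pairs contributing no
   variants and pairs whose variants failed the quality filter, because
   pairs are counted at fetch time, before per-variant filtering.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `absthresh` | 2 | min concordant read-pairs per variant |
| `proportionthresh` | 0.15 | min fraction of assigned pairs |
| `qualthresh` | off | min Phred quality in both mates (SNV/INS) |
| `min_overlap` | 0.9 | per-mate on-insert aligned fraction |

The 2 / 0.15 / 20 operating point is the documented default for germline
screening. `min_overlap` must be chosen against the panel geometry: when
primers map inside the reads (the usual case), a mate's span is
insert + 2·primer, so e.g. 100 bp inserts with 20 bp primers give a
maximum attainable fraction of 100/140 ≈ 0.71 and a threshold of 0.7 is
appropriate; the 0.9 default suits designs whose primer share is under
5% per side or pipelines that hard-clip primers upstream.

## Synthetic data generator

`paircall.synth` emulates the overlap regime: per amplicon region
(insert + 2 primers laid on a random reference), each pair draws its
alleles per planted variant at the given allele fraction, both mates copy
the resulting template over the full region in opposite orientations
(reverse mate flagged and stored forward-strand, as BAM does), read bases
beyond the template are soft-clipped as adapter read-through, and
substitution errors are injected independently per mate. CIGAR and MD are
computed against the generated reference. Defaults — 150 b reads, 100 bp
inserts, 20 bp primers, 50 pairs per amplicon, error-free — model a
typical multiplexed panel on a 150-cycle paired-end run; tests use
per-base error 0.01 where error behaviour is under study.

The truth table is exact, not expected-value: SNV support counts pairs
whose *final* (post-error) base equals the alternate on both mates, so an
error destroying — or coincidentally recreating — the allele is
accounted for; insertions require the applied allele intact on both
mates; deletions are structural and untouched by substitution errors.

What the generator does **not** model: correlated quality/error profiles
along the read, GC or amplicon-representation bias, primer-synthesis
errors, alignment artifacts from segmental duplication, chimeric PCR
products, or indel-adjacent misalignment. Passing tests therefore
demonstrate algorithmic correctness under the stated error model, not
end-to-end accuracy on real libraries, where upstream mapping quality
dominates.

## Numerical and design choices

- Coordinates are 0-based half-open internally; the call writer alone
  converts to the 1-based inclusive annotation-input dialect (SNV
  start = end = pos+1; DEL start = pos+1, end = pos+|ref|; INS
  start = end = anchor+1 with ref "-").
- Insertions are left-anchored at the preceding reference base; indels
  are reported where the aligner placed them, with no left-normalization
  across repeat tracts — concordance between mates is unaffected when
  both mates are aligned consistently, but positions may differ from
  left-aligned VCF representations.
- Adjacent mismatches stay separate SNVs (no MNV merging).
- Multi-base deletions are one event per `^`-run.
- Pairing is by query name among primary records in the fetch window;
  mate-position fields are not trusted (robust to aligner dialects, and
  short-insert mates always co-locate).
- Both thresholds and the overlap fraction are inclusive (≥).
- Output rows are sorted by (chrom, position, ref, alt, amplicon,
  sample), chromosomes lexicographic, proportions fixed to 4 decimals:
  two runs over the same inputs are byte-identical.
- Zero-pair amplicons are reported in coverage with 0 so under-performing
  regions are visible; they emit no calls (the proportion is undefined).
- Sample identifier = input filename minus directory and extension.

## Verification strategy

Unit suites cover each stage against hand-derived examples; randomized
CIGAR/MD alignments are decoded and cross-checked against htslib's
independent MD machinery (pysam `get_reference_sequence` /
`get_aligned_pairs`); a naive brute-force pair-enumeration caller built
on that independent decoder must agree exactly with the production path
over 50 varied seeded fixtures; threshold nesting, primer clipping and
byte-level CLI determinism are asserted end to end. Problem sizes (≤ 5
amplicons, ≤ 200 pairs per fixture; a 12-sample × 10-amplicon cohort in
the acceptance study) keep the whole suite in seconds while exercising
every code path; counts scale linearly and the algorithm has no
size-dependent behaviour beyond the tally.

## Known limitations

- No genotype likelihoods, strand-bias or somatic/germline modelling:
  filtering is purely count/proportion/quality based by design.
- Variants longer than a read, or amplicons whose insert exceeds the
  read length, are out of scope (the overlap premise fails).
- Overlapping amplicons yield one record per amplicon for the same
  variant; deduplication is left to downstream consumers.
- The quality filter treats a multi-base insertion as a conjunction over
  all its bases, the most conservative choice; partial-quality alleles
  are discarded entirely for that pair.
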