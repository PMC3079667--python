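# Methods

This note documents the models, algorithms and numerical choices behind
`amplisnp`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## Experimental design model

The design is combinatorial dual barcoding: each sample in a group carries
a (forward MID, reverse MID) pair from 6 x 6 = 36 combinations; groups are
sequenced in separate plate regions, so MID pairs are only unique *within*
a group and group identity is an input to demultiplexing, never inferred.
Coordinates are 1-based inclusive on a linear reference; the mitochondrial
circle is treated as linear because no amplicon in the panel spans the
origin.

The packaged 20-amplicon panel fixture carries the real per-amplicon insert
lengths (7,215 bp total over 10 regions) and per-amplicon variant-class
counts as configuration (`amplisnp/data/panel_table.tsv`); primer and
reference *sequences* are synthetic, generated once from a fixed internal
seed, since real primer sequences add nothing to the computational chain.
The 12 packaged MIDs are likewise synthetic 10-mers constructed with
pairwise edit distance >= 5 — the property that makes 2-error decoding
unambiguous — standing in for the commercial tag sets designed to the same
criterion.

## MID decoding

A MID is decoded from the first/last 12 bases of the read (tag length + 2,
tolerating terminal indels) as the unique tag at minimum edit distance <= 2
to a prefix of that window (edlib, prefix mode). Edit distance, not
Hamming, because pyrosequencing's dominant errors are indels. Any tie at
the minimum leaves the read unassigned: under whole-tag comparison a tie
implies >= 3 errors, and under windowed prefix matching the rare tie from a
shifted prefix is still evidence too weak to assign. Both MIDs are
required; single-tag rescue is deliberately not implemented, because the
traceability contract of the design demands both ends. The practical
consequences, measured in the test suite: assigned reads never contradict
ground truth (zero misassignment with up to 2 planted errors per tag), at
the cost of a fraction of a percent of reads refused as ambiguous.

Unassignment is always attributed to exactly one reason code
(`missing-MID`, `ambiguous-MID`, `unknown-pair`, `primer-mismatch`,
`no-amplicon`, `empty-insert`), so the accounting partitions the input.

## Alignment

Reads are routed to an amplicon by their primer pair (each primer <= 2
edits at the expected terminus; ambiguous routing refuses the read), then
the trimmed insert is aligned to the amplicon's reference insert with
affine-gap semi-global DP (Gotoh; numba-compiled): match +1, mismatch −1,
gap open −2, gap extend −1 (a k-base gap costs 2 + (k−1)), free end-gaps on
the read only, so truncated reads start or end inside the insert without
penalty. Determinism: traceback prefers match/mismatch over deletion over
insertion on equal score and ends at the rightmost maximal column. Indel
events are left-normalized against the reference before pileup entry
(anchored at the first deleted base / the base an insertion follows), so
equivalent gap placements from different reads aggregate at one canonical
anchor; normalization never crosses an insert boundary into a primer site.

Reads whose alignment identity (matches / aligned columns) falls below 70 %
— or whose length exceeds 2x the amplicon — are excluded from the pileup
and counted in a QC ledger. The 70 % cutoff is this package's explicit,
configurable substitute for the unstated quality trimming of the original
vendor software.

One knowable blind spot: a deletion within ~2 bases of a read end can be
absorbed by the free end-gap (the read simply "starts later") instead of
being recorded; interior events are anchored by flanking matches and are
unaffected. The synthetic generator therefore plants indels >= 10 bp from
insert edges, which real panels effectively do too (variants at primer
boundaries are not reliably callable by any amplicon method).

## Validation cascade

Stages run in a fixed order: enumerate -> artifact rejection -> both-strand
-> replicate support -> multi-individual. All per-sample criteria are
conjunctive, so the surviving set does not depend on stage order; the order
only shapes the intermediate trace counts. The rescue clause is evaluated
after all per-sample fractions are known, making the cascade independent of
read order.

- **Support arithmetic.** The 90 % denominator is the sample's covering
  depth at the site after QC (reads truncated before the site are not in
  the denominator). "More than 10 supporting reads in both read
  directions" is read as *total* supporting > 10 with >= 1 read per
  direction (the both-strand criterion already guarantees each direction);
  the stricter per-direction reading is available as
  `FilterThresholds(strict_direction=True)`. Rationale: the rescue clause
  speaks of "less than 10 supporting reads" as a single total.
- **Zero-depth samples** are excluded at a site, not failed — absence of
  coverage is not evidence against a variant.
- **Artifact flags.** Homopolymer under-read: a 1-bp deletion inside or
  adjacent to a reference run of >= 3 identical bases (`min_hp_len`
  configurable). Carry-forward: a 1-bp insertion duplicating a reference
  base 1–2 positions upstream of the insertion site; because events are
  left-normalized the duplicated base may sit immediately downstream of the
  canonical anchor, and that position is checked too. Both flags reject the
  candidate unless overridden by strong evidence — >= 2 samples each with
  both strands, support fraction >= 0.95 and > 20 supporting reads
  (configurable). The override is the codified substitute for manual
  flowgram review of suspicious indels, and it applies to both artifact
  classes for the same reason: a true 1-bp event with overwhelming,
  double-stranded, multi-sample support is distinguishable from a
  stochastic flow-chemistry error. Multi-base indels (e.g. 2-bp control
  region events) are never artifact-flagged.
- **Multiallelic positions** count once per validated alternate allele in
  variant totals; loci with > 1 validated alternate get a shared group id
  and are emitted as one multiallelic VCF record.

## Synthetic data generator

The generator emulates what the downstream chain consumes, under the
published study conditions as defaults:

- **Coverage**: reads per (sample, amplicon) drawn as a rounded normal
  with floor 0, default mean 27.3 / SD 11.74 (the study's supporting-reads
  distribution; only mean and SD are known, so a truncated normal is the
  minimal-assumption choice). Strand is Bernoulli(0.5) — both-strand
  evidence is required downstream but no orientation bias is documented.
- **Errors**: per-base substitutions (uniform); homopolymer under-reads as
  a 1-bp deletion per run of >= 3 identical bases with the configured
  per-run probability; carry-forward as a 1-bp insertion duplicating the
  base 1–2 positions upstream of a uniformly chosen site, biased to skip a
  different intervening base; read truncation removing one terminal MID
  (plus up to 3 bases). All rates default to 0; study-condition values
  used in the acceptance properties are substitution 0.002, under-read
  0.1/run, carry-forward 0.05/read, truncation 0.015.
- **Planted variants**: unique positions inside amplicon inserts, >= 4 bp
  apart; substitutions >= 2 bp and indels >= 10 bp from insert edges;
  indels are 2-bp events, mirroring the documented control-region
  insertion/deletion and keeping planted truth disjoint from the 1-bp
  artifact classes. Carrier counts are drawn from a configurable
  distribution. Planted variants are canonicalized with the same
  left-normalization as called events, so truth and calls compare by key.
- **Provenance**: every read has exactly one record (sample, amplicon,
  strand, errors applied), the acceptance oracle for demultiplexing and
  recovery checks.
- Quality strings are a constant placeholder: the cascade is count-based,
  as the original criteria were.

What the generator does *not* model — flow-space signal, quality-dependent
error profiles, chimeras, contamination, PCR duplicates, plate-region yield
variation — bounds what passing tests show: they demonstrate the
correctness of the decoding, alignment, accounting and filtering logic
under the stated error classes, not robustness to every failure mode of
real pyrosequencing data.

## Problem sizes

The desk-scale stand-in for the full 16 x 36 x 20 design is 2 groups x 12
samples x 4 amplicons at depth 25 (2,400 reads), used for the end-to-end
identity and demultiplexing properties; the artifact-rejection property
runs 20 seeded replicates at 1 group x 6 samples x 2 amplicons (300 reads
each); the supporting-coverage statistic uses 2 x 12 x 8 amplicons with 80
planted variants at the study's depth model, a size at which the
Monte-Carlo error of the pooled mean is well under the reporting
tolerance. The end-to-end identity runs use fixed depth (SD 0): the
property under test is exact recovery, and stochastic depth would
occasionally push a carrier below the >10-read criterion and test the
threshold rather than the pipeline.

## Known limitations

- Haploid calling only: one consensus allele per sample per site is
  assumed (appropriate for mtDNA); heteroplasmy is out of scope.
- No quality-aware genotype likelihoods; the cascade is deliberately the
  count-based published rule set.
- The stringent 90 % criterion can drop a true variant whose alternate
  allele extends a homopolymer run under heavy under-read noise — the
  documented sensitivity cost of the artifact-robust design (the test
  suite exhibits exactly this case).
- Amplicon routing assumes primers are mutually distinguishable within 2
  edits; degenerate panels would need longer primers or routing by
  alignment score.
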