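# Methods

This note documents the models, rules and numerical choices behind
`tseq_eval`, in the order the pipeline applies them.

## Problem setting

A targeted amplicon-resequencing experiment enriches a few hundred PCR
amplicons (here: a 384-amplicon exon panel, 300–600 bp each, ~173 kb of
target) from a set of related samples, sequences them deeply, and asks
four questions: (1) how efficient and even is the enrichment; (2) how
accurate are genotypes called from per-site allele counts; (3) how well
can minor alleles be recovered from a *pooled* (non-barcoded) library in
which each sample contributes a fraction of the reads; (4) how many
samples can be multiplexed into one sequencing unit at a given coverage
goal. The package evaluates all four stages on data with known truth.

## Coordinates and formats

Internally every interval is 0-based half-open; conversions from the
1-based inclusive conventions of GFF, samtools pileup text and genotype
tables happen only in `io_formats`. Primer footprints are stored as a
length on each amplicon end rather than as separate intervals (no primer
coordinate exchange format exists to round-trip); the *analyzable*
interior of an amplicon excludes them, because bases under a primer
reflect primer sequence rather than template and cannot support variant
analysis. The missing-genotype token in genotype tables is fixed as
`NN`.

## Coverage metrics

* **On-target specificity** uses the full amplicon span including
  primers — enrichment reads genuinely cover primers — and counts a
  mapped read as on-target if it overlaps ≥ 1 base of any amplicon.
* **Depth metrics** (ADoC, C1/C20/C30/C50/C100, uniformity) are computed
  over analyzable bases only, matching the variant-analysis footprint.
  C*k* is the percentage of analyzable bases at depth ≥ k; uniformity is
  the percentage at ≥ 0.2× the sample's mean depth and is invariant
  under uniform depth scaling by construction.
* Zero-read inputs yield explicitly missing percentages, never 0.
* Report percentages are rounded half-up to one decimal at write time
  only; full precision is kept internally.

## Genotype caller

Evidence is the post-filter pileup: A/C/G/T counts plus the reference
base. Rules, with defaults:

| parameter | default | meaning |
|---|---|---|
| `min_coverage` | 5 | below → no-call |
| `max_coverage` | 15 000 | above → no-call (collapsed repeats) |
| `min_allele_freq` | 0.10 | non-reference fraction below → hom-ref |
| `hom_freq` | 0.90 | non-reference fraction at/above → hom-alt |
| `min_reads_per_allele` | 5 | support needed per genotype allele for *detected* |
| `min_het_total` | 10 | minimum depth for a detected het |

The top non-reference base is the candidate alternate; ties break by
fixed base order A<C<G<T. Boundary convention: exactly 90% → homozygous,
exactly 10% → heterozygous. A site whose *second* non-reference base
also reaches `min_reads_per_allele` is flagged multiallelic but still
classified on the top base. The default `max_coverage` is 15 000; the
source protocol for this style of filtering has also been run at 50 000
elsewhere, so the value is configurable. Base-quality filtering is
deliberately out of model: the caller consumes already-filtered counts.

## Concordance and Mendelian checks

Concordance is computed over detected calls only; the false-negative
rate is `100 · not-detected / reference-genotyped sites`. Strata
("homozygous"/"heterozygous") follow the *reference* genotype's
zygosity — the published tables do not state which side defines the
stratum, and reference zygosity is the stable choice since it does not
move with caller errors. Reference sites that are hom-ref still count in
the denominator: the genotype table governs membership, not variant
status. The published per-sample "Detection" percentages use a larger
dbSNP-derived site set that is not reconstructable from counts, so the
package defines its own `detection_rate` over reference sites and does
not attempt to reproduce that column.

A Mendelian error is a child allele pair that cannot be formed from one
paternal and one maternal allele; only sites detected in all three trio
members are tested.

Positive-control inference cross-validates the individual samples'
calls: a site qualifies when it has a detected, replicate-consistent
genotype in at least `min_samples` (default 2) samples and no trio with
complete genotypes violates transmission. For pooled *sensitivity*
scoring, the positive-control SNP set is further restricted to inferred
sites whose predicted composite non-reference fraction is > 0 — a site
at which every pool member is hom-ref is not a SNP and cannot
meaningfully be "detected" in the pool.

## Pooled analysis

For an equimolar six-member pool, a single heterozygote dilutes to 1/12
of the alleles at its site. Predicted composite fractions are
`Σ w_m · dosage_m / 2`; the pooled detection rule requires the top
non-reference count to be ≥ `min_nonref_count` (swept over {5, 10, 20})
*and* ≥ 1% of the site's depth. The 1% floor is applied per site — the
only reading compatible with per-SNP detection. Sensitivity is
monotonically non-increasing in the count threshold because the detected
set can only shrink.

MAF-bin summaries use half-open bins centred on the three smallest
equimolar dosage fractions (1/12, 2/12, 3/12) plus the remainder of
(0, 0.5]. The agreement check compares the observed median to the
predicted median within half the *observed* interquartile range:
predicted values inside a bin are usually a single exact dosage
fraction with zero IQR, so the observed spread is the only usable scale.
Note a small systematic offset is expected: under the substitution-error
model the observed top-alternate fraction at a true fraction f has mean
`f(1−e) + (1−f)e/3`, i.e. ≈ +0.2% at f = 1/12 and e = 1%.

## Capacity arithmetic

Exact integer chain: required bases per sample = target bases ×
coverage goal; samples per unit = floor(available on-target bases per
unit / required); flow-cell and run totals multiply by 8 wells per flow
cell and 2 flow cells per run (both configurable; "run = 2 flow cells"
is inferred from the published 320 = 2 × 160). The default panel
footprint is 172 805 bases — the published capacity chain
(17 280 500 / 20 / 160 / 320) only reconciles with that figure, although
172 053 is also quoted for the same panel elsewhere in the source
material; the package treats 172 805 as authoritative for capacity and
leaves it a parameter. The published per-octet yield constant
361 073 648 is used as printed (7 221 473 reads × 50 bp would give
…650; the two-base discrepancy is the source's, not ours).

## Synthetic-data generator

What it emulates, per `SimConfig` (defaults in parentheses):

* **Panel** (384 amplicons, 300–600 bp, 20 bp primers, random 50–200 bp
  gaps) on one synthetic chromosome.
* **Genotypes** (333 sites, two trios): site MAFs uniform on
  [0.10, 0.50] unless given explicitly; parents are independent
  Hardy–Weinberg draws, the child inherits one uniformly chosen allele
  from each parent, so Mendelian consistency holds by construction.
* **Depth** (mean 2000×, log-scale sd 1.02): one log-normal multiplier
  per amplicon, constant across its bases — coverage evenness in
  amplicon data is dominated by between-amplicon variation, not
  within-amplicon jitter. By default the multipliers are a systematic
  quantile lattice of the log-normal, permuted by the seed
  ("stratified"); this keeps the realised dispersion equal to the
  calibrated one instead of adding 384-draw sampling noise, so the
  uniformity statistic is stable across seeds. An `iid` mode draws
  independently. The dispersion constant 1.02 was calibrated once
  against the closed-form log-normal tail so that default uniformity at
  0.2× mean lands near 85–86%, then frozen.
* **Allele counts**: a multinomial draw per site; each read carries its
  true allele and substitutes to one of the other three bases uniformly
  with probability `per_base_error` (0.005), so at a hom-ref site the
  expected total non-reference fraction equals the error rate.
* **Reads**: each amplicon is tiled with 50 bp chunks emitted once per
  depth layer, so read-derived depth equals the drawn amplicon depth
  exactly; off-target mapped reads are placed on a decoy contig at 34%
  of mapped reads, and unmapped reads pad the total to a 33% mapped
  fraction.
* **Pools**: composite fractions are the dosage-weighted member mean;
  replicates use distinct substreams of the same seed. The pipeline runs
  pools at 2400× with 1% error (pooling adds handling), versus 500× /
  0.5% for the individual libraries in the analysis scripts — sizes
  chosen to match the emulated study design at the pooled scale while
  keeping individual libraries at a depth where recovery is expected to
  be essentially perfect.

What it does **not** emulate: read-level artefacts (qualities, strand,
mapping ambiguity), indels, GC or amplification (WGA) bias, barcode
effects, within-amplicon coverage ramps. Passing recovery tests
therefore demonstrates the *analysis layer* is correct under the stated
statistical model, not that real libraries will reach the same numbers.

## Determinism

All randomness flows from `SimConfig.seed` through named
`numpy` `SeedSequence` substreams keyed by (seed, purpose, sample,
replicate), so per-sample data are independent of simulation order and
identical configs produce byte-identical panels, truth, pileups and
reports.

## Known limitations

* Pool evaluation currently runs on simulated pools only; file-based
  pool pileups can be pushed through `pool_analysis` directly.
* The simulator's constant-depth-per-amplicon model makes C1 ≈ 100% at
  realistic depths; dropped amplicons must be emulated via the `iid`
  mode or explicit zero-depth configuration.
* Percent agreement with the published per-sample coverage table is not
  a goal: those values derive from deposited raw reads; only their
  arithmetic relationships and the synthetic-recovery properties are
  checked.
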