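# Methods

## Signal model

Array CGH reports, per probe, the log2 ratio of patient to reference
signal. For a diploid locus the expectation is 0. A CNV carried by a
fraction *f* of cells (f = 1 for constitutional events) shifts the
expectation to

| event                           | expected log2 |
|---------------------------------|---------------|
| heterozygous loss               | log2((2 − f)/2) |
| heterozygous (one-copy) gain    | log2((2 + f)/2) |
| homozygous loss                 | log2((2 − 2f)/2), floored |
| homozygous gain                 | log2((2 + 2f)/2) |
| hemizygous male-X loss          | log2(1 − f), floored |
| hemizygous male-X gain          | log2(1 + f) |

Ratios of zero or below are clipped to a configurable floor (default
−3.0): real arrays never report −∞, and −3 corresponds to the dynamic
range typically seen for single-copy male-X deletions. The simulator
adds i.i.d. Gaussian noise per probe; probe-level noise magnitude is
not a published platform constant, and the default `noise_sd = 0.15`
is this package's choice, representative of a well-behaved clinical
hybridization. Heavy-tailed outliers and GC/wave artifacts are
deliberately not modelled, so passing recovery benchmarks here bounds
performance on ideal data, not on degraded hybridizations.

## Caller

The caller declares a loss on every maximal run of at least
`min_probes` (default 3) consecutive probes with log2 strictly below
`del_log2` (default −0.6), and a gain symmetrically above `gain_log2`
(default 0.4). "Consecutive" means adjacent rows of the
position-sorted probe table: there is no gap tolerance and no merging
of nearby runs, runs never cross a chromosome boundary, and call
boundaries are the first/last supporting probe positions (the minimal
interval convention of clinical arrays, and the convention that makes
boundary-recovery tests exact). Unsorted input is an error rather than
being silently re-sorted, because silent reordering can mask sample
mix-ups. Input is assumed pre-normalized; centralization and wave
correction belong upstream. The same thresholds apply on male chrX;
dosage interpretation happens downstream.

Thresholded calling has a hard detectability boundary: a heterozygous
loss mosaic is callable only if log2((2 − f)/2) < −0.6, i.e.
f > 2 − 2·2^(−0.6) ≈ 0.68, and a one-copy gain only if f ≳ 0.64.
This is a property of the method, not of any cohort.

## Mosaic-fraction estimation

Inverting the heterozygous signal model at the call's mean log2 gives
f̂ = 2 − 2^(m+1) for losses and f̂ = 2^(m+1) − 2 for gains, clamped to
(0, 1]. Constitutional hemizygous losses (m near the floor) clamp to
1.0. A mean signal implying f̂ ≤ 0 returns no estimate with a
"sub_threshold" flag. The estimator assumes a one-copy event on a
diploid background; for homozygous events it is not meaningful and is
not applied in the benchmarks.

## Annotation

Coordinates are 1-based inclusive everywhere in files and in the API;
sizes are `end − start + 1` (the printed kb/Mb values of clinical
tables are insensitive to the ±1 convention). A gene is overlapped by
a call when the call intersects the gene's genomic hull (first exon
start to last exon end, introns included): intronic deletions can
disrupt a gene and clinical practice counts them, and purely exonic
overlap would be the stricter, less conventional choice. An exon is
"affected" on any partial overlap. Sizes render as nearest-kb below
1 Mb and one-decimal Mb above.

Disease status per gene and context: a heterozygous autosomal CNV hits
a "known disease gene" when the gene has an OMIM AD (or AR) mode; a
hemizygous male-X CNV when it has XL (or AR). AR genes count as known
but are interpreted as a potential recessive carrier state. SFARI
listing is carried as supporting evidence, never as OMIM status.

## Classification

Rule precedence is fixed (the category definitions alone do not induce
a unique order): exclusions → pathogenic → likely benign → non-disease
region → VUS.

1. **excluded_polymorphic** — reciprocal overlap ≥ 0.7 with a
   same-type benign polymorphic (DGV-like) entry. 0.7 is the standard
   CNV-comparison convention; no published value exists for this
   pipeline. CNVs overlapping a configured disease-associated region
   escape this exclusion (the allow-list is an explicit input track;
   no automatic criteria exist).
2. **excluded_segdup** — ≥ 0.5 of the call inside (merged) segmental
   duplications.
3. **excluded_small_no_gene** — size < 500 kb with no genes.
4. **pathogenic** — overlap with a configured known
   microdeletion/microduplication region; deletion of a
   dosage-sensitive AD gene at any size; intragenic duplication of
   such a gene; gene-containing duplication > 2 Mb; duplication > 1 Mb
   containing any dosage-sensitive gene.
5. **likely_benign** — < 1 Mb and gene-less, or < 1 Mb with any
   same-type DGV support and observed inherited multiple times in the
   cohort database.
6. **non_disease_region** — < 1 Mb, rare (no DGV reciprocal match and
   internal cohort frequency < 1%), only genes without disease
   implication.
7. **vus** — everything else; deletions whose implicated genes are all
   AR-only carry the rationale `recessive_carrier_state`.

"Dosage sensitive" is an input flag in the gene metadata; its
provenance (ClinGen curation, internal lists) is outside this package.

## Inheritance and the cascade

A child call is inherited from a parent iff that parent has a
same-type call on the same chromosome with reciprocal overlap ≥ 0.5
(parental confirmation in practice used lookup assays without a stated
fraction; 0.5 is the package default and configurable). De novo
requires both parents tested and negative — paternity is assumed, not
molecularly confirmed. One negative parent with the other untested is
`unknown` (the untested parent cannot be excluded); both parents
matching yields `inherited_unknown_parent`.

The cascade routes each proband CNV into exactly one bucket by gene
count (1 / 2–5 / >5 parked / gene-less) and inheritance, with male
chrX deletions forming their own hemizygous bucket regardless of
inheritance (checked before the de novo/inherited split, since
hemizygous events follow X-linked logic). Routing is conservative by
construction: bucket counts always sum to the proband call count, and
loss/gain subtotals reconstruct totals. Candidate-gene extraction
emits one row per (candidate gene, CNV) from the de novo and male-X
buckets of both tiers; known-disease genes are not emitted, but in the
2–5-gene tier they still count toward the gene-count partition.

## WES LOF filter

LOF = stop-gain, frameshift or splicing. Exclusions, applied in fixed
order for tally attribution (class, coverage, VAF, common-MAF,
ExAC-MAF): coverage < 20 reads; alt/total < 0.2; MAF > 0.001 in ESP,
1000 Genomes or the local database; MAF > 0.0001 in ExAC. All
exclusion inequalities are strict, so boundary values (coverage 20,
VAF 0.20, MAF exactly at a ceiling) pass. Absent or missing MAF fields
are treated as 0 — unobserved is not evidence of commonness. Zero-depth
variants fall under the coverage rule without a division error.
Pass/fail per variant is order-independent; only the tally attribution
depends on the rule order. A separate `missense` channel applies the
same support/rarity rules for manual follow-up and is never counted as
LOF.

## Prioritization

Integer tally per gene: +2 for ≥ 2 de novo CNVs (+1 for exactly one);
+1 each for ≥ 2 male-X CNVs, ≥ 1 additional overlapping deletion
≤ 5 Mb in the call database, ≥ 1 rare WES LOF variant,
haploinsufficiency support (HI rank percentile ≤ 10 or pLI ≥ 0.9),
literature support, and phenotype overlap (the last two are manual
boolean inputs); −1 when pLI ≤ 0.1 **and** the gene has no de novo CNV.
Tiers: strong ≥ 4, moderate 2–3, weak ≤ 1; ties break by de novo count
then symbol. The weights and cutoffs are this package's configuration —
the underlying criteria are standard, but no canonical combination
formula exists — and all live in `ScoreWeights`. The penalty is gated
on absent de novo evidence deliberately: recurrent de novo events are
direct human-genetic evidence and can reflect mechanisms other than
haploinsufficiency (the published HI/pLI scores of genes like STK3
argue against haploinsufficiency even where de novo deletions recur),
so computational intolerance scores must not erase observed CNV
evidence. HI and pLI are inputs, never recomputed; published HI values
appear on inconsistent scales across sources, which is a further
reason the supportive/tolerant flags can be supplied directly as data.

## Synthetic cohorts and what the benchmarks show

The simulator emulates the study conditions end to end on a bundled
toy genome (chr1 10 Mb, chr2 8 Mb, chr3 6 Mb, chrX 8 Mb) with
fabricated multi-exon gene models (2–18 exons of 80–320 bp, 2–8 kb
introns). The array design places evenly spaced probes (endpoints
included) per exon — at least 3, topped up to a design mean of
≥ 4.2 probes/exon — leaving a seeded ≤ 10% of exons under-covered to
mimic placement failures, plus 10 kb intronic and 30 kb backbone
probes (backbone skips segdup intervals when supplied). The design is
treated as a fixed instrument (internal seed); only event placement
and noise vary with the user seed.

The standard recovery benchmark implants 50 CNVs across 30 trios, each
spanning 3–200 consecutive probes (log-uniform), 75% losses, roughly a
third de novo, the rest split maternal/paternal; male-X events are
hemizygous and never paternal; inherited events are implanted
constitutionally in the carrier parent. About 12% of de novo autosomal
losses are mosaic with f ∈ [0.85, 1) over ≥ 20 probes: fractions below
≈ 0.68 are undetectable by a −0.6 threshold caller by construction
(see above), and 0.85 keeps the expected in-CNV signal more than one
noise-SD beyond the threshold, which is the regime in which clinical
arrays actually flag mosaicism. Truth boundaries coincide with the
first/last overlapped probe and events within a child are separated by
at least three probes, so zero-noise recovery can be asserted exactly
(boundaries, type, inheritance, and mosaic fraction to ~1e-16).
Implanted events overlapping no probe are flagged `undetectable`
rather than rejected.

Because the generator omits wave artifacts, probe-quality variation,
cellularity gradients and reference-batch effects, the 100% zero-noise
and > 95% noisy-sensitivity results certify the correctness of the
implementation, not expected clinical sensitivity.

The WES simulator draws per-(sample, gene) LOF and missense variants
with Poisson coverage (mean 60), binomial het alt reads and
population MAFs log-uniform over [1e-6, 1e-2] (half of variants absent
from all databases), and appends a deterministic fixture straddling
every filter boundary (coverage 19/20/21, VAF 0.19/0.20/0.21, MAFs
around 1e-3 and 1e-4).

## Numerical and procedural choices

- Strict inequalities at both caller thresholds and all WES exclusion
  thresholds; boundary values are on the pass/no-call side.
- Reciprocal overlap = min(overlap/len(a), overlap/len(b)).
- Segdup coverage is computed on the merged union of track intervals.
- Gene-overlap queries and cascade outputs are sorted deterministically
  (position, then symbol/sample), so results are independent of input
  order.
- Cohort-level tests and the acceptance script use 1000 random
  10,000-probe profiles for caller/oracle equivalence and the
  30-trio / 50-event benchmark for recovery — sizes chosen to exercise
  every code path at comfortable desk-scale runtimes.
- Seeds: all generators take explicit integer seeds; identical seeds
  give byte-identical outputs.

## Known limitations

- Cohort-scale headline counts of the motivating clinical application
  derive from a proprietary call database and are not reproducible
  here; the cascade is validated on conservation identities and
  synthetic truth instead.
- No HMM/CBS segmentation, B-allele frequencies, normalization or
  wave correction; no transcript-isoform or UTR/CDS awareness; no
  automatic literature or phenotype curation (manual flags).
- The classifier implements fixed-precedence clinical reporting rules,
  not ACMG/ClinGen point scoring.
- The mosaic estimator assumes a single event type per call on a
  diploid background and degrades for overlapping or homozygous
  events.
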