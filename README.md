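# exoncnv

Analysis pipeline for **exon-targeted array CGH** data: probe-level CNV
calling, gene/exon annotation, clinical classification, trio-based
de novo / X-linked / inherited filtering, WES loss-of-function variant
filtering, and candidate-disease-gene prioritization — plus a synthetic
cohort simulator so every stage can be validated against a known truth
set.

## Who this is for

Exon-targeted aCGH platforms place several interrogating oligos on each
exon of thousands of disease and candidate genes (>90% of exons with at
least three probes, on average >4.2 probes per exon, intronic probes
every 10 kb and a 30 kb genome backbone), which makes deletions and
duplications as small as a single exon detectable. `exoncnv` implements
the analysis a clinical-genomics group would run downstream of such an
array: from per-probe log2 ratios to a ranked table of candidate disease
genes supported by de novo CNVs, hemizygous male-X deletions, recurrent
database deletions and rare LOF point variants.

## The core methods

**Caller.** A deletion is declared wherever at least three consecutive
probes have log2 ratio < −0.6; a duplication wherever at least three
consecutive probes are > 0.4 (strict inequalities, maximal runs, no gap
tolerance, runs never cross a chromosome). Call boundaries are the
first/last supporting probe positions.

**Mosaic fraction.** A CNV carried by a fraction *f* of cells attenuates
the signal: a one-copy loss gives log2((2 − f)/2), a one-copy gain
log2((2 + f)/2). Inverting the mean call signal gives
f̂ = 2 − 2^(m+1) for losses and f̂ = 2^(m+1) − 2 for gains,
clamped to (0, 1].

**Classification.** Fixed-precedence rules: polymorphic (DGV-matched at
≥0.7 reciprocal overlap) / segdup-buried / small-gene-less CNVs are
excluded from reporting; deletions of dosage-sensitive AD genes (any
size), intragenic duplications of such genes, gene-containing
duplications > 2 Mb and dosage-sensitive duplications > 1 Mb are
pathogenic; the rest resolves to likely benign, non-disease region, or
VUS (AR-gene deletions are VUS flagged as a potential recessive carrier
state).

**Cascade.** Surviving proband CNVs are partitioned by gene count
(1 / 2–5 / more) and inheritance (de novo requires both parents tested
and negative at ≥0.5 reciprocal overlap; male chrX deletions form their
own hemizygous bucket), and candidate (non-OMIM) genes are extracted
from the de novo and male-X buckets.

**WES LOF filter.** Stop-gain/frameshift/splicing variants with
coverage ≥ 20 reads, VAF ≥ 0.2, MAF ≤ 0.001 (ESP / 1000 Genomes /
local) and ≤ 0.0001 (ExAC); exclusion thresholds are strict, so
boundary values pass.

**Prioritization.** Per gene, an integer evidence tally over de novo
CNV recurrence, recurrent male-X CNVs, additional database deletions
≤ 5 Mb, WES LOF hits, haploinsufficiency support (HI rank 0–10% or
pLI ≥ 0.9) and manual literature/phenotype flags, with a penalty for
LOF-tolerant genes lacking de novo support.

## Worked example

```python
from exoncnv import (
    make_validation_cohort, evaluate_recovery,
    GeneIndex, overlap_genes, run_cascade, extract_candidate_genes,
)
from exoncnv.pipeline import call_cohort

cohort = make_validation_cohort(seed=7, n_trios=6, n_cnvs=10, noise_sd=0.15)
calls = call_cohort(cohort.profiles)
rep = evaluate_recovery(cohort)
print(f"sensitivity {100*rep.sensitivity:.0f}%  false calls {rep.n_false_calls}  "
      f"max mosaic-fraction error {rep.max_mosaic_error:.2e}")

index = GeneIndex(cohort.gene_models)
annotated = [overlap_genes(c, index) for cl in calls.values() for c in cl]
counts, routed = run_cascade(annotated, cohort.pedigree)
print("cascade buckets:", {k: v for k, v in counts.bucket_counts.items() if v})
print(extract_candidate_genes(routed).to_string(index=False))
```

Output:

```
sensitivity 100%  false calls 0  max mosaic-fraction error 1.44e-02
cascade buckets: {'single_de_novo': 5, 'single_inherited': 3, 'single_other': 2, 'multi_de_novo': 1, 'multi_inherited': 3}
   gene           tier                            cnv_id type inheritance  size_bp
GENE005 single_de_novo T002-CH:chr1:3259454-3316569:loss loss     de_novo    57116
GENE028 single_de_novo T005-CH:chr2:6649687-6657322:gain gain     de_novo     7636
GENE020  multi_de_novo T003-CH:chr2:2122036-2539750:loss loss     de_novo   417715
```

All ten implanted CNVs (including a mosaic deletion) were recovered
under probe noise, no spurious calls were produced, the mosaic fraction
was estimated to within ~1% of the implanted value, and the three CNVs
hitting genes without an OMIM disease entry surfaced as candidate-gene
evidence rows. `single_other` holds calls whose inheritance could not
be resolved into the de novo or inherited buckets (for example X-linked
events in girls).

A console script exposes the same pipeline
(`exoncnv simulate design|cohort|wes`, `exoncnv call`,
`exoncnv cascade`); see `exoncnv --help`.

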