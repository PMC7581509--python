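# fhtwohit

Two-hit somatic variant interpretation for fumarate hydratase (FH) deficient
tumors from tumor-only panel sequencing.

FH-deficient uterine leiomyomas (ULs) arise when both alleles of the *FH*
tumor suppressor are inactivated — by a small variant (SNV/indel) plus loss of
the second allele, or by biallelic deletion. Without a matched normal sample,
deciding whether a variant is somatic or germline (and hence whether a patient
may have the hereditary leiomyomatosis and renal cell cancer syndrome, HLRCC)
has to come from quantitative reasoning about allele fractions, tumor purity
and copy number. `fhtwohit` implements that analytic chain as a tested,
reusable library:

- **Purity/VAF model** (`fhtwohit.vaf`): under loss of heterozygosity the
  expected variant allele fraction is `AF = TP + (1 − TP)·z`, with tumor
  purity `TP` and initial zygosity `z` (0 somatic, 0.5 germline het). The
  model is invertible (`required_purity`), supports purity estimation from
  clonal somatic heterozygous variants (`2 × VAF`), and classifies each
  variant's likely origin. A copy-number-aware variant
  (`AF = (TP + (1−TP)·2z)/(2 − TP)`) is available behind a flag.
- **Copy-number interpretation** (`fhtwohit.cnv`): log2 copy ratios convert to
  purity-corrected integer copy numbers via
  `cn = round(ploidy·(2^log2 − (1 − TP))/TP)` with a 1e-3 copy-ratio floor;
  segment sizing, per-gene loss summaries, and a Fisher-exact /
  Bonferroni-adjusted case-control recurrence test.
- **Two-hit calling** (`fhtwohit.twohit`): integrates both into a per-sample
  status (`snv_plus_loh`, `biallelic_deletion`, `single_hit`, `none`) with an
  intratumoral-heterogeneity flag for deletions whose depth falls between the
  clonal monoallelic and biallelic expectations, or SNVs whose VAF implies an
  implausibly low somatic purity.
- **Saturation mutagenesis** (`fhtwohit.saturation`): every variant reachable
  by one base exchange in a CDS (3·|CDS| variants), codon-level consequences,
  exon-terminal splice-region flags, domain mapping and a hypergeometric
  domain-enrichment test.
- **3D clustering** (`fhtwohit.structure`): mean pairwise Cα distance of
  mutated residues on a protein structure with a seeded bootstrap null
  (add-one empirical p), plus a colocalization test between two residue sets.
- **Carrier frequency & epidemiology** (`fhtwohit.epi`): gene-level carrier
  frequency from population allele counts (ACMG class 4/5 only), expected
  subtype prevalence, expected germline fraction among cases, screening
  enrichment, and exact binomial tails.
- **Synthetic cohorts** (`fhtwohit.simulate`): fully labelled tumor cohorts
  generated from the same models (binomial read counts at model-implied VAFs,
  Gaussian-noise log2 ratios), population tables with known carrier frequency,
  and toy transcript/helix-structure fixtures — so every downstream module is
  testable against ground truth.

A 13-sample FH-deficient UL reference cohort (printed read counts, region
calls and log2 ratios) is bundled in `fhtwohit.datasets` and drives the worked
example below.

## Worked example

```python
import numpy as np
from fhtwohit import cnv, twohit, vaf
from fhtwohit.datasets import fh_ul_cohort

cohort = fh_ul_cohort()

# Allele fractions of the eight FH SNVs/indels
print(np.median([v.vaf for v in cohort.variants]))   # 0.766
# Germline explanation of the lowest VAF needs negative purity -> untenable
tp, feasible = vaf.required_purity(0.443, zygosity=0.5)
print(round(tp, 3), feasible)                        # -0.114 False
# Purity anchor from a clonal somatic heterozygous TP53 variant
print(vaf.purity_from_somatic_het([0.408]).mean)     # 0.816

# Purity-corrected copy number at the assumed purity of 0.8
print(cnv.log2_to_cn(-0.85, purity=0.8))             # 1  (monoallelic loss)
print(cnv.log2_to_cn(-9.97, purity=0.8))             # 0  (biallelic loss)

losses = cnv.summarize_losses(cohort.segments, cohort.gene)
print(losses.min_kb, losses.max_kb, losses.median_kb)  # 15.9 42757.4 4897.2

calls = [
    twohit.classify_sample(
        [v for v in cohort.variants if v.sample_id == s],
        [g for g in cohort.segments if g.sample_id == s],
        cohort.gene, purity=0.8, sample_id=s)
    for s in cohort.sample_ids
]
summary = twohit.summarize_cohort(calls)
print(summary.counts)        # {'snv_plus_loh': 8, 'biallelic_deletion': 5, ...}
print(round(100 * summary.snv_fraction, 1))            # 61.5
print([c.sample_id for c in calls if c.heterogeneity_flag])  # ['S05']
```

Eight of thirteen tumors carry one SNV/indel plus loss of the other allele,
five carry biallelic deletions, and one sample (S05: VAF 0.443 with a
deletion at log2 −1.87, between the clonal monoallelic and biallelic bands)
is flagged as heterogeneous — multiple subclonal second hits.

The epidemiological chain from the same inputs:

```python
from fhtwohit import epi
prev_hi = epi.expected_prevalence(0.70, 0.016)                          # 0.0112
print(round(epi.germline_fraction_among_cases(1/3247, prev_hi)[0], 4))  # 0.0275
print(round(epi.prob_no_carriers(0.139, 13), 3))                        # 0.143
print(round(epi.screening_enrichment(5, 2060, 1/2563), 1))              # 6.2
```

So even at the upper carrier-frequency bound, only ~2.7–13.9% of women with
an FH-deficient UL are expected to carry a germline *FH* variant, and finding
no carrier among 13 cases is unremarkable (p ≈ 0.143).

## Command line

```bash
fhtwohit simulate --n-samples 13 --seed 1 --outdir cohort/
fhtwohit twohit cohort/variants.tsv cohort/segments.seg --purity 0.8
fhtwohit cn-call cohort/segments.seg --purity 0.8
fhtwohit cluster3d structure.pdb --residues 315,275,273 --n-boot 10000 --seed 1
fhtwohit epi --screen 5,2060
```

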