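# Methods

## The purity/VAF model

In a tumor-only design the variant allele fraction (VAF) is the ratio of
alternate-supporting to total reads at a site. Assume the tumor is a mixture
of a fraction `TP` of tumor cells (purity) and `1 − TP` diploid normal cells,
and that in tumor cells the wild-type allele of the target gene has been lost
(LOH). Then every tumor cell contributes the variant allele and each normal
cell contributes it with its initial zygosity `z` (0 for a somatic variant,
0.5 for a germline heterozygote), giving

    AF = TP + (1 − TP) · z                                   (linear form)

The linear form counts alleles per cell without re-normalizing for the copy
number at the locus: post-LOH tumor cells carry one allele where normal cells
carry two, so the exact diploid-equivalent expectation is

    AF = (TP + (1 − TP) · 2z) / (2 − TP)                      (cn-aware form)

The package implements the linear form as the default — it is the convention
this analysis chain was built around, it is monotone and invertible, and its
inverse has the convenient closed forms `TP = AF` (somatic) and
`TP = 2·AF − 1` (germline) — and exposes the cn-aware form behind a
`cn_aware=True` flag. `required_purity` returns the algebraic inverse even
when it leaves (0, 1]; an out-of-range requirement is precisely the evidence
that a hypothesis is untenable, so it is flagged rather than clamped.

Clonal somatic variants that are heterozygous in tumor cells (no LOH) have
expectation `TP/2`, so doubling their VAF estimates purity; the estimator
flags inputs above 0.5 whose doubled value would exceed 1.

Origin classification compares the observed VAF to both hypotheses'
expectations at an assumed purity and favors the closer one; calls are
`ambiguous` when the two absolute residuals differ by less than a tolerance
(default 0.05, half the spread of purity-consistent VAFs in the reference
cohort). Both required purities are always reported.

## Copy-number interpretation

For a segment with integer tumor copy number `cn` in a specimen of purity
`p` (diploid normal background), the expected copy ratio is
`(p·cn + (1 − p)·ploidy)/ploidy`. Ratios are floored at 1e-3 before the log
(log2 ≈ −9.966, printing as −9.97), which is where clonal biallelic
deletions in effectively pure material saturate. The inverse conversion

    cn = max(0, round(ploidy · (2^log2 − (1 − p)) / p))

uses half-away-from-zero rounding; none of the reference values sits at a
rounding boundary, so the tie-break is cosmetic there but is fixed for
reproducibility. Coordinates are 1-based inclusive and segment size is
`end − start`, reported to 0.1 kb — the convention that reproduces the
reference region calls' printed sizes exactly.

Gene-level recurrence against a control cohort uses a per-gene 2×2 table
(samples affected vs not, case vs control; affected = any overlapping
segment with purity-corrected CN below — or above, for gains — the ploidy),
a two-sided Fisher exact test, and Bonferroni adjustment by default. The
multiple-testing method is configurable (any `statsmodels` method name);
Bonferroni is the most conservative standard choice.

## Two-hit calling and the heterogeneity flag

The per-sample decision table takes the copy state at the target gene from
the deepest overlapping segment (pre-set integer calls are honored,
otherwise the formula above) and the filtered target-gene SNVs/indels
(coverage ≥ 10 reads, VAF ≥ 10%):

| copy state | SNV/indel present | status |
|---|---|---|
| 0 | no | `biallelic_deletion` |
| 0 (log2 ≤ clonal-biallelic expectation) | yes | `biallelic_deletion`, anomaly noted |
| in-gap log2 | yes | `snv_plus_loh`, flagged |
| 1 | yes | `snv_plus_loh` |
| 1 | no | `single_hit` |
| 2 | yes | `single_hit` |
| 2 | no | `none` |

Intratumoral heterogeneity — distinct subclones carrying different second
hits — leaves two quantitative signatures, either of which raises the flag:

1. a deletion log2 strictly between the clonal biallelic expectation at the
   assumed purity (log2(1 − p), −2.32 at p = 0.8; never above the
   configurable band edge −2.5) and the monoallelic band (default
   [−1.5, −0.3]): deeper than one clonally lost allele, shallower than two;
2. a target-gene SNV whose implied somatic purity (its VAF under the LOH
   model) falls more than a margin (default 0.3) below the cohort purity.

The gap's lower bound is purity-dependent by design: a clean clonal
biallelic deletion sits exactly at log2(1 − p) and must not flag, while the
reference cohort's heterogeneous sample (log2 −1.87, VAF 0.443 at p = 0.8)
falls inside the gap and trips both rules. The band edges and VAF margin are
configuration (`Bands`), not constants, because the boundary between
"exceptionally deep monoallelic" and "biallelic" is ultimately a judgment
about noise.

When an SNV co-occurs with an unambiguously biallelic deletion (not observed
in the reference data), copy state dominates and the anomaly is surfaced in
the notes rather than hidden.

## Saturation mutagenesis

Every single-base exchange in a CDS yields 3·|CDS| variants. Consequences
follow the standard nuclear codon table: `synonymous`, `missense`,
`nonsense` (gain of stop), `stop_lost`, and `start_lost` for any
substitution in the initiator codon (ATG has no synonymous single-base
neighbor, and non-AUG initiation is not modelled). Exon-terminal coding
bases are flagged (`first_base`/`last_base` exactly at an internal exon
boundary, `near_terminal` within 3 coding bases) because such substitutions
frequently disrupt splicing regardless of their annotated protein
consequence; splice-effect prediction itself is input, not computed. Domain
intervals are configuration — residue ranges differ between protein
annotations, so none are hard-coded. Domain enrichment of an observed
residue set is a one-sided Fisher exact test, equal to the hypergeometric
tail of in-domain counts among the protein's residues.

The windowed score profile is a centered moving average over per-residue
mean scores (residues without scores contribute 0; windows truncate at the
ends so constant inputs stay constant). It is a deliberately transparent
substitute for model-based score smoothing, which is out of scope.

## 3D clustering statistic and bootstrap

The clustering statistic is the mean pairwise Euclidean Cα distance of the
mutated residues — chosen over black-box clustering pipelines because it is
exhaustively verifiable: on a 20-residue structure the complete null
(C(20,3) = 1,140 triples) can be enumerated and the bootstrap checked
against it. The null resamples equally sized residue sets uniformly without
replacement from the structure; the empirical p-value uses the add-one
correction `p = (1 + #{null ≤ observed}) / (B + 1)`, which never returns 0
and is uniform on its lattice under the null. Distances are summed in
sorted order so a resampled set's statistic does not depend on draw order.
Published clustering p-values from other tools are therefore comparable only
qualitatively, not numerically.

Colocalization of a set B with a fixed reference set A uses the mean over B
of the minimum Cα distance to A, with B resampled from the residues outside
A. Residue numbering offsets between variant nomenclature and crystal
numbering are configuration on the PDB reader.

## Carrier frequency and the epidemiological chain

The default estimator treats every pathogenic allele (ACMG class 4/5) as one
carrier: `CF = Σ_i AC_i/(AN_i/2)`, the rare-variant approximation;
`count_hom_once=True` counts homozygous individuals once. Records with
AN = 0 are skipped with a warning. The chain then computes: expected subtype
prevalence `prevUL × propFH-dUL`; expected germline-carrier fraction among
subtype cases `CF / prevalence` (valid under independence of carrier status
and tumor occurrence, which is stated in every report and flagged when the
ratio exceeds 1); screening enrichment `(k/n)/CF`; the zero-carrier
probability `(1 − f)^n`; and exact binomial tails by direct summation.

## The synthetic-cohort generator

The generator is the generative inverse of the analysis models and its
defaults are the reference study design: 13 samples, mechanism quota 8/13
SNV+LOH and 5/13 biallelic deletion (quota assignment by largest remainder,
so tests can pin cohort composition exactly; multinomial sampling is also
available), purity uniform on (0.75, 0.85) around the assumed 0.8,
per-variant depth Poisson around 150 (matching the reference read depths of
136–193) floored at the DP ≥ 10 filter boundary, and log2 noise SD 0.15
(the SD of the seven observed monoallelic log2 ratios, −0.77 to −1.26, is
≈ 0.16). Samples carry ground-truth labels (mechanism, purity, integer CN,
variant origin) plus clonal somatic heterozygous passenger variants at
expected VAF `TP/2` (purity anchors) and neutral background segments.

Heterogeneous samples are modelled as two equal tumor subclones above a
shared monoallelic first hit: one subclone carries the SNV (on the retained
allele), the other an independent second deletion. With equal subclones at
purity 0.8 this yields a target VAF of `TP/2 = 0.4` and a mixture log2 of
−1.32 — depressed VAF and intermediate deletion depth. Such samples flag via
the low-VAF rule; matching the observed −1.87 exactly would need a larger
deleted-subclone fraction, which is configurable (`subclone_fraction`).

Population tables split a target carrier frequency equally over the
pathogenic variants and draw allele counts binomially at the implied
per-allele frequency, so the summed estimator is unbiased; benign/VUS
records with non-trivial counts are interleaved as decoys.

What the generator does **not** emulate: read-level errors, FFPE artifacts,
mapping bias, segmentation (segments are emitted directly, not re-segmented
from bins), germline CNV polymorphism, and allele-specific copy number.
Passing recovery tests therefore demonstrates the correctness of the
interpretation chain given well-formed calls, not robustness to upstream
calling errors.

Toy fixtures: a four-exon transcript (random stop-free codons, ATG…stop)
embedded in a synthetic genomic context, and an ideal α-helix Cα trace
(100°/residue twist, 1.5 Å rise, radius solved for exact 3.8 Å consecutive
spacing) with residues 5–7 as a designated tight spatial triple.

## Validation scale and known limitations

The test suite and acceptance script run at desk scale: 500-sample cohorts
for recovery rates, 4,000 bootstrap replicates against the exhaustive
1,140-triple null, 200 null draws for p-value calibration, 100 seeds for
carrier-frequency recovery — all within seconds on one CPU, chosen as the
smallest sizes at which the Monte-Carlo error bands are decisive.

Known limitations:

- Origin classification from VAF alone is depth-limited. At sequencing depth
  100 the somatic and germline expectations differ by `(1 − TP)/2` — 0.075
  at purity 0.85 — while the binomial SD of the VAF is ≈ 0.036, so
  forced-choice recovery on synthetic cohorts plateaus near 94% under the
  default purity range rather than reaching 95%; deeper coverage (≥ 200×) or
  lower purity separates the hypotheses cleanly. The per-variant required
  purities are reported so users can apply cohort-level reasoning instead of
  relying on single-variant calls.
- The linear VAF model is kept as the default for fidelity to the analysis
  convention it implements; the cn-aware form is the more exact model and
  the two diverge as purity grows.
- The two-hit decision table assumes a diploid background and a single
  target gene; phasing, hit order, and allele-specific copy number are out
  of scope.
- Carrier-frequency estimates depend on the population database snapshot
  supplied; the estimator's summation rule is configurable because no single
  convention is universal.
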