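# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limits of what the tests demonstrate.

## Editing-site model and filter cascade

Unstranded full-length single-nucleus RNA-seq cannot distinguish an
A>G edit on the plus strand from a T>C variant read off the minus
strand, and without a donor genome a germline SNP is indistinguishable
from a fully edited site at the single-record level. The cascade
therefore relies on orthogonal evidence:

1. **Cell QC.** Cells with mitochondrial read fraction strictly
   greater than 0.15 (apoptosis proxy) or detected-gene count below a
   complexity threshold are excluded. The complexity threshold is not
   standardized in the field; the default is 1000 detected genes and
   is a prominent, logged parameter.
2. **Coverage/prevalence.** A candidate must have depth ≥ 5 *and*
   minor-allele count ≥ 2, in ≥ 10 QC-passing cells; every qualifying
   cell must satisfy both thresholds individually (the alternative
   reading — any nonzero detection counts toward prevalence — is
   strictly weaker and is not implemented). All thresholds are
   inclusive ("at least"). Independent library preparation per nucleus
   makes ≥ 10 independent detections a strong guard against PCR
   artifacts. The replication configuration lowers prevalence to ≥ 3
   cells for small data sets.
3. **SNP removal** is an exact (chrom, pos, ref, alt) anti-join
   against the common-SNP list. Since the simulated donor carries a
   SNP in every cell at dosage/2 allele fraction, list-based removal
   is the only mechanism that can catch these sites; the planted-truth
   fixture verifies it removes all of them.
4. **Strand/overlap rule.** A site survives iff it is cataloged
   (rescue), or lies in exactly one gene's footprint with the cognate
   variant class. Overlap with *any* second gene disqualifies
   (ambiguous template strand); catalog rescue overrides only this
   rule, never coverage/prevalence. Kept sites are canonicalized to
   A>G on the gene strand.
5. **Annotation.** Repeat context has precedence Alu > repetitive
   non-Alu > nonrepetitive when intervals nest. Genic feature takes
   the most specific overlapping class (stop_codon > UTR > exon;
   intron = in gene, outside exons). Novelty is absence from every
   supplied catalog, with per-catalog membership retained for
   intersection censuses.

Coordinates: VCF/GFF3 are 1-based inclusive, BED 0-based half-open;
conversions are confined to `scredit.io` and the two interval lookups.

## Editing indices

GEI is the unweighted mean of per-site edited fractions over sites
transcribed in the cell — not a pooled-count ratio — so deeply covered
sites do not dominate. "Edited in a cell" means alternate count ≥ 1 at
a transcribed site (an alt ≥ 2 alternative is exposed as an option).
Undefined indices (no eligible transcribed site) propagate as missing,
never zero. Group comparisons are OLS with log10 mapped reads as the
library-size covariate; the grouping unit (phenotype, subgroup or
region × phenotype) is a parameter with phenotype as default.

## Site-level differential editing

Pseudobulk samples are (subgroup × region) sums of edited and
unedited allele counts. The variance filter removes sites whose
**edited-count** variance across pseudoreplicates is ≤ 0.2 (the
fraction-variance alternative is implemented and switchable; the
count reading is the default because the downstream model works on
counts).

Each site's paired counts are modeled with a negative-binomial GLM in
the differential-methylation style: observations are the 2G
(edited, unedited) counts, with one blocking indicator per sample
(absorbing total coverage), an editing-status main effect, status ×
adjustment terms, and the status × contrast interaction — the log
editing-odds ratio between contrast levels — as the coefficient of
interest. By the Poisson–multinomial equivalence the blocking term
makes this a conditional model of the edited proportion, while
coverage still weights the evidence (lowly covered, highly variable
sites cannot dominate, unlike ratio-based tests).

Inference with few pseudoreplicates (df ≈ 5 at 8 samples) needs care:

- a **common NB dispersion** (method of moments over per-site Poisson
  fits, median across sites) captures the mean–variance trend;
- a **per-site quasi-dispersion** from the NB Pearson statistic is
  squeezed toward the across-site median with prior df 20, and the
  Wald statistic is referred to Student-t with prior + residual df.

A plain Wald-z reference measurably inflates type-I error (~0.07–0.08
on the package's null simulation); the moderated-t brings it to
~0.05. On null simulations (2000 sites, 8 pseudoreplicates) the
empirical type-I error at α = 0.05 is 0.047–0.055 across seeds, and on
small instances the p-values rank-correlate ≥ 0.95 with an exact
beta-binomial likelihood-ratio oracle. Continuity handling: when a
whole arm of a site (all edited or all unedited counts of one contrast
level) is zero, 0.5 is added to every count of that site and the site
is flagged. Swapping contrast labels negates every log fold-change and
preserves p-values exactly (treatment coding).

## Gene-level directional test

Per site, an ordinary t-statistic of the contrast coefficient is
computed from per-sample logit editing proportions
(log((edited+0.5)/(unedited+0.5))); the gene statistic is the mean
site t. The null is a rotation null: under spherically symmetric
residuals, rotating one site's (effect, residual) vector uniformly
makes the rotated t exactly Student-t with the residual df,
*independent of the site's magnitude*. Sites are treated as
conditionally independent given the pseudobulk design, so the null of
the gene mean-t is sampled from independent t draws (`n_perm`
rotations, default 10⁴, minimum 100); two one-sided p-values are
combined into a direction and p, with BH FDR across genes (threshold
0.1 by convention for this test).

Design note: a *shared* rotation across sites (the fully
correlation-robust variant) collapses the gene statistic's null onto a
single t with ~5 df at 8 pseudoreplicates, so no amount of consistent
sites can produce a small p-value — the test would be structurally
powerless at this sample count. Independent rotations are exact when
site-level residual noise is independent across sites, which holds in
the generator (independent binomial sampling and per-site sample
effects). **Limitation:** in real data, sites of one gene share cells
and could carry gene-level random effects; such correlation would make
the independent-rotation null anti-conservative. With more
pseudoreplicates a shared-rotation or residual-correlation-adjusted
variant is the conservative choice.

Minimum sites per gene defaults to 2. The disease-overlap test is a
two-sided Fisher exact test on disease-site membership × biased-gene
membership over the full candidate-site universe; an empty margin
yields OR = NaN, p = 1, flagged degenerate.

## Abundance–editing associations

Per gene, OLS of the editing index on log10 TPM, phenotype and log10
library size over expressing cells only (TPM > 0; a pseudocount
alternative is exposed through the data rather than the model). Genes
expressed in fewer than 300 cells — the background-expression
convention used for enrichment analyses — or with constant abundance
are skipped with a reason. BH FDR across fitted genes; significance
requires FDR < 0.05 and |β| > 0.01. The downsampling check refits
genes expressed in more than 1500 cells on a seeded subsample of 1500
and reports sign/significance concordance. Cross-data-set comparison
correlates shared-gene βs (Pearson) and, for a labeled prior subset,
tests β separation between labels with Mann–Whitney (the choice of a
rank test reflects the heavy-tailed β distributions).

## Synthetic-data generator

The generator emulates the statistical structure the analysis
assumes; defaults are the study conditions:

| parameter | default | rationale |
|---|---|---|
| phenotype mix | 75% excitatory / 25% inhibitory | ~1 inhibitory : 3 excitatory neurons |
| regions | six Brodmann-area labels | six cortical regions |
| subgroups | 8 per phenotype | 16 transcriptomic subgroups, the pseudobulk unit |
| transcription rate | 0.045 | each site transcribed in ~4.5% of cells |
| coverage | NB(mean 20, shape 2), zero-inflated | deep-on-few-cells SMART-seq profile |
| bimodal mixture | low 0.05, high 0.90, weight 0.40 | the two-point per-cell mixture; the source data's empirical mixture parameters are unpublished, so these are free parameters of the generator |
| per-site mixture weight | Beta(0.4·3, 0.6·3) | yields positively skewed cross-cell mean frequencies |
| cell heterogeneity | logit-SD 0.3 | cell-to-cell editing propensity spread |
| catalog fraction | 0.80 | ~80% of sites previously cataloged |
| cell-type effect | +0.8 log-odds on 20% of sites in inhibitory cells | produces a clearly detectable inhibitory editing excess (~0.024 GEI) at study scale, matching the qualitative result |
| SNP fraction | 0.05 | donor genomic SNPs at dosage/2 allele fraction in every cell |
| antisense decoys | 0.05 | non-cognate variant class, exercise the strand rule |
| overlap sites | 0.03 | inside antisense gene overlaps, exercise catalog rescue |
| mito / complexity failures | 1% + 1% | planted QC failures, exact by construction |

Allele counts are binomial given a per-cell per-site probability drawn
from the two-point mixture (drawing the probability per cell yields
the beta-binomial-like cross-cell behaviour); depth is zero-inflated
negative binomial. One RNG stream per sub-generator, all derived from
the master seed, so components are reproducible independently;
identical seed and configuration give byte-identical output files.

Planted associations run **abundance → editing**: association genes
get large per-cell biological abundance variation (0.7 decades SD,
high-mean low-dispersion counts, long gene body so they stay a
negligible share of the TPM denominator), and each cell's editing
propensity is shifted so that its expected mean editing is exactly
linear in the cell's *observed* log10 TPM with the planted slope
(per-cell logit offsets solved by Newton iteration). This matches the
modulator hypothesis the association model tests and makes the
planted β the true regression coefficient; planting the reverse
direction (editing → latent abundance) leaves an errors-in-variables
attenuation of several percent that no correct regression can
recover.

What the generator does **not** emulate: read-level artifacts
(alignment bias, base-quality structure), real genome coordinates and
repeat geometry, correlated editing across sites within a gene,
ambient RNA, doublets, or batch effects. Passing tests demonstrate
correctness of the statistical machinery under the stated model, not
robustness to those real-data phenomena.

## Numerical choices and degenerate inputs

- Logit transforms clip probabilities to [1e-9, 1−1e-9]; pseudocount
  0.5 in pseudobulk logit proportions.
- GLM failures (separation, non-convergence) yield NaN p-values that
  are excluded from FDR rather than silently imputed.
- Percentages use decimal half-up rounding at the stated precision,
  and every reported percentage carries its numerator and denominator.
- Variance filtering with a single pseudobulk sample is undefined and
  disabled (all sites kept).
- Nearest-neighbor distances exclude singleton (chrom, context)
  classes; ties in feature assignment resolve by the specificity
  order above.
- Problem sizes in the validation experiments (5000 × 500 filter
  fixture; 2000-site null; 500 null genes with 2000 rotations; 100
  power replicates; 2000-cell association runs; 3000-cell index
  contrast) are chosen to estimate each quantity with comfortable
  Monte-Carlo margins while keeping a full validation run in tens of
  seconds on one CPU.

## Known limitations

- The site-level model's moderated-t calibration is validated at 8
  pseudoreplicates; with 4 or fewer samples the quasi-dispersion
  estimate is essentially the prior and p-values become approximate.
- The gene test's independence assumption (above) is the main caveat
  for real data.
- Catalog rescue trusts the catalog: a cataloged genomic SNP absent
  from the SNP list would survive the cascade.
- The unstranded design cannot detect editing in unannotated
  intergenic transcripts: uncataloged intergenic sites are dropped by
  construction.
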