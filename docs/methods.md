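# Methods

`methylseq-dm` re-implements, as a tested library, the analysis chain used
to compare cord-blood DNA methylomes between a control group and an
ART/hypofertile group from targeted capture bisulfite sequencing: QC
filtering of a CpG count matrix, reference-based cell-composition
estimation, per-CpG binomial-GLM differential methylation with q-value FDR,
direction-aware region merging, PC1-gap changepoint outlier screening,
imprinting-control-region (ICR) statistics, and the small-table cohort
comparisons.  Because the underlying cohort data are controlled-access, the
package ships a synthetic-cohort generator that reproduces the *structure*
of such data; every behavioural claim below is demonstrated on generated
cohorts with known ground truth, not on the original samples.

## Data model and site funnel

A `MethylomeMatrix` holds per-CpG, per-sample (methylated, total) read
counts with an explicit missingness mask.  Positions are 1-based in TSV
files (CpG-report convention) and 0-based internally and in BED intervals;
conversion happens only at I/O boundaries.  Counts are assumed pre-merged
across the two strands of a CpG dinucleotide and addressed by the
forward-strand C.

The retention funnel runs in a fixed order: (1) drop CpGs intersecting any
exclusion BED (SNPs, blacklists) using half-open interval semantics;
(2) mask every cell whose total read count lies outside the inclusive
[15, 500] window; (3) drop sites non-missing in fewer than 30 samples;
(4) drop sex-chromosome sites.  The minimum-sample rule counts samples
*after* the per-cell coverage mask — the funnel narrative implies this
order, and it is the stricter reading.  Filtering is monotone and
idempotent, and preserves site and sample order (property-tested).

## Synthetic cohorts

The generator emulates: 36 control + 37 case samples, each assigned a sex
(default ratio 0.5) and a case subgroup split ~17 in vivo / 20 in vitro;
7-cell-type mixing weights drawn from a Dirichlet law whose default
concentration gives a granulocyte-dominated cord-blood-like composition;
per-site baseline betas from a bimodal Beta mixture (mostly methylated
genome, CpG-island-like low tail); inter-CpG spacings from a short/long
mixture so CpGs cluster as they do in islands; read depths from a
discretised log-normal (median ~60x, default log-SD 0.8) clipped to
[1, 600] so the 15x/500x filter is exercised on both tails; and
completely-at-random missingness.

Group effects act on the logit scale (keeping betas in (0,1) for any effect
size, and matching the analysis model).  Each planted effect has a scope:
`both`, `male_only`, `female_only`, or `opposite` (+e in case males, -e in
case females).  Sites carrying planted effects draw baselines within
[0.15, 0.85] by default so a given logit effect yields at least the
intended beta shift (a 1.5-logit effect then shifts beta by >= ~0.11
everywhere).  ICR blocks are dense CpG intervals at baseline beta 0.5 with
small per-sex logit shifts in the case group.  Outlier samples receive a
global logit shift on a random subset of sites (default 30-40%).

Counts are beta-binomial with intra-class correlation `dispersion_rho`.
The published analysis does not report overdispersion, so rho is a free,
documented parameter: rho=0 reproduces the binomial analysis model exactly
(used for type-I-error checks), and small positive rho (0.01) is used for
robustness/recovery experiments.  What passing tests therefore show is that
the chain recovers what it models; real bisulfite data add overdispersion,
batch structure and informative missingness that the generator deliberately
omits.

## Cell-composition estimation

Marker panels mimic a cord-blood reference of B cells, CD4+/CD8+ T cells,
granulocytes, monocytes, NK cells and nucleated RBCs: 50 markers per cell
type by default (within the 43-58 per-type range of the reference panel the
study used), each separating its cell type from all others by >= 0.5
methylation fraction.  Panel CpGs present in the matrix and non-missing in
>= 90% of samples are kept; remaining missing betas are imputed with the
mean of all other samples at that CpG.  Proportions are then estimated per
sample by nonnegative least squares (`scipy.optimize.nnls`) without a
sum-to-one constraint, matching the projection method the study's
covariates came from; an optional flag renormalizes for reporting.
Solutions satisfy the NNLS KKT conditions to 1e-8 (asserted in tests), and
on noiseless mixtures recovery is exact to 1e-10.

## Differential methylation

At each CpG the counts (m, t-m) are regressed on intercept + group +
covariates by binomial logistic IRLS (tolerance 1e-8 on deviance, max 50
iterations), using only samples non-missing at that site; the group
coefficient's Wald z gives a two-sided p.  The implementation is verified
against `statsmodels` GLM to 1e-6 on random instances and against the
closed-form two-group MLE.  Covariates follow the published battery:
combined analyses adjust for sex and the 7 estimated cell proportions
(as produced, not renormalized); sex-stratified analyses adjust for cell
proportions only; pregnancy complications can be added.  If the design
matrix is ill-conditioned (condition number > 1e10) the last proportion
column is dropped with a logged warning.  Sites that fail to converge or
show |coefficient| > 20 (quasi-separation) are marked untestable, counted,
and excluded from the q-value input rather than assigned p = 1, keeping the
tested-site null distribution uniform.

q-values follow the Storey construction: q(i) = min over j >= i of
pi0 * m * p(j)/j on sorted p-values.  pi0 is estimated on the lambda grid
0.05..0.95 (step 0.05) by a cubic least-squares polynomial evaluated at
lambda = 0.95 and clamped to (0, 1] — a least-squares stand-in for the
reference implementation's df-3 smoothing spline; with fewer than 100
p-values the smoother is unstable and pi0 falls back to 1.  `fixed_one`
mode forces pi0 = 1, which makes the result exactly Benjamini-Hochberg
(property-tested to machine precision).  DMCs are sites with q < 0.05.
Methylation difference is the case-minus-control difference of per-sample
beta means over non-missing samples, and direction (hyper/hypo) follows its
sign; reported |difference| bins are <10%, 10-20%, >20%.  DMC-set
comparisons report overlaps, direction concordance, and the +/-5%
"similar magnitude" rule, with shared-fraction printed under both the
union and summed-list-size conventions.

## Regions

DMRs merge neighbouring same-direction DMCs whose positional gap is
<= 250 bp (inclusive — the natural reading of "within 250 bp", fixed here
so results are bit-reproducible), in a single left-to-right pass per
chromosome and direction.  Chains of >= 2 CpGs become DMRs; singletons are
tabulated separately, and size statistics are reported both with and
without them since published size summaries are ambiguous on this point.
DMR size is end - start + 2, spanning the trailing CpG dinucleotide.
Annotation assigns each site one category per family (genic, CpG-context,
repeat) by user-declared precedence with a fallback (intergenic/open sea);
single assignment keeps count tables conserved, unlike multi-assigning
annotators.  Enrichment of a foreground proportion against the genome-wide
background uses the Yates-corrected chi-square on the 2x2 table.

## Outlier screening

Only sites covered in every sample enter the PCA (complete cases; the
generator's default missingness is calibrated so roughly a third of sites
qualify at n=73, as in deep capture data).  Betas are site-centered and
decomposed by SVD; PC1 is oriented so the sample of maximum |score| is
positive.  Samples are sorted along PC1 and the n-1 neighbouring gap sizes
are tested for at most one mean change (AMOC): the score vector is first
divided by its population SD (the standard changepoint routine's Normal
cost assumes unit-variance data), then the best of the m-1 splits of the
gap sequence into two mean segments is accepted iff the residual
sum-of-squares reduction exceeds the MBIC-style penalty 3*ln(m).  The
samples strictly beyond the changepoint gap on the side with fewer samples
are the outliers; an interior split with both sides >= n/2 declares none.

Two deliberate numerical choices here: (a) the cost is unit-variance, not
variance-normalized — spacings of sorted Gaussian scores are heavy-tailed,
so any scale-invariant likelihood ratio flags a tail sample in nearly every
homogeneous cohort, while the standardized-score cost declares none on
homogeneous cohorts yet fires on a sample separated by ~5+ standardized
SDs (a 10-within-cluster-SD planted shift comfortably exceeds this);
(b) only one changepoint is ever considered.  The penalty is a parameter
(`--penalty`).  Outlier enrichment by group or sex uses the two-sided
Fisher exact test, with p = 1 by convention when no outliers are declared.

## Imprinting control regions

To avoid skew from missing data, methylation is first averaged across
samples per CpG within each (group x sex) cell; these per-CpG means are the
observation unit everywhere downstream — CpGs, not samples, are the
replicates, exactly as the averaging rule prescribes (the per-sample
alternative is noted but not used).  A 2x2 factorial ANOVA (group, sex,
interaction; Type II sums of squares, robust to mild unbalance from
per-cell missingness) runs on those means, with within-sex group contrasts
Bonferroni-corrected by a factor of 2.  Direction tallies average the
per-CpG difference within each ICR (combined and per sex) and count
hypo/hyper blocks and blocks where the female difference is below the male
one; blocks capturing zero CpGs are excluded from denominators.  Coverage
accounting reports the fraction of each ICR's total CpGs present in a site
set (e.g. capture panel vs array subset).

## Cohort statistics

2x2 Fisher exact p-values use the two-sided "probability at most that of
the observed table" convention (via `scipy.stats.fisher_exact`, which
implements it) with p = 1 for degenerate margins.  The r x c
(Freeman-Halton) extension is enumerated exactly over all margin-consistent
tables (relative tie tolerance 1e-7) up to a configurable cap, beyond which
a seeded Monte-Carlo estimate with standard error is provided.  Chi-square
tests are Pearson with df = (r-1)(c-1); Yates' correction applies to 2x2
only.  Summary t-tests default to pooled variance (plain "unpaired t
test"), with Welch available; recomputing the published cohort table from
its printed mean (SD)/count inputs reproduces the printed p-values for
infant sex (0.82), delivery route (0.46), subgroup infant sex (0.51),
smoking (0.79), maternal BMI (0.81, using the footnoted complete-case n of
35/32) and gestational age (0.79); the maternal/paternal age rows recompute
to 0.75/0.50 from the rounded summaries and are printed with a note, never
silently corrected.  `cohort_table` picks the test per row: pooled t for
numerics, exact Fisher when any expected cell is < 5, else chi-square.

## Problem sizes and reproducibility

The bundled experiments run at desk scale by design: 20,000-CpG cohorts
for null/type-I checks, 10,000 CpGs with 500 planted effects for recovery,
2,000-CpG cohorts for the outlier and end-to-end runs.  These sizes give
stable rates (binomial SE ~0.0015 on the 5% type-I fraction at 20,000
sites) while keeping every experiment seconds-long; genome-scale matrices
(~2.4M sites) stream through the same code path linearly.  All randomness
flows through explicit integer seeds; reruns are byte-identical, and
`scripts/acceptance.py --seed N --out f.json` recomputes every headline
quantity from scratch.

## Known limitations

- Binomial (not beta-binomial) testing: overdispersed data will inflate
  the per-site test statistic; the generator's rho quantifies this but the
  tester does not shrink for it (DSS/methylKit-style shrinkage is out of
  scope).
- MCAR missingness only; informative missingness is not modelled.
- The outlier detector's unit-variance cost presumes standardized PC1
  scores; scores are standardized internally, so only the *relative* gap
  structure matters, and shifts below ~5 standardized SDs are undetectable
  by construction of the penalty.
- Annotation requires user-supplied BEDs; no genome-sequence-derived
  CpG-island or repeat calling.
- No read-level simulation, SNP calling, GO/network analysis, or figure
  rendering.
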