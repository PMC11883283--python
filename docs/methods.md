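# Methods

This note documents the models and estimators implemented in
`heartregen`, the choices made where the design was genuinely open, what
the synthetic-data generators do and do not emulate, and the package's
known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Count model and normalization

Counts for gene *g* in sample *j* are modelled as negative binomial,
E[y] = μ, Var[y] = μ + φμ², with a single pooled dispersion φ shared by
all genes. This is deliberately the simplest member of the edgeR-style
model family: no tagwise shrinkage, no GLM layer. The package is built
for designs with 2–4 replicates per cell, where a common dispersion is
estimable and per-gene dispersions are not.

**TMM factors.** For each sample against a reference, genes zero in
either profile are dropped; M-values (log₂ ratio of relative abundances)
are doubly trimmed — 30% by M rank (15% per tail) and 5% by A rank
(2.5% per tail), the defaults of the original TMM method — and the
surviving M-values are combined in a weighted mean with inverse
asymptotic binomial variances (1/y − 1/N summed over the two samples).
Factors are re-centred to geometric mean 1. The reference is the sample
whose upper-quartile relative expression is closest to the mean upper
quartile (the standard convention). Ranks are averaged across exact ties
so tied values are kept or dropped together. Note one subtlety: because
the precision weights are the *sum* of the two samples' variance terms,
doubling every count of one sample (a pure depth change) leaves its M-
and A-values intact but halves only its own weight term, so the factor
is invariant only to ≈5·10⁻⁴ rather than exactly.

**Pooled dispersion.** On counts rescaled to a common effective library
size, each (gene, replicate-group) pair yields the moment estimate
z = (s² − μ̂)/μ̂². The pooled φ is the clipped mean of z over pairs with
μ̂ ≥ 5. Two rejected alternatives and why: the *median* of z is badly
biased low at n = 3 (the sampling distribution of s² is right-skewed, so
the median of a clipped ratio sits well under φ — measured ≈0.065 for
true 0.1); a *ratio of sums* Σ(s²−μ̂)/Σμ̂² weights genes by μ², so under a
long-tailed expression distribution a handful of top genes dominate and
the estimate is unstable across datasets (measured 0.093–0.116 for true
0.1). The equally-weighted mean is stable (0.095–0.098 across 12
simulation replicates) at a small negative bias from Jensen's inequality
in 1/μ̂², which the downstream calibration tolerates. The μ̂ ≥ 5 floor
removes genes whose moments are pure Poisson noise; if no gene reaches
the floor the estimator falls back to all positive-mean genes.

**Exact test.** Within each contrast, library sizes are pseudo-equalized
by scaling counts to the geometric mean of the effective sizes and
rounding the group sums. Conditional on the total *t*, the group-A sum
follows the negative hypergeometric law P(z|t) ∝ C(z+r_A−1, z)·
C(t−z+r_B−1, t−z) with r = n/φ (binomial in the Poisson limit φ = 0),
computed in log space over the full support. The two-sided p-value sums
P(z|t) over all z no more probable than the observed one.

A discrete two-sided p defined this way stochastically dominates the
uniform distribution by roughly half the modal probability — at the
simulated depths the null ECDF sits 0.01–0.02 below the diagonal, which
a Kolmogorov–Smirnov test against uniformity on 2,000 genes will flag
for a noticeable fraction of datasets even when φ is known exactly. The
`midp=True` variant therefore counts only half the probability of
outcomes exactly as likely as the observed one; it is calibrated on
average (0 KS failures at α = 0.01 across 12 simulation replicates) and
is the variant to use when the p-value *distribution* is the object of
interest (FDR estimation, uniformity checks). The default remains the
plain conservative sum, which never exceeds the nominal level and keeps
the closed-form Poisson-limit identities exact.

**Fold-changes** are log₂ ratios of group mean CPM with a 0.5 prior
added on the CPM scale, used only for reporting, never for testing. A
CPM-scale prior makes fold-changes exactly invariant to pure
depth changes of a sample. Genes with zero total count in a contrast are
excluded from its table.

## Response classification

The master list keeps transcripts with p < `p_cut` (default 0.05,
*unadjusted* — the selection rule names raw p-values; BH-adjusted
filtering is available via `use_adjusted`) in both genotypes'
regeneration contrasts and |log₂FC| > `lfc_cut` (default 1) in at least
one. An unweighted OLS line through the (WT, MUT) fold-change points
yields per-transcript residuals; |residual| > τ (default 1 log₂ unit,
exposed as a flag) defines the increased/decreased calls.

Two statistical properties of this procedure, visible in the synthetic
runs, are worth keeping in mind when interpreting real output: the
fitted slope is attenuated below 1 because the x-coordinate is itself a
noisy estimate (errors-in-variables), and transcripts responding in only
one genotype never reach the master list because the p < 0.05 criterion
must hold in both — the classifier detects *quantitative* response
differences, not all-or-nothing ones.

## Promoter chromatin categories

Promoters are strand-aware windows [TSS−up, TSS+down) (mirrored on the −
strand), default ±1 kb, clipped at coordinate 0; all coordinates are
0-based half-open per the BED standard and touching intervals do not
overlap. A gene's category is H3.3_CM if its promoter shares ≥1 bp with
any H3.3-CM interval (regardless of H3K27ac), K27ac_only if it overlaps
H3K27ac but not H3.3-CM, else neither — a partition, queried through
per-chromosome interval trees. Genes without a promoter record are
reported as unresolved rather than silently dropped.

## ddPCR

λ = −ln(negatives/accepted) is the maximum-likelihood estimate of mean
copies per droplet under Poisson loading; concentration in copies/µl is
λ divided by the droplet volume (default 0.85 nl, the QX200 convention)
times the dilution factor. Replicate wells of one sample/target at one
dilution are pooled by summing droplet counts *before* estimation, which
makes the estimate invariant to how droplets were split across wells
(averaging per-well λ̂ would not be). QC gates are strict inequalities as
printed in the instrument workflow: accepted > 10,000, negatives >
1,000, positives strictly above the matched no-RT control. A fully
positive well is saturated and refuses to quantify.

## Image quantifications

`threshold_particles` reproduces the ImageJ sequence: binary threshold
(≥), 3x3 median despeckle, 8-connected components, drop areas ≤
min_area (default 50 px). The median filter erodes single-pixel corners
of rectilinear shapes (a solid 10x10 square keeps 96 px) — accepted as
inherent to the stated despeckle. Mean fluorescence is pooled
(total intensity / total area over all retained particles), not a mean
of per-particle means; thresholds are explicit per-channel inputs (an
Otsu helper exists in scikit-image for exploration, but reproducible
measurements use fixed thresholds across hearts). The proliferation
index averages section indices within a heart (each section counts
equally regardless of cell count) before any group statistics, and group
comparisons route through the gated two-group test. AFOG composition is
closed by subtraction, orange = 100 − red − blue, and rejects
red + blue > 100 as a thresholding inconsistency.

## Statistics

The gated rule: a two-sided F-test on the variance ratio, p = 2·min(P(F
≤ f), P(F ≥ f)), gates between Welch's t-test (default) and the
Mann-Whitney U test (when gate p < 0.05). Mann-Whitney uses exact
enumeration for min(n) ≤ 8 without ties, otherwise the normal
approximation with tie correction. Identical constant groups return
p = 1 with a degeneracy flag. The composition chi-square treats two
percentage triples as a 2x3 table of percent units (row totals 100, 2
df) — whether the original analyses used mean percentages or per-heart
counts is not documented, so percent units are the declared convention
here — and errors on any zero expected column.

## Synthetic data

One global seed fans out to fixed named substreams (counts, droplets,
sections, images, intervals), so generators are independently
reproducible and adding one never perturbs another.

*Counts*: baseline per-gene means are lognormal (median 100, log-sd 1);
library-size factors lognormal (log-sd 0.15); 3 replicates per
genotype x condition cell; NB sampling via the gamma-Poisson mixture
(φ default 0.1). 10% of genes respond to regeneration with log₂FC of
random sign and magnitude 1 + Exp(0.75), equal in both genotypes; 15% of
responders are differential, with the mutant response shifted by ±δ
(default 2 log₂ units). Each responder class is planted on both up- and
down-regulated genes with WT magnitudes chosen so both genotypes'
responses stay individually detectable (|log₂FC| ≥ 1.5) — an imbalanced
planting (increases only on up-regulated genes) would correlate the
shift with the x-axis and tilt the regression line, confounding the
recovery measurement. Genome-scale default is 20,000 genes; tests and
the acceptance script use ~2,000 to keep runtimes in seconds.

*Droplets*: positives ~ Binomial(accepted, 1 − e^(−λ)); the target's λ
follows the four-condition design (4.3-fold WT induction, 2.4-fold
mutant, shared baseline λ = 0.05); the reference gene is constant at
λ = 0.5 read at 1:10 dilution; one near-empty no-RT well per condition.

*Sections*: Mef2⁺ counts Poisson(250) per section, 3 sections per heart,
24 WT vs 19 mutant hearts; doubles Binomial(mef2, π) with π = 9.11% (WT)
and 11.71% (mutant).

*Images*: two half-frame compartments carrying the same layout of
soft-edged uniform-intensity cell disks, compartment A scaled by the
planted ratio (default 7.36), background 5 ADU, Gaussian noise sd 2;
marker channels light up exactly the cell footprints so the
threshold-and-measure protocol recovers the planted ratio (to ~1%; the
residual bias is the background's share of the measured mean).

*Intervals*: 305 genes on two chromosomes, alternating strands, 100 kb
spacing; exactly round(0.613·n) promoters receive an H3.3-CM interval
(half of those also H3K27ac) and round(0.075·n) an H3K27ac interval
only, so category fractions are met by construction; background
intervals land midway between promoters.

What the generators do **not** emulate: gene-gene correlation, GC or
length biases, batch effects, tagwise dispersion variation, droplet
volume variation or rain (partially amplified droplets), cell-shape and
optical effects (point-spread, bleaching, autofluorescence), or
realistic peak-width distributions for chromatin marks. Passing tests on
synthetic data therefore demonstrate correctness of the computations and
calibration under the stated models, not robustness to these real-data
phenomena.

## Problem sizes used in validation

Null calibration: 2,000 genes, 3 replicates per cell, φ = 0.1.
End-to-end recovery: 1,920 genes (1,800 null + 120 planted responders at
δ = 2), the same design. ddPCR recovery: 500 simulated wells of 20,000
droplets at each λ ∈ {0.01, 0.1, 1}. Oracle-equivalence checks run on
50–60-gene matrices and a few hundred random intervals/queries. The full
test suite runs in well under a minute on one CPU.

## Known limitations

- One pooled dispersion: genes with atypical biological variability get
  miscalibrated p-values; the package is not a replacement for
  edgeR/DESeq2 on large designs.
- The exact test's pseudo-equalization rounds scaled group sums to
  integers; at very small counts combined with very unequal library
  sizes this rounding is a source of approximation.
- The residual classifier inherits OLS attenuation; τ is interpreted on
  the residual scale of the *fitted* line, not the identity line.
- BED parsing is deliberately strict (rejects malformed lines with line
  numbers) and does not attempt liftover or chromosome-name aliasing.
- No segmentation: cell counts enter as tables; the imaging module
  measures masks and intensities only.
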