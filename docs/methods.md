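# Methods

`pleiocfdr` implements a cross-trait pleiotropy analysis for paired GWAS
summary statistics: empirical conditional false discovery rates (cFDR) and
their conjunction (ccFDR), preceded by LD pruning and stratified conditional
Q-Q enrichment, and complemented by a shared-single-causal-variant
fine-mapping approximation and two-sample Mendelian randomization.  This
note records the statistical model behind each stage, the defaults and why
they were chosen, the numerical decisions, and what the synthetic-data
validation does and does not establish.

## Summary-statistic model and harmonization

Each trait contributes a per-SNP table of signed z-scores and two-sided
p-values (z and p related through the standard normal; both source analyses
are normal-approximation GWAS).  Harmonization intersects the two panels by
SNP identifier and aligns trait 2's z-score to trait 1's effect allele:
swapped allele pairs flip the sign, complementary-strand records are
flipped to the first panel's strand before comparison, and strand-ambiguous
SNPs (A/T, C/G) are dropped.  Dropping is the conservative choice: without
allele frequencies the strand of an ambiguous SNP cannot be arbitrated, and
a silent mis-orientation would corrupt the signed effects consumed by MR.
All drops are counted and logged.

Genomic control estimates the inflation factor
`lambda = median(z^2) / median(chi^2_1)` (the denominator is
0.45494, evaluated by `scipy`) and, when `lambda > 1`, divides every z^2 by
it, inflates standard errors by `sqrt(lambda)`, and recomputes p.  `lambda`
is floored at 1 — no deflation, following standard practice.  Because the
consortium studies this pipeline is modeled on release already-corrected
statistics, correction is off by default and exposed as an explicit flag.
A p-value of exactly 0 is floored to 1e-300: the cFDR estimator divides by
an empirical cdf evaluated at p, so p must be strictly positive.

## LD pruning

Pruning scans, per chromosome, a window of 50 consecutive currently
retained SNPs; any pair with squared Pearson correlation r² strictly above
0.2 loses its smaller-MAF member immediately (MAF ties drop the later SNP
in position order — a deterministic rule where the convention is otherwise
unspecified).  The window advances 5 SNPs and passes repeat until a scan
removes nothing.

One subtlety: with a step of 5, window starts aligned to the step can never
cover a retained pair sitting 46–49 positions apart, so stepped passes
alone do not guarantee the advertised post-condition.  The implementation
therefore alternates stepped passes with a step-1 audit pass until both are
clean, after which *no* window of 50 consecutive retained SNPs contains a
pair with r² > 0.2 — a property the test suite verifies exhaustively.
r² uses pairwise-complete samples; monomorphic vectors are an error rather
than a silent 0.  Pairs at exactly the threshold are kept (the rule is a
strict inequality).

## Conditional FDR

For SNP *i* with observed p-values (p1, p2) for the principal and
conditional traits, the conditional false discovery rate is estimated
empirically as

    cFDR(p1 | p2) = min(1, p1 * n_cond / n_joint)
    n_cond  = #{ j : p2_j <= p2 }     n_joint = #{ j : p1_j <= p1, p2_j <= p2 }

i.e. p1 divided by the empirical conditional cdf of the principal p-value
given the conditional exceedance.  Comparisons are inclusive and ties are
counted as-is (no jitter), so the index SNP always counts itself and the
denominator is at least 1.  When every conditional p equals 1 the statistic
collapses to the unconditional empirical FDR p·M/rank — the
Benjamini–Hochberg-style quantity for distinct p — which is both a sanity
check and a tested identity.  The conjunction ccFDR is the maximum of the
two orderings; cFDR < 0.05 (strict) flags single-trait significance and
ccFDR < 0.05 flags a pleiotropic locus.

Counting is exact: SNPs are processed in ascending conditional-p order,
tie groups inserted into a Fenwick tree over dense principal-p ranks before
any member is queried (O(M log M)).  The brute-force O(M²) double loop
gives bit-identical counts and serves as the test oracle.  A one-ulp guard
clamps the estimate below at p1, since `p1 * n / n` can round just under
p1 when the two counts coincide; the mathematical invariant cFDR ≥ p then
holds exactly in floating point.

Stratified conditional Q-Q curves visualize the enrichment the estimator
exploits: within nested strata defined by conditional-trait cutoffs
(p < 1, 0.1, 0.01, 0.001, 0.0001 — strict `<`, matching the conventional
stratum labels), the empirical quantiles of the principal trait's p-values
are evaluated on a shared grid of 512 points equally spaced in −log10(q)
from 0 to log10(m).  The scalar enrichment summary per stratum is the
nominal −log10 p at empirical q = 0.01, relative to the all-SNP stratum.
For null calibration the package provides a simultaneous
Kolmogorov–Smirnov band: for n independent uniform p-values the entire
empirical quantile curve stays within the transformed band
q ± c(α)/√n with probability 1 − α.  A simultaneous band is the
appropriate object for a whole-curve check — the quantile curve is a
dependent order-statistic process, and demanding that every one of 512
*pointwise* bands contain it would fail far more often than α even under
the null.

## Fine-mapping

The locus model assumes exactly one causal variant shared by both traits.
Each SNP receives a Wakefield-style approximate Bayes factor per trait,

    ABF(z, W) = sqrt(1 / (1 + W)) * exp(z^2 W / (2 (1 + W))) ,

the density ratio N(z; 0, 1+W) / N(z; 0, 1) for a normal effect prior with
variance W on the z² scale.  Per-trait Bayes factors multiply across the
two traits, and the posterior that SNP k is the shared causal variant is
the prior-weighted, log-sum-exp-normalized product; ties in the posterior
break to the smaller position.  W defaults to 10 — weakly informative at
GWAS z-score scale — and is configurable; the model is deliberately a
simplification of annotation-aware multi-causal frameworks, under which the
marginal z at the causal SNP is sufficient for ranking, so a supplied LD
matrix is carried for reporting only.  All arithmetic is in log space:
z-scores of magnitude 40 must not overflow, and the tests check they do
not.

## Mendelian randomization

Instruments are exposure SNPs with p < 5e-8, greedily clumped in
ascending-p order so that no retained pair has r² > 0.01 (genome-wide, no
window limit).  Each instrument's Wald ratio beta_y/beta_x estimates the
causal effect with first-order delta-method SE se_y/|beta_x| — adequate
for instruments strong enough to clear the selection threshold.  The IVW
estimate is the fixed-effect inverse-variance-weighted mean of the ratios
(random-effects inflation is deliberately not applied).  The ML estimator
maximizes the joint likelihood

    beta_x_i ~ N(xi_i, se_x_i^2),    beta_y_i ~ N(theta xi_i, se_y_i^2)

over (theta, xi_1..k) by BFGS with an analytic gradient from the IVW
start, followed by Newton polishing on the closed-form profile
log-likelihood (xi profiles out analytically) until the gradient norm is
below 1e-8; non-convergence raises with diagnostics.  The SE of theta is
the inverse square root of the profile observed information.  As all
se_x → 0 the profile collapses to the IVW objective and the two estimators
agree to numerical precision — a tested identity.

The MR simulator draws xi_i ~ N(0.1, 0.02²) with se_x = 0.005 and
se_y = 0.01: instruments at roughly 20 standard errors, consistent with
the p < 5e-8 selection rule, where the first-order Wald SE is accurate and
both estimators should be near-nominal.  Coverage is validated at k = 46
instruments — the scale of a birth-weight instrument set — and 95% CIs
cover a true theta = 0.25 in 93–97% of 1,000 draws.

## Synthetic-data generator

The generator emulates the post-pruning situation the cFDR estimator
operates in.  Each of m SNPs is assigned one of four components with
probabilities (pi00, pi10, pi01, pi11) — null for both traits, trait-1
only, trait-2 only, pleiotropic — and a trait's z-score is N(0, 1) when
null and N(0, 1 + sigma²) when non-null, independently across SNPs and,
given the component, across traits.  Defaults are m = 100,000 SNPs (the
order of a pruned genome-wide overlap panel), pi11 = 0.02, pi10 = pi01 =
0.04, sigma = 3; the FDR-control simulations set pi11 = 0 with pi10 =
pi01 = 0.05 so that trait-1 signal exists but any conjunction is spurious.

The genotype panel is separate: within blocks of 50 SNPs each haplotype's
latent Gaussian follows an AR(1) with parameter rho (default 0.8) and is
thresholded at the normal quantile of a target allele frequency drawn from
(0.05, 0.5); dosages sum two independent haplotypes, blocks are
independent and never straddle a chromosome boundary, and metadata MAFs
are the realized minor-allele frequencies.  This is the simplest
construction with a tunable adjacent-SNP r².

What the generator does *not* emulate, and hence what passing tests do not
show: LD-induced correlation among z-scores (summary statistics are
independent of the panel — the operative assumption being that pruning
precedes cFDR), allele-frequency-dependent power, population
stratification, sample overlap between studies, and any coupling of effect
sizes beyond shared component labels.  In particular the empirical FDR
bound (mean false-discovery proportion ≤ 0.10 among cFDR < 0.05 calls,
over 200 replicates at m = 20,000) is a conservativeness check of the
estimator under independence, not a theorem about arbitrarily structured
real data.

## Problem sizes used in validation

The test suite and the acceptance script size their simulations to the
smallest scales at which each property is informative: counting-oracle
equivalence on 500 random tables of 2,000 SNP pairs (exact equality, so
size only affects tie coverage); FDR control at m = 20,000 over 200 (suite)
or 50 (script) replicates; enrichment monotonicity at m = 100,000 over 100
replicates; pruning oracles on 30–100-SNP block panels where exhaustive
auditing is feasible; MR coverage over 1,000 (suite) or 500 (script)
draws; fine-mapping recovery over 100 loci of 51 SNPs.

## Known limitations

* The empirical cFDR estimator is approximate; it controls the false
  discovery proportion only in the conservative, on-average sense
  validated here, and per-SNP values on real data depend on the merged
  panel's composition.
* The fine-mapping posterior assumes a single shared causal variant and a
  shared prior variance across traits; loci violating either assumption
  get well-normalized but mis-specified posteriors.
* MR estimators are the plain IVW and ML pair; no pleiotropy-robust
  estimators (Egger, weighted median) are provided, so instrument validity
  is assumed, not tested.
* Annotation and novelty flagging run entirely from user-supplied offline
  gene intervals and association catalogs.
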