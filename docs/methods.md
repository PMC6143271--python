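# Methods

## The inference chain

The package implements the statistical chain used to ask whether natural
selection has acted on a polygenic trait in one population of a panel:

1. construct the phenotype (composite hemoglobin measures; log-odds
   residuals for binomial proportion traits);
2. run a linear mixed-model GWAS with a standardized genetic relatedness
   matrix;
3. reduce hits to an independent, effect-polarized SNP set (distance
   lumping for cohort GWAS; greedy LD pruning for external summary
   statistics);
4. score single-locus differentiation with per-SNP F_ST and the
   population branch statistic;
5. test for polygenic adaptation with matched-control empirical nulls
   (frequency-difference, overdispersion, outlier tests);
6. map selection coefficients to association-test power and invert for
   the minimum detectable coefficient.

## Synthetic data: what it emulates, and what it does not

The generator draws ancestral allele frequencies Uniform(0.05, 0.95)
(keeping most SNPs past the maf ≥ 0.05 analysis filter) and propagates
them down a rooted population tree: each branch perturbs frequencies by
a Gaussian with variance c·p(1−p), truncated to [0, 1], where c ≥ 0 is
the branch's drift amount. Truncated-Gaussian drift was chosen over a
Balding–Nichols Beta because the downstream null model of the
genetic-value tests is multivariate normal; matching the generator to
that assumption makes calibration checks interpretable. For leaves i, j
the covariance of standardized frequency deviations is the summed c over
shared branches, which the tests' drift covariance F estimates from
control SNPs.

The default tree has six leaves: an outgroup, three lowland populations,
and a high-altitude pair nested inside the regional clade — the
qualitative structure (target and sister population at altitude, a
lowland comparison group, a distant outgroup) of the study design this
models. The drift amounts (0.004–0.04 per branch) give leaf-pair F_ST of
roughly 0.01–0.1, the range typical of within-continental and
continental human comparisons. No source states a drift process for a
reference panel of real populations; any tree consistent with the MVN
drift model serves the tests' purposes.

Cohort genotypes are two independent allele draws per SNP from the focal
leaf's frequencies. Declared relative pairs share a parent: each member
receives one allele transmitted from the common parent (chosen
independently per SNP) plus one independent population draw, giving an
expected standardized-GRM entry of 0.25 — the value the pair-detection
checks assert. Phenotypes are linear in causal genotypes with Gaussian
noise; count phenotypes are the rounded, floored continuous value
(matching the Gaussian-LMM treatment of count traits rather than a
Poisson model); binomial phenotypes draw successes through a logistic
link on the centered linear predictor. SNP positions lie on a single
synthetic chromosome at uniform 5 kb spacing, 1-based, so that the
200 kb peak-lumping rule is exercised.

Not emulated: linkage disequilibrium between panel SNPs (each SNP drifts
independently), recombination, sequencing or imputation error, and
ascertainment bias of genotyping arrays. Passing calibration tests
therefore shows the statistics behave correctly under their own model
assumptions, not that real-data complications (LD between "independent"
hits, stratified GWAS errors) are harmless.

B-values (background-selection strength, 0–1000) are uniform random
integers unless a BED-like annotation is supplied: the tests need
matching *correctness*, not biologically realistic B landscapes.

## Phenotype construction

oxyHb = Hb·SaO₂/100 and deoxyHb = Hb − oxyHb (g/dL); the two parts sum
back to total hemoglobin by construction. For proportion traits
(successes of trials per individual), a binomial GLM with logit link and
per-individual trials is fitted on covariates, and the phenotype is the
residual on the log-odds scale: observed log-odds minus fitted log-odds.
The log-odds scale is used rather than raw odds because odds differences
are unbounded and asymmetric. Observed counts receive a 0.5
(Haldane–Anscombe) continuity correction so all-success and all-failure
individuals remain finite. Covariate lists are user-supplied; stepwise
covariate selection is deliberately out of scope. Collinear covariate
columns are dropped with a warning, which also makes the residuals
invariant to adding linear combinations of existing covariates.

## Mixed-model association

The GRM standardizes each SNP column by its estimated allele frequency
(centred at 2p̂, scaled by √(2p̂(1−p̂))); K = XXᵀ/M. Missing genotypes
are mean-imputed per SNP; monomorphic and sub-threshold-maf SNPs are
excluded and counted. For very small cohorts, reference allele
frequencies can be supplied, since sample centering biases off-diagonals
by −1/(n−1).

The LMM y = Wγ + gβ + u + ε with u ~ N(0, σ_g²K) is fitted
EMMAX-style: the variance ratio λ = σ_g²/σ_e² is estimated once on the
covariate-only model by 1-D maximum-likelihood in the eigenbasis of K,
then each SNP is tested by generalized least squares at that λ. The
likelihood-ratio statistic n·log(RSS₀/RSS₁) on the rotated, weighted
scale is referred to χ²₁; the standard error uses the (n−p) denominator.
At K = I this reduces *exactly* to OLS with its ML likelihood-ratio
test, which is the oracle the equivalence tests assert at 10⁻⁸ relative
error. The approximation (variance components not re-estimated per SNP)
trades a negligible power loss for orders-of-magnitude speed and is
standard at this scale. A ridge of 10⁻⁶ is added to K's diagonal if its
smallest eigenvalue is negative.

## Ascertainment

Cohort GWAS: SNPs at p ≤ 10⁻⁴ chain into a peak while each adjacent
significant pair on a chromosome is ≤ 200 kb apart (single-linkage on
neighbours, not a cap on peak span — "maximum inter-SNP distance"
supports neighbour chaining); the smallest-p SNP represents the peak,
ties breaking to the smaller position. External summary statistics:
candidates at p ≤ 10⁻⁵ present in the reference panel are pruned
greedily — pairs visited by descending dosage-r², the larger-p member
dropped whenever r² > 0.2 — leaving a pairwise r² ≤ 0.2 set. Both routes
polarize effects to the trait-increasing allele (α ≥ 0); polarization is
idempotent.

## Differentiation

Hudson's F_ST estimator is the default — at the frequency level
(p₁−p₂)²/(p₁(1−p₂)+p₂(1−p₁)), with the finite-sample correction when
haploid counts are given — because it is the modern, ratio-of-averages,
bias-robust choice; Reynolds' estimator sits behind a switch for
comparability with the branch statistic's original formulation. Negative
estimates are clamped to 0 so branch lengths stay non-negative, and
F_ST is capped at 1−10⁻¹² so T = −log(1−F_ST) stays finite; two
populations fixed for the same allele give F_ST = 0. PBS may legally be
negative (a target branch shorter than drift predicts).

The window scan flags SNPs above the empirical 99.9th PBS percentile and
scores non-overlapping windows by a binomial tail test of their flagged
count against the genome-wide flag rate. This is an explicit stand-in
for a region-enrichment procedure whose exact published form is not
described, not a reproduction of it.

## Matched controls and the adaptation tests

Controls are drawn per ascertained SNP from the panel SNPs sharing its
minor-allele-frequency bin (width 0.02) and, when enabled, its B-value
bin (width 100). Which frequency defines "minor" is configurable
(`maf_source`): the across-panel mean for the pairwise
frequency-difference test, the GWAS population for the genetic-value
tests — both readings of the matching rule appear in the literature, so
both are exposed with per-test defaults. An empty matching cell is an
error, never silently widened. Duplicates are forbidden within a set and
allowed across sets; defaults are 10,000 sets for the pairwise test and
5,000 for the genetic-value nulls.

Null sets inherit their partners' orientation by minor-allele status
(a control's "trait-increasing" allele is its minor allele exactly when
the partner's is), preserving the frequency-matching logic under
orientation. Empirical p-values use (r+1)/(B+1), so a reported 0.0000
means p < 1/B, never literal zero.

The diploid factor 2 in Z (and 4 in V_A) follows the genetic-value
machinery's source; it cancels in every standardized statistic and only
sets Z's reported scale. F is estimated on deviations standardized by
√(p̄(1−p̄)); its pseudo-inverse uses a relative eigenvalue tolerance of
10⁻⁸ restricted to the mean-centered (M−1)-dimensional subspace.

**Outlier test conditioning.** Standardized genetic values are centered,
so they satisfy Σ_m Z′_m = 0 exactly and F is singular with null vector
1. Conditioning a population on *all* others would therefore be
degenerate (the constraint determines it). One non-focal population is
dropped from the conditioning set — the constraint absorbs it — making
the MVN conditional proper; with two populations the subset is compared
to its unconditional drift SD. The dropped coordinate is the last
non-subset population in panel order, a deterministic choice; empirical
p-values are computed from null sets under the identical rule, so the
test is internally calibrated regardless of which coordinate is dropped
(the zero-shift rejection rate sits at the nominal level in the
calibration suite).

Excluding a dominant locus (a sweep SNP dominating the hit list) is a
drop-one re-run by set subtraction; no code path changes.

## Selection coefficients and power

The additive fitness model gives sW₀ = sW_m/(1+2sp); the implied
genotype–phenotype correlation uses the Hardy–Weinberg variance 2p(1−p),
which the standardization forces. Power for the two-sided zero-
correlation test defaults to the bias-corrected Fisher-z approximation
of the critical correlation (the form used by standard power packages;
both rejection tails are included so zero effect yields power ≈ α); a
noncentral-t variant sits behind a flag and agrees to ~0.01. Inversion
uses bracketed Brent root finding on s ∈ [0, 10] (tolerance well below
10⁻⁵; the round-trip test asserts 10⁻⁵). With the fertility-count
summary inputs (mean 5.67, SD 2.87, allele frequency 0.248, n = 991) the
minimum detectable coefficient at 80% power is ≈ 7.6% per allele — the
published per-locus figures of 6.6%/7.4% rest on an unstated sample
size, so only the order of magnitude is comparable, and the tests assert
exactly that.

## Problem sizes and numerical choices

The calibration suite runs 1,000 null drift replicates of a
five-population, 20,000-SNP panel with 40 ascertained SNPs and B = 500
null sets — enough for binomial 99% bounds of ±0.018 around the nominal
5% level while keeping the suite to a couple of minutes; the acceptance
script uses 500 replicates for the same check. Parameter recovery probes
shifts of 0.01/0.02/0.04 (where power rises from ~0.1 to ~0.8) over 80
replicates each at B = 200. All randomness flows from a single seed
through named per-stage substreams (numpy `SeedSequence`), so fixed
seeds give byte-identical outputs.

Degenerate inputs are errors, not silent fixes: all-zero effect sizes
(V_A = 0), empty matching cells, zero phenotypic variance, non-PSD
kinship after the ridge, subset equal to the full population list.
Boundary clipping during selection injection is flagged per SNP.

## Known limitations

* Panel SNPs are independent; LD-induced correlation between
  "independent" ascertained SNPs, the main practical threat to these
  tests, is not simulated.
* The EMMAX-style single variance-component estimate slightly misstates
  per-SNP test statistics when a SNP explains a large variance share.
* The truncated-Gaussian drift model distorts frequencies near 0/1
  under strong drift; calibration was verified at the default drift
  depths, not for highly diverged panels.
* Genotype uncertainty (imputation posteriors) is not modelled; hard
  calls are assumed, with mean imputation for missing genotypes.
* The binomial residual phenotype assumes per-woman binomial sampling
  with trials as weights; overdispersed (beta-binomial) outcomes will
  shrink residual variance estimates.
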