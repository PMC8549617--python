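# Methods

This note documents the statistical models, the numerical choices behind
them, and what the synthetic data generator does and does not emulate.

## Data model and QC

Genotypes are biallelic SNP dosages — counts of the alternate allele in
a diploid genotype, 0/1/2, with a sentinel (−1) for failed calls. The
"alternate" orientation follows the VCF ALT allele; re-orienting any
column to the per-SNP rare allele only flips the sign of its z-scores
and provably changes no kinship entry or test statistic (covered by an
invariance test), so no re-orientation is performed.

QC runs sequentially: (1) drop non-biallelic records, (2) drop SNPs with
missing fraction > 0.10 over current samples, (3) drop individuals with
missing fraction > 0.25 over the surviving SNPs. Missingness is
recomputed after each step — the stricter, order-stable reading — and
the filter is idempotent. No Hardy–Weinberg filtering is done anywhere:
when the phenotype itself may be under selection, HWE pruning would
remove exactly the signals of interest.

Standardization z-scores each SNP over its observed entries, with the
sample standard deviation (denominator N_obs − 1, matching R's default;
`ddof` is an argument if the population variant is wanted) and imputes
missing entries as 0, the mean z-score. Monomorphic columns are dropped
and reported, never silently kept.

## Kinship, PCA, pairwise Fst

K = XXᵀ/2n over the n standardized SNP columns; for a fully observed
panel trace(K) = (N−1)/2 exactly, which the tests use as an algebraic
anchor. PCA is a full symmetric eigendecomposition with eigenvalues
descending and a deterministic sign convention (largest-|loading| entry
positive) so repeated runs and plots are reproducible.

Pairwise F<sub>ST</sub> between sampling locations uses the
kinship-moment route: the raw moment matrix A_jk = mean over
co-observed loci of (x_j − 1)(x_k − 1) satisfies E[A_jk] = (1 − 4v) +
4v φ_jk, with v the mean ancestral heterozygosity term and φ the
kinship relative to the ancestral population. Anchoring at the
between-population mean of A (the most distant admissible pair, assumed
kinship 0) removes the unknown v: φ̂ = (A − A_between)/(1 − A_between).
For a pair of populations, F<sub>ST</sub> is the group-balanced mean of
the implied self-kinship (inbreeding) coefficients 2φ̂_jj − 1, clipped
to [0, 1]. The estimator is validated against an independent
Hudson-style ratio-of-averages oracle across F ∈ {0.05, 0.1, 0.2, 0.3}
(observed agreement within ±0.003 at 200 × 2,000 scale; the test bound
is ±0.03).

## Genetic sex

The sex chromosome makes males nearly uniformly heterozygous across its
markers, which injects a two-cluster direction into the kinship
spectrum. Rather than hard-coding which PC carries it (data-dependent;
PC3 on both the real survey and the default fixture), the PC among the
first ten with maximal point-biserial correlation to known phenotypic
sex is selected; if no PC reaches |r| > 0.5 the routine refuses with a
"no sex signal" error instead of guessing — removing the sex chromosome
must abolish the split, and does. Clustering is one-dimensional 2-means
with deterministic initialization at the 10th/90th percentiles and ties
assigned to the lower-center cluster; clusters map to sexes by majority
of the known labels, and agreement is summarized by a plain Pearson
chi-square without continuity correction. The per-SNP logistic scan
(sex ~ dosage, Wald test) uses a Newton fit with step-halving-free
damped updates; complete separation is detected by coefficient
divergence, capped at |z| = 30 and flagged.

## Random-intercept mixed model GWAS

Per SNP the model is √Hg = β₀ + β_g g + β_s sex + Σ_ℓ γ_ℓ length·1[ℓ]
+ b_loc + ε, with b_loc ~ N(0, σ²_b) on the sampling location and
length slopes nested within location (growth rates differ between
sites, so equal length does not mean equal age across sites). Location
is deliberately the *only* random effect: kinship and shared
environment are confounded at the location level, and one random
intercept absorbs both without pretending to separate them. Missing
dosages are mean-imputed per SNP so n is constant across the scan.

REML estimation profiles the variance ratio λ = σ²_b/σ²_e: V(λ) =
I + λZZᵀ is block diagonal with one rank-one block per location, so
V⁻¹ quantities reduce to per-group sums (Sherman–Morrison), and the
profile criterion

  (N−p) log RSS(λ) + log|V| + log|XᵀV⁻¹X|

is minimized over log λ ∈ [−10, 10] by bounded Brent search (tolerance
1e−8), with an explicit boundary check returning the σ²_b = 0 OLS fit
when the profile maximum sits at the lower bound. The engine reproduces
the balanced-design ANOVA closed form (σ̂²_e = MSW, σ̂²_b = (MSB −
MSW)/n) to 1e−6 and is never beaten by a dense-matrix profile grid.

The scan vectorizes this across SNPs: a coarse shared grid over log λ
(81 points) brackets each SNP's optimum, then golden-section search
runs on all per-SNP brackets simultaneously, with the covariate block
of each normal-equation system assembled from per-group rank-one
corrections as a batched (M × p × p) tensor. Scan and scalar engine
agree to ~1e−7 in −log₁₀ p.

P-values are two-sided Wald z-tests on the SNP coefficient — the mixed
model machinery this analysis mirrors reports none natively, and at
n ≈ 500 with 21 groups the normal reference is adequate (null scans
show genomic inflation ≈ 1.05 and uniform p by Kolmogorov–Smirnov);
Satterthwaite degrees of freedom would be the refinement if small-group
designs were targeted. The standardized effect size z-scores √Hg over
the analysis set and refits the same model for one SNP, giving the
per-allele effect in phenotype-SD units.

A note on parameterization: whether the per-location length terms ride
alongside a global intercept or replace it is a reparameterization that
leaves the SNP Wald test unchanged; the global-intercept form is used
throughout. In the nested length/sediment OLS comparison the
global-intercept form is not optional: per-location *intercepts* would
be exactly collinear with the location-constant sediment covariate and
make the 1-df F-test undefined (they would also contradict the
23-parameter accounting of the motivating analysis), so model 1 is
intercept + per-location slopes, and model 2 adds sediment.

## Significance thresholds

The family-wise null is the distribution of the largest −log₁₀ p among
m independent Uniform(0,1) p-values. Simulation uses the order-statistic
shortcut — the minimum of m uniforms is Beta(1, m), so one Beta draw per
replicate — with the direct m-draw route kept as a cross-check; both are
exposed and tested for mutual agreement. Closed forms
−log₁₀(1 − q^(1/m)) for q ∈ {0.5, 0.95} serve as analytic anchors
(4.6133 and 5.7441 at m = 28,450); at 10⁴ replicates the Monte-Carlo
standard errors are ≈ 0.006 (median) and ≈ 0.019 (95th percentile).
The Bonferroni line α/m is reported alongside.

## Phenotype models

Mercury is square-root transformed exactly once (recorded in each
report; negative mercury is rejected at the type level). Basin effects
on √Hg use the mixed-model engine with two orthogonal contrasts —
first basin vs the mean of the other two, second vs third — encoded via
the generalized-inverse coding C(CᵀC)⁻¹ so each coefficient *is* its
contrast of basin means. Sediment mercury differences between basins
are a location-level one-way ANOVA on √sediment with Tukey HSD
pairwise tests; Tukey p-values come from the studentized range
distribution (scipy's implementation, numerically integrated).

## LFMM

With the standardized genotype matrix Y as response, the model
Y = UVᵀ + XBᵀ + E is fitted by minimizing ‖Y − UVᵀ − XBᵀ‖²_F +
λ‖B‖²_F. The global minimizer is analytic: with the SVD X = QΣRᵀ, the
objective equals ‖Φ(Y − W)‖²_F in W = UVᵀ where Φ shrinks the
covariate subspace by √(λ/(σ² + λ)); hence W = Φ⁻¹·svd_K(ΦY) and B
solves the ridge system on the residual. An alternating-least-squares
route is kept as fallback (λ = 0 with K > 0) and as the independent
oracle in tests (agreement 1e−6). Defaults: K = 7 latent factors (the
leading components that absorb metapopulation structure) and λ = 1e−5
(near-minimal shrinkage; the penalty exists to stabilize the covariate
block, and no cross-validation of either is attempted). Mercury enters
the covariate block as √Hg, matching the LMM's response scale.

Association tests regress each SNP on [1, X, U] by OLS and take the
t-statistic of the target covariate as z; the genomic inflation factor
median(z²)/0.4549 rescales z² before the χ²₁ upper tail. With seven
factors against 21 demes the raw statistics remain inflated (GIF ≈ 4–5
on the default fixture) — precisely the regime the GIF calibration is
for; calibrated p-values are monotone in |z| by construction.

## Fst outliers

Weir–Cockerham (1984) variance components a (between-population), b
(between individuals within) and c (within individuals) are computed
per locus from per-group allele frequencies, sizes and observed
heterozygosities, missing genotypes excluded locus-wise. Two ratios are
kept: the finite-sample corrected a/(a+b+c), and an uncorrected variant
in which the correction factors are replaced by their large-n limits
(a_nc = (n̄/n_c)s², b_nc + c_nc = p̄q̄ − s²(r−1)/r). The uncorrected
ratio is never negative, exceeds the corrected one in expectation, and
— the point of keeping it — its neutral distribution is approximately
(F̄ST/df)·χ²_df.

The neutral null (F̄ST, df) is inferred by maximum likelihood on the
central body: loci with He < 0.1 removed, lowest and highest 5 % of
uncorrected FST trimmed, likelihood truncated to the kept interval, and
nested bounded 1-D optimization (profile over log df, inner over log
F̄ST, tolerances 1e−7/1e−8, bound hits flagged). Parameter recovery on
(df = 20, F̄ST = 0.05)·χ² draws is within (±10 %, ±5 %), and with no
trimming the fitted F̄ST reproduces the sample mean. Right-tail
p-values from the fitted null get Benjamini–Hochberg q-values (a
deterministic, dependency-free stand-in for the q-value estimator some
implementations use) among He-passing loci; outliers are q < 0.05. The
scan runs separately by the 21 locations and by the 3 basins, always
excluding the sex chromosome, whose sex-linked differentiation would
otherwise flood the tail.

## Synthetic metapopulation

The generator emulates the survey design: 21 demes in 3 basins (7
each), 25 fish per deme, 5,000 SNPs over 21 chromosomes named
groupI…groupXXI. Allele frequencies follow a two-level Balding–Nichols
hierarchy — ancestral p₀ ~ U(0.05, 0.95), basin ~ BN(p₀, F_b = 0.05),
deme ~ BN(basin, F_d = 0.15) — chosen because BN's expected FST equals
its F parameter, giving analytic calibration bands: same-basin pairs
differentiate by F_d, cross-basin by F_b + (1−F_b)F_d ≈ 0.19, mean
pairwise FST ≈ 0.18, the ~0.2 regime of the real survey.

Sex is phenomenological XY: on groupXIX, 150 of ~240 SNPs are
sex-linked (males fixed heterozygous with 2 % flip noise; females
~Binomial(2, 0.05)). Near-chromosome-wide linkage is the realistic
condition — in the real data essentially every sex-chromosome SNP is
strongly sex-associated — and is what makes a top-10 PC carry the sex
split against FST ≈ 0.2 background structure; a 20-SNP sex signal is
only recoverable under weak structure, which a dedicated test
exercises.

The phenotype is built on the √ scale: deme intercept (basin means
8/11.5/10.5 √(ng/g), deme SD 1.2), location-specific length slope
(0.06 ± 0.02 per mm, length ~ N(deme mean, 8 mm)), a 0.2 sex effect,
one causal SNP on groupIV at 0.24 SD per allele (converted to a raw
slope via the analytic total-SD implied by the variance components;
ancestral frequency drawn from U(0.3, 0.7) so the variant is common),
and N(0, 1) residuals; mercury is the square, floored just above zero.
Because the realized total SD varies between seeds with the 21 deme
draws, recovery tests compare the estimate to the *realized* planted
standardized effect (raw slope over the realized phenotype SD).
Sediment mercury is log-normal per location with basin-level medians
(~60/250/350 µg/kg) — correlated with muscle mercury through basin, as
in the field. Missingness is completely at random at 2 %, plus 100
designated high-missingness SNPs (20 %) and 3 individuals (35 %) so the
QC filters always have work to do.

Deliberately not modelled: linkage disequilibrium and recombination
(every SNP drifts independently), migration dynamics, assay error in
mercury chemistry, and age as distinct from length. Passing recovery
tests therefore demonstrate correctness of the estimators under the
stated generative assumptions, not robustness to LD structure or
spatially autocorrelated environments.

## Problem sizes and determinism

Default sizes — 5,000 SNPs for fixtures, 28,450 tests only in the
threshold simulation where the real panel's multiplicity matters, 10⁴
threshold replicates, 20-replicate power studies — keep every analysis
to seconds-to-minutes on a single core while leaving Monte-Carlo error
well inside the test tolerances. All randomness flows from explicit
seeds through `numpy.random.default_rng`; the pipeline writes no
timestamps, so identical configs reproduce byte-identical report
bundles (verified by checksum in the tests).
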