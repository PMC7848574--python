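# Methods

This note records the models, estimators, parameter choices and known
limitations of `glpanmix`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Genotype likelihoods and allele frequencies

Reads at a biallelic site are conditionally independent given the
genotype. With dosage g copies of the minor allele and base error ε,

    P(read = major | g) = (1 − g/2)(1 − ε) + (g/2)(ε/3)
    P(read = minor | g) = (g/2)(1 − ε) + (1 − g/2)(ε/3)
    P(read = other | g) = 2ε/3            (constant in g)

The site likelihood is the product over reads, stored log-normalized so
max_g log L(g) = 0; adding any constant to the three log-likelihoods
changes no downstream estimate (tested). ε is a single scalar per run:
the simulator has one error rate, and the ≥Q20 base-quality regime this
emulates makes near-constant error a fair desk-scale model. Real
per-base qualities are out of scope.

Population allele frequencies maximize the observed-data likelihood
under Hardy–Weinberg by EM: posterior expected dosages at the current f,
then f ← mean dosage / 2 over individuals with at least one read.
Start f₀ = 0.1, tolerance |Δf| < 1e-8, ≤200 iterations, with an
active-set update (converged sites drop out) and a monotonicity check on
every run. Individuals with zero reads are excluded from the mean, which
makes the estimate exactly invariant to adding uncovered individuals.
The EM agrees with a 1-D grid search of the same likelihood to ≤1e-3
(tested on random small instances).

SNP calling uses LRT = 2[log L(f̂) − log L(0)] against the upper tail of
χ²(1), threshold p < 1e-6. At the f = 0 boundary the correct null is the
mixture ½χ²(0) + ½χ²(1); using plain χ²(1) is conservative and matches
the convention of the tools this replaces. MAF thresholds are inclusive
(≥ 0.05, ≥ 0.10) on the folded frequency; allele ties break
lexicographically (A < C < G < T).

## PCA, admixture, kinship

PCA iterates individual allele frequencies: iteration 0 gives every
individual the pooled f; each pass standardizes posterior expected
dosages by √(2f(1−f)), forms C = XXᵀ/M, takes the top-e eigenvectors
(e = largest gap among the leading 10 eigenvalues unless fixed), and
rebuilds per-individual frequencies from the rank-e reconstruction,
clamped to [1e-4, 1−1e-4]. Stops when C changes < 1e-7 in max norm or
after 100 passes. On fully certain likelihoods this equals PCA of the
true standardized dosage matrix to 1e-6 (tested). A caveat documented
for iterative schemes of this kind: under a pure null the rank-e
feedback can mildly inflate one or two leading eigenvalues; the
selection statistic's eigenvalue normalization absorbs this.

Admixture maximizes Σᵢⱼ log Σ_g GL_ijg·Binom(g; 2, h_ij), h = QF, by EM
with F clamped to [1e-6, 1−1e-6]. Plain EM needs thousands of
iterations to converge Q on this likelihood, so each cycle applies
SQUAREM extrapolation (two base EM steps, a quasi-Newton step length,
one stabilizing EM step) and falls back to the plain double step
whenever extrapolation does not improve the likelihood — monotonicity is
asserted every cycle. Multi-start (default 5 seeds) keeps the best
likelihood; convergence at |Δ log L| < 1e-4 per cycle. Sites beyond a
2,000,000 cap are uniformly downsampled with the run seed.

Kinship is the correlation of per-site-centered posterior expected
dosages, dropping site pairs where either individual has no reads.
Identical genotype vectors give 1.0; a diploid pair sharing one founder
haplotype correlates ~0.25–0.5 over the block. Note that heterozygote
carriers of a two-haplotype block are mixtures: their correlation with
founder homozygotes exceeds their correlation with each other, so
"within-class kinship > between-class" holds for the homozygote classes
while the heterozygotes are identified by their middle position on the
kinship leading eigenvector.

## Scans

The ΔAF track is the signed difference of group-wise EM frequencies on a
shared oriented site list (so orientation mismatches cannot arise), with
a 100-SNP rolling mean of |ΔAF| per chromosome, step 1, defined only
where a full window fits. |ΔAF| is averaged rather than the signed value
because signed means cancel. The binomial reference noise for groups of
n_A, n_B diploids is √(f(1−f)(1/2n_A + 1/2n_B)); at 1.4× the
GL-estimation error inflates the realized noise ~1.3–1.5-fold above this
floor, which the 3× bound comfortably accommodates.

The per-SNP selection statistic is D_j = (u₁ᵀx̃_j)² / λ̂₁ with x̃_j the
standardized posterior dosages, u₁ the unit-norm leading eigenvector and
λ̂₁ its Rayleigh quotient on the scanned SNPs. This makes mean(D) = 1
identically and D ~ χ²(1) under neutrality (null calibration and
p-value uniformity are tested at 20,000 SNPs, 400 diploids). A plain
(n−1)r² form is inflated by the top-eigenvalue noise of the estimated
PC (Marchenko–Pastur λ₁ ≈ (1+√(n/M))²) and was rejected for that
reason. P-values are upper-tail χ²(1) — the convention for outlier
scans; a source describing the same computation as "two-tailed with
lower.tail = TRUE" is internally inconsistent and was not followed.
Because mean(D) = 1, the inside/outside separation at an inversion
scales like (1/0.455)(1/frac)(median r²/mean r²) with frac the block's
share of scanned SNPs: expect ~20–50× at desk scale and 100× or more
only when the block is a sub-percent fraction of the SNP list, as in a
whole-genome scan.

## Inversion-haplotype genotyping

Candidate-region SNPs are ranked by the selection statistic; the top
fraction (default 0.10, minimum 20; the pipeline keeps ~200 SNPs as its
kinship panel) feeds a kinship matrix whose leading eigenvector is
clustered by 1-D k-means, k = 3. The middle cluster on the axis is the
heterozygote group; of the two extremes, the smaller cluster is labeled
hom2, because haplotype 2 is by definition the less common regional
haplotype. (Ordering clusters by raw mean minor dosage is not monotone
in haplotype copy number under a two-founder architecture, since the
block-tagging allele is not consistently the minor allele site by site.)
Individuals beyond 3 within-cluster SD of their center are left
unassigned; if the three clusters are indistinguishable (silhouette
< 0.2) everything is unassigned with a warning. Which individuals real
data would leave unassignable is unknowable here; the 3-SD rule is this
package's own determinism-friendly choice.

The haplotype-frequency homogeneity test is the Pearson χ² on the 2×L
table of hap2/hap1 allele counts across localities (df = L−1, no
continuity correction), dropping localities without assigned
individuals.

## Diversity

Alleles are polarized by the pooled outgroup read majority (ties and
uncovered sites → N, site skipped). Sites keep a per-population total
depth in [15, 1000]; an individual contributes at a site only with ≥1
read — the fractional per-individual depth flag of the original tooling
is recorded but not given fractional semantics. No MAF filter is applied
at this stage, since frequency cutoffs bias SFS-based estimators.

The sample-allele-frequency likelihood over derived counts d ∈ 0..2n is

    P(X | d) = Σ_{g: Σg=d} Π_i L_i(g_i) C(2, g_i) / C(2n, d),

computed by DP convolution with the (1, 2, 1) heterozygote weight and
the hypergeometric C(2n, d) normalization. The weighting matters: an
unweighted configuration sum over-weights intermediate d combinatorially
whenever individuals are uncovered, which at 1.4× inflates θ_π enough to
invert group contrasts. A brute-force enumeration oracle (n ≤ 3) checks
the DP exactly.

The unfolded SFS is the EM maximizer of Σ_sites log Σ_d SFS_d·SAF(s,d)
(tolerance 1e-6 relative, ≤500 iterations, monotonicity asserted), used
as an empirical-Bayes prior for per-site posteriors:
θ_π-site = E[d(2n−d)]/C(2n,2), segregation probability P(0 < d < 2n).
Windows of 5,000 bp sum these and divide by the usable-site count;
Tajima's D uses the window totals with the standard 1989 constants at
2n chromosomes, where n is the group size — with the flat-likelihood
convention uncovered individuals still enter the SAF, so the nominal
sample size is the consistent choice. D is emitted as missing (not 0)
when the window has no expected segregating sites. Group-wise regional
D uses an SFS prior estimated from all of the group's sites, not the
region alone, mirroring the genome-wide-prior-then-windows flow of the
tooling this replaces; a few hundred region-only sites under-regularize
low-coverage posteriors.

## Synthetic data: what it emulates and what it does not

Ancestral (derived-allele) frequencies are uniform on [0.05, 0.95];
locality frequencies are Balding–Nichols draws whose Hudson-estimator
FST equals the target (±0.01 at 50,000 sites, tested), with
fst_target = 0 giving exact panmixia. The outgroup mostly retains the
ancestral allele (half-normal derived frequency, scale 0.2) and is fixed
for the opposite of the ingroup major at 15% of sites — the genome-wide
fixed interspecies differences. The inversion is a zero-recombination
block with two founder classes: haplotype 1 draws alleles at the
ancestral frequencies, haplotype 2 is a single founder configuration
plus new mutations at 0.002 per site per copy, giving hap2 homozygotes
their depressed diversity; frequencies 0.29 (ingroup) and 0.98
(outgroup, emulating the post-sweep state). Introgression copies
100-kb outgroup segments onto one chromosome copy in designated
localities until the per-individual ancestry fraction is reached.
Depth is Poisson(1.4); reads follow the same error model the GL stage
assumes.

Deliberately not emulated: recombination and linkage outside the block
(sites are exchangeable given frequencies), rare variants below 5%
ancestral frequency and invariant sites (every simulated site is a
common SNP, so absolute θ values are per-SNP, not per-bp — comparisons
between groups and regions are meaningful, genome-wide absolute
diversity is not), indels and other structural variation, per-base
quality variation, and mapping artifacts. Passing tests therefore show
that the estimators are correct and calibrated under the stated
generative model, not that they are robust to alignment or quality
pathologies of real data.

## Load model

Genotype fitnesses 1 : 1−s/2 : 1−s give the one-generation recursion
p' = (p − pqs/2)/(1 − qs), solved in closed form
s = Δp / (q(p' − p/2)); shifts beyond the s = 1 ceiling (p' = 1 − q/2)
raise an error. Survival is mean fitness relative to the fittest
genotype, w̄ = 1 − qs, and multiplies across independent loci; reporting
rounds mortality to the nearest integer percent and reciprocal survival
to the nearest power of ten. A finite-cohort simulation (10⁶
individuals, viability proportional to fitness) reproduces both the
realized Δp and the survival fraction (tested). The parameterization —
p₀ = 0.5, codominance, fittest-genotype normalization, multiplicative
independence — is a reconstruction validated by reproducing both
published summary values exactly; every constant is an argument.

## Pipeline and reproducibility

`run_panmixia_study` fans a single seed into per-stage child seeds
through one `default_rng(seed).integers(2³¹)` draw, so identical
configuration and seed give byte-identical JSON reports (wall time is
deliberately excluded). The report's three panmixia surfaces are:
one-way ANOVA of PC1–4 scores on locality (no differentiation when
min p > 1e-3); admixture with the between/within locality Q-variance
ratio < 2 and a Q-on-locality ANOVA p > 1e-3 — the ratio alone cannot
flag modest structure at 1.4× because estimation noise dominates
within-locality variance; and the ΔAF surface combining the 3×-binomial
window bound with a label-permutation calibration of mean squared ΔAF
(ratio < 1.25), because a 100-SNP rolling mean cannot exceed 3× binomial
noise at any desk-scale FST even when structure is real. The
`structured` preset (FST 0.05, 24 diploids per locality) trips all three
surfaces; the `panmictic` preset clears them.

Problem sizes used by the test suite — 20,000 SNPs × 400 diploids for
null calibration, five replicate seeds of 4,000 SNPs × 449 individuals
for inversion recovery, 50,000 sites for the FST oracle — were chosen as
the scale at which the tested quantities stabilize on one CPU.
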