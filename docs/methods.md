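# Methods

This note documents the models and estimators implemented in `metabogwas`,
the defaults and why they were chosen, what the synthetic cohorts do and do
not emulate, and the numerical conventions used throughout.

## Coordinates and formats

All internal coordinates are 1-based inclusive (VCF/GFF3 convention); BED
export converts to 0-based half-open. Genotypes are additive alt-allele
dosages 0/1/2 with `nan` for missing; phasing is ignored and multi-allelic
records are skipped (or rejected in strict mode). Missing dosages are kept
in the matrix — consumers (kinship, scans) mean-impute per SNP, which is
deterministic and keeps a single source of truth.

## Variant and gene QC

SNPs are retained when MAF ≥ 0.05, missing rate ≤ 0.2, and the
Hardy–Weinberg exact-test p ≥ 1e-6. The HWE test is the exact conditional
test: with allele counts fixed, the probability of every heterozygote
configuration is enumerated and those no more likely than the observed one
are summed (no mid-p correction) — the standard VCF-QC behaviour and fully
deterministic. Genes are kept when expressed at ≥ 1 FPKM in ≥ 80% of
accessions, boundaries inclusive; both cutoffs are parameters, since the
">" vs "≥" reading of this filter is genuinely ambiguous in practice and
changes only boundary cases.

## Mixed-model metabolite GWAS

Traits are log abundances. The model is y = Xβ + u + e with
u ~ N(0, σ²_g K) and e ~ N(0, σ²_e I). K is the centered genomic
relationship matrix Z Zᵀ / (2 Σ p(1−p)) with Z the frequency-centered
dosage matrix (mean diagonal ≈ 1 in an HWE panel; with sample-frequency
centering row sums are zero, so the mean off-diagonal is exactly
−mean(diag)/(n−1)). Population structure enters as fixed covariates: an
intercept plus the top genotype principal components (default 3). A
supplied ancestry matrix can be used instead; PCs were chosen because they
fill the same covariate role without an external structure-estimation tool.

REML estimation profiles the restricted likelihood over δ = σ²_e/σ²_g on
the kinship spectrum: K is eigendecomposed once, the likelihood is
evaluated on a 64-point grid of log δ over [1e-5, 1e5] and refined by
bounded scalar minimization (xatol 1e-10). The per-marker scan reuses the
null-model variance components for every SNP (the P3D/EMMAX
approximation), whitens the rotated data by (λᵢ+δ)^{-1/2}, residualizes
trait and dosages against the covariates, and computes Wald t statistics
with n − q − 1 degrees of freedom. The per-SNP explained variance r² is the
squared partial correlation t²/(t²+df). With K = I this reduces exactly to
OLS, which the tests assert at 1e-10 relative. An exact mode re-optimizes
the restricted likelihood with the marker as a fixed effect
(`lmm_scan(..., exact=True)`); it is quadratic-cost and intended for small
cross-checks — the P3D approximation and the exact mode agree in ranking
but not to numerical precision, which is the known cost of P3D.

The genome-wide significance default is the constant 3.19e-7, kept verbatim
from the study design this package follows; it is not 0.05/486,009, so it
is stored as a named constant and `bonferroni_threshold(n, alpha)` remains
available for plain corrections (0.05/22,374 = 2.23e-6 is the
correlation-network default).

**Lead SNPs** are extracted per trait by greedy clumping: repeatedly take
the most significant remaining marker below threshold (ties broken by
leftmost chrom/pos) and remove all significant markers within 100 kb on the
same chromosome. Distance clumping was chosen over fixed tiling because it
is order-invariant and does not split a peak across a tile boundary.

**Hotspots.** The genome is tiled into non-overlapping 1-Mb windows from
position 1 (last partial window kept). Under the null, the observed number
of lead SNPs is re-placed uniformly at random over the filtered SNP
positions; each of 1000 permutations records the genome-wide maximum
per-window count, and the cutoff is the smallest integer c with
P(max ≥ c) < 0.05 — family-wise control by construction. Re-placement over
SNP positions (rather than base pairs) preserves the panel's SNP-density
profile. On a lead-SNP load and genome size comparable to the study's
(8,685 leads, ~225 Mb), the permutation cutoff lands within a few counts of
the analytic maximum-of-Poisson value, in the same range as the study's
printed per-season cutoffs (50 and 59).

## eQTL mapping

Expression is log2(FPKM+1)-transformed and residualized against the same PC
covariates (no kinship random effect — matching the standard matrix-eQTL
model class); dosages are residualized identically. For every (gene, SNP)
pair the slope t statistic comes from the residual correlation with
n − 2 − q degrees of freedom, computed in chunked matrix form, and records
are streamed above a p ≤ 1e-3 prefilter to bound output size. A record is
cis when the SNP lies on the gene's chromosome within 30 kb of the
strand-aware TSS (start on +, end on −; boundary inclusive), else trans.
Per-gene greedy clumping at a 30-kb radius uses the kind-specific defaults
p ≤ 1.99e-3 (cis) and p ≤ 1.99e-6 (trans), kept as constants because their
denominators are not derivable from the printed test counts; a plain
Bonferroni mode is available. Trans-hotspots reuse the mGWAS permutation
machinery on clumped trans-eQTL positions.

## Integration

Gene–metabolite edges are Pearson correlations of the log2(x+1) matrices
with p from the two-sided t transform; edges need r > 0.4 and
p < 0.05/22,374. Candidate genes for a metabolite are genes whose span
expanded by 25 kb contains one of its lead SNPs and which hold a retained
edge to it; the flank is interpreted as gene-span-to-lead distance.

Co-expression modules use unsigned adjacency a_ij = |cor|^β with β = 8,
topological overlap TOM_ij = (Σ_k a_ik a_kj + a_ij)/(min(k_i,k_j)+1−a_ij),
average-linkage clustering of 1 − TOM, and a static tree cut. With β = 8
the between-branch merges concentrate just below dissimilarity 1 while
within-branch merges sit lower, so the default cut is placed in the middle
of the largest gap between consecutive merge heights in the upper half of
the dendrogram — deterministic, parameter-free, and exact on block
structure; a fixed cut height can be supplied instead. Clusters smaller
than 30 genes go to an unassigned pool. Eigengenes are the first principal
component of the scaled member expression, sign-anchored to correlate
positively with the mean member profile. Module–metabolite association is
eigengene–metabolite Pearson correlation with a Bonferroni default over
modules × metabolites.

## Metabolome statistics

CV is the sample (n−1) standard deviation over the mean, on raw
abundances. Broad-sense heritability uses the two seasonal replicates in a
one-way random-effects ANOVA with accession as the grouping factor:
var_E = MS_within, var_G = max(0, (MS_between − MS_within)/2),
H² = var_G/(var_G+var_E), computed on log abundances. This is the minimal
estimator consistent with the ratio definition and two replicates.

PLS-DA is NIPALS PLS1 on the centered two-group indicator with features
log2(x+1)-transformed and unit-variance scaled (2 components by default;
the transform is a documented convention, configurable). VIP_j =
√(p · Σ_a SS_a w²_ja / Σ_a SS_a) with SS_a the y sum of squares explained
by component a; Σ VIP² = p holds identically. Differential metabolites
require FC = mean(A)/mean(B) on raw abundances ≥ 1.5 or ≤ 0.67 and
VIP ≥ 1; group order is explicit because the printed thresholds are
asymmetric (0.67 ≠ 1/1.5 exactly), and an option sets fc_low = 1/fc_high
for strict direction symmetry. Means (not medians) define FC. A feature is
group-specific when detected (≥ floor) in ≥ 80% of that group's samples and
in ≤ 5% of every other group's. Environmental levels bin rainfall
(1–370–740–1110–1480–1850 mm) and growing-season temperature
(7–10–13–16–19–23 °C) into five classes, interior boundaries half-open
[lower, upper), outermost upper bound inclusive.

## Selection scans

The site estimator is the two-population Weir–Cockerham (1984) analysis of
variance with components a (among populations), b (among individuals), and
c (within individuals); θ = a/(a+b+c). Fixed differences give a = 1/2,
θ = 1 exactly; identical all-heterozygote samples give a = 0, θ = 0
exactly. Windows of 100 kb stepped by 10 kb aggregate by the weighted
estimator Σa/Σ(a+b+c) over usable sites (sites monomorphic across both
groups excluded); the weighted form is the consistent one — the plain mean
of per-site ratios is biased downward by Jensen's inequality, which the
tests demonstrate. Negative window values are retained for quantile
computation; the top 5% (linear-interpolation quantile, ties included) are
sweeps, merged into regions for reporting, genome-wide rather than
per-chromosome. The three standard contrasts are domestication (wild +
ornamental vs landrace), improvement (landrace vs improved), and
differentiation (eastern vs western improved).

## Synthetic cohorts

`simulate_population` draws Balding–Nichols genotypes: ancestral frequency
p₀ ~ U(0.05, 0.95), group frequency ~ Beta(p₀(1−F)/F, (1−p₀)(1−F)/F) with
background F = 0.1 by default, genotypes Binomial(2, p_group). Group sizes
default to 40 wild, 90 landrace, 60 eastern and 62 western improved
(252 accessions); eight 28-Mb chromosomes approximate a 224-Mb genome.
Sites with realized pooled MAF < 0.05 are redrawn, mimicking a post-QC
panel. Inside declared sweep windows the contrast groups' frequencies are
forced to opposite extremes (gap 0.8 by default). SNP counts are a desk-
scale density (defaults in the low thousands); experiments choose counts
per scenario and state them in their docstrings.

Metabolites have unit-variance latent log traits per season: an optional
single causal SNP (variance share `mqtl_pve`), a polygenic part drawn from
N(0, K) filling the genetic share to `h2_target` (components are rescaled
to exact realized variances), a season-wide shift ~ N(0, 0.3²) common to
all accessions, and residual noise with variance 1 − h² − σ²_season.
Because the shift is common, the two-replicate ANOVA sees
var_E = σ²_noise + σ²_season, so the estimator recovers `h2_target` on
average — the tests check a mean bias below 0.05 at 500 metabolites.
Abundances are exp(latent), giving the positively skewed, high-CV
intensities typical of metabolite features. Expression is built the same
way with planted cis SNPs (nearest SNP within 30 kb of the TSS), one shared
trans-regulator SNP for a block of genes, and disjoint latent-factor module
blocks; FPKM-like values are exp rescaled to median 5.

What the generator does **not** emulate: linkage disequilibrium beyond
window-level coincidence (each SNP is drawn independently, so clumps are
single markers and localization tests are easier than on real LD blocks),
recombination maps, measurement batch structure, detection limits/missing
features in the metabolome, and mass-spectral artifacts. Passing recovery
tests therefore demonstrates the correctness of the inference chain under
its own assumptions, not field performance on real panels.

## Experiment sizes and determinism

The bundled experiments (`metabogwas.evaluation`) use: 300 samples × 2,000
SNPs × 100 traits for null calibration; 20 planted-mQTL traits at PVE 0.2
over 3,000 SNPs for localization; 10 seeds × (100 genes, 1,500 SNPs,
50-gene trans block) for hotspot recovery; 10 seeds × 2 planted 100-kb
windows over 5,000 SNPs for sweeps; 500 metabolites for H²; and three
50-gene blocks among 180 genes for modules. These sizes give stable rates
while keeping each experiment in the seconds-to-a-minute range. Every
source of randomness descends from a named seed through
`numpy.random.SeedSequence`; permutation tests take explicit seeds; reruns
of the pipeline with the same config are byte-identical, which the
acceptance script verifies by hashing all outputs.
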