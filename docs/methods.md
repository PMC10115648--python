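# Methods

This note documents the statistical models implemented in `nlpipe`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Data model and conventions

All tables are TSV with a header row; missing values are written as `NA`
(empty cells are accepted on read). After alignment, sample order is
canonicalized to sorted sample id so every downstream stage is
order-stable. Analyses are complete-case: a sample missing any variable a
model touches is dropped from that model, with counts logged per reason.
Categorical covariates are dummy-encoded against the lexicographically
first level; the design matrix always carries an intercept and is checked
for full column rank, with offending columns reported rather than dropped.
Missing lipid concentrations (the upstream quantification does not define
an imputation) simply exclude that sample from analyses touching that
lipid.

## QC and transforms

*Technical-variance filter.* A species is excluded when the ordinary
least-squares R² of its raw concentration on processing batch plus
injection order strictly exceeds 0.10. The filter runs on raw
concentrations because it precedes any transformation; with a single batch
level it reduces to injection order alone. Note the null expectation of
this R² is roughly p/n for p design columns, so at small n with many
batches the filter removes noise species — it is intended for cohort-scale
data.

*Statistical outliers.* Per sample we compute (1) an extremeness count —
the number of species whose single-pass z-score exceeds 3 in absolute
value — and (2) a PCA distance. Both 99th-percentile thresholds use the
empirical quantile (linear/type-7 interpolation), and a sample is flagged
only when it exceeds both (an AND rule). Two open points were resolved as
follows: z-scores are computed in one pass with candidate outliers
included, because iterative re-estimation makes the flag depend on the
visit order and is harder to reproduce; and the PCA distance uses the full
score vector, which equals the Euclidean norm of the centered z-score row
and avoids an arbitrary choice of component count. Storage outliers are
flagged at ≥ 2,500 days (inclusive).

*Transforms.* The rank-based inverse normal transform maps ranks through
Φ⁻¹((r − ½)/n) with average ranks for ties; the ½ offset is the symmetric
standard in omics and is configurable. The collection-time covariate is
sin(2π·t/2400) for 24-h clock values. Inferred clinical lipids follow the
ontology: total cholesterol = free cholesterol + the cholesteryl ester
class; total triglycerides = the TG single-ion-monitoring class. Class
totals sum member species, except TG and TG(O) which are totaled from
their SIM species only.

## OREML

The model is y = Cβ + Wu + e with u ~ N(0, Iσ²_u), e ~ N(0, Iσ²_e) and W
the column-standardized inverse-normal lipid matrix, equivalently
var(y) = A_o σ²_o + I σ²_e with A_o = WW′/m. With one variance component
only the ratio φ = σ²_o/(σ²_o + σ²_e) matters after profiling out the
total variance, so the REML log-likelihood is maximized over φ ∈ [0, 1) by
bounded Brent search on the exact profiled criterion, evaluated cheaply in
the eigenbasis of A_o (one n×n eigendecomposition per ORM, then O(n·p)
per candidate φ). This makes the optimum directly checkable against a grid
search, which the tests do. Estimates are clamped at the φ = 0 boundary;
standard errors for (σ²_o, σ²_e) come from the inverse average-information
matrix at the optimum and the SE of R² by the delta method (one-sided at
the boundary). The σ²_o = 0 test refers 2Δlog L to the 50:50 mixture of
χ²₀ and χ²₁ appropriate for a parameter on its boundary, so
p = ½·P(χ²₁ ≥ LRT) with p = 1 at LRT = 0. Binary traits are analyzed on
the observed 0/1 scale; no liability-scale conversion is attempted. An ORM
proportional to the identity makes the two components unidentifiable and
raises an error. When several traits are analyzed, FDR control across
traits is Benjamini–Hochberg.

## LWAS and multiple testing

Quantitative traits are modeled as trait ~ lipid + covariates and binary
traits as logistic diagnosis ~ lipid + covariates; the regression
direction for the quantitative family was an open choice and trait-as-
response was selected so effect signs are comparable across the two
families. The linear family is computed by Frisch–Waugh–Lovell
partialling, which is algebraically the joint OLS fit but vectorizes
across hundreds of lipids; tests assert equality with explicit statsmodels
fits to 1e-8. Logistic separation or non-convergence flags the lipid with
a missing p and a reason rather than failing the scan.

The effective number of tests m_eff is the smallest number of principal
components of the lipid correlation matrix (correlation, not covariance,
so each transformed lipid counts equally) whose cumulative explained
variance reaches the threshold, inclusive; the corrected significance
threshold is 0.05/m_eff, applied per trait. At 0.99 this reproduces
1.66 × 10⁻⁴ for 302 effective species and 1.56 × 10⁻³ for 32 effective
classes; 0.95 is carried as a sensitivity denominator.

The joint model over significant hits starts from all hits plus
covariates and removes the lipid whose removal most lowers the AIC until
no removal helps; covariates are never dropped, and exact duplicate
columns are pruned first (with a log line) instead of pseudo-inverting a
singular system. Group-variance differences use the classical Levene
statistic (deviations from the group mean; the median-centered variant is
available via an argument) on covariate residuals, corrected by the same
0.05/m_eff rule. A mixed-model association variant was deliberately not
implemented: on data this correlated it deflates test statistics, and the
fixed-effects models above are the supported path.

## LSEA

Per-lipid t (or logistic z) statistics come from the marginal LWAS fits
with the identical covariate set. The covariate-adjusted lipid correlation
R is the correlation of covariate residuals. For a set G,
S = Σ_{i∈G} t_i / √(Σ_{i,j∈G} R_ij) and p refers S² to χ²₁ (the
finite-sample statistic is an F, which converges to χ²₁ at these sample
sizes). The denominator is the null standard deviation of the numerator,
which yields singleton identity (S = t), duplication invariance, and
cancellation of opposite-signed effects — all asserted exactly in tests. A
set whose summed correlation is non-positive breaks the variance
approximation and is reported as an error, not clamped. Sets are every
class/subclass/feature/domain annotation with at least `min_set_size = 2`
analyzed members (singletons duplicate the LWAS); when composite
annotations share a hierarchical label only the most significant is kept;
q-values are Benjamini–Hochberg across all tested sets within a trait
(stratification by annotation level was an open choice; joint correction
is the more conservative reading).

## Profiles, diet, microbiome, dissection

A trait's lipidome profile is PC1 of the standardized significant hit
species. PC1's sign is arbitrary, so it is oriented by a sign-weighted
vote: flip when Σ_i loading_i · sign(effect_i) < 0. (A loading–effect
correlation was considered and rejected: with near-constant loadings, as a
one-factor hit set produces, its sign is noise.) With a single hit the
profile degenerates to that standardized lipid, with a warning. An
additional global flip is available for presentation.

Dietary shares are centered log-ratio transformed (zeros replaced by half
the smallest positive share in that sample) before PCA, making the
pipeline invariant to per-sample rescaling; raw PC scores (zero mean,
total variance preserved) and standardized scores (used as dietary PC
covariates) are both returned.

The microbiome stage implements the pairwise log-ratio W statistic: for
each feature i, log((c_i+1)/(c_j+1)) is regressed on the exposure plus
covariates for every other retained feature j, and W_i is the fraction of
those m−1 tests with BH-adjusted p < 0.05; detection is declared at
W > 0.7 (robust) or W > 0.6 (nominal). Features present in fewer than 10
samples are dropped first. The structural-zero handling and taxa-wise
refinements of the full ANCOM 2.1 procedure are intentionally omitted —
the W decision rule at these thresholds is the part the analysis consumes.
Effect sizes are reported as CLR-scale slopes per exposure standard
deviation, with a pseudocount of 1 on counts. Note the null distribution
of max W is heavy-tailed when feature dispersions are very unequal; the
0.7 threshold is calibrated against an exchangeable null.

Variance dissection is sequential (type-I) ANOVA: terms enter in the
stated order and each term's R² is its incremental regression sum of
squares over the total; F statistics use the full-model residual mean
square. Conditional attenuation fits the same decomposition with and
without a mediator preceding the trait term and reports the drop in the
trait's R² and p; no causal-mediation estimands are computed. Nested
model comparisons use likelihood-ratio tests (χ² with df = added
columns). The outlier-overlap question uses Fisher's exact test with the
conditional maximum-likelihood odds ratio and a central 95% CI.

## Genetics

Clumping is greedy by ascending p: a SNP is removed if within 250 kb and
r² ≥ 0.10 of a retained SNP (both configurable); missing LD for an
in-window pair is treated as independence with a logged warning.
Polygenic scores sum effect × dosage over clumped loci, flip signs on
swapped alleles, drop palindromic (A/T, C/G) SNPs, and are z-standardized
within the scored cohort. The SMR estimate at an instrument SNP is
b_xy = b_zy/b_zx with delta-method variance
b²_xy(se²_zy/b²_zy + se²_zx/b²_zx) and a χ²₁ p-value. HEIDI standardizes
the deviations d_i = b_xy(i) − b_xy(instrument) over eligible SNPs
(exposure p < 1.57 × 10⁻³, 0.05 ≤ r² ≤ 0.9 with the instrument, at most
20 by exposure association — the published defaults of the reference
implementation, all configurable) using a delta-method covariance built
from the LD correlations, and refers Σz² to a two-moment (Satterthwaite)
scaled χ² matched to the correlated null. This is simpler than a
saddlepoint approximation; simulations bound its anti-conservativeness at
a null rejection rate of about 0.10 at α = 0.05, with power near 1
against a second causal variant at GWAS n = 10,000. TWAS prediction is a
weighted dosage sum per gene with the same harmonization rules. This
module never fits genotype–phenotype regressions; GWAS summary statistics
for simulations come from the generator's independent oracle cohort.

## Synthetic data generator

The generator exists so that every stage is testable with known ground
truth. Log-scale lipid abundances follow a factor model: a global factor
with loading √ρ_b, one factor per class with loading √ρ_w, and
independent noise, giving within-class correlation ρ_w + ρ_b and
between-class correlation ρ_b (validity requires ρ_w + ρ_b < 1). Defaults
are 765 samples, 783 species in 41 classes, ρ_w = 0.55, ρ_b = 0.15, with
age, sex, batch (12 batches), injection-order and storage effects on the
log scale; storage acts only on a labeled "oxidized" class, mirroring
degradation chemistry. Traits are drawn first (ASD-like group labels with
63% prevalence, a cognitive score, a sleep score) and lipids conditionally:
each trait shifts a designated class subset by a standardized β (default
0.25 on 8–20 species), recorded in the ground truth. Concentrations are
exponentiated, so they are positive and right-skewed and effects act
multiplicatively. Dietary compositions are logistic-normal over 13 food
groups with optional group shifts; microbiome counts are
Dirichlet-multinomial (heterogeneous concentrations by default; a common
concentration yields an exchangeable panel) with spiked features
multiplying relative abundance by exp(effect × standardized exposure);
genotypes are HWE dosages with optional LD blocks, oligogenic lipid
effects, and GWAS summary statistics computed on an independent simulated
cohort (n = 10,000 by default). A separate helper draws a trait with an
exact population lipidome-explained proportion for variance-component
recovery tests, and an LD-decay panel (dichotomized AR latent Gaussians)
supports the SMR/HEIDI simulations. Identical config and seed give
bit-identical output.

What the generator does not emulate: assay noise structure beyond
log-normality (no censoring at detection limits, no heteroscedastic
technical replicates), realistic human LD maps or allele-frequency
spectra, family structure, or real lipid ontology chemistry. Passing
tests therefore demonstrate the statistical machinery is correct and
calibrated under the assumed generating process, not that any biological
conclusion transfers to real cohorts.

## Problem sizes and numerics

The test and acceptance runs use cohorts of 300–800 samples on the full
783-species panel, 25 replicates for variance-component recovery
(n = 400, m = 150), 10,000 correlated-null sets for enrichment
calibration, and 10-replicate GWAS simulations at n = 10,000 for
SMR/HEIDI — sizes chosen so each check is statistically informative while
a full run stays in the minutes range on one CPU. Numerical choices:
REML optimization tolerance 1e-10 on the ratio with estimates clamped at
the boundary; rank checks via `numpy.linalg.matrix_rank` defaults;
residualization through QR projection (orthogonality to 1e-8·scale,
idempotent); PCA through SVD of the centered matrix with eigenvalue
clipping at zero where sampling noise produces tiny negatives; ties in
ranks averaged; quantiles type-7.
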