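# nlpipe

`nlpipe` is a pipeline for association analysis of a pediatric plasma
lipidome — hundreds of strongly correlated lipid species measured alongside
neurodevelopmental traits (diagnosis group, cognitive score, sleep
disturbances), demographics, technical batch variables, diet, medications,
microbiome counts and genotypes. It is aimed at analysts who have a
quantified concentration table (samples × species) plus a lipid ontology and
sample metadata, and who want the full analysis chain with calibrated
multiple-testing behavior — not at raw mass-spectrometry processing, which
is out of scope.

## What it computes

**QC and transforms.** Species whose concentration is confounded with data
generation are removed when batch + injection order explain more than 10% of
their variance (strict inequality). Statistical outlier samples are flagged
when both an extremeness count (number of species with |z| > 3) and the PCA
distance (norm of the full z-score vector) exceed their empirical 99th
percentiles; long-stored samples are flagged at ≥ 2,500 days. Before any
association model, each species is rank-based inverse-normal transformed:
Φ⁻¹((rank − ½)/n).

**OREML.** The trait variance associated with the whole lipidome is
estimated from the one-component mixed model

    y = Cβ + Wu + e,   var(y) = A_o σ²_o + I σ²_e,   A_o = WW′/m,

where W holds the standardized transformed lipids. Because there is a single
component, the REML likelihood is profiled down to the ratio
R² = σ²_o/(σ²_o + σ²_e) and maximized exactly by bounded 1-D optimization;
standard errors come from the inverse average-information matrix and the
test of σ²_o = 0 uses the boundary mixture ½χ²₀ + ½χ²₁.

**LWAS.** One model per lipid: quantitative traits by linear regression
(trait ~ lipid + covariates, t-test), binary traits by logistic regression
(Wald z). The multiple-testing threshold is 0.05/m_eff, where m_eff is the
number of principal components of the lipid correlation matrix explaining
≥ 99% of the variance (95% as a sensitivity denominator). For a panel with
302 effective species this gives P < 1.66 × 10⁻⁴ and for 32 effective
classes P < 1.56 × 10⁻³.
Significant hits can be condensed by AIC-based backward stepwise selection,
and group variance differences are scanned with Levene's test on covariate
residuals.

**LSEA.** For an annotation set G with per-lipid statistics t_i and the
covariate-adjusted residual correlation matrix R,

    S = Σ_{i∈G} t_i / √(Σ_{i,j∈G} R_ij),    p = P(χ²₁ ≥ S²),

so perfectly duplicated lipids do not double-count and a singleton reduces
to the per-lipid test. Benjamini–Hochberg q-values are computed across all
sets per trait.

**Integration.** A trait's lipidome profile is PC1 of its significant hit
species, sign-aligned with the association effects. Dietary percent-energy
shares go through a centered log-ratio transform before PCA; microbiome
counts are tested ANCOM-style (per-feature fraction W of rejected pairwise
log-ratio regressions, detection at W > 0.7 / 0.6); sequential (type-I)
ANOVA dissects profile variance across ordered term groups; conditional
attenuation quantifies mediation of a trait term; a 2 × 2 exact test covers
outlier-overlap questions.

**Genetics.** Greedy LD clumping (250 kb, r² ≥ 0.10), standardized polygenic
scores from allele dosages with harmonization, the SMR ratio estimate
b_xy = b_zy/b_zx with delta-method standard error, the HEIDI heterogeneity
test (Satterthwaite-matched correlated χ² sum, up to 20 SNPs), and TWAS
prediction by weighted dosage sums.

Every stage is exercisable without external data through `nlpipe.synth`, a
synthetic cohort generator with recorded ground truth (class-factor lipid
correlation, batch/storage effects, planted trait effects, compositional
diet, oligogenic SNP effects with an independent GWAS oracle,
Dirichlet-multinomial microbiome counts).

## Worked example

```
nlp simulate --seed 3 --n-samples 400 --out demo/sim
nlp qc     --in demo/sim --out demo/qc
nlp oreml  --trait iq_dq --in demo/qc --out demo/oreml
nlp lwas   --trait iq_dq --in demo/qc --out demo/lwas
nlp lsea   --trait iq_dq --in demo/qc --out demo/lsea
nlp profile --trait iq_dq --in demo/qc --out demo/profile
```

prints

```
simulated cohort written to demo/sim
qc complete: 0 species excluded, 3 statistical outliers
OREML iq_dq: R2 = 0.819 (s.e. 0.054), p = 2.13e-05, n = 397
LWAS iq_dq: m_eff = 331, threshold = 0.000151, hits = 8
LSEA iq_dq: 52 sets, top = class:Class09 (q = 0.488)
profile iq_dq: 8 hits, PC1 explains 75.3% of hit variance
```

The simulated cohort plants a standardized effect of 0.25 on eight species
of one class for the cognitive score. QC removes nothing (no confounded
species at this size) and flags three statistical outliers, which are then
excluded. OREML attributes a large share of trait variance to the lipidome
(the affected class's unaffected members let the model cancel shared factor
noise, so the multivariate signal is much stronger than any single lipid).
The LWAS recovers exactly the eight planted species at the corrected
threshold 0.05/331, the top enrichment set is the planted class, and the
trait's lipidome profile (PC1 of the eight hits) captures 75% of their
variance. Library functions mirror each subcommand (`run_lwas`,
`fit_oreml`, `run_lsea`, `lipidome_profile`, ...) for use from Python.

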