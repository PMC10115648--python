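"""Synthetic cohort generator with recorded ground truth.

Emulates the statistical structure the analysis assumes: a highly
correlated lipid panel with class structure (class + global factor model
on the log scale, so concentrations are positive and right-skewed),
demographic/batch/storage covariate effects, trait effects concentrated
on labeled lipid subsets, compositional diet (logistic-normal),
oligogenic SNP -> lipid effects with an independent large-cohort GWAS
oracle, and Dirichlet-multinomial microbiome counts with spiked features.

Defaults mirror a realistic pediatric autism cohort: 765 children, 783
lipid species in 41 classes, three participant groups (ASD/SIB/UNR),
storage-duration confounding restricted to an "oxidized" species subset,
and traits that shift a small annotated set of species.  Identical config + seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import DataModelError, LipidAnnotation, LipidomeMatrix

FOOD_GROUPS = (
    "vegetables", "fruit", "meat", "alt_proteins", "grains", "dairy",
    "sweet_drinks", "packed_snacks", "confectionery", "baked", "takeaway",
    "condiments", "fatty_meats",
)

#: leading classes carry the ontology semantics the QC stage relies on
SPECIAL_CLASSES = ("COH", "CE", "TG", "TG(SIM)", "TG(O)", "TG(O)(SIM)", "ox")


@dataclass
class TraitEffect:
    """One simulated trait and its lipidome footprint.

    ``beta`` is the standardized mean shift on the log-lipid scale per
    standard deviation of the trait (or between groups for binary traits).
    ``affected_class`` picks the member species of one annotation class as
    the affected set; ``n_affected`` limits the set size.
    """

    kind: str = "continuous"       # "continuous" or "binary"
    mean: float = 0.0
    sd: float = 1.0
    prevalence: float = 0.5        # binary only
    affected_class: str | None = None
    n_affected: int = 20
    beta: float = 0.0


@dataclass
class SimConfig:
    n_samples: int = 765
    n_species: int = 783
    n_classes: int = 41
    within_class_correlation: float = 0.55
    between_class_correlation: float = 0.15
    log_sd: float = 0.6
    n_batches: int = 12
    batch_effect_sd: float = 0.05
    injection_order_slope: float = 0.0
    storage_slope: float = 0.0008      # per day, on the oxidized subset only
    n_oxidized: int = 12
    frac_long_storage: float = 0.085   # ASD-only samples stored >= 2,500 days
    age_effect_sd: float = 0.02        # per-species slope sd on age (years)
    sex_effect_sd: float = 0.05
    traits: dict[str, TraitEffect] = field(default_factory=dict)
    h2_o: float = 0.5                  # lipidome-explained proportion for variance-component traits
    diet_missing_rate: float = 0.65
    diet_group_shift: dict[str, float] = field(default_factory=dict)  # food group -> ASD log-share shift
    n_snps: int = 50
    snp_h2: float = 0.3
    n_causal_snps: int = 5
    ld_block_size: int = 1
    n_gwas: int = 10_000
    n_microbiome: int = 50
    microbiome_alpha: float | None = None  # common concentration => exchangeable features
    library_size: int = 50_000
    microbiome_spikes: dict[str, float] = field(default_factory=dict)  # feature -> effect per exposure s.d.
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.within_class_correlation < 1):
            raise DataModelError("within_class_correlation must be in [0, 1)")
        if self.within_class_correlation + self.between_class_correlation >= 1:
            raise DataModelError("correlation parameters imply a non-PSD lipid covariance")
        if self.between_class_correlation < 0:
            raise DataModelError("between_class_correlation must be non-negative")

    @staticmethod
    def study_like(seed: int = 0, **overrides) -> "SimConfig":
        """Config with the three neurodevelopmental traits planted."""
        traits = {
            "asd": TraitEffect(kind="binary", prevalence=0.63,
                               affected_class="Class08", n_affected=8, beta=-0.25),
            "iq_dq": TraitEffect(mean=75.0, sd=20.0,
                                 affected_class="Class09", n_affected=8, beta=0.25),
            "cshq_total": TraitEffect(mean=48.0, sd=8.0,
                                      affected_class="Class10", n_affected=20, beta=-0.25),
        }
        return SimConfig(traits=traits, seed=seed, **overrides)


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst would estimate."""

    affected_species: dict[str, list[str]] = field(default_factory=dict)
    trait_betas: dict[str, float] = field(default_factory=dict)
    h2_o: dict[str, float] = field(default_factory=dict)
    snp_effects: pd.DataFrame | None = None
    spiked_features: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "affected_species": self.affected_species,
            "trait_betas": self.trait_betas,
            "h2_o": self.h2_o,
            "spiked_features": self.spiked_features,
        }
        if self.snp_effects is not None:
            out["snp_effects"] = self.snp_effects.to_dict(orient="list")
        return out


# ---------------------------------------------------------------------------
# ontology


def _make_annotation(config: SimConfig) -> LipidAnnotation:
    """Build a species ontology with class / subclass / feature / domain levels."""
    n, k = config.n_species, config.n_classes
    class_names = list(SPECIAL_CLASSES) + [f"Class{i:02d}" for i in range(len(SPECIAL_CLASSES), k)]
    # species per class: COH has 1, oxidized class has n_oxidized, rest even split
    sizes = {name: 0 for name in class_names}
    sizes["COH"] = 1
    sizes["ox"] = config.n_oxidized
    remaining = n - 1 - config.n_oxidized
    rest = [c for c in class_names if c not in ("COH", "ox")]
    base = remaining // len(rest)
    for c in rest:
        sizes[c] = base
    for c in rest[: remaining - base * len(rest)]:
        sizes[c] += 1
    rows = []
    domains = ("glycerophospholipid", "sphingolipid", "sterol", "glycerolipid")
    features = ("FA18:2", "FA20:4", "FA22:6", "omega-3", "omega-6")
    subclasses = ("plasmalogen", "ether", "lyso")
    idx = 0
    for ci, cls in enumerate(class_names):
        for j in range(sizes[cls]):
            sp = f"{cls}({idx:03d})"
            rows.append({
                "species_id": sp,
                "class_id": cls,
                "subclass_ids": subclasses[ci % len(subclasses)] if ci % 2 else "",
                "feature_ids": ";".join(
                    {features[idx % len(features)], features[(idx // 7) % len(features)]}),
                "domain_id": domains[ci % len(domains)],
            })
            idx += 1
    table = pd.DataFrame(rows).set_index("species_id")
    return LipidAnnotation(table)


# ---------------------------------------------------------------------------
# lipidome + metadata


def simulate_lipidome(config: SimConfig
                      ) -> tuple[LipidomeMatrix, LipidAnnotation, pd.DataFrame, GroundTruth]:
    """Generate an aligned lipidome, ontology, metadata and ground truth.

    Traits are generated first; lipid log-abundances are then drawn
    conditionally from the factor model plus covariate and trait effects,
    and exponentiated to positive concentrations.
    """
    rng = np.random.default_rng(config.seed)
    annotation = _make_annotation(config)
    species = annotation.species_ids
    classes = annotation.classes()
    n, m = config.n_samples, len(species)
    sample_ids = [f"S{i:04d}" for i in range(n)]

    # --- metadata ---------------------------------------------------------
    age = rng.uniform(2.0, 17.0, n)
    sex = rng.choice(np.array(["female", "male"]), size=n, p=[0.35, 0.65])
    group = rng.choice(np.array(["ASD", "SIB", "UNR"]), size=n, p=[0.63, 0.21, 0.16])
    batch = rng.integers(0, config.n_batches, n)
    injection = rng.permutation(n) + 1
    storage = rng.uniform(300, 2300, n)
    asd_idx = np.flatnonzero(group == "ASD")
    n_long = int(round(config.frac_long_storage * n))
    long_idx = rng.choice(asd_idx, size=min(n_long, len(asd_idx)), replace=False)
    storage[long_idx] = rng.uniform(2500, 3200, len(long_idx))
    collection_time = rng.uniform(0, 2400, n)
    bmi_z = rng.normal(0, 1, n)

    meta = pd.DataFrame({
        "age": age, "sex": sex, "group": group,
        "batch_id": [f"B{b:02d}" for b in batch],
        "injection_order": injection, "storage_days": storage,
        "collection_time": collection_time, "bmi_z": bmi_z,
        "fatty_plasma_flag": rng.random(n) < 12 / 765,
    }, index=pd.Index(sample_ids, name="sample_id"))

    truth = GroundTruth()
    trait_std: dict[str, np.ndarray] = {}
    for name, tr in config.traits.items():
        if tr.kind == "binary":
            if name == "asd":
                vals = (group == "ASD").astype(float)
            else:
                vals = (rng.random(n) < tr.prevalence).astype(float)
            meta[name] = vals.astype(int)
            std = (vals - vals.mean()) / vals.std(ddof=0)
        else:
            vals = rng.normal(tr.mean, tr.sd, n)
            meta[name] = vals
            std = (vals - tr.mean) / tr.sd
        trait_std[name] = std
        truth.trait_betas[name] = tr.beta

    # --- lipid log-abundance factor model ---------------------------------
    rho_w, rho_b = config.within_class_correlation, config.between_class_correlation
    g = rng.normal(0, 1, n)                       # global factor
    class_names = sorted(classes.unique())
    f = {c: rng.normal(0, 1, n) for c in class_names}
    noise_sd = np.sqrt(max(1.0 - rho_w - rho_b, 0.0))
    Z = np.empty((n, m))
    cls_arr = classes.to_numpy()
    for j, sp in enumerate(species):
        Z[:, j] = (np.sqrt(rho_b) * g + np.sqrt(rho_w) * f[cls_arr[j]]
                   + noise_sd * rng.normal(0, 1, n))

    # covariate effects on the log scale
    age_slopes = rng.normal(0, config.age_effect_sd, m)
    sex_eff = rng.normal(0, config.sex_effect_sd, m)
    Z += np.outer(age - age.mean(), age_slopes)
    Z += np.outer((sex == "male").astype(float), sex_eff)
    batch_eff = rng.normal(0, config.batch_effect_sd, (config.n_batches, m))
    Z += batch_eff[batch]
    if config.injection_order_slope:
        Z += np.outer((injection - injection.mean()) / n, np.full(m, config.injection_order_slope))
    ox_cols = np.flatnonzero(cls_arr == "ox")
    Z[:, ox_cols] += config.storage_slope * (storage - storage.mean())[:, None]

    # trait effects on labeled subsets
    for name, tr in config.traits.items():
        if tr.affected_class is None or tr.beta == 0:
            truth.affected_species[name] = []
            continue
        members = [s for s, c in classes.items() if c == tr.affected_class][: tr.n_affected]
        cols = [species.index(s) for s in members]
        Z[:, cols] += tr.beta * trait_std[name][:, None]
        truth.affected_species[name] = members

    base_log = rng.normal(3.0, 1.0, m)            # per-species abundance scale
    values = np.exp(base_log + config.log_sd * Z)
    matrix = LipidomeMatrix(pd.DataFrame(values, index=sample_ids, columns=species))

    # --- dietary composition on a subset -----------------------------------
    diet = simulate_diet(config, group=group, rng=rng)
    has_diet = rng.random(n) >= config.diet_missing_rate
    for gi, fg in enumerate(FOOD_GROUPS):
        col = np.full(n, np.nan)
        col[has_diet] = diet[has_diet, gi]
        meta[f"diet_frac_{fg}"] = col
    return matrix, annotation, meta, truth


def simulate_trait_from_lipidome(matrix: LipidomeMatrix, h2_o: float,
                                 rng: np.random.Generator) -> np.ndarray:
    """Trait with a known lipidome-explained variance proportion.

    y = W u + e with u ~ N(0, h2/m) on standardized lipids and
    e ~ N(0, 1 - h2), so the population proportion sigma2_o / sigma2_p
    equals ``h2_o`` exactly.
    """
    W = matrix.values.to_numpy(float)
    W = (W - W.mean(axis=0)) / W.std(axis=0, ddof=0)
    m = W.shape[1]
    u = rng.normal(0, np.sqrt(h2_o / m), m)
    e = rng.normal(0, np.sqrt(1 - h2_o), W.shape[0])
    return W @ u + e


# ---------------------------------------------------------------------------
# diet


def simulate_diet(config: SimConfig, group=None, rng=None) -> np.ndarray:
    """Logistic-normal per-sample diet composition over the food groups.

    Optional group shifts move designated food-group log-shares in the
    ASD group (e.g. lower meat).  Rows sum to 1.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, k = config.n_samples, len(FOOD_GROUPS)
    base = np.log(np.linspace(2.0, 1.0, k))       # mildly uneven baseline shares
    z = base + rng.normal(0, 0.4, (n, k))
    if config.diet_group_shift and group is not None:
        is_asd = np.asarray(group) == "ASD"
        for fg, shift in config.diet_group_shift.items():
            z[is_asd, FOOD_GROUPS.index(fg)] += shift
    expz = np.exp(z - z.max(axis=1, keepdims=True))
    return expz / expz.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# genotypes + GWAS oracle


def simulate_genotypes(config: SimConfig, lipid_sd: float = 1.0
                       ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Dosage matrix, oracle GWAS summary statistics and true SNP effects.

    Cohort dosages are drawn in {0,1,2} under Hardy-Weinberg equilibrium;
    optional LD blocks copy an index SNP with flip noise.  The "external
    GWAS" summary statistics are computed by per-SNP least squares on an
    independent simulated cohort of ``config.n_gwas`` individuals and are
    returned in .ma-style columns (SNP A1 A2 freq b se p n).
    """
    rng = np.random.default_rng(config.seed + 1)
    p = rng.uniform(0.1, 0.9, config.n_snps)
    positions = np.sort(rng.integers(1, 50_000_000, config.n_snps))

    def draw_cohort(n: int, rng_: np.random.Generator) -> np.ndarray:
        if config.ld_block_size <= 1:
            return rng_.binomial(2, p, (n, config.n_snps)).astype(float)
        X = np.empty((n, config.n_snps))
        for start in range(0, config.n_snps, config.ld_block_size):
            block = slice(start, min(start + config.ld_block_size, config.n_snps))
            idx = rng_.binomial(2, p[start], n).astype(float)
            for j in range(block.start, block.stop):
                flip = rng_.random(n) < 0.03
                col = idx.copy()
                col[flip] = rng_.binomial(2, p[start], int(flip.sum()))
                X[:, j] = col
        return X

    dosages = draw_cohort(config.n_samples, rng)
    # oligogenic architecture: few causal SNPs, equal-variance split of snp_h2
    step = max(config.ld_block_size, 1)
    candidates = np.arange(0, config.n_snps, step)
    causal = rng.choice(candidates, size=min(config.n_causal_snps, len(candidates)),
                        replace=False)
    var_per = config.snp_h2 * lipid_sd**2 / len(causal)
    geno_var = 2 * p[causal] * (1 - p[causal])
    betas = np.sqrt(var_per / geno_var) * rng.choice([-1, 1], len(causal))
    effects = pd.DataFrame({"snp": [f"rs{i:05d}" for i in causal],
                            "index": causal, "beta": betas})

    X_gwas = draw_cohort(config.n_gwas, np.random.default_rng(config.seed + 2))
    e_sd = np.sqrt(max(lipid_sd**2 * (1 - config.snp_h2), 1e-9))
    y = X_gwas[:, causal] @ betas + rng.normal(0, e_sd, config.n_gwas)

    n_g = config.n_gwas
    xm = X_gwas.mean(axis=0)
    xc = X_gwas - xm
    sxx = (xc**2).sum(axis=0)
    b = (xc * (y - y.mean())[:, None]).sum(axis=0) / sxx
    resid_var = np.array([np.var(y - b[j] * X_gwas[:, j], ddof=2) for j in range(config.n_snps)])
    se = np.sqrt(resid_var / sxx)
    from scipy import stats
    pvals = 2 * stats.t.sf(np.abs(b / se), df=n_g - 2)
    sumstats = pd.DataFrame({
        "SNP": [f"rs{i:05d}" for i in range(config.n_snps)],
        "A1": "A", "A2": "G",
        "freq": X_gwas.mean(axis=0) / 2,
        "b": b, "se": se, "p": pvals, "n": n_g,
        "bp": positions,
    })
    dosage_df = pd.DataFrame(dosages, columns=sumstats["SNP"],
                             index=[f"S{i:04d}" for i in range(config.n_samples)])
    return dosage_df, sumstats, effects


def _per_snp_gwas(X: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Single-SNP least-squares summary statistics in .ma-style columns."""
    from scipy import stats
    n = len(y)
    xm = X.mean(axis=0)
    xc = X - xm
    sxx = (xc**2).sum(axis=0)
    b = xc.T @ (y - y.mean()) / sxx
    se = np.empty_like(b)
    yc = y - y.mean()
    for j in range(X.shape[1]):
        r = yc - b[j] * xc[:, j]
        se[j] = np.sqrt((r @ r) / (n - 2) / sxx[j])
    p = 2 * stats.t.sf(np.abs(b / se), n - 2)
    return pd.DataFrame({"SNP": [f"rs{j:05d}" for j in range(X.shape[1])],
                         "A1": "A", "A2": "G", "freq": X.mean(axis=0) / 2,
                         "b": b, "se": se, "p": p, "n": n})


def simulate_ld_panel(rng: np.random.Generator, n: int, n_snps: int = 25,
                      rho: float = 0.92, freq: float = 0.5) -> np.ndarray:
    """Dosage panel with smooth LD decay.

    Haplotypes are dichotomized latent Gaussians with AR(rho) correlation,
    summed in pairs to dosages in {0,1,2} under HWE.
    """
    from scipy import stats
    C = rho ** np.abs(np.subtract.outer(np.arange(n_snps), np.arange(n_snps)))
    L = np.linalg.cholesky(C)
    thr = stats.norm.ppf(freq)

    def hap(k: int) -> np.ndarray:
        return (rng.normal(size=(k, n_snps)) @ L.T < thr).astype(float)

    return hap(n) + hap(n)


def simulate_smr_datasets(seed: int, n_gwas: int = 10_000, n_snps: int = 25,
                          two_causal: bool = False, n_ref: int = 4000
                          ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, str]:
    """Exposure/outcome GWAS summary statistics, LD reference and instrument.

    Under the single-causal model one SNP drives both the exposure and the
    outcome (the SMR null of no heterogeneity); under ``two_causal`` the
    outcome gains an extra causal variant in LD, the linkage scenario the
    HEIDI test is designed to reject.  Exposure and outcome cohorts are
    independent; LD comes from a third reference panel.
    """
    rng = np.random.default_rng(seed)
    Xa = simulate_ld_panel(rng, n_gwas, n_snps)
    Xb = simulate_ld_panel(rng, n_gwas, n_snps)
    Xr = simulate_ld_panel(rng, n_ref, n_snps)
    c1, c2 = n_snps // 5, int(n_snps * 0.72)
    yx = 0.25 * Xa[:, c1] + rng.normal(0, 1, n_gwas)
    if two_causal:
        yy = 0.1 * Xb[:, c1] + 0.15 * Xb[:, c2] + rng.normal(0, 1, n_gwas)
    else:
        yy = 0.12 * Xb[:, c1] + rng.normal(0, 1, n_gwas)
    ssx = _per_snp_gwas(Xa, yx)
    ssy = _per_snp_gwas(Xb, yy)
    ld = pd.DataFrame(np.corrcoef(Xr.T), index=ssx["SNP"].to_numpy(),
                      columns=ssx["SNP"].to_numpy())
    instrument = str(ssx["SNP"].iloc[int(ssx["p"].idxmin())])
    return ssx, ssy, ld, instrument


# ---------------------------------------------------------------------------
# microbiome


def simulate_microbiome(config: SimConfig, exposure: np.ndarray | None = None,
                        rng=None) -> pd.DataFrame:
    """Dirichlet-multinomial count table with optional spiked features.

    Spiked features multiply their relative abundance by
    exp(effect * standardized exposure).  Row sums equal the configured
    library size.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    n, m = config.n_samples, config.n_microbiome
    names = [f"taxon{j:03d}" for j in range(m)]
    if config.microbiome_alpha is not None:
        alpha = np.full(m, float(config.microbiome_alpha))
    else:
        alpha = rng.uniform(0.5, 5.0, m)
    rel = rng.dirichlet(alpha, size=n)
    if config.microbiome_spikes:
        if exposure is None:
            raise DataModelError("microbiome spikes require an exposure vector")
        x = np.asarray(exposure, float)
        x = (x - x.mean()) / x.std(ddof=0)
        for feat, eff in config.microbiome_spikes.items():
            j = names.index(feat)
            rel[:, j] *= np.exp(eff * x)
        rel /= rel.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(config.library_size, rel[i]) for i in range(n)])
    return pd.DataFrame(counts, columns=names,
                        index=[f"S{i:04d}" for i in range(n)])
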