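"""Summary-statistics genetics: clumping, polygenic scores, SMR/HEIDI and
individual-level TWAS prediction.

Everything here consumes pre-computed tables: .ma-style GWAS summary
statistics (SNP A1 A2 freq b se p n), samples x SNPs dosage matrices in
[0, 2], SNP-SNP LD correlation matrices and TWAS weight tables.  The SMR
ratio estimate b_xy = b_zy / b_zx measures the effect of an exposure
(lipid) on an outcome at an instrumental SNP; the HEIDI test asks
whether b_xy is homogeneous across SNPs in LD with the instrument
(heterogeneity indicates linkage rather than pleiotropy/causality).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import DataModelError

logger = logging.getLogger("nlpipe")

MA_COLUMNS = ["SNP", "A1", "A2", "freq", "b", "se", "p", "n"]
PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}


def read_ma(path) -> pd.DataFrame:
    """Read whitespace-delimited .ma summary statistics."""
    df = pd.read_csv(path, sep=r"\s+")
    missing = set(MA_COLUMNS) - set(df.columns)
    if missing:
        raise DataModelError(f".ma file missing columns: {sorted(missing)}")
    if (df["se"] <= 0).any():
        raise DataModelError("non-positive standard errors in summary statistics")
    return df


def write_ma(sumstats: pd.DataFrame, path) -> None:
    cols = MA_COLUMNS + [c for c in sumstats.columns if c not in MA_COLUMNS]
    sumstats[cols].to_csv(path, sep=" ", index=False)


def clump(sumstats: pd.DataFrame, ld: pd.DataFrame, window_kb: float = 250.0,
          r2: float = 0.10, p_threshold: float = 5e-8) -> list[str]:
    """Greedy LD clumping by ascending p-value.

    Among SNPs passing ``p_threshold``, the most significant is retained
    and any SNP within ``window_kb`` of a retained SNP with squared LD
    correlation >= ``r2`` is removed.  Positions come from a ``bp``
    column; missing LD for an in-window pair is treated as independence
    with a logged warning.  Output order is by ascending p, independent
    of input row order.
    """
    if "bp" not in sumstats.columns:
        raise DataModelError("clumping requires a 'bp' position column")
    cand = sumstats[sumstats["p"] <= p_threshold].sort_values(["p", "SNP"])
    kept: list[str] = []
    kept_bp: list[float] = []
    for _, row in cand.iterrows():
        snp, bp = row["SNP"], float(row["bp"])
        independent = True
        for ksnp, kbp in zip(kept, kept_bp):
            if abs(bp - kbp) > window_kb * 1000:
                continue
            if snp in ld.index and ksnp in ld.columns:
                r = float(ld.loc[snp, ksnp])
            else:
                logger.warning("clump: no LD for in-window pair (%s, %s); treating as independent",
                               snp, ksnp)
                continue
            if r**2 >= r2:
                independent = False
                break
        if independent:
            kept.append(snp)
            kept_bp.append(bp)
    return kept


def _harmonize(effect_allele, other_allele, b, ref_a1, ref_a2, drop_palindromic=True):
    """Return (sign, ok) matching an effect to reference allele coding."""
    if drop_palindromic and frozenset((effect_allele, other_allele)) in PALINDROMIC:
        return 0.0, False
    if (effect_allele, other_allele) == (ref_a1, ref_a2):
        return 1.0, True
    if (effect_allele, other_allele) == (ref_a2, ref_a1):
        return -1.0, True
    return 0.0, False


def pgs_score(dosages: pd.DataFrame, sumstats: pd.DataFrame, snps: list[str] | None = None,
              dosage_a1: pd.Series | None = None, dosage_a2: pd.Series | None = None,
              standardize: bool = True) -> pd.Series:
    """Polygenic score: sum of effect size x allele dosage over independent loci.

    ``dosage_a1``/``dosage_a2`` give the dosage-counted and alternate
    allele per SNP (defaulting to the summary-statistics coding); allele
    mismatches that are resolvable by swapping flip the effect sign,
    unresolvable or palindromic SNPs are excluded with a log line.  The
    score is z-standardized within the scored cohort.
    """
    ss = sumstats.set_index("SNP")
    use = [s for s in (snps if snps is not None else list(ss.index)) if s in dosages.columns]
    if not use:
        raise DataModelError("no overlapping SNPs between dosages and summary statistics")
    score = np.zeros(len(dosages))
    n_used = 0
    for snp in use:
        b = float(ss.loc[snp, "b"])
        a1, a2 = str(ss.loc[snp, "A1"]), str(ss.loc[snp, "A2"])
        d1 = str(dosage_a1.loc[snp]) if dosage_a1 is not None else a1
        d2 = str(dosage_a2.loc[snp]) if dosage_a2 is not None else a2
        sign, ok = _harmonize(a1, a2, b, d1, d2)
        if not ok:
            logger.info("pgs_score: excluding unresolvable/palindromic SNP %s", snp)
            continue
        score += sign * b * dosages[snp].to_numpy(float)
        n_used += 1
    if n_used == 0:
        raise DataModelError("no SNPs usable after allele harmonization")
    out = pd.Series(score, index=dosages.index, name="pgs")
    if standardize:
        out = (out - out.mean()) / out.std(ddof=0)
    return out


@dataclass
class SmrResult:
    instrument: str
    b_xy: float
    se_xy: float
    p_smr: float
    p_heidi: float | None = None
    n_heidi_snps: int = 0


def smr(instrument: str, sumstats_x: pd.DataFrame, sumstats_y: pd.DataFrame,
        instrument_p_threshold: float = 5e-8) -> SmrResult:
    """Summary-data Mendelian randomization ratio estimate at one SNP.

    b_xy = b_zy / b_zx with the delta-method variance
    b_xy^2 (se_zy^2/b_zy^2 + se_zx^2/b_zx^2); the p-value refers
    (b_xy/se_xy)^2 to chi-squared(1).  A weak instrument (exposure p
    above ``instrument_p_threshold``) is allowed with a warning.
    """
    sx = sumstats_x.set_index("SNP")
    sy = sumstats_y.set_index("SNP")
    if instrument not in sx.index or instrument not in sy.index:
        raise DataModelError(f"instrument {instrument} absent from summary statistics")
    if (str(sx.loc[instrument, "A1"]), str(sx.loc[instrument, "A2"])) != \
            (str(sy.loc[instrument, "A1"]), str(sy.loc[instrument, "A2"])):
        raise DataModelError("instrument alleles not harmonized between x and y")
    b_zx, se_zx = float(sx.loc[instrument, "b"]), float(sx.loc[instrument, "se"])
    b_zy, se_zy = float(sy.loc[instrument, "b"]), float(sy.loc[instrument, "se"])
    if b_zx == 0:
        raise DataModelError("zero exposure effect at the instrument")
    if float(sx.loc[instrument, "p"]) > instrument_p_threshold:
        logger.warning("smr: weak instrument %s (p_x = %.3g)", instrument,
                       float(sx.loc[instrument, "p"]))
    b_xy = b_zy / b_zx
    if b_zy == 0:
        se_xy = abs(se_zy / b_zx)
    else:
        se_xy = np.sqrt(b_xy**2 * (se_zy**2 / b_zy**2 + se_zx**2 / b_zx**2))
    p = float(stats.chi2.sf((b_xy / se_xy) ** 2, df=1)) if se_xy > 0 else np.nan
    return SmrResult(instrument=instrument, b_xy=float(b_xy), se_xy=float(se_xy), p_smr=p)


def heidi(instrument: str, snp_set, sumstats_x: pd.DataFrame, sumstats_y: pd.DataFrame,
          ld: pd.DataFrame, p_x_threshold: float = 1.57e-3,
          r2_range: tuple[float, float] = (0.05, 0.9), max_snps: int = 20) -> tuple[float, int]:
    """HEIDI heterogeneity test around an SMR instrument.

    Eligible SNPs have exposure association p below ``p_x_threshold`` and
    LD with the instrument inside ``r2_range``; at most ``max_snps`` are
    kept, by strongest exposure association.  For each eligible SNP the
    deviation d_i = b_xy(i) - b_xy(instrument) is standardized using a
    delta-method covariance built from the LD correlations, and the sum
    of squared standardized deviations is referred to a two-moment
    (Satterthwaite) scaled chi-squared matching the correlated null.
    Returns (p_heidi, number of SNPs used).
    """
    sx = sumstats_x.set_index("SNP")
    sy = sumstats_y.set_index("SNP")
    elig = []
    for snp in snp_set:
        if snp == instrument or snp not in sx.index or snp not in sy.index:
            continue
        if snp not in ld.index or instrument not in ld.columns:
            continue
        r2i = float(ld.loc[snp, instrument]) ** 2
        if float(sx.loc[snp, "p"]) < p_x_threshold and r2_range[0] <= r2i <= r2_range[1]:
            elig.append(snp)
    elig = sorted(elig, key=lambda s: float(sx.loc[s, "p"]))[:max_snps]
    if len(elig) < 3:
        raise DataModelError(f"HEIDI needs >= 3 eligible SNPs besides the instrument (got {len(elig)})")

    snps = [instrument] + elig
    b_zx = sx.loc[snps, "b"].to_numpy(float)
    se_zx = sx.loc[snps, "se"].to_numpy(float)
    b_zy = sy.loc[snps, "b"].to_numpy(float)
    se_zy = sy.loc[snps, "se"].to_numpy(float)
    R = ld.loc[snps, snps].to_numpy(float)
    b_xy = b_zy / b_zx
    k = len(snps)
    # delta-method covariance of b_xy across SNPs (x and y GWAS independent)
    cov_bxy = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            cov_bxy[i, j] = (R[i, j] * se_zy[i] * se_zy[j] / (b_zx[i] * b_zx[j])
                             + b_zy[i] * b_zy[j] * R[i, j] * se_zx[i] * se_zx[j]
                             / (b_zx[i]**2 * b_zx[j]**2))
    # d_i = b_xy(i) - b_xy(instrument), i over eligible SNPs
    d = b_xy[1:] - b_xy[0]
    cov_d = (cov_bxy[1:, 1:] - cov_bxy[1:, [0]] - cov_bxy[[0], 1:] + cov_bxy[0, 0])
    sd = np.sqrt(np.diag(cov_d))
    z = d / sd
    corr_d = cov_d / np.outer(sd, sd)
    T = float(z @ z)
    lam = np.clip(np.linalg.eigvalsh(corr_d), 0.0, None)
    s1, s2 = lam.sum(), (lam**2).sum()
    if s2 == 0:
        return 1.0, len(elig)
    c = s2 / s1
    nu = s1**2 / s2
    p = float(stats.chi2.sf(T / c, df=nu))
    return p, len(elig)


def smr_with_heidi(instrument: str, snp_set, sumstats_x, sumstats_y, ld, **heidi_kwargs
                   ) -> SmrResult:
    """SMR ratio estimate plus the HEIDI linkage test in one result."""
    res = smr(instrument, sumstats_x, sumstats_y)
    p_h, n_h = heidi(instrument, snp_set, sumstats_x, sumstats_y, ld, **heidi_kwargs)
    res.p_heidi, res.n_heidi_snps = p_h, n_h
    return res


def twas_predict(dosages: pd.DataFrame, weights: pd.DataFrame,
                 dosage_a1: pd.Series | None = None,
                 dosage_a2: pd.Series | None = None) -> pd.DataFrame:
    """Genetically predicted expression: weighted dosage sums per gene.

    ``weights`` columns: SNP, A1, A2, weight, gene.  Allele harmonization
    follows the polygenic-score rules (swap flips the sign, palindromic
    SNPs dropped).
    """
    required = {"SNP", "A1", "A2", "weight", "gene"}
    if not required <= set(weights.columns):
        raise DataModelError(f"weight table needs columns {sorted(required)}")
    out = {}
    for gene, sub in weights.groupby("gene"):
        pred = np.zeros(len(dosages))
        n_used = 0
        for _, row in sub.iterrows():
            snp = row["SNP"]
            if snp not in dosages.columns:
                continue
            d1 = str(dosage_a1.loc[snp]) if dosage_a1 is not None else str(row["A1"])
            d2 = str(dosage_a2.loc[snp]) if dosage_a2 is not None else str(row["A2"])
            sign, ok = _harmonize(str(row["A1"]), str(row["A2"]), row["weight"], d1, d2)
            if not ok:
                continue
            pred += sign * float(row["weight"]) * dosages[snp].to_numpy(float)
            n_used += 1
        if n_used == 0:
            raise DataModelError(f"no overlapping usable SNPs for gene {gene}")
        out[gene] = pred
    return pd.DataFrame(out, index=dosages.index)
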