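"""Trait lipidome profiles and their environmental dissection.

Covers: the per-trait lipidome profile (PC1 of the significant LWAS hit
species), compositional dietary PCA on centered log-ratio (CLR)
transformed percent-energy shares, ANCOM-style pairwise log-ratio W
statistics for microbiome features against a continuous exposure,
sequential (type-I) ANOVA variance dissection, conditional attenuation
of a trait term by a mediator, nested likelihood-ratio tests, and the
exact 2x2 enrichment test used for outlier overlap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import DataModelError, LipidomeMatrix
from .qc import residualize

logger = logging.getLogger("nlpipe")


# ---------------------------------------------------------------------------
# compositional transforms


def clr_transform(composition, zero_replacement: str = "half-min"):
    """Centered log-ratio transform: log(x_i / geometric mean of x).

    Zeros are replaced by half the smallest positive share in the same
    row (``half-min``) or rejected (``error``).  Output rows sum to 0,
    and the transform is invariant to rescaling a row by a constant.
    """
    arr = np.asarray(composition, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[None, :]
    if (arr < 0).any():
        raise DataModelError("compositions must be non-negative")
    out = arr.copy()
    for i in range(out.shape[0]):
        row = out[i]
        if (row == 0).all():
            raise DataModelError(f"all-zero composition in row {i}")
        if (row == 0).any():
            if zero_replacement == "half-min":
                row = np.where(row == 0, 0.5 * row[row > 0].min(), row)
                out[i] = row
            else:
                raise DataModelError(f"zero share in row {i}")
    logc = np.log(out)
    clr = logc - logc.mean(axis=1, keepdims=True)
    if isinstance(composition, pd.DataFrame):
        return pd.DataFrame(clr, index=composition.index, columns=composition.columns)
    return clr[0] if squeeze else clr


@dataclass
class DietaryPCA:
    scores: pd.DataFrame        # raw PC scores (zero mean)
    scores_std: pd.DataFrame    # standardized scores, used as dietary PCs downstream
    loadings: pd.DataFrame      # food group x component
    explained_variance: np.ndarray


def dietary_pca(compositions: pd.DataFrame, n_components: int = 3) -> DietaryPCA:
    """PCA of CLR-transformed diet composition (percent energy by food group)."""
    comp = compositions.dropna()
    if len(comp) < 3:
        raise DataModelError("dietary_pca needs at least 3 samples with diet data")
    if n_components > min(comp.shape):
        raise DataModelError("more components requested than samples/food groups")
    clr = clr_transform(comp)
    X = clr.to_numpy(float)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = n_components
    scores = U[:, :k] * s[:k]
    cols = [f"diet_pc{i+1}" for i in range(k)]
    scores_df = pd.DataFrame(scores, index=comp.index, columns=cols)
    std = scores_df / scores_df.std(ddof=0)
    loadings = pd.DataFrame(Vt[:k].T, index=comp.columns, columns=cols)
    expl = (s**2) / len(comp)
    return DietaryPCA(scores_df, std, loadings, expl[:k])


# ---------------------------------------------------------------------------
# trait lipidome profile


@dataclass
class LipidomeProfile:
    trait: str
    members: list[str]
    scores: pd.Series            # per-sample PC1 score
    loadings: pd.Series          # unit-norm
    variance_explained: float
    sign_aligned: bool


def lipidome_profile(matrix: LipidomeMatrix, hits, effects: pd.Series | None = None,
                     trait: str = "", global_flip: bool = False) -> LipidomeProfile:
    """PC1 of the significant hit species, as a one-variable trait signature.

    ``hits`` is the list of significant species; ``effects`` their
    association effect directions, used to orient PC1 so that the
    correlation between loadings and effect signs is positive.  With a
    single hit, the profile degenerates to that standardized lipid.
    ``global_flip`` applies a final presentation sign flip.
    """
    members = list(hits)
    if not members:
        raise DataModelError("lipidome_profile needs at least one hit species")
    sub = matrix.values[members]
    if sub.isna().any().any():
        raise DataModelError("hit species have missing values; subset to complete cases")
    X = sub.to_numpy(float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    if len(members) == 1:
        warnings.warn("single hit: profile equals the standardized lipid", stacklevel=2)
        scores = pd.Series(Z[:, 0], index=matrix.sample_ids)
        load = pd.Series([1.0], index=members)
        var_expl = 1.0
    else:
        U, s, Vt = np.linalg.svd(Z - Z.mean(axis=0), full_matrices=False)
        load = pd.Series(Vt[0], index=members)
        scores = pd.Series(U[:, 0] * s[0], index=matrix.sample_ids)
        var_expl = float(s[0]**2 / (s**2).sum())
    aligned = False
    if effects is not None:
        # sign-weighted vote: robust when loadings are near-constant
        score = float(load.to_numpy() @ np.sign(effects.loc[members].to_numpy()))
        if score < 0:
            load, scores = -load, -scores
        aligned = True
    if global_flip:
        load, scores = -load, -scores
    return LipidomeProfile(trait=trait, members=members, scores=scores, loadings=load,
                           variance_explained=var_expl, sign_aligned=aligned)


# ---------------------------------------------------------------------------
# sequential ANOVA


@dataclass
class VarianceDissection:
    table: pd.DataFrame  # index term; columns df, r2, F, p (plus a residual row)
    total_r2: float


def _term_matrix(data: pd.DataFrame, cols) -> np.ndarray:
    sub = data[list(cols)] if not isinstance(cols, str) else data[[cols]]
    parts = []
    for c in sub.columns:
        s = sub[c]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.to_numpy(float)[:, None])
        else:
            levels = sorted(s.astype(str).unique())
            parts.append(np.column_stack(
                [(s.astype(str) == lv).to_numpy(float) for lv in levels[1:]]) if len(levels) > 1
                else np.zeros((len(s), 0)))
    return np.hstack(parts) if parts else np.zeros((len(data), 0))


def variance_dissection(response, ordered_terms, data: pd.DataFrame) -> VarianceDissection:
    """Sequential (type-I) sum-of-squares decomposition.

    ``ordered_terms`` is a list of (term_name, columns) pairs added in
    the stated order after the intercept; each term's R^2 is its
    incremental regression sum of squares over the total sum of squares.
    F statistics use the full-model residual mean square.
    """
    y = (data[response].to_numpy(float) if isinstance(response, str)
         else np.asarray(response, float))
    n = len(y)
    sst = float(((y - y.mean())**2).sum())
    if sst == 0:
        raise DataModelError("constant response")
    X = np.ones((n, 1))
    rss_prev = sst
    rows = []
    for name, cols in ordered_terms:
        T = _term_matrix(data, cols)
        Xn = np.hstack([X, T])
        rank_before = np.linalg.matrix_rank(X)
        rank_after = np.linalg.matrix_rank(Xn)
        df_term = rank_after - rank_before
        if df_term == 0:
            raise DataModelError(f"term {name!r} adds no rank (collinear with earlier terms)")
        Q, _ = np.linalg.qr(Xn)
        resid = y - Q[:, :rank_after] @ (Q[:, :rank_after].T @ y)
        rss = float(resid @ resid)
        rows.append((name, df_term, (rss_prev - rss) / sst, rss_prev - rss))
        X, rss_prev = Xn, rss
    df_resid = n - np.linalg.matrix_rank(X)
    mse = rss_prev / df_resid
    table = pd.DataFrame(
        [(name, df, r2, (ss / df) / mse, stats.f.sf((ss / df) / mse, df, df_resid))
         for name, df, r2, ss in rows],
        columns=["term", "df", "r2", "F", "p"]).set_index("term")
    table.loc["residual"] = (df_resid, rss_prev / sst, np.nan, np.nan)
    return VarianceDissection(table, total_r2=1.0 - rss_prev / sst)


def conditional_attenuation(profile, trait_col: str, mediator_col: str,
                            design_cols, data: pd.DataFrame) -> pd.DataFrame:
    """Trait-term R^2 and p with and without adjusting for a mediator.

    Two sequential-ANOVA fits of the profile: covariates (+ mediator)
    first, the trait last; the attenuation is the drop in the trait
    term's incremental R^2 once the mediator precedes it.
    """
    base = [("covariates", design_cols)] if design_cols else []
    without = variance_dissection(profile, base + [(trait_col, [trait_col])], data)
    with_med = variance_dissection(
        profile, base + [(mediator_col, [mediator_col]), (trait_col, [trait_col])], data)
    out = pd.DataFrame({
        "r2": [without.table.loc[trait_col, "r2"], with_med.table.loc[trait_col, "r2"]],
        "p": [without.table.loc[trait_col, "p"], with_med.table.loc[trait_col, "p"]],
    }, index=["without_mediator", "with_mediator"])
    out.attrs["attenuation"] = float(out.loc["without_mediator", "r2"]
                                     - out.loc["with_mediator", "r2"])
    return out


def nested_lrt(model0_cols, model1_cols, response: str, data: pd.DataFrame,
               family: str = "linear") -> tuple[float, float]:
    """Likelihood-ratio test of nested regression models.

    ``model0_cols`` must be a subset of ``model1_cols``; the statistic
    2 * (logL1 - logL0) is referred to chi-squared with df equal to the
    number of added design columns.
    """
    set0, set1 = set(model0_cols), set(model1_cols)
    if not set0 <= set1:
        raise DataModelError("model0 terms must be nested within model1")
    y = data[response].to_numpy(float)

    def fit(cols):
        X = np.column_stack([np.ones(len(y)), _term_matrix(data, cols)]) if cols \
            else np.ones((len(y), 1))
        if family == "linear":
            return sm.OLS(y, X).fit()
        if family == "logistic":
            return sm.Logit(y, X).fit(disp=0)
        raise DataModelError(f"unknown family {family!r}")

    fit0, fit1 = fit(list(model0_cols)), fit(list(model1_cols))
    df = fit1.df_model - fit0.df_model
    lrt = max(2.0 * (fit1.llf - fit0.llf), 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(lrt, df=df))
    return float(lrt), p


# ---------------------------------------------------------------------------
# ANCOM-style microbiome associations


@dataclass
class AncomResult:
    table: pd.DataFrame  # index feature; columns W, clr_mean_difference, detected_0.7, detected_0.6
    n_features: int


def ancom_w(counts: pd.DataFrame, exposure: pd.Series, design: pd.DataFrame | None = None,
            min_prevalence: int = 10, alpha: float = 0.05) -> AncomResult:
    """Pairwise log-ratio W statistic against a continuous exposure.

    For each retained feature i, every log ratio log((c_i+1)/(c_j+1)) is
    regressed on the exposure plus covariates; W_i is the fraction of the
    m-1 tests whose BH-adjusted p falls below ``alpha``.  Features present
    in fewer than ``min_prevalence`` samples are dropped first.  The
    effect size is reported as the CLR-scale slope per exposure s.d.
    """
    idx = counts.index
    x = exposure.loc[idx].to_numpy(float)
    keep = (counts > 0).sum(axis=0) >= min_prevalence
    feats = list(counts.columns[keep])
    m = len(feats)
    if m < 3:
        raise DataModelError(f"need >= 3 features after prevalence filter (got {m})")
    logc = np.log(counts[feats].to_numpy(float) + 1.0)
    if design is not None:
        D = design.loc[idx].to_numpy(float)
    else:
        D = np.ones((len(idx), 1))
    p_cov = D.shape[1]
    Q, _ = np.linalg.qr(D)
    xr = x - Q @ (Q.T @ x)
    Yr = logc - Q @ (Q.T @ logc)
    n = len(x)
    df = n - p_cov - 1
    sxx = float(xr @ xr)
    s = Yr.T @ xr              # x'Y per feature
    G = Yr.T @ Yr              # feature Gram matrix of residuals
    W = np.zeros(m)
    diag = np.diag(G)
    for i in range(m):
        b = (s[i] - s) / sxx
        yy = diag[i] + diag - 2 * G[i]
        rss = yy - b**2 * sxx
        mask = np.arange(m) != i
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(rss[mask] / df / sxx)
            t = b[mask] / se
        pv = 2 * stats.t.sf(np.abs(t), df=df)
        pv = np.where(np.isnan(pv), 1.0, pv)
        W[i] = float(multipletests(pv, method="fdr_bh")[1].__lt__(alpha).mean())
    # CLR effect per exposure s.d.
    clr = logc - logc.mean(axis=1, keepdims=True)
    clr_r = clr - Q @ (Q.T @ clr)
    x_sd = x.std(ddof=0)
    slopes = (clr_r.T @ xr) / sxx * x_sd
    table = pd.DataFrame({
        "W": W,
        "clr_mean_difference": slopes,
        "detected_0.7": W > 0.7,
        "detected_0.6": W > 0.6,
    }, index=pd.Index(feats, name="feature"))
    return AncomResult(table, n_features=m)


# ---------------------------------------------------------------------------
# exact 2x2 test


def fisher_exact(table) -> tuple[float, tuple[float, float], float]:
    """Fisher's exact test on a 2x2 table.

    Returns (conditional-MLE odds ratio, central 95% CI, two-sided p by
    summing hypergeometric probabilities <= that of the observed table).
    """
    tab = np.asarray(table, dtype=int)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise DataModelError("need a 2x2 table of non-negative integers")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise DataModelError("zero margin in 2x2 table")
    _, p = stats.fisher_exact(tab, alternative="two-sided")
    orr = stats.contingency.odds_ratio(tab, kind="conditional")
    ci = orr.confidence_interval(confidence_level=0.95)
    return float(orr.statistic), (float(ci.low), float(ci.high)), float(p)
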