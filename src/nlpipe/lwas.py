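"""Lipidome-wide association: per-lipid models, effective-test correction,
joint stepwise selection and the group-variance scan.

Quantitative traits are modeled as trait ~ lipid + covariates (linear,
t-test on the lipid coefficient); binary traits as trait ~ lipid +
covariates (logistic, Wald z).  Multiple testing uses the effective
number of independent lipids: the number of principal components of the
lipid correlation matrix explaining >= 99% of variance (95% as a
sensitivity denominator), with the corrected threshold 0.05 / m_eff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datamodel import DataModelError, LipidomeMatrix
from .qc import residualize

logger = logging.getLogger("nlpipe")


@dataclass
class AssociationTable:
    """Per-lipid effect, s.e., statistic and p for one trait."""

    table: pd.DataFrame  # index lipid; columns b, se, stat, p, n
    family: str          # "linear" or "logistic"
    trait: str = ""
    covariate_set: str = ""

    def significant(self, alpha: float) -> pd.Index:
        return self.table.index[self.table["p"] < alpha]

    def mark_significant(self, alpha99: float, alpha95: float | None = None) -> None:
        self.table["significant_0.99"] = self.table["p"] < alpha99
        if alpha95 is not None:
            self.table["significant_0.95"] = self.table["p"] < alpha95


@dataclass
class EffectiveTests:
    m_eff_99: int
    m_eff_95: int
    n_lipids: int
    alpha_99: float = field(init=False)
    alpha_95: float = field(init=False)

    def __post_init__(self) -> None:
        self.alpha_99 = corrected_threshold(self.m_eff_99)
        self.alpha_95 = corrected_threshold(self.m_eff_95)


def _is_binary(y: np.ndarray) -> bool:
    vals = np.unique(y[~np.isnan(y)])
    return len(vals) == 2 and set(vals) <= {0.0, 1.0}


def run_lwas(matrix: LipidomeMatrix, trait: pd.Series, design: pd.DataFrame,
             family: str = "auto") -> AssociationTable:
    """One association model per lipid.

    The linear family is computed by Frisch-Waugh-Lovell partialling
    (residualize trait and lipid on the covariates, then simple
    regression with the joint-model degrees of freedom), which is
    algebraically identical to the full joint OLS fit.  The logistic
    family fits the full joint model per lipid; separation or
    non-convergence flags that lipid with a missing p and a reason.
    """
    y = trait.loc[matrix.sample_ids].to_numpy(float)
    if np.isnan(y).any():
        raise DataModelError("trait has missing values on the analysis subset; subset first")
    X = design.loc[matrix.sample_ids].to_numpy(float)
    n, p = X.shape
    if family == "auto":
        family = "logistic" if _is_binary(y) else "linear"

    L = matrix.values.to_numpy(float)
    if family == "linear":
        complete = ~np.isnan(L).any(axis=0)
        Q, _ = np.linalg.qr(X)
        yr = y - Q @ (Q.T @ y)
        rows = {}
        # vectorized path for fully observed lipids
        Lc = L[:, complete]
        Lr = Lc - Q @ (Q.T @ Lc)
        sxx = (Lr**2).sum(axis=0)
        sxy = Lr.T @ yr
        with np.errstate(divide="ignore", invalid="ignore"):
            b = sxy / sxx
            rss = yr @ yr - b * sxy
            df = n - p - 1
            se = np.sqrt(rss / df / sxx)
            tstat = b / se
        pvals = 2 * stats.t.sf(np.abs(tstat), df=df)
        for j, lip in enumerate(np.array(matrix.species_ids)[complete]):
            rows[lip] = (b[j], se[j], tstat[j], pvals[j], n, "")
        # per-lipid complete cases for lipids with missing entries
        for j, lip in enumerate(matrix.species_ids):
            if complete[j]:
                continue
            obs = ~np.isnan(L[:, j])
            nj = int(obs.sum())
            if nj <= p + 2:
                rows[lip] = (np.nan, np.nan, np.nan, np.nan, nj, "too few complete cases")
                continue
            Qj, _ = np.linalg.qr(X[obs])
            yrj = y[obs] - Qj @ (Qj.T @ y[obs])
            xrj = L[obs, j] - Qj @ (Qj.T @ L[obs, j])
            sxxj = float(xrj @ xrj)
            bj = float(xrj @ yrj) / sxxj
            rssj = float(yrj @ yrj) - bj**2 * sxxj
            sej = np.sqrt(rssj / (nj - p - 1) / sxxj)
            tj = bj / sej
            rows[lip] = (bj, sej, tj, 2 * stats.t.sf(abs(tj), df=nj - p - 1), nj, "")
    elif family == "logistic":
        rows = {}
        for j, lip in enumerate(matrix.species_ids):
            obs = ~np.isnan(L[:, j])
            nj = int(obs.sum())
            Xj = np.column_stack([X[obs], L[obs, j]])
            try:
                with np.errstate(all="ignore"):
                    fit = sm.Logit(y[obs], Xj).fit(disp=0, maxiter=100)
                if not fit.mle_retvals.get("converged", True) or np.isnan(fit.bse[-1]) \
                        or fit.bse[-1] > 1e4:
                    rows[lip] = (np.nan, np.nan, np.nan, np.nan, nj, "separation/non-convergence")
                    continue
                bj, sej = fit.params[-1], fit.bse[-1]
                zj = bj / sej
                rows[lip] = (bj, sej, zj, 2 * stats.norm.sf(abs(zj)), nj, "")
            except Exception as exc:  # perfect separation raises in some statsmodels versions
                rows[lip] = (np.nan, np.nan, np.nan, np.nan, nj, f"separation: {type(exc).__name__}")
    else:
        raise DataModelError(f"unknown family {family!r}")

    table = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=["b", "se", "stat", "p", "n", "note"])
    table = table.loc[matrix.species_ids]
    table["n"] = table["n"].astype(int)
    return AssociationTable(table, family=family, trait=str(trait.name or ""))


def effective_tests(matrix: LipidomeMatrix, thresholds=(0.99, 0.95)) -> EffectiveTests:
    """Effective number of independent lipids from lipid-correlation PCA.

    m_eff at a threshold is the smallest number of principal components
    whose cumulative explained variance reaches (>=) the threshold.
    """
    vals = matrix.values.to_numpy(float)
    n, m = vals.shape
    if n <= 2:
        raise DataModelError("effective_tests needs more than two samples")
    Z = (vals - vals.mean(axis=0)) / vals.std(axis=0, ddof=0)
    corr = (Z.T @ Z) / n
    eig = np.linalg.eigvalsh(corr)[::-1]
    eig = np.clip(eig, 0.0, None)
    cum = np.cumsum(eig) / eig.sum()
    m99 = int(np.searchsorted(cum, thresholds[0] - 1e-12) + 1)
    m95 = int(np.searchsorted(cum, thresholds[1] - 1e-12) + 1)
    return EffectiveTests(m_eff_99=m99, m_eff_95=m95, n_lipids=m)


def corrected_threshold(m_eff: int) -> float:
    """Bonferroni-style threshold for the effective number of lipids."""
    if m_eff < 1:
        raise DataModelError("m_eff must be a positive integer")
    return 0.05 / m_eff


def joint_stepwise(matrix: LipidomeMatrix, trait: pd.Series, design: pd.DataFrame,
                   family: str = "auto") -> tuple[list[str], object]:
    """Backward stepwise joint model over significant lipids, by AIC.

    Starts from the full joint model (all hits + covariates), repeatedly
    removes the lipid whose removal most improves (lowers) the AIC, and
    stops when no removal improves it.  Covariates are never dropped.
    Exact duplicate lipid columns are pruned up front.
    """
    if matrix.n_species < 1:
        raise DataModelError("joint_stepwise needs at least one significant lipid")
    y = trait.loc[matrix.sample_ids].to_numpy(float)
    if family == "auto":
        family = "logistic" if _is_binary(y) else "linear"
    lip = matrix.values.copy()
    dup = lip.T.duplicated()
    if dup.any():
        dropped = list(lip.columns[dup])
        logger.info("joint_stepwise: dropping exact duplicate lipids %s", dropped)
        lip = lip.loc[:, ~dup]
    X0 = design.loc[matrix.sample_ids]

    def fit(cols: list[str]):
        Xf = pd.concat([X0, lip[cols]], axis=1).to_numpy(float)
        if family == "linear":
            return sm.OLS(y, Xf).fit()
        return sm.Logit(y, Xf).fit(disp=0)

    current = list(lip.columns)
    model = fit(current)
    while len(current) > 1:
        best_cols, best_model, best_aic = None, None, model.aic
        for c in current:
            reduced = [x for x in current if x != c]
            cand = fit(reduced)
            if cand.aic < best_aic:
                best_cols, best_model, best_aic = reduced, cand, cand.aic
        if best_cols is None:
            break
        current, model = best_cols, best_model
    # a single remaining lipid can still be dropped if the null model is better
    if len(current) == 1 and fit([]).aic < model.aic:
        current, model = [], fit([])
    return current, model


def variance_difference_scan(matrix: LipidomeMatrix, group: pd.Series,
                             design: pd.DataFrame, center: str = "mean") -> pd.DataFrame:
    """Per-lipid Levene test for group variance differences.

    Concentrations are residualized on the design first; the classical
    Levene statistic (deviations from the group ``center``) compares the
    two groups.  Each group must have at least 10 samples.
    """
    g = group.loc[matrix.sample_ids]
    levels = sorted(g.dropna().unique())
    if len(levels) != 2:
        raise DataModelError("variance_difference_scan expects exactly two groups")
    counts = g.value_counts()
    if (counts < 10).any():
        raise DataModelError(f"each group needs n >= 10 (got {counts.to_dict()})")
    resid = residualize(matrix.values, design.loc[matrix.sample_ids])
    a_mask = (g == levels[0]).to_numpy()
    rows = {}
    for lip in matrix.species_ids:
        r = resid[lip].to_numpy(float)
        ra, rb = r[a_mask], r[~a_mask]
        if np.ptp(ra) < 1e-12 and np.ptp(rb) < 1e-12:
            raise DataModelError(f"degenerate (constant) residuals for {lip}")
        stat, p = stats.levene(ra, rb, center=center)
        rows[lip] = (float(np.var(ra, ddof=1)), float(np.var(rb, ddof=1)), stat, p)
    out = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=[f"var_{levels[0]}", f"var_{levels[1]}", "stat", "p"])
    out.index.name = "lipid"
    return out
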