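"""OREML: trait variance associated with the whole lipidome.

One-component linear mixed model y = C beta + W u + e with
var(y) = A_o sigma2_o + I sigma2_e, where A_o = W W' / m is the omics
relationship matrix built from standardized (inverse-normal transformed)
lipid measures.  Because there is a single component, the REML
log-likelihood can be profiled down to the ratio
phi = sigma2_o / (sigma2_o + sigma2_e) and maximized exactly by bounded
1-D optimization; standard errors come from the inverse average-
information matrix at the optimum, and the test of sigma2_o = 0 is
referred to the 50:50 mixture of chi-squared(0) and chi-squared(1)
appropriate for a boundary null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .datamodel import DataModelError, LipidomeMatrix


@dataclass
class OmicsRelationshipMatrix:
    """n x n sample-similarity matrix from standardized lipid measures."""

    values: np.ndarray
    m: int  # number of lipids used
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        A = self.values
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise DataModelError("ORM must be square")
        if not np.allclose(A, A.T, atol=1e-10):
            raise DataModelError("ORM must be symmetric")


@dataclass
class VarianceComponents:
    sigma2_o: float
    sigma2_e: float
    r2: float                 # sigma2_o / (sigma2_o + sigma2_e)
    se_sigma2_o: float
    se_sigma2_e: float
    se_r2: float
    reml_loglik: float
    lrt: float
    lrt_p: float
    n: int
    boundary: bool = False    # estimate clamped at phi = 0 (SE one-sided there)


def build_orm(matrix: LipidomeMatrix) -> OmicsRelationshipMatrix:
    """A_o = W W' / m with W column-standardized lipid measures.

    Expects the inverse-normal transformed matrix with no missing cells;
    columns are (re)standardized to mean 0, variance 1 so diagonal
    elements average 1.
    """
    if matrix.transform_state != "inverse_normal":
        raise DataModelError("build_orm expects an inverse-normal transformed matrix")
    W = matrix.values.to_numpy(float)
    if np.isnan(W).any():
        raise DataModelError("ORM requires complete data; handle missingness upstream")
    m = W.shape[1]
    if m == 0:
        raise DataModelError("no lipids available for ORM")
    W = (W - W.mean(axis=0)) / W.std(axis=0, ddof=0)
    A = (W @ W.T) / m
    return OmicsRelationshipMatrix(A, m, matrix.sample_ids)


def _profile_reml(phi: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray) -> tuple:
    """REML log-likelihood at ratio phi, with total variance profiled out.

    Works in the eigenbasis of A (eigenvalues d, rotated response yt and
    design Xt).  Returns (loglik, sigma2_p, beta, w).
    """
    n, p = Xt.shape
    w = 1.0 / (phi * d + (1.0 - phi))
    XtW = Xt * w[:, None]
    XtWX = Xt.T @ XtW
    XtWy = XtW.T @ yt
    beta = np.linalg.solve(XtWX, XtWy)
    yPy = float(yt @ (w * yt) - XtWy @ beta)
    sigma2_p = yPy / (n - p)
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    if sign <= 0 or sigma2_p <= 0:
        return -np.inf, np.nan, beta, w
    ll = -0.5 * (-np.sum(np.log(w)) + logdet_XtWX + (n - p) * np.log(sigma2_p) + (n - p))
    return ll, sigma2_p, beta, w


def fit_oreml(y, orm: OmicsRelationshipMatrix, design, max_phi: float = 1 - 1e-6
              ) -> VarianceComponents:
    """REML estimate of (sigma2_o, sigma2_e) and the proportion R^2.

    Binary traits are analyzed on the observed 0/1 scale.  Raises if the
    relationship matrix is proportional to the identity (the two
    components are then unidentifiable).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    A = orm.values
    if y.shape[0] != n or A.shape[0] != n:
        raise DataModelError("y, design and ORM dimensions disagree")
    if np.isnan(y).any():
        raise DataModelError("y must be complete on the analysis subset")
    if np.linalg.matrix_rank(X) < p:
        raise DataModelError("design matrix is rank-deficient")

    d, U = np.linalg.eigh(A)
    if d.max() - d.min() < 1e-10:
        raise DataModelError("ORM proportional to identity: variance components unidentifiable")
    yt = U.T @ y
    Xt = U.T @ X

    neg = lambda phi: -_profile_reml(phi, d, yt, Xt)[0]
    res = optimize.minimize_scalar(neg, bounds=(0.0, max_phi), method="bounded",
                                   options={"xatol": 1e-10})
    if not res.success:
        raise DataModelError(f"REML optimization did not converge: {res.message}")
    phi = float(res.x)
    ll0, _, _, _ = _profile_reml(0.0, d, yt, Xt)
    ll, sigma2_p, beta, w = _profile_reml(phi, d, yt, Xt)
    if ll < ll0:  # optimizer stuck off the boundary under a flat likelihood
        phi, ll = 0.0, ll0
        _, sigma2_p, beta, w = _profile_reml(0.0, d, yt, Xt)
    boundary = phi < 1e-8
    if boundary:
        phi = 0.0

    sigma2_o = phi * sigma2_p
    sigma2_e = (1.0 - phi) * sigma2_p

    # average-information matrix for (sigma2_o, sigma2_e), in the eigenbasis
    XtW = Xt * w[:, None]
    XtWX_inv = np.linalg.inv(Xt.T @ XtW)

    def apply_P(v: np.ndarray) -> np.ndarray:
        wv = w * v
        return (wv - XtW @ (XtWX_inv @ (XtW.T @ v))) / sigma2_p

    Py = apply_P(yt - 0.0)
    # residualize via P directly on yt (P X = 0 so beta drops out)
    APy = d * Py
    IPy = Py
    PAPy = apply_P(APy)
    PIPy = apply_P(IPy)
    AI = 0.5 * np.array([
        [APy @ PAPy, APy @ PIPy],
        [IPy @ PAPy, IPy @ PIPy],
    ])
    try:
        AI_inv = np.linalg.inv(AI)
        se_o, se_e = np.sqrt(np.maximum(np.diag(AI_inv), 0.0))
        grad = np.array([sigma2_e, -sigma2_o]) / (sigma2_o + sigma2_e) ** 2
        se_r2 = float(np.sqrt(max(grad @ AI_inv @ grad, 0.0)))
    except np.linalg.LinAlgError:
        se_o = se_e = se_r2 = np.nan

    lrt = max(2.0 * (ll - ll0), 0.0)
    lrt_p = 0.5 * stats.chi2.sf(lrt, df=1) + 0.5 * (lrt <= 0.0)
    return VarianceComponents(
        sigma2_o=sigma2_o, sigma2_e=sigma2_e, r2=phi,
        se_sigma2_o=float(se_o), se_sigma2_e=float(se_e), se_r2=se_r2,
        reml_loglik=float(ll), lrt=float(lrt), lrt_p=float(lrt_p),
        n=n, boundary=boundary,
    )


def reml_loglik_grid(y, orm: OmicsRelationshipMatrix, design,
                     grid: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Profile REML log-likelihood on a grid over the ratio phi.

    Exposed as the brute-force cross-check of the 1-D optimizer.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    d, U = np.linalg.eigh(orm.values)
    yt, Xt = U.T @ y, U.T @ X
    if grid is None:
        grid = np.linspace(0.0, 0.98, 50)
    lls = np.array([_profile_reml(g, d, yt, Xt)[0] for g in grid])
    return grid, lls
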