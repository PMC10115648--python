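"""Quality control, outlier screening and per-variable transforms.

The QC stage mirrors a single-pass lipidomics screen: technical-variance
filtering of species (batch + injection order R^2 > 10%), a two-criterion
statistical-outlier flag per sample (extremeness count and PCA distance,
both above their empirical 99th percentiles), a storage-duration flag
(>= 2,500 days), inferred clinical lipids from the ontology, and the
rank-based inverse normal transformation applied lipid-wise before the
association stages.  All decisions are pure functions of data + thresholds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import DataModelError, LipidAnnotation, LipidomeMatrix

logger = logging.getLogger("nlpipe")


@dataclass
class OutlierReport:
    """Per-sample outlier diagnostics and flags (thresholds retained)."""

    extremeness_count: pd.Series      # lipids with |z| > z_cut per sample
    pca_distance: pd.Series           # Euclidean norm of the full PC score vector
    count_threshold: float            # empirical 99th percentile of counts
    distance_threshold: float
    statistical_outlier: pd.Series    # AND of the two criteria
    storage_outlier: pd.Series | None = None
    fatty_plasma: pd.Series | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "extremeness_count": self.extremeness_count,
            "pca_distance": self.pca_distance,
            "statistical_outlier": self.statistical_outlier,
        })
        if self.storage_outlier is not None:
            out["storage_outlier"] = self.storage_outlier
        if self.fatty_plasma is not None:
            out["fatty_plasma"] = self.fatty_plasma
        return out


@dataclass
class ClinicalLipids:
    """Inferred total cholesterol and triglycerides per sample."""

    total_cholesterol: pd.Series
    total_triglycerides: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "total_cholesterol": self.total_cholesterol,
            "total_triglycerides": self.total_triglycerides,
        })


def inverse_normal_transform(values, offset: float = 0.5):
    """Rank-based inverse normal transform: Phi^-1((rank - offset) / n).

    Ties receive average ranks (tied inputs map to identical outputs);
    missing values stay missing and do not consume ranks.  Requires at
    least 3 non-missing values and at least two distinct values.
    """
    x = np.asarray(values, dtype=float)
    out = np.full_like(x, np.nan)
    obs = ~np.isnan(x)
    n = int(obs.sum())
    if n < 3:
        raise DataModelError("inverse_normal_transform needs >= 3 non-missing values")
    v = x[obs]
    if np.all(v == v[0]):
        raise DataModelError("inverse_normal_transform undefined for constant input")
    ranks = stats.rankdata(v, method="average")
    out[obs] = stats.norm.ppf((ranks - offset) / n)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def transform_lipidome(matrix: LipidomeMatrix, offset: float = 0.5) -> LipidomeMatrix:
    """Apply the inverse normal transform to every species column."""
    transformed = matrix.values.apply(lambda col: inverse_normal_transform(col, offset))
    return LipidomeMatrix(transformed, transform_state="inverse_normal")


def filter_batch_confounded(matrix: LipidomeMatrix, metadata: pd.DataFrame,
                            r2_threshold: float = 0.10) -> list[str]:
    """Species whose raw concentration is confounded with data generation.

    A species is excluded iff the R^2 of concentration ~ batch + injection
    order strictly exceeds ``r2_threshold``.  With a single batch level the
    model reduces to injection order alone.  Runs on raw concentrations
    (the filter precedes any transformation).
    """
    meta = metadata.loc[matrix.sample_ids]
    cols = [np.ones(len(meta))]
    batches = meta["batch_id"].astype(str)
    levels = sorted(batches.unique())
    for lv in levels[1:]:
        cols.append((batches == lv).to_numpy(float))
    cols.append(meta["injection_order"].to_numpy(float))
    X = np.column_stack(cols)
    excluded = []
    Q, _ = np.linalg.qr(X)
    for sp in matrix.species_ids:
        y = matrix.values[sp].to_numpy(float)
        obs = ~np.isnan(y)
        if obs.all():
            yv, Qv = y, Q
        else:
            yv = y[obs]
            Qv, _ = np.linalg.qr(X[obs])
        yc = yv - yv.mean()
        sst = float(yc @ yc)
        if sst == 0.0:
            continue
        fitted = Qv @ (Qv.T @ yv)
        resid = yv - fitted
        r2 = 1.0 - float(resid @ resid) / sst
        if r2 > r2_threshold:
            excluded.append(sp)
    logger.info("filter_batch_confounded: excluding %d / %d species (R^2 > %.2f)",
                len(excluded), matrix.n_species, r2_threshold)
    return excluded


def detect_statistical_outliers(matrix: LipidomeMatrix, z_cut: float = 3.0,
                                percentile: float = 99.0) -> OutlierReport:
    """Two-criterion statistical outlier flag.

    Per sample: (1) extremeness count = number of species with |z| > z_cut
    (z-scores computed species-wise in a single pass, flagged candidates
    included); (2) PCA distance = Euclidean norm of the full PC score
    vector of the z-scored matrix (equal to the norm of the z-score row).
    A sample is flagged iff BOTH exceed their own empirical ``percentile``
    quantiles (linear / type-7 interpolation).
    """
    if matrix.n_samples < 100:
        warnings.warn("percentile thresholds unstable for n < 100 samples", stacklevel=2)
    X = matrix.values.to_numpy(float)
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=1)
    sd[sd == 0] = np.nan
    Z = (X - mu) / sd
    counts = pd.Series(np.nansum(np.abs(Z) > z_cut, axis=1).astype(int),
                       index=matrix.sample_ids, name="extremeness_count")
    # full-score-vector PCA distance == row norm of centered z-scores
    Zc = Z - np.nanmean(Z, axis=0)
    dist = pd.Series(np.sqrt(np.nansum(Zc ** 2, axis=1)), index=matrix.sample_ids,
                     name="pca_distance")
    q = percentile / 100.0
    count_thr = float(np.quantile(counts.to_numpy(), q))
    dist_thr = float(np.quantile(dist.to_numpy(), q))
    flag = (counts > count_thr) & (dist > dist_thr)
    logger.info("detect_statistical_outliers: %d flagged of %d (count>%g AND dist>%g)",
                int(flag.sum()), matrix.n_samples, count_thr, dist_thr)
    return OutlierReport(counts, dist, count_thr, dist_thr, flag.rename("statistical_outlier"))


def flag_storage_outliers(metadata: pd.DataFrame, threshold_days: float = 2500) -> pd.Series:
    """Storage-duration outlier flag: storage_days >= threshold (inclusive)."""
    if "storage_days" not in metadata.columns:
        raise DataModelError("metadata lacks storage_days")
    return (metadata["storage_days"] >= threshold_days).rename("storage_outlier")


def infer_clinical_lipids(matrix: LipidomeMatrix, annotation: LipidAnnotation,
                          free_cholesterol_class: str = "COH",
                          cholesteryl_ester_class: str = "CE",
                          triglyceride_sim_class: str = "TG(SIM)") -> ClinicalLipids:
    """Infer clinical lipids from the ontology.

    Total cholesterol = free cholesterol species + sum of the cholesteryl
    ester class; total triglycerides = sum of the TG single-ion-monitoring
    class.
    """
    classes = annotation.classes()
    chol_species = [s for s in matrix.species_ids
                    if classes.get(s) in (free_cholesterol_class, cholesteryl_ester_class)]
    tg_species = [s for s in matrix.species_ids if classes.get(s) == triglyceride_sim_class]
    missing = [name for name, members in
               (("free cholesterol/CE", chol_species), ("TG(SIM)", tg_species)) if not members]
    if missing:
        raise DataModelError(f"annotation lacks required categories: {missing}")
    chol = matrix.values[chol_species].sum(axis=1, min_count=1)
    tg = matrix.values[tg_species].sum(axis=1, min_count=1)
    return ClinicalLipids(chol.rename("total_cholesterol"), tg.rename("total_triglycerides"))


def cosine_time(collection_time):
    """Periodic transform of 24-h collection time: sin(2*pi*t / 2400)."""
    t = np.asarray(collection_time, dtype=float)
    obs = ~np.isnan(t)
    if ((t[obs] < 0) | (t[obs] >= 2400)).any():
        raise DataModelError("collection_time out of [0, 2400)")
    return np.sin(2 * np.pi * t / 2400.0)


def class_totals(matrix: LipidomeMatrix, annotation: LipidAnnotation,
                 sim_only_classes: tuple[str, ...] = ("TG", "TG(O)")) -> pd.DataFrame:
    """Per-class total concentrations (sum over member species).

    For the TG and TG(O) classes, only the single-ion-monitoring species
    (class labels with a "(SIM)" suffix) enter the totals; the
    neutral-loss duplicates are skipped.
    """
    classes = annotation.classes()
    totals: dict[str, pd.Series] = {}
    for cls in sorted(classes.unique()):
        if cls in sim_only_classes:
            continue  # summed from the matching "(SIM)" class instead
        members = [s for s in matrix.species_ids if classes.get(s) == cls]
        if not members:
            continue
        target = cls[:-5] if cls.endswith("(SIM)") else cls
        totals[target] = matrix.values[members].sum(axis=1, min_count=1)
    return pd.DataFrame(totals)


def residualize(values, design) -> np.ndarray | pd.DataFrame | pd.Series:
    """Residuals of each column of ``values`` on the design matrix.

    Residuals are orthogonal to every design column; applying twice with
    the same design is a no-op (projection idempotence).
    """
    X = np.asarray(design, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DataModelError("residualize: design matrix is rank-deficient")
    Q, _ = np.linalg.qr(X)
    arr = np.asarray(values, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[:, None]
    resid = arr - Q @ (Q.T @ arr)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(resid, index=values.index, columns=values.columns)
    if isinstance(values, pd.Series):
        return pd.Series(resid[:, 0], index=values.index, name=values.name)
    return resid[:, 0] if squeeze else resid
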