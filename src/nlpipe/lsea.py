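"""Correlated-random-variable lipid set enrichment analysis (LSEA).

For a lipid set G with per-lipid association t-statistics t_i and the
covariate-adjusted lipid correlation matrix R (correlation of covariate
residuals), the enrichment statistic is

    S = sum_{i in G} t_i / sqrt( sum_{i,j in G} R_ij )

The denominator is the standard deviation of the numerator when the t_i
are unit-variance and correlated as R, so under the null S^2 is
approximately chi-squared with one degree of freedom; the signed S keeps
the direction of enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import DataModelError, LipidAnnotation, LipidomeMatrix
from .lwas import AssociationTable, run_lwas
from .qc import residualize


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # index set_id; columns level, size, S, p, q, direction
    trait: str = ""


def adjusted_correlation(matrix: LipidomeMatrix, design: pd.DataFrame) -> pd.DataFrame:
    """Species x species correlation of covariate residuals."""
    resid = residualize(matrix.values, design.loc[matrix.sample_ids])
    arr = resid.to_numpy(float)
    sd = arr.std(axis=0, ddof=0)
    if (sd == 0).any():
        bad = [s for s, z in zip(matrix.species_ids, sd == 0) if z]
        raise DataModelError(f"constant residual columns: {bad[:5]}")
    Z = (arr - arr.mean(axis=0)) / sd
    R = (Z.T @ Z) / arr.shape[0]
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=matrix.species_ids, columns=matrix.species_ids)


def lsea_statistic(members, t_vector: pd.Series, R: pd.DataFrame) -> tuple[float, float]:
    """Signed enrichment statistic and its chi-squared(1) p-value.

    Raises if the summed set correlation is non-positive (the variance
    approximation breaks down there; the set is reported, not clamped).
    """
    members = list(members)
    if not members:
        raise DataModelError("empty lipid set")
    denom = float(R.loc[members, members].to_numpy().sum())
    if denom <= 0:
        raise DataModelError(f"non-positive summed correlation ({denom:.3g}) for set of size {len(members)}")
    S = float(t_vector.loc[members].sum()) / np.sqrt(denom)
    p = float(stats.chi2.sf(S**2, df=1))
    return S, p


def run_lsea(matrix: LipidomeMatrix, trait: pd.Series, design: pd.DataFrame,
             annotation: LipidAnnotation, assoc: AssociationTable | None = None,
             min_set_size: int = 2, family: str = "auto",
             collapse_features: bool = True) -> EnrichmentResult:
    """Enrichment over all ontology sets with BH q-values per trait.

    The per-lipid t (or logistic z) statistics come from the marginal
    association fits with the identical covariate set; sets are every
    class/subclass/feature/domain annotation with >= ``min_set_size``
    analyzed members.  When ``collapse_features`` is set, composite
    annotations sharing a hierarchical label keep only the most
    significant entry (smallest p).
    """
    if assoc is None:
        assoc = run_lwas(matrix, trait, design, family=family)
    t = assoc.table["stat"].dropna()
    analyzed = [s for s in matrix.species_ids if s in t.index]
    sets = annotation.lipid_sets(min_set_size=min_set_size)
    sets = {k: [s for s in v if s in t.index] for k, v in sets.items()}
    sets = {k: v for k, v in sets.items() if len(v) >= min_set_size}
    if not sets:
        raise DataModelError("no lipid sets reach the minimum size")
    R = adjusted_correlation(matrix.subset_species(analyzed), design)
    rows = {}
    for set_id, members in sets.items():
        S, p = lsea_statistic(members, t, R)
        level = set_id.split(":", 1)[0]
        rows[set_id] = (level, len(members), S, p, np.sign(S))
    table = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=["level", "size", "S", "p", "direction"])
    if collapse_features:
        # one row per hierarchical label: keep the most significant composite
        table["label"] = [i.split(":", 1)[1] for i in table.index]
        table = (table.sort_values("p").groupby(["level", "label"], as_index=False)
                 .head(1).drop(columns="label"))
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    table = table.sort_values("p")
    table.index.name = "set_id"
    return EnrichmentResult(table, trait=str(trait.name or ""))
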