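"""Typed data model and tabular I/O for the lipidome association pipeline.

The pipeline operates on three aligned tables: a samples x species
concentration matrix, a lipid ontology annotation table (species ->
class / subclasses / features / domain) and a per-sample metadata table
(demographics, batch/technical variables, trait scores, medication flags
and dietary composition).  All tables are TSV with a header row; missing
values are written as ``NA`` (empty cells are also accepted on read).

Sample order is canonicalized to sorted sample id after alignment so
that every downstream stage is order-stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("nlpipe")

NA_VALUES = ["", "NA"]

#: metadata columns with special semantics (everything else is carried through)
GROUP_LEVELS = ("ASD", "SIB", "UNR")
SEX_LEVELS = ("female", "male")


class DataModelError(ValueError):
    """Raised on malformed or inconsistent input tables."""


@dataclass
class LipidAnnotation:
    """Lipid ontology: species -> one class, zero+ subclasses/features, one domain.

    Subclass and feature entries are ';'-separated in the TSV; the union of
    all annotation categories defines the lipid sets used for enrichment.
    """

    table: pd.DataFrame  # index species_id; columns class_id, subclass_ids, feature_ids, domain_id

    def __post_init__(self) -> None:
        required = {"class_id", "domain_id"}
        missing = required - set(self.table.columns)
        if missing:
            raise DataModelError(f"annotation table missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise DataModelError(f"duplicate species in annotation: {dups[:5]}")

    @property
    def species_ids(self) -> list[str]:
        return list(self.table.index)

    def classes(self) -> pd.Series:
        return self.table["class_id"]

    def multi(self, column: str) -> dict[str, list[str]]:
        """Split a ';'-separated multi-valued column into lists per species."""
        out = {}
        for sp, val in self.table[column].items():
            if pd.isna(val) or val == "":
                out[sp] = []
            else:
                out[sp] = [v for v in str(val).split(";") if v]
        return out

    def lipid_sets(self, min_set_size: int = 2) -> dict[str, list[str]]:
        """Annotation-level -> member species, across class/subclass/feature/domain.

        Set ids are prefixed with their hierarchical level, e.g.
        ``class:PC`` or ``feature:FA20:4``.
        """
        sets: dict[str, list[str]] = {}
        for sp, cls in self.table["class_id"].items():
            sets.setdefault(f"class:{cls}", []).append(sp)
        for sp, dom in self.table["domain_id"].items():
            sets.setdefault(f"domain:{dom}", []).append(sp)
        for col, tag in (("subclass_ids", "subclass"), ("feature_ids", "feature")):
            if col in self.table.columns:
                for sp, vals in self.multi(col).items():
                    for v in vals:
                        sets.setdefault(f"{tag}:{v}", []).append(sp)
        return {k: v for k, v in sets.items() if len(v) >= min_set_size}


@dataclass
class LipidomeMatrix:
    """Samples x lipid-species concentration matrix.

    ``values`` holds concentrations (arbitrary positive units, pmol/ml
    semantics) with NaN marking missing entries explicitly.
    ``transform_state`` tracks whether columns are raw concentrations,
    rank-based inverse-normal transformed, or covariate residuals.
    """

    values: pd.DataFrame  # index sample_id, columns species_id
    transform_state: str = "raw"

    _STATES = ("raw", "inverse_normal", "residualized")

    def __post_init__(self) -> None:
        if self.transform_state not in self._STATES:
            raise DataModelError(f"unknown transform_state {self.transform_state!r}")
        if self.values.index.has_duplicates:
            raise DataModelError("duplicate sample ids")
        if self.values.columns.has_duplicates:
            raise DataModelError("duplicate species ids")
        arr = self.values.to_numpy()
        if np.isinf(arr).any():
            raise DataModelError("non-finite concentration values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_species(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "LipidomeMatrix":
        return LipidomeMatrix(self.values.loc[list(sample_ids)], self.transform_state)

    def subset_species(self, species_ids) -> "LipidomeMatrix":
        return LipidomeMatrix(self.values[list(species_ids)], self.transform_state)


@dataclass
class CovariateSpec:
    """Named covariate set expanded into a design matrix.

    ``columns`` are metadata column names; ``age2`` and ``cos_time`` are
    derived terms (age squared; sin(2*pi*t/2400) of collection time).
    Categorical columns (sex, group, batch_id and any non-numeric column)
    are dummy-encoded dropping the lexicographically first level.
    """

    columns: tuple[str, ...] = ()
    name: str = "custom"

    #: standard covariate sets for the analysis stages
    PRESETS = {
        "nocov": (),
        "covdemog": ("age", "age2", "sex", "batch_id", "injection_order", "storage_days"),
        "covdemogdiet": (
            "age", "age2", "sex", "batch_id", "injection_order", "storage_days",
            "diet_pc1", "diet_pc2", "diet_pc3",
        ),
        "covdemogtime": (
            "age", "age2", "sex", "batch_id", "injection_order", "storage_days", "cos_time",
        ),
    }

    @classmethod
    def preset(cls, name: str) -> "CovariateSpec":
        if name not in cls.PRESETS:
            raise DataModelError(f"unknown covariate set {name!r}; choose from {sorted(cls.PRESETS)}")
        return cls(columns=cls.PRESETS[name], name=name)

    def required_metadata_columns(self) -> list[str]:
        out = []
        for c in self.columns:
            if c == "age2":
                out.append("age")
            elif c == "cos_time":
                out.append("collection_time")
            else:
                out.append(c)
        return sorted(set(out))


# ---------------------------------------------------------------------------
# readers / writers


def load_lipidome(path, annotation_path) -> tuple[LipidomeMatrix, LipidAnnotation]:
    """Read a concentration matrix (samples in rows) and its ontology table.

    Every species column must have an annotation row; species missing from
    the annotation are reported by name.
    """
    values = pd.read_csv(path, sep="\t", index_col=0, na_values=NA_VALUES, keep_default_na=False)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    non_numeric = [c for c in values.columns if not pd.api.types.is_numeric_dtype(values[c])]
    if non_numeric:
        raise DataModelError(f"non-numeric concentration columns: {non_numeric[:5]}")
    matrix = LipidomeMatrix(values)

    ann = pd.read_csv(annotation_path, sep="\t", index_col=0, na_values=NA_VALUES,
                      keep_default_na=False, dtype=str)
    ann.index = ann.index.astype(str)
    annotation = LipidAnnotation(ann)
    missing = [s for s in matrix.species_ids if s not in ann.index]
    if missing:
        raise DataModelError(f"species without annotation rows: {missing}")
    annotation = LipidAnnotation(ann.loc[matrix.species_ids])
    n_missing = int(matrix.values.isna().sum().sum())
    logger.info("loaded lipidome %s: %d samples x %d species (%d missing cells)",
                path, matrix.n_samples, matrix.n_species, n_missing)
    return matrix, annotation


def write_lipidome(matrix: LipidomeMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")


def load_metadata(path) -> pd.DataFrame:
    """Read the per-sample metadata table, validating ranged fields."""
    meta = pd.read_csv(path, sep="\t", index_col=0, na_values=NA_VALUES, keep_default_na=False)
    meta.index = meta.index.astype(str)
    if meta.index.has_duplicates:
        raise DataModelError("duplicate sample ids in metadata")
    if "collection_time" in meta.columns:
        t = meta["collection_time"].dropna()
        bad = t[(t < 0) | (t >= 2400)]
        if len(bad):
            raise DataModelError(f"collection_time out of [0, 2400): samples {list(bad.index[:5])}")
    diet_cols = [c for c in meta.columns if c.startswith("diet_frac_")]
    if diet_cols:
        comp = meta[diet_cols].dropna()
        if len(comp):
            if (comp.to_numpy() < 0).any():
                raise DataModelError("negative dietary composition entries")
            sums = comp.sum(axis=1)
            off = sums[(sums - 1.0).abs() > 1e-9]
            if len(off):
                raise DataModelError(f"dietary composition does not sum to 1: samples {list(off.index[:5])}")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")


def write_annotation(annotation: LipidAnnotation, path) -> None:
    annotation.table.to_csv(path, sep="\t", na_rep="NA", index_label="species_id")


# ---------------------------------------------------------------------------
# alignment and design


def align_and_subset(matrix: LipidomeMatrix, metadata: pd.DataFrame,
                     required_columns=()) -> tuple[LipidomeMatrix, pd.DataFrame]:
    """Restrict to samples present in both tables with complete required data.

    Sample order is canonicalized to sorted sample id; the count of samples
    dropped per reason is logged (complete-case convention: analyses use
    only samples observed on every variable they touch).
    """
    common = sorted(set(matrix.sample_ids) & set(metadata.index))
    if not common:
        raise DataModelError("no overlapping samples between lipidome and metadata")
    n_lip_only = matrix.n_samples - len(common)
    n_meta_only = len(metadata) - len(common)
    meta = metadata.loc[common]
    keep = pd.Series(True, index=meta.index)
    for col in required_columns:
        if col not in meta.columns:
            raise DataModelError(f"required metadata column {col!r} absent")
        dropped = int((keep & meta[col].isna()).sum())
        if dropped:
            logger.info("align_and_subset: dropping %d samples missing %s", dropped, col)
        keep &= meta[col].notna()
    kept = list(meta.index[keep])
    if not kept:
        raise DataModelError("no samples remain after complete-case subsetting")
    logger.info("align_and_subset: kept %d samples (%d lipidome-only, %d metadata-only removed)",
                len(kept), n_lip_only, n_meta_only)
    return matrix.subset_samples(kept), meta.loc[kept]


def _encode_column(meta: pd.DataFrame, col: str) -> pd.DataFrame:
    """Expand one covariate term into numeric design columns."""
    if col == "age2":
        return pd.DataFrame({"age2": meta["age"].astype(float) ** 2})
    if col == "cos_time":
        from .qc import cosine_time  # derived technical covariate
        return pd.DataFrame({"cos_time": cosine_time(meta["collection_time"].to_numpy(float))},
                            index=meta.index)
    if col not in meta.columns:
        raise DataModelError(f"covariate column {col!r} absent from metadata")
    series = meta[col]
    if pd.api.types.is_numeric_dtype(series) and not pd.api.types.is_bool_dtype(series):
        return pd.DataFrame({col: series.astype(float)})
    # categorical/boolean -> dummies dropping the lexicographically first level
    levels = sorted(series.astype(str).unique())
    dummies = pd.get_dummies(series.astype(str), prefix=col, dtype=float)
    dummies = dummies[[f"{col}_{lv}" for lv in levels[1:]]]
    return dummies


def build_design(metadata: pd.DataFrame, spec: CovariateSpec) -> pd.DataFrame:
    """Build a full-rank design matrix (with intercept) from a covariate spec.

    Rank deficiency is reported with the offending columns rather than
    silently dropped.
    """
    parts = [pd.DataFrame({"intercept": np.ones(len(metadata))}, index=metadata.index)]
    for col in spec.columns:
        parts.append(_encode_column(metadata, col).set_axis(metadata.index, axis=0))
    design = pd.concat(parts, axis=1)
    if design.isna().any().any():
        bad = list(design.columns[design.isna().any()])
        raise DataModelError(f"missing values in design columns {bad}; subset to complete cases first")
    X = design.to_numpy(float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by greedy QR-style scan
        bad = []
        cols_so_far = np.empty((X.shape[0], 0))
        for j, name in enumerate(design.columns):
            cand = np.column_stack([cols_so_far, X[:, j]])
            if np.linalg.matrix_rank(cand) == cols_so_far.shape[1]:
                bad.append(name)
            else:
                cols_so_far = cand
        raise DataModelError(f"design matrix rank-deficient; collinear columns: {bad}")
    return design
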