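import numpy as np
import pandas as pd
import pytest

from nlpipe import (
    CovariateSpec,
    SimConfig,
    align_and_subset,
    build_design,
    simulate_lipidome,
    transform_lipidome,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Small simulated cohort with planted trait effects (seeded)."""
    config = SimConfig.study_like(seed=11, n_samples=300, n_species=120, n_classes=12)
    matrix, annotation, meta, truth = simulate_lipidome(config)
    return matrix, annotation, meta, truth


@pytest.fixture(scope="session")
def analysis_ready(small_cohort):
    """Aligned, complete-case, transformed data plus a covdemog design."""
    matrix, annotation, meta, truth = small_cohort
    spec = CovariateSpec.preset("covdemog")
    m2, meta2 = align_and_subset(matrix, meta,
                                 required_columns=["iq_dq"] + spec.required_metadata_columns())
    design = build_design(meta2, spec)
    transformed = transform_lipidome(m2)
    return transformed, annotation, meta2, design, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
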