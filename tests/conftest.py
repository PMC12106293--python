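import numpy as np
import pytest

from amspipe.cohort import GeneratorConfig, generate_cohort
from amspipe.matrix import AbundanceMatrix
from amspipe.modules import concatenate_omics
from amspipe.preprocess import log2_transform


@pytest.fixture(scope="session")
def default_cohort():
    """One default-config cohort (train only, no corruption) shared by tests
    that need realistic module structure."""
    cfg = GeneratorConfig(seed=7, n_valid=0, missing_rate_mcar=0.0,
                          outlier_cell_rate=0.0, sample_scale_sd=0.0)
    proteins, metabolites, clinical, truth = generate_cohort(cfg)
    return cfg, proteins, metabolites, clinical, truth


@pytest.fixture(scope="session")
def integrated_default(default_cohort):
    _, proteins, metabolites, clinical, truth = default_cohort
    x = concatenate_omics(log2_transform(proteins), log2_transform(metabolites))
    return x, clinical, truth


def make_matrix(values, omic="protein", scale="raw", prefix="F"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return AbundanceMatrix(
        samples=[f"S{i}" for i in range(n)],
        features=[f"{prefix}{j}" for j in range(p)],
        values=values, omic=omic, scale=scale,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
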