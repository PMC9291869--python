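import numpy as np
import pytest
from hypothesis import settings

from oxtmap.atlas_io import ExpressionMatrix
from oxtmap.synthetic import SyntheticConfig, generate_dataset

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """Small synthetic bundle with a planted OXTR effect and co-expression pair."""
    cfg = SyntheticConfig(
        seed=11,
        n_subcortical=300,
        n_cortical=400,
        n_excluded=40,
        n_subcortical_affected=60,
        n_cortical_affected=50,
        effect_z={"OXTR": 1.0},
        coexpr_effect=[(("OXTR", "AVPR1A"), 0.4)],
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def null_dataset():
    """Small synthetic bundle with no planted effects."""
    cfg = SyntheticConfig(
        seed=13,
        n_subcortical=300,
        n_cortical=0,
        n_excluded=20,
        n_subcortical_affected=60,
        n_cortical_affected=0,
    )
    return generate_dataset(cfg)


def gene_matrix(ds) -> ExpressionMatrix:
    """Gene x sample matrix built from each gene's designated probe."""
    genes = list(ds.config.genes)
    values = np.vstack(
        [ds.expression.row(ds.truth.designated_probes[g]) for g in genes]
    )
    return ExpressionMatrix(genes, list(ds.expression.col_ids), values, "log2_intensity")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
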