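import numpy as np
import pytest

from phylink import (
    ExpressionMatrix,
    SimulationConfig,
    simulate_annotations,
    simulate_expression,
    simulate_profiles,
)
from phylink.simulate import gene_roster


@pytest.fixture(scope="session")
def small_sim():
    """A small planted-module world shared by integration-style tests."""
    config = SimulationConfig(
        n_species=60, n_genes=80, n_modules=4, module_size=6,
        n_samples=60, seed=11,
    )
    matrix, membership = simulate_profiles(config)
    expr = simulate_expression(config, membership)
    _, _, background = gene_roster(config)
    annotations = simulate_annotations(
        membership, terms_per_module=2, annotation_noise=0.3,
        rng_seed=12, background_genes=background,
    )
    return config, matrix, membership, expr, annotations


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_expression(values, state="raw", genes=None, samples=None):
    """Small helper: wrap a 2-D array in an ExpressionMatrix."""
    import pandas as pd

    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        normalization_state=state,
    )
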