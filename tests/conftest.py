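import numpy as np
import pandas as pd
import pytest

from m6astrat.io_core import ExpressionMatrix
from m6astrat.synthetic_cohort import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Compact cohort for fast structural tests."""
    cfg = SimulationConfig(n_samples=120, n_background_genes=150,
                           n_prognostic_genes=40, n_immune_genes=20, seed=123)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Cohort at the default study conditions (n=400, sep=4, beta=0.8)."""
    return simulate_cohort(SimulationConfig(seed=2024))


def make_expr(values, genes=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
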