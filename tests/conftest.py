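import numpy as np
import pandas as pd
import pytest

from proteoscreen import ExpressionMatrix, SimulationConfig, generate_expression
from proteoscreen.pipeline import worked_example_tables


@pytest.fixture(scope="session")
def worked_example():
    """In-memory worked-example tables: (lpon, ole, protein, network, annotations, names)."""
    return worked_example_tables()


@pytest.fixture
def small_expr():
    """10 genes x (3+3) samples, fixed seed, strictly positive."""
    rng = np.random.default_rng(42)
    genes = [f"g{i:02d}" for i in range(10)]
    samples = ["a1", "a2", "a3", "b1", "b2", "b3"]
    values = pd.DataFrame(
        np.exp(rng.normal(5.0, 0.3, (10, 6))), index=genes, columns=samples
    )
    conditions = pd.Series(["A"] * 3 + ["B"] * 3, index=samples)
    return ExpressionMatrix(values=values, conditions=conditions)


@pytest.fixture
def quiet_config():
    """Low-noise simulation used to exercise screening logic deterministically."""
    return SimulationConfig(
        n_genes=120, n_specific=8, n_shared=8, noise_sd=0.02, seed=7
    )


@pytest.fixture
def quiet_experiment(quiet_config):
    return generate_expression(quiet_config)
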