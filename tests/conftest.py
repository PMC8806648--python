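import numpy as np
import pandas as pd
import pytest

from itaemt import (
    ExpressionMatrix,
    SimulationConfig,
    generate_cohort,
)


def fast_config(**kwargs) -> SimulationConfig:
    """A small-but-structured cohort config for unit tests."""
    defaults = dict(n_samples=250, n_genes=600, n_extra_sets=5,
                    n_signature_background=100, seed=42)
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(fast_config())


@pytest.fixture(scope="session")
def null_cohort():
    return generate_cohort(fast_config(beta_emt=0.0, beta_ita=0.0, seed=77))


@pytest.fixture()
def tiny_expr():
    rng = np.random.default_rng(3)
    data = pd.DataFrame(
        rng.uniform(0, 50, size=(20, 5)),
        index=[f"g{i}" for i in range(20)],
        columns=[f"s{j}" for j in range(5)],
    )
    return ExpressionMatrix(data)
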