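import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cimpkit import CohortConfig, ExpressionMatrix, simulate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort42():
    """Default cohort at seed 42 (n=80), shared read-only across tests."""
    return simulate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def small_expr():
    """A small seeded expression matrix on the rpkm scale."""
    rng = np.random.default_rng(3)
    genes = [f"g{i:02d}" for i in range(30)]
    samples = [f"s{i:02d}" for i in range(12)]
    vals = rng.gamma(2.0, 50.0, size=(30, 12))
    return ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=samples),
                            scale="rpkm")
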