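import numpy as np
import pandas as pd
import pytest

from amlstack import (
    CohortSpec,
    ExpressionMatrix,
    FeatureSpec,
    generate_cohort,
)
from amlstack.io import network_from_edges


@pytest.fixture(scope="session")
def small_cohort():
    """Modest synthetic cohort shared by unit tests (fast to fit)."""
    return generate_cohort(
        CohortSpec(
            seed=11,
            n_patients=80,
            n_drugs=4,
            n_genes=200,
            n_subtypes=3,
            n_centers=4,
            noise_sd=0.15,
            missing_screen_fraction=0.2,
        )
    )


@pytest.fixture(scope="session")
def small_spec():
    return FeatureSpec(variance_top_k=50, correlation_top_k=50)


@pytest.fixture
def tiny_expr():
    return ExpressionMatrix(
        pd.DataFrame(
            [[1.0, 4.0], [2.0, 5.0], [3.0, 9.0]],
            index=["g1", "g2", "g3"],
            columns=["s1", "s2"],
        )
    )


@pytest.fixture
def path_network():
    # a - b - c - d - e chain plus (b, f)
    return network_from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("b", "f")])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
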