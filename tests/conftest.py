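import numpy as np
import pandas as pd
import pytest

from symptomnet import calibrated_spec, default_instrument, generate_responses


@pytest.fixture(scope="session")
def instrument():
    return default_instrument()


@pytest.fixture(scope="session")
def cohort(instrument):
    """One calibrated synthetic cohort (503 x 40) shared across tests."""
    return generate_responses(calibrated_spec(n_participants=503, seed=7))


@pytest.fixture
def toy_matrix():
    """Hand-checkable 6 participants x 5 items with ties."""
    return pd.DataFrame(
        {
            "a": [0, 1, 1, 2, 3, 0],
            "b": [1, 1, 2, 2, 3, 0],
            "c": [0, 0, 1, 3, 2, 1],
            "d": [2, 2, 2, 3, 3, 1],
            "e": [0, 1, 0, 1, 2, 2],
        }
    )


def prevalence_column(count: int, n: int, name: str = "x") -> pd.DataFrame:
    """A single-item matrix in which exactly ``count`` of ``n`` score >= 1."""
    return pd.DataFrame({name: [1] * count + [0] * (n - count)})
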