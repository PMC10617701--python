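import numpy as np
import pandas as pd
import pytest

from healtheq import SurveyTable


@pytest.fixture
def rng():
    return np.random.default_rng(20231031)


def random_binary_table(rng, n=None):
    """Small random weighted table for identity/property checks."""
    if n is None:
        n = int(rng.integers(4, 51))
    scores = rng.normal(size=n)
    if rng.random() < 0.3:  # ties with positive probability
        scores = np.round(scores, 1)
    weights = rng.uniform(0.2, 5.0, size=n)
    h = (rng.random(n) < 0.5).astype(int)
    if h.sum() == 0:
        h[int(rng.integers(0, n))] = 1
    return h, scores, weights


@pytest.fixture
def four_unit_table():
    """The hand-computed example: 4 equal weights, only the richest positive."""
    df = pd.DataFrame(
        {
            "h": [0, 0, 0, 1],
            "wealth_score": [1.0, 2.0, 3.0, 4.0],
            "weight": [1.0, 1.0, 1.0, 1.0],
            "cluster": ["a", "a", "b", "b"],
            "stratum": ["s", "s", "s", "s"],
        }
    )
    return SurveyTable(df)
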