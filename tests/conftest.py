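import numpy as np
import pandas as pd
import pytest

from tissuetau import ExpressionMatrix, SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_matrix():
    """One gene per category: null, weak, wide-spread, specific."""
    values = pd.DataFrame(
        {
            "liver": [0.2, 2.0, 40.0, 0.5],
            "brain": [0.9, 3.0, 50.0, 0.8],
            "testis": [1.0, 9.5, 60.0, 200.0],
        },
        index=pd.Index(["g_null", "g_weak", "g_wide", "g_spec"], name="Gene ID"),
    )
    return ExpressionMatrix(values=values, units="FPKM")


def small_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Scaled-down synthetic study: same levels and noise, fewer genes."""
    defaults = dict(
        n_tissues=12,
        n_null=40,
        n_weak=60,
        n_housekeeping=240,
        specific_counts={1: 40, 2: 12, 3: 8},
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)
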