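import numpy as np
import pandas as pd
import pytest

from pdxspace import SynthConfig, generate_cohort, planted_signatures


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared by read-only tests."""
    cfg = SynthConfig(seed=7)
    X, C, annotation, truth = generate_cohort(cfg)
    stromal, immune = planted_signatures(cfg)
    return dict(
        config=cfg, X=X, C=C, annotation=annotation, truth=truth,
        stromal=stromal, immune=immune,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def random_calls(rng):
    """Small random binary call matrix."""
    return pd.DataFrame(
        rng.integers(0, 2, (30, 20)),
        index=[f"g{i:03d}" for i in range(30)],
        columns=[f"s{i:02d}" for i in range(20)],
    )
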