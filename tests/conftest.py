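import numpy as np
import pandas as pd
import pytest

from methpattern.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with full planted structure (TME blocks included)."""
    cfg = SyntheticConfig(n_samples=150, n_genes=500, n_sig_genes=100, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the full study conditions (n=600, 2000 genes)."""
    return generate_cohort(SyntheticConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def toy_expression():
    rng = np.random.default_rng(5)
    return pd.DataFrame(
        rng.normal(6, 1, (30, 12)),
        index=[f"g{i:02d}" for i in range(30)],
        columns=[f"s{i:02d}" for i in range(12)],
    )
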