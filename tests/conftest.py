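import numpy as np
import pandas as pd
import pytest

from cpgmediate import SimulationConfig, generate_cohort, generate_methylation, generate_outcome


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_participants=300, n_mediators=400, seed=42)


@pytest.fixture(scope="session")
def small_study(small_config):
    """One small synthetic study shared by read-only tests."""
    pheno, items = generate_cohort(small_config)
    x = pheno["exposure_true"].to_numpy()
    meth, cells, truth = generate_methylation(small_config, x)
    y = generate_outcome(small_config, x, meth, truth)
    return dict(pheno=pheno, items=items, x=x, meth=meth, cells=cells,
                truth=truth, y=y)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240101)
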