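import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_counts():
    """The four-gene filtering hand-trace matrix (4 samples)."""
    return pd.DataFrame(
        [[0, 0, 0, 0], [1, 1, 1, 0], [10, 10, 0, 0], [5, 0, 3, 2]],
        index=["g1", "g2", "g3", "g4"],
        columns=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture
def two_groups_14():
    samples = [f"s{j}" for j in range(14)]
    return pd.Series(["high"] * 7 + ["low"] * 7, index=samples)


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study bundle, shared across tests."""
    from imfnet import SimConfig, generate_study

    cfg = SimConfig(n_genes=250, n_animals=60, n_snps=300, n_qtl=50,
                    n_de=24, n_regulators=1, module_size=12, seed=42)
    return generate_study(cfg)
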