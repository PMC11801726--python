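import numpy as np
import pytest

from methylpredict import BetaMatrix, PhenotypeTable, SyntheticConfig, generate_study
import pandas as pd


@pytest.fixture(scope="session")
def small_study():
    """Tiny but signal-rich study shared by pipeline tests."""
    cfg = SyntheticConfig(
        n_samples=70, n_probes=250, n_signal_probes=12,
        noise_sd=0.1, effect_size_range=(0.05, 0.15), seed=101,
    )
    return generate_study(cfg)


@pytest.fixture
def tiny_beta():
    rng = np.random.default_rng(0)
    values = rng.uniform(0.05, 0.95, size=(5, 8))
    return BetaMatrix(
        sample_ids=[f"s{i}" for i in range(5)],
        probe_ids=[f"cg{j}" for j in range(8)],
        values=values,
    )


@pytest.fixture
def tiny_pheno():
    return PhenotypeTable(
        data=pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(5)], "target": [3.0, 9.0, 15.0, 6.0, 12.0]}
        )
    )
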