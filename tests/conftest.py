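import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from crossfdr import SimConfig, SumstatsTable, harmonize_pair, simulate_pair


@pytest.fixture
def small_table():
    """Five well-formed records, canonical columns."""
    df = pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(1, 6)],
            "chrom": ["1", "1", "2", "2", "3"],
            "pos": [100, 200, 50, 150, 10],
            "pvalue": [0.5, 0.01, 0.2, 1e-6, 0.9],
        }
    )
    return SumstatsTable(trait_name="toy", df=df)


@pytest.fixture(scope="session")
def planted_pair():
    """Medium simulated pair with planted sharing, plus its truth labels.

    Session-scoped: several tests read it, none mutates it.
    """
    cfg = SimConfig(
        n_snps=20_000,
        pi_null=0.95,
        pi_a_only=0.02,
        pi_b_only=0.02,
        pi_shared=0.01,
        sigma2_a=25.0,
        sigma2_b=25.0,
        seed=7,
    )
    a, b, truth = simulate_pair(cfg)
    pair = harmonize_pair(a, b)
    assert np.array_equal(pair.snp_ids, truth.snp_ids)
    return pair, truth
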