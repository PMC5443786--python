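import numpy as np
import pandas as pd
import pytest

from smdiv.synthetic_data import CommunitySpec, generate_community


@pytest.fixture(scope="session")
def clean_community():
    """Small error-free, chimera-free community shared across tests."""
    spec = CommunitySpec(
        n_families_per_site=8,
        reads_per_sample=120,
        error_rate=0.0,
        chimera_rate=0.0,
        seed=11,
    )
    return generate_community(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_metadata():
    rows = []
    for site in ("P1", "P2", "P3"):
        for stage in ("emergence", "senescence"):
            for rep in (1, 2, 3):
                rows.append(
                    {
                        "sample_id": f"{site}_{stage[:3]}_{rep}",
                        "site": site,
                        "stage": stage,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)
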