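import numpy as np
import pandas as pd
import pytest

from seacosm import NoiseSpec, simulate_campaign


@pytest.fixture(scope="session")
def noiseless_campaign():
    """Four-season synthetic campaign with noise disabled."""
    return simulate_campaign(seed=11, noise=NoiseSpec(kind="none"))


@pytest.fixture()
def toy_abundance():
    """Two groups, one season, two treatments, exact exponentials."""
    rows = []
    for treatment, rep in [("CT_L", 1), ("CT_L", 2), ("PR_L", 1), ("PR_L", 2)]:
        for group, k in [("SAR11", 0.3), ("ALT", 1.2)]:
            for t in (0.0, 16.0, 32.0, 48.0):
                rows.append(
                    {
                        "season": "spring",
                        "treatment": treatment,
                        "replicate": rep,
                        "group": group,
                        "time_h": t,
                        "cells_per_ml": 1e5 * np.exp(k * t / 24.0),
                    }
                )
    return pd.DataFrame(rows)
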