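import numpy as np
import pandas as pd
import pytest

import movespec as ms
from movespec.priors import default_priors
from movespec.synchrony import McmcConfig


@pytest.fixture(scope="session")
def priors():
    return default_priors()


@pytest.fixture(scope="session")
def fast_mcmc():
    """Short sampler settings for unit tests (not for final inference)."""
    return McmcConfig(chains=2, iterations=1500, seed=1234)


@pytest.fixture(scope="session")
def study_like():
    """Synthetic panel at the study conditions: N=6, L=64, cutoff 3."""
    cfg = ms.SyntheticConfig(seed=20060203)
    panel, truth, distances = ms.simulate_panel(cfg)
    return panel, truth, distances


@pytest.fixture()
def toy_tracks():
    """Four-day, two-individual fix table with hand-computable distances."""
    rows = []
    coords = {
        "a": [(0.0, 0.0), (3.0, 4.0), (3.0, 4.0), (6.0, 8.0)],
        "b": [(10.0, 0.0), (10.0, 1.0), (12.0, 1.0), (12.0, 4.0)],
    }
    for ind, pts in coords.items():
        for day, (e, n) in enumerate(pts):
            rows.append(
                {
                    "individual": ind,
                    "date": pd.Timestamp("2006-02-03") + pd.Timedelta(days=day),
                    "easting": e,
                    "northing": n,
                }
            )
    return pd.DataFrame(rows)
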