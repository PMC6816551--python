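import numpy as np
import pandas as pd
import pytest

from mirrormix import (
    CorrectOrGuessParams,
    SMCParams,
    canonical_layout,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def arctic():
    return canonical_layout("arctic")


@pytest.fixture(scope="session")
def jetty():
    return canonical_layout("jetty")


@pytest.fixture(scope="session")
def cog_trials_528(arctic):
    """One simulated dataset at the published recovery conditions."""
    return simulate_dataset("cog", CorrectOrGuessParams(pc=1 / 3, sigma=0.15),
                            arctic, 528, seed=11)


@pytest.fixture(scope="session")
def smc_trials_small(arctic):
    """A small stage-tree dataset for fast fitting tests."""
    return simulate_dataset("smc", SMCParams(p1=0.8, p2=0.8, p3=0.6, sigma=0.15),
                            arctic, 128, seed=5)


def random_trials(layout, n, rng):
    """Arbitrary (not model-generated) trials for likelihood oracles."""
    tids = rng.choice(layout.target_ids, size=n)
    resp = rng.uniform(-2, 2, size=(n, 2))
    return pd.DataFrame({
        "target_id": tids,
        "response_x_m": resp[:, 0],
        "response_y_m": resp[:, 1],
    })
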