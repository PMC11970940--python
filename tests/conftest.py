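import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).resolve().parent))  # for oracles.py

import ppgstress as ps


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def random_rr(rng):
    """One seeded irregular RR series spanning well over 10 s."""
    rr = 800.0 + rng.uniform(-120.0, 120.0, size=60)
    return ps.RRSeries(rr, np.cumsum(rr) / 1000.0)


@pytest.fixture(scope="session")
def labeled_table():
    """Default 3-class synthetic feature table (shared: costly to build)."""
    return ps.generate_labeled_features(n_per_class=60, seed=1234)


@pytest.fixture(scope="session")
def trained_model(labeled_table):
    return ps.train(labeled_table)
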