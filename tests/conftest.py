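import numpy as np
import pandas as pd
import pytest

from rampclamp.io import Frame, Topology
from rampclamp.synth import make_toy_complex


@pytest.fixture(scope="session")
def toy():
    """(topology, frame, bead model) of the coarse-grained complex."""
    return make_toy_complex()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def minimal_topology(n, **overrides):
    """Plain n-atom topology for geometric tests (carbon beads, no flags)."""
    cols = {
        "serial": np.arange(1, n + 1),
        "name": ["X"] * n,
        "resname": ["RES"] * n,
        "resid": np.arange(1, n + 1),
        "chain": ["A"] * n,
        "element": ["C"] * n,
        "charge": np.zeros(n),
        "lj_epsilon": np.zeros(n),
        "lj_rmin_half": np.full(n, 2.0),
        "donor": [False] * n,
        "acceptor": [False] * n,
        "fixed": [False] * n,
    }
    cols.update(overrides)
    return Topology(atoms=pd.DataFrame(cols))


def frame_of(coords):
    return Frame(time=0.0, coords=np.asarray(coords, float))
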