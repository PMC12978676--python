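import numpy as np
import pandas as pd
import pytest

import restspeech as rs

SCALED = dict(n_nodes=60, n_excluded=6, n_networks=6, n_language=5)


@pytest.fixture(scope="session")
def small_cohort():
    """One scaled-down cohort (60 nodes, 6 base networks, 5 language nodes)."""
    cfg = rs.CohortConfig(n_younger=10, n_older=8, seed=42, **SCALED)
    return rs.generate_cohort(cfg)


@pytest.fixture(scope="session")
def toy_atlas():
    """4 included nodes in two 2-node networks plus one excluded node."""
    return pd.DataFrame(
        {
            "node_id": ["a", "b", "c", "d", "e"],
            "x": [0.0] * 5,
            "y": [0.0] * 5,
            "z": [0.0] * 5,
            "network": ["net1", "net1", "net2", "net2", "net1"],
            "excluded": [False, False, False, False, True],
            "language_side": ["none"] * 5,
        }
    )


def toy_connectivity(z, nodes):
    """ConnectivityMatrix from an explicit symmetric matrix."""
    return rs.ConnectivityMatrix(participant="p", nodes=list(nodes),
                                 z_matrix=np.asarray(z, dtype=float))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
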