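import numpy as np
import pytest

import alphadyn as ad


@pytest.fixture(scope="session")
def default_eeg():
    """One standard synthetic subject (32 ch, 195 s at 100 Hz, snr 4)."""
    rec, truth = ad.generate_alpha_eeg(ad.EEGSimSpec(seed=11))
    return rec, truth


@pytest.fixture(scope="session")
def analyzed_subject(default_eeg):
    """Full pipeline products for the standard synthetic subject."""
    rec, _ = default_eeg
    return ad.analyze_subject(rec)


@pytest.fixture(scope="session")
def toy_graph():
    """4-node weighted graph with a known maximum spanning tree.

    Weights (0-indexed nodes): w(0,1)=.9, w(0,2)=.5, w(1,2)=.8, w(2,3)=.7,
    w(0,3)=.2, w(1,3)=.1; the MST is {(0,1),(1,2),(2,3)}, total weight 2.4.
    """
    W = np.zeros((4, 4))
    for i, j, w in [(0, 1, .9), (0, 2, .5), (1, 2, .8), (2, 3, .7),
                    (0, 3, .2), (1, 3, .1)]:
        W[i, j] = W[j, i] = w
    return ad.connectivity.ConnectivityGraph(weights=W, kind="ciplv_epoch")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_connected_graph(rng, n, density=0.7):
    """Random symmetric weighted graph guaranteed connected via a ring."""
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                W[i, j] = W[j, i] = rng.uniform(0.05, 1.0)
    for i in range(n):  # ring keeps it connected
        j = (i + 1) % n
        if W[i, j] == 0:
            W[i, j] = W[j, i] = rng.uniform(0.05, 1.0)
    return W
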