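"""Shared fixtures.

Unit tests run on small networks (hundreds of cells) with the reference
nearest-neighbour connectivity, which is fast to build; the acceptance
suite builds desk-scale (2000-cell) networks with the full exploration
pipeline once per session and shares them across tests.
"""

import numpy as np
import pytest

import wavenav as wn


@pytest.fixture(scope="session")
def open_small():
    """Small open arena with reference connectivity (600 cells)."""
    env = wn.make_environment("open")
    pmap = wn.assign_place_fields(env, 600, seed=11)
    W = wn.nearest_neighbor_connectivity(pmap, 0, env=env)
    return env, pmap, W


@pytest.fixture()
def small_net(open_small):
    env, pmap, W = open_small
    net = wn.SpikingNetwork(W, rng=7)
    net.snapshot_baseline()
    return env, pmap, net


def chain_network(n=30, w0=1.0, **neuron_kwargs):
    """1-D chain with reciprocal nearest-neighbour synapses; returns
    (net, positions).  The synaptic jump is raised so a single input can
    relay the activity (the 2-D cooperative threshold does not apply in
    one dimension)."""
    import scipy.sparse as sp

    neuron_kwargs.setdefault("syn_jump", 4.0)

    rows, cols = [], []
    for k in range(n - 1):
        rows += [k + 1, k]
        cols += [k, k + 1]
    W = sp.coo_matrix(
        (np.full(len(rows), w0), (rows, cols)), shape=(n, n)
    ).tocsr()
    net = wn.SpikingNetwork(W, params=wn.NeuronParams(**neuron_kwargs), rng=0)
    net.snapshot_baseline()
    pos = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
    return net, pos


@pytest.fixture()
def chain():
    return chain_network()
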