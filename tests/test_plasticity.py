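import numpy as np
import pytest
import scipy.sparse as sp

import wavenav as wn
from wavenav.network import STDPConfig, pair_kernel
from wavenav.oracles import allpairs_stdp

from conftest import chain_network


@pytest.fixture()
def cfg():
    return STDPConfig()


class TestPairKernel:
    def test_zero_lag_on_causal_branch(self, cfg):
        assert pair_kernel(0.0, cfg) == pytest.approx(cfg.a_plus)

    def test_causal_closed_form(self, cfg):
        assert pair_kernel(-cfg.tau_w, cfg) == pytest.approx(cfg.a_plus / np.e)

    def test_anticausal_closed_form(self, cfg):
        assert pair_kernel(cfg.tau_w, cfg) == pytest.approx(-cfg.a_minus / np.e)

    def test_reverse_polarity_semantics(self, cfg):
        """Under d = -1 a causal pairing weakens the synapse and an
        anti-causal one strengthens it."""
        d = -1
        causal = d * pair_kernel(-0.005, cfg)
        anticausal = d * pair_kernel(+0.005, cfg)
        assert causal == pytest.approx(-cfg.a_plus * np.exp(-0.005 / cfg.tau_w))
        assert causal < 0 < anticausal

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError):
            STDPConfig(a_plus=0.5, a_minus=0.5)
        with pytest.raises(ValueError):
            STDPConfig(tau_w=-1.0)
        with pytest.raises(ValueError):
            STDPConfig(a_decay=+0.1)


class TestOnlineSTDP:
    def test_frozen_during_movement(self, chain):
        """d = 0: weights are bit-identical no matter how much activity."""
        net, pos = chain
        net.set_phase("navigate")
        before = net.W.data.copy()
        rng = np.random.default_rng(0)
        sched = {
            int(s): rng.integers(0, net.n, size=2)
            for s in range(0, 2000, 25)
        }
        net.run(0.5, forced_schedule=sched, spikes_guard=None)
        assert np.array_equal(net.W.data, before)

    def test_decay_without_spikes(self):
        net, _ = chain_network()
        net.stdp = STDPConfig(a_decay=-0.1)
        net._k_w = np.exp(-net.p.dt / net.stdp.tau_w)
        net.set_phase("plan")
        before = net.W.data.copy()
        net.run(0.5)
        assert np.allclose(net.W.data, before - 0.1 * 0.5, atol=1e-9)

    def test_chain_wavefront_asymmetry_and_mirror(self):
        """A front moving right under reverse STDP leaves every
        toward-source (leftward) synapse stronger than its rightward
        partner; mirroring the front mirrors the asymmetry exactly."""
        deltas = {}
        for direction in ("right", "left"):
            net, _ = chain_network(n=30)
            net.set_phase("plan")
            order = range(30) if direction == "right" else range(29, -1, -1)
            sched = {5 * k: np.array([i]) for k, i in enumerate(order)}
            net.run(0.2, forced_schedule=sched, spikes_guard=None)
            deltas[direction] = net.W - sp.csr_matrix(
                (net.W_baseline, net.W.indices, net.W.indptr), shape=net.W.shape
            )
        dr = deltas["right"]
        for k in range(1, 29):
            left = dr[k - 1, k]   # synapse k -> k-1, toward the source
            right = dr[k + 1, k]  # synapse k -> k+1, along the front
            assert left > 0 > right
        dl = deltas["left"]
        asym_r = np.array([dr[k - 1, k] - dr[k + 1, k] for k in range(1, 29)])
        asym_l = np.array([dl[k + 1, k] - dl[k - 1, k] for k in range(1, 29)])
        assert np.allclose(np.sort(asym_r), np.sort(asym_l), rtol=1e-9)

    def test_online_equals_allpairs(self):
        """The trace implementation reproduces the exact all-pairs
        evaluation of the exponential pair rule to 1e-9 relative."""
        rng = np.random.default_rng(42)
        n = 20
        dense = rng.random((n, n)) < 0.3
        np.fill_diagonal(dense, False)
        W = sp.csr_matrix(dense.astype(float))
        net = wn.SpikingNetwork(
            W, stdp=STDPConfig(learning_rate=0.01), rng=1
        )
        net.snapshot_baseline()
        net.set_phase("plan")
        # ~100 spikes honouring the refractory period
        sched = {}
        last = np.full(n, -100)
        for step in range(0, 2500, 5):
            cand = rng.integers(0, n, size=1)
            if step - last[cand[0]] > 12:
                sched[step] = cand
                last[cand[0]] = step
        rec = net.run(0.5, forced_schedule=sched, spikes_guard=None)
        assert len(rec) >= 80
        online = net.W.data - net.W_baseline
        oracle = allpairs_stdp(rec.ids, rec.times, net._mask, net.stdp, d=-1)
        oracle_data = np.asarray(oracle[net._mask.nonzero()]).ravel()
        online_full = sp.csr_matrix(
            (online, net.W.indices, net.W.indptr), shape=W.shape
        )
        online_data = np.asarray(online_full[net._mask.nonzero()]).ravel()
        scale = np.abs(oracle_data).max()
        assert scale > 0
        assert np.max(np.abs(online_data - oracle_data)) < 1e-9 * scale

    def test_single_causal_pair_equals_kernel(self):
        cfg = STDPConfig(learning_rate=1.0)
        W = sp.csr_matrix(np.array([[0.0, 0.0], [1.0, 0.0]]))  # synapse 0 -> 1
        net = wn.SpikingNetwork(W, stdp=cfg, rng=0)
        net.snapshot_baseline()
        net.set_phase("plan")
        lag_steps = 10
        net.run(
            0.02,
            forced_schedule={0: [0], lag_steps: [1]},
            spikes_guard=None,
        )
        lag = lag_steps * net.p.dt
        expected = -1 * cfg.learning_rate * pair_kernel(-lag, cfg)
        assert net.W[1, 0] - 1.0 == pytest.approx(expected, rel=1e-12)

    def test_empty_record_allpairs_is_zero(self, cfg):
        W = sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        out = allpairs_stdp(np.empty(0, int), np.empty(0), W, cfg)
        assert out.nnz == 0 or np.all(out.data == 0)


class TestResetSynapses:
    def test_exact_restore_and_zero_field(self, small_net):
        env, pmap, net = small_net
        res = wn.run_planning(
            net, pmap, wn.TargetSet(locations=[[0.5, 0.5]]), seed=1
        )
        assert not np.array_equal(net.W.data, net.W_baseline)
        net.reset_synapses()
        assert np.array_equal(net.W.data, net.W_baseline)
        field = wn.compute_svf(net.W, pmap, 0, baseline=net.W_baseline)
        assert np.all(field.norms == 0)

    def test_missing_snapshot_rejected(self):
        net, _ = chain_network()
        net.W_baseline = None
        with pytest.raises(RuntimeError):
            net.reset_synapses()

    def test_new_target_after_reset_moves_attractor(self, small_net):
        """Reset then a front from a different target: the attractor
        follows the new target within one grid pitch."""
        env, pmap, net = small_net
        wn.run_planning(net, pmap, wn.TargetSet(locations=[[0.25, 0.25]]), seed=1)
        net.reset_synapses()
        res2 = wn.run_planning(
            net, pmap, wn.TargetSet(locations=[[0.7, 0.75]]), seed=2
        )
        field = wn.compute_svf(net.W, pmap, 0)
        att = wn.svf.locate_attractor(field, net.W)
        assert np.linalg.norm(att - [0.7, 0.75]) < pmap.grid_pitch
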