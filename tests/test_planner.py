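import numpy as np
import pytest

import wavenav as wn
from wavenav.planner import TargetSet, propagate_labels, reward_to_delays


class TestTargetSet:
    def test_rewards_default_equal(self):
        t = TargetSet(locations=[[0.1, 0.1], [0.9, 0.9]])
        assert np.all(t.rewards == 1.0)

    def test_invalid_rewards_rejected(self):
        with pytest.raises(ValueError):
            TargetSet(locations=[[0, 0]], rewards=[-1.0])
        with pytest.raises(ValueError):
            TargetSet(locations=[[0, 0], [1, 1]], rewards=[1.0])


class TestRewardToDelays:
    def test_equal_rewards_zero_delay(self):
        t = TargetSet(locations=[[0, 0], [1, 1]], rewards=[2.0, 2.0],
                      cost_rate=1.0, front_speed=1.0)
        assert np.all(reward_to_delays(t) == 0.0)

    def test_formula(self):
        t = TargetSet(locations=[[0, 0], [1, 1]], rewards=[2.0, 1.0],
                      cost_rate=1.0, front_speed=1.0)
        assert reward_to_delays(t) == pytest.approx([0.0, 1.0])

    def test_ordering_inverse_to_rewards(self):
        t = TargetSet(locations=[[0, 0], [1, 1], [0, 1]],
                      rewards=[3.0, 1.0, 2.0], cost_rate=2.0, front_speed=5.0)
        d = reward_to_delays(t)
        assert d[0] == 0.0
        assert d[2] < d[1]

    def test_invalid_constants_rejected(self):
        t = TargetSet(locations=[[0, 0]], front_speed=None)
        with pytest.raises(ValueError):
            reward_to_delays(t)
        t2 = TargetSet(locations=[[0, 0]], cost_rate=0.0, front_speed=1.0)
        with pytest.raises(ValueError):
            reward_to_delays(t2)


class TestSeeding:
    def test_footprint_cell_count_at_desk_scale(self):
        env = wn.make_environment("open")
        pmap = wn.assign_place_fields(env, 2000, seed=1)
        cells = wn.seed_wavefront(pmap, [0.5, 0.5])
        assert 5 <= len(cells) <= 15

    def test_too_small_footprint_rejected(self, open_small):
        env, pmap, W = open_small
        with pytest.raises(ValueError, match="cooperative"):
            wn.seed_wavefront(pmap, [0.5, 0.5], radius=1e-4)

    def test_seeded_cells_fire_synchronously(self, small_net):
        env, pmap, net = small_net
        res = wn.run_planning(net, pmap, TargetSet(locations=[[0.5, 0.5]]), seed=0)
        seeds = res.seed_cells[0]
        assert np.all(np.isfinite(res.first_spike[seeds]))
        assert np.nanmax(res.first_spike[seeds]) <= 0.002

    def test_single_isolated_cell_cannot_launch_front(self, small_net):
        """One forced spike is below the cooperative threshold: no
        propagation follows."""
        env, pmap, net = small_net
        net.set_phase("plan")
        net.reset_state()
        rec = net.run(0.3, forced_schedule={0: np.array([100])},
                      stop_when_quiet=0.06)
        assert len(rec) <= 3


class TestRunPlanning:
    def test_single_firing_and_coverage(self, small_net):
        env, pmap, net = small_net
        res = wn.run_planning(net, pmap, TargetSet(locations=[[0.5, 0.5]]), seed=0)
        counts = res.record.spike_counts(net.n)
        assert res.coverage >= 0.99
        assert np.sum(counts > 1) == 0

    def test_first_spike_tracks_geodesic_distance(self, small_net):
        env, pmap, net = small_net
        res = wn.run_planning(net, pmap, TargetSet(locations=[[0.5, 0.5]]), seed=0)
        stats = wn.measure_front_speed(res, pmap, net._mask)
        assert stats["pearson_r"] >= 0.95
        assert stats["r2"] >= 0.9
        assert stats["v"] > 0

    def test_agent_position_terminates_early(self, small_net):
        env, pmap, net = small_net
        full = wn.run_planning(net, pmap, TargetSet(locations=[[0.2, 0.2]]), seed=0)
        net.reset_synapses()
        net.reset_state()
        part = wn.run_planning(
            net, pmap, TargetSet(locations=[[0.2, 0.2]]),
            agent_pos=[0.45, 0.45], seed=0,
        )
        assert part.terminated_by_agent
        assert len(part.record) < len(full.record)

    def test_noiseless_run_deterministic(self, small_net):
        env, pmap, net = small_net
        a = wn.run_planning(net, pmap, TargetSet(locations=[[0.5, 0.5]]),
                            noise_rate=0.0, seed=1)
        net.reset_synapses()
        net.reset_state()
        b = wn.run_planning(net, pmap, TargetSet(locations=[[0.5, 0.5]]),
                            noise_rate=0.0, seed=1)
        assert np.array_equal(a.record.ids, b.record.ids)
        assert np.array_equal(a.record.times, b.record.times)

    def test_wall_respect_no_causal_edge_crosses_wall(self):
        """Fronts cannot jump barriers: consecutive-generation spikes are
        linked only through synapses, which the exploration laid out
        along open space."""
        env = wn.make_environment("T")
        pmap = wn.assign_place_fields(env, 600, seed=2)
        W = wn.nearest_neighbor_connectivity(pmap, 0, env=env)
        net = wn.SpikingNetwork(W, rng=1)
        net.snapshot_baseline()
        res = wn.run_planning(net, pmap, TargetSet(locations=[[0.1, 0.85]]), seed=0)
        coo = net._mask.tocoo()
        c = pmap.centers[0]
        ok = env.segments_inside(c[coo.col], c[coo.row])
        assert ok.all()

    def test_injected_noise_count_matches_rate(self, small_net):
        env, pmap, net = small_net
        from wavenav.planner import _noise_schedule

        rng = np.random.default_rng(5)
        rate, T = 10.0, 2.0
        sched = _noise_schedule(net.n, rate, T, net.p.dt, rng)
        total = sum(len(v) for v in sched.values())
        expect = rate * net.n * T
        assert abs(total - expect) < 5 * np.sqrt(expect)

    def test_noise_rate_zero_reproduces_noiseless(self, small_net):
        env, pmap, net = small_net
        a = wn.run_planning(net, pmap, TargetSet(locations=[[0.6, 0.4]]),
                            noise_rate=0.0, seed=3)
        net.reset_synapses()
        net.reset_state()
        b = wn.run_planning(net, pmap, TargetSet(locations=[[0.6, 0.4]]), seed=3)
        assert np.array_equal(a.record.ids, b.record.ids)


class TestLabels:
    def test_labels_partition_matches_voronoi(self, small_net):
        env, pmap, net = small_net
        locs = [[0.2, 0.2], [0.8, 0.8]]
        res = wn.run_planning(net, pmap, TargetSet(locations=locs), seed=0)
        from wavenav.oracles import geodesic_voronoi, nearest_cells

        t0 = nearest_cells(pmap, locs[0])[0]
        t1 = nearest_cells(pmap, locs[1])[0]
        oracle, dist, _ = geodesic_voronoi(net._mask, pmap, [t0, t1])
        fired = np.isfinite(res.first_spike) & (res.labels >= 0)
        agree = np.mean(res.labels[fired] == oracle[fired])
        assert agree >= 0.9

    def test_spurious_root_gets_negative_label(self):
        rec = wn.SpikeRecord()
        rec.append([3], 0.0)   # no labelled ancestry
        import scipy.sparse as sp

        W = sp.csr_matrix((5, 5))
        labels = propagate_labels(rec, W, {0: 0}, 5)
        assert labels[3] == -1
        assert labels[4] == -1  # never fired


class TestSecondFront:
    def test_blocked_then_recovered(self, small_net):
        env, pmap, net = small_net
        short = wn.second_front_blocked(net, pmap, [0.5, 0.5],
                                        gap=0.1 * net.p.tau_ca)
        assert short["first_coverage"] >= 0.99
        assert short["second_coverage"] < 0.10
        net.reset_synapses()
        net.reset_state()
        lng = wn.second_front_blocked(net, pmap, [0.5, 0.5],
                                      gap=5 * net.p.tau_ca)
        assert lng["second_coverage"] >= 0.99
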