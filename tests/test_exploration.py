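import numpy as np
import pytest
import scipy.sparse as sp

import wavenav as wn
from wavenav.exploration import (
    ExplorationConfig,
    accumulate_pairs,
    build_connectivity,
    poisson_field_spikes,
)


@pytest.fixture(scope="module")
def t_env():
    return wn.make_environment("T")


class TestTrajectory:
    def test_billiard_mirror_law(self):
        """Without heading noise the path is straight segments with
        specular bounces: speed is constant and heading only changes at
        walls."""
        env = wn.make_environment("open")
        cfg = ExplorationConfig(duration=20.0, speed=0.5)
        traj = wn.explore_trajectory(env, cfg, seed=3, heading_noise=False,
                                     start=[0.5, 0.5])
        steps = np.diff(traj.pos, axis=0)
        speeds = np.linalg.norm(steps, axis=1) / cfg.dt
        # chord speed equals the walking speed except at bounce steps,
        # where the kink shortens the chord
        assert np.all(speeds <= cfg.speed * 1.02)
        assert np.mean(np.abs(speeds - cfg.speed) < 1e-6 * cfg.speed) > 0.98
        assert env.contains(traj.pos).all()
        # headings take only two distinct |angles| per axis: the initial
        # one and its mirror images -> direction cosines repeat
        straight = np.abs(speeds - cfg.speed) < 1e-6 * cfg.speed
        angles = np.arctan2(steps[straight, 1], steps[straight, 0])
        assert len(np.unique(np.round(np.abs(np.cos(angles)), 6))) <= 2

    def test_heading_decorrelates_over_persistence_length(self):
        env = wn.make_environment("open", side=50.0)  # effectively wall-free
        cfg = ExplorationConfig(duration=400.0, speed=0.5, persistence_length=2.0)
        traj = wn.explore_trajectory(env, cfg, seed=4, start=[25.0, 25.0])
        steps = np.diff(traj.pos, axis=0)
        theta = np.unwrap(np.arctan2(steps[:, 1], steps[:, 0]))
        # autocorrelation of heading: exp(-arc/lp); estimate the 1/e arc
        dirs = np.column_stack([np.cos(theta), np.sin(theta)])
        arc_per_step = cfg.speed * cfg.dt
        for lag_arc in (cfg.persistence_length,):
            lag = int(lag_arc / arc_per_step)
            c = np.mean(np.sum(dirs[:-lag] * dirs[lag:], axis=1))
            assert 0.15 < c < 0.65  # 1/e = 0.37 within estimation noise

    def test_coverage_of_all_arms(self, t_env):
        cfg = ExplorationConfig(duration=300.0)
        traj = wn.explore_trajectory(t_env, cfg, seed=5)
        probes = {"left": (0.08, 0.85), "right": (0.92, 0.85), "stem": (0.5, 0.08)}
        for name, p in probes.items():
            d = np.linalg.norm(traj.pos - np.array(p), axis=1)
            assert d.min() < 0.1, f"arm {name} never visited"

    def test_deterministic_and_start_validation(self, t_env):
        cfg = ExplorationConfig(duration=5.0)
        a = wn.explore_trajectory(t_env, cfg, seed=1)
        b = wn.explore_trajectory(t_env, cfg, seed=1)
        assert np.array_equal(a.pos, b.pos)
        with pytest.raises(ValueError, match="outside"):
            wn.explore_trajectory(t_env, cfg, seed=1, start=[0.05, 0.05])


class TestAccumulatePairs:
    def test_simultaneous_pair_weight_one(self):
        ids = np.array([0, 1])
        times = np.array([1.0, 1.0])
        P = accumulate_pairs(ids, times, 2, tau_e=0.02)
        assert P[1, 0] == pytest.approx(1.0)  # exp(0)

    def test_known_lag_weight(self):
        ids = np.array([0, 1])
        times = np.array([1.0, 1.02])
        P = accumulate_pairs(ids, times, 2, tau_e=0.02)
        assert P[1, 0] == pytest.approx(np.exp(-1.0))
        assert P[0, 1] == 0.0  # no later spike of 0 after 1

    def test_distant_cells_never_pair(self):
        env = wn.make_environment("open")
        pmap = wn.assign_place_fields(env, 400, seed=2)
        cfg = ExplorationConfig(duration=60.0)
        traj = wn.explore_trajectory(env, cfg, seed=2)
        ids, times = poisson_field_spikes(traj, pmap, 0, cfg, seed=2)
        P = accumulate_pairs(ids, times, 400, cfg.tau_e)
        c = pmap.centers[0]
        far = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1) > 0.5
        Pd = P.toarray()
        # pairing strength between far-apart cells is negligible vs near pairs
        assert Pd[far].max() < 0.01 * Pd.max()

    def test_no_spikes_rejected(self):
        with pytest.raises(ValueError):
            accumulate_pairs(np.empty(0, int), np.empty(0), 10, 0.02)


class TestBuildConnectivity:
    def test_m1_chain_connects_nearest(self):
        # pair potentials decaying with 1-D distance
        n = 10
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        P = sp.csr_matrix(np.exp(-d.astype(float)) - np.eye(n))
        W = build_connectivity(P, m=1, w0=2.0)
        for j in range(1, n):
            assert W[j, j - 1] == 2.0 or W[j, j + 1 if j + 1 < n else j - 1] == 2.0
        assert W.nnz == n

    def test_rank_ties_broken_by_index(self):
        P = sp.csr_matrix(np.array([[0, 1.0, 1.0, 1.0], [0, 0, 0, 0],
                                    [0, 0, 0, 0], [0, 0, 0, 0]]))
        W = build_connectivity(P, m=2)
        assert set(W[0].indices) == {1, 2}  # lowest indices win the tie

    def test_incoming_degree_and_uniform_strength(self, t_env):
        pmap = wn.assign_place_fields(t_env, 400, seed=3)
        cfg = ExplorationConfig(duration=240.0, m=6)
        W, _ = wn.explore_and_connect(t_env, pmap, 0, cfg, seed=3)
        deg = np.diff(W.indptr)
        assert np.all(deg <= 6) and np.median(deg) == 6
        assert np.all(W.data == cfg.w0)
        assert W.diagonal().sum() == 0

    def test_selection_insensitive_to_tau_e(self, t_env):
        """Halving the pair-weighting constant changes the selected top-m
        sets by less than 10% on the same spike record."""
        pmap = wn.assign_place_fields(t_env, 400, seed=3)
        cfg = ExplorationConfig(duration=240.0, m=6)
        traj = wn.explore_trajectory(t_env, cfg, seed=3)
        ids, times = poisson_field_spikes(traj, pmap, 0, cfg, seed=3)
        sets = {}
        for tau in (cfg.tau_e, cfg.tau_e / 2):
            P = accumulate_pairs(ids, times, 400, tau)
            W = build_connectivity(P, cfg.m)
            sets[tau] = [
                frozenset(W.indices[W.indptr[j]:W.indptr[j + 1]])
                for j in range(400)
            ]
        a, b = sets.values()
        jac = np.mean([
            len(x & y) / len(x | y) for x, y in zip(a, b) if x | y
        ])
        assert jac > 0.9

    def test_pair_potential_nearly_symmetric(self, t_env):
        """Undirected exploration: P_ji and P_ij agree within 20% for the
        synapses that get selected."""
        pmap = wn.assign_place_fields(t_env, 400, seed=3)
        cfg = ExplorationConfig(duration=480.0, m=6)
        traj = wn.explore_trajectory(t_env, cfg, seed=3)
        ids, times = poisson_field_spikes(traj, pmap, 0, cfg, seed=3)
        P = accumulate_pairs(ids, times, 400, cfg.tau_e)
        W = build_connectivity(P, cfg.m)
        coo = W.tocoo()
        asym = []
        for j, i in zip(coo.row, coo.col):
            pji, pij = P[j, i], P[i, j]
            if pji + pij > 0:
                asym.append(abs(pji - pij) / (pji + pij))
        assert np.median(asym) < 0.2
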