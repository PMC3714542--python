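"""Exploration phase: trajectory, co-activation statistics, connectivity.

A simulated animal wanders through the environment on a noisy straight line
at constant speed, bouncing specularly off walls.  Place cells spike while
the animal crosses their fields; every ordered pre-before-post spike pair
within a synapse accumulates a potential exp(-|dt|/tau_e).  When the
exploration ends, each cell keeps incoming synapses of one common baseline
strength from the m presynaptic partners with the largest accumulated
potential — which, for extensive exploration, is close to connecting each
cell to its m nearest neighbours, except that walls (which the trajectory
cannot cross) are respected.

The spike emission used here is a rate-proportional Poisson process driven
by the Gaussian sensory field.  The pairing statistic only consumes spike
timings and is robust to the details of emission, so the cheap emitter is
the default; the full membrane dynamics add nothing to the selected
synapse sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .environment import Environment, PlaceFieldMap

__all__ = [
    "ExplorationConfig",
    "Trajectory",
    "explore_trajectory",
    "accumulate_pairs",
    "build_connectivity",
    "nearest_neighbor_connectivity",
    "explore_and_connect",
]


@dataclass
class ExplorationConfig:
    speed: float = 0.5              # m/s, constant
    persistence_length: float | None = None  # m; default largest dimension
    duration: float = 2400.0        # s
    dt: float = 0.005               # s, trajectory sampling step
    rate_max: float = 60.0          # Hz, peak place-cell rate at field centre
    tau_e: float = 0.02             # s, pair-weighting time constant
    m: int = 12                     # incoming synapses kept per neuron
    w0: float = 1.0                 # baseline synaptic strength

    def __post_init__(self):
        if self.speed <= 0 or self.duration <= 0:
            raise ValueError("speed and duration must be positive")
        if self.persistence_length is not None and self.persistence_length <= 0:
            raise ValueError("persistence_length must be positive")
        if self.m < 4:
            raise ValueError("m >= 4 needed for two-dimensional propagation")


@dataclass
class Trajectory:
    t: np.ndarray          # (k,)
    pos: np.ndarray        # (k, 2)
    seed: int | None = None

    def __len__(self):
        return len(self.t)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.t, "x": self.pos[:, 0], "y": self.pos[:, 1]}
        )


def explore_trajectory(
    env: Environment,
    cfg: ExplorationConfig,
    seed: int | np.random.Generator = 0,
    start=None,
    heading_noise: bool = True,
) -> Trajectory:
    """Noisy straight-line walk at constant speed with specular bounces.

    The heading diffuses so that its autocorrelation decays over one
    persistence length of arc; with `heading_noise` off the path is a
    perfect billiard trajectory (useful for checking the mirror law).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x0, y0, x1, y1 = env.bounds
    lp = cfg.persistence_length or max(x1 - x0, y1 - y0)

    if start is None:
        for _ in range(1000):
            p = np.array([rng.uniform(x0, x1), rng.uniform(y0, y1)])
            if env.contains(p):
                break
        else:
            raise RuntimeError("could not draw a starting point inside")
    else:
        p = np.asarray(start, dtype=float)
        if not env.contains(p):
            raise ValueError("starting point outside the environment")

    n = int(round(cfg.duration / cfg.dt))
    theta = rng.uniform(0, 2 * np.pi)
    # heading decorrelation rate v/lp => per-step angular sd
    sd = np.sqrt(2.0 * cfg.speed / lp * cfg.dt) if heading_noise else 0.0
    step_len = cfg.speed * cfg.dt

    pos = np.empty((n + 1, 2))
    pos[0] = p
    noise = rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)
    for k in range(n):
        theta += noise[k]
        d = np.array([np.cos(theta), np.sin(theta)]) * step_len
        q = p + d
        if env.contains(q):
            p = q
        else:
            p, u = env.reflect(p, q)
            theta = np.arctan2(u[1], u[0])
        pos[k + 1] = p
    t = np.arange(n + 1) * cfg.dt
    return Trajectory(t=t, pos=pos, seed=seed if isinstance(seed, int) else None)


def poisson_field_spikes(
    traj: Trajectory,
    pmap: PlaceFieldMap,
    env_index: int,
    cfg: ExplorationConfig,
    seed: int | np.random.Generator = 0,
    cutoff_sigmas: float = 3.0,
):
    """Poisson spikes with rate rate_max * exp(-d^2 / 2 sigma^2).

    Returns (neuron_ids, times) sorted by time.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centers = pmap.centers[env_index]
    tree = cKDTree(centers)
    dt = float(traj.t[1] - traj.t[0]) if len(traj) > 1 else cfg.dt

    pairs = tree.query_ball_point(traj.pos, cutoff_sigmas * pmap.sigma)
    lengths = np.fromiter((len(p) for p in pairs), dtype=np.int64, count=len(pairs))
    if lengths.sum() == 0:
        raise RuntimeError("trajectory never enters any place field")
    flat_cells = np.concatenate([np.asarray(p, dtype=np.int64) for p in pairs if p])
    flat_samples = np.repeat(np.arange(len(pairs)), lengths)
    d2 = np.sum((centers[flat_cells] - traj.pos[flat_samples]) ** 2, axis=1)
    rates = cfg.rate_max * np.exp(-d2 / (2.0 * pmap.sigma**2))
    counts = rng.poisson(rates * dt)
    nz = counts > 0
    ids = np.repeat(flat_cells[nz], counts[nz])
    base_t = np.repeat(traj.t[flat_samples[nz]], counts[nz])
    times = base_t + rng.uniform(0.0, dt, size=len(base_t))
    order = np.argsort(times, kind="stable")
    return ids[order], times[order]


def accumulate_pairs(
    spike_ids: np.ndarray,
    spike_times: np.ndarray,
    n_cells: int,
    tau_e: float,
    window_sigmas: float = 5.0,
    chunk: int = 200_000,
) -> sp.csr_matrix:
    """Pairwise synapse potential P[post, pre] = sum exp(-dt / tau_e).

    Every ordered spike pair with the presynaptic spike at most
    `window_sigmas * tau_e` before the postsynaptic one contributes; the
    truncation error of the finite window is below exp(-window_sigmas).
    """
    if len(spike_ids) == 0:
        raise ValueError("no spikes recorded during exploration")
    t = np.asarray(spike_times, dtype=float)
    ids = np.asarray(spike_ids, dtype=np.int64)
    if np.any(np.diff(t) < 0):
        order = np.argsort(t, kind="stable")
        t, ids = t[order], ids[order]
    window = window_sigmas * tau_e
    starts = np.searchsorted(t, t - window, side="left")
    counts = np.arange(len(t)) - starts  # partners strictly before each spike

    P = sp.csr_matrix((n_cells, n_cells))
    lo = 0
    while lo < len(t):
        hi = lo
        tot = 0
        while hi < len(t) and tot + counts[hi] <= chunk:
            tot += counts[hi]
            hi += 1
        hi = max(hi, lo + 1)
        post_idx = np.repeat(np.arange(lo, hi), counts[lo:hi])
        # index of each earlier partner within the window
        offsets = np.concatenate(
            [np.arange(starts[k], k) for k in range(lo, hi)]
        ) if hi > lo else np.empty(0, np.int64)
        if len(offsets):
            w = np.exp(-(t[post_idx] - t[offsets]) / tau_e)
            pre = ids[offsets]
            post = ids[post_idx]
            keep = pre != post
            P = P + sp.coo_matrix(
                (w[keep], (post[keep], pre[keep])), shape=(n_cells, n_cells)
            ).tocsr()
        lo = hi
    return P


def build_connectivity(
    P: sp.spmatrix,
    m: int,
    w0: float = 1.0,
) -> sp.csr_matrix:
    """Keep, for every postsynaptic cell, the m incoming synapses with the
    largest accumulated pair potential, all at the common strength w0.

    Ties at rank m are broken toward the lower presynaptic index.  Cells
    with fewer than m active partners keep what they have.
    """
    P = sp.csr_matrix(P)
    n = P.shape[0]
    rows, cols, vals = [], [], []
    for j in range(n):
        sl = slice(P.indptr[j], P.indptr[j + 1])
        pre = P.indices[sl]
        pot = P.data[sl]
        if len(pre) == 0:
            continue
        # sort by (-potential, index): deterministic tie-break
        order = np.lexsort((pre, -pot))[:m]
        rows.append(np.full(len(order), j, dtype=np.int64))
        cols.append(pre[order])
        vals.append(np.full(len(order), w0))
    if not rows:
        raise ValueError("empty pair potential: no synapses to establish")
    W = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    W.setdiag(0)
    W.eliminate_zeros()
    return W


def nearest_neighbor_connectivity(
    pmap: PlaceFieldMap,
    env_index: int,
    m: int = 12,
    w0: float = 1.0,
    env: Environment | None = None,
) -> sp.csr_matrix:
    """Reference connectivity: each cell receives synapses from its m
    geometrically nearest neighbours whose connecting segment does not
    cross a wall.  This is the structure extensive exploration converges
    to, and serves as its independent check."""
    centers = pmap.centers[env_index]
    n = len(centers)
    tree = cKDTree(centers)
    k = min(n, 4 * m + 1)
    dists, idx = tree.query(centers, k=k)
    rows, cols = [], []
    for j in range(n):
        cand = idx[j][idx[j] != j]
        if env is not None:
            p = np.repeat(centers[j][None, :], len(cand), axis=0)
            ok = env.segments_inside(p, centers[cand])
            cand = cand[ok]
        rows.append(np.full(min(m, len(cand)), j, dtype=np.int64))
        cols.append(cand[:m])
    W = sp.coo_matrix(
        (
            np.full(sum(len(r) for r in rows), w0),
            (np.concatenate(rows), np.concatenate(cols)),
        ),
        shape=(n, n),
    ).tocsr()
    return W


def explore_and_connect(
    env: Environment,
    pmap: PlaceFieldMap,
    env_index: int = 0,
    cfg: ExplorationConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[sp.csr_matrix, Trajectory]:
    """Full exploration pipeline: trajectory -> spikes -> pair potential ->
    top-m baseline connectivity for one environment."""
    cfg = cfg or ExplorationConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    traj = explore_trajectory(env, cfg, rng)
    ids, times = poisson_field_spikes(traj, pmap, env_index, cfg, rng)
    P = accumulate_pairs(ids, times, pmap.n_cells, cfg.tau_e)
    W = build_connectivity(P, cfg.m, cfg.w0)
    return W, traj
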