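"""Independent brute-force oracles for validating emergent behaviour.

The simulator's claims — wavefront arrival times track shortest-path
distance, basins of attraction are geodesic Voronoi cells, the online
plasticity equals the pair-sum rule — are checked against exact
computations on the connectivity graph: Dijkstra geodesics with per-source
offsets, argmin labelling, and an all-pairs evaluation of the STDP window.
Edges are the structural synapses; edge length is the Euclidean distance
between field centres, because the baseline weights are uniform and the
front crosses each link at a common speed.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .environment import PlaceFieldMap
from .network import STDPConfig, pair_kernel

__all__ = [
    "geodesic_distances",
    "descent_directions",
    "geodesic_voronoi",
    "allpairs_stdp",
    "point_geodesic",
    "nearest_cells",
]


def _length_graph(weights: sp.spmatrix, centers: np.ndarray) -> sp.csr_matrix:
    """Directed graph along synapses (pre -> post) with Euclidean edge
    lengths.  weights[j, i] > 0 means an edge i -> j."""
    W = sp.csr_matrix(weights)
    coo = W.tocoo()
    pre, post = coo.col, coo.row
    lengths = np.linalg.norm(centers[post] - centers[pre], axis=1)
    return sp.csr_matrix((lengths, (pre, post)), shape=W.shape)


def geodesic_distances(
    weights: sp.spmatrix,
    pmap: PlaceFieldMap,
    sources,
    env_index: int = 0,
    offsets=None,
    return_predecessors: bool = False,
):
    """Exact single/multi-source shortest-path distances on the synapse
    graph.  `sources` is an array of neuron indices (one row of output
    per source); `offsets` adds a per-source head start (metres), used to
    express reward-dependent wavefront initiation delays as distances.
    Unreachable cells get +inf.
    """
    centers = pmap.centers[env_index]
    G = _length_graph(weights, centers)
    sources = np.atleast_1d(np.asarray(sources, dtype=np.int64))
    out = dijkstra(
        G, directed=True, indices=sources, return_predecessors=return_predecessors
    )
    if return_predecessors:
        dist, pred = out
    else:
        dist, pred = out, None
    if offsets is not None:
        dist = dist + np.asarray(offsets, dtype=float)[:, None]
    return (dist, pred) if return_predecessors else dist


def descent_directions(
    pmap: PlaceFieldMap,
    pred: np.ndarray,
    source_row: int = 0,
    env_index: int = 0,
) -> np.ndarray:
    """Unit vector per cell pointing one graph hop toward the source along
    the shortest path (zero at the source and unreachable cells)."""
    centers = pmap.centers[env_index]
    pred_row = pred[source_row] if pred.ndim == 2 else pred
    dirs = np.zeros_like(centers)
    has = pred_row >= 0
    d = centers[pred_row[has]] - centers[has]
    nrm = np.linalg.norm(d, axis=1)
    nz = nrm > 0
    idx = np.flatnonzero(has)[nz]
    dirs[idx] = d[nz] / nrm[nz, None]
    return dirs


def geodesic_voronoi(
    weights: sp.spmatrix,
    pmap: PlaceFieldMap,
    target_cells,
    offsets=None,
    env_index: int = 0,
):
    """Per-cell nearest-target label: argmin_k (distance_k + offset_k).

    Returns (labels, distances); ties go to the lowest target index and
    are reported in `labels_tied` as a boolean mask.
    """
    dist = geodesic_distances(weights, pmap, target_cells, env_index, offsets)
    labels = np.argmin(dist, axis=0)
    srt = np.sort(dist, axis=0)
    tied = np.isfinite(srt[0]) & (srt[0] == srt[1]) if dist.shape[0] > 1 else np.zeros(
        dist.shape[1], bool
    )
    labels = labels.astype(np.int64)
    labels[~np.isfinite(srt[0])] = -1
    return labels, dist, tied


def allpairs_stdp(
    spike_ids: np.ndarray,
    spike_times: np.ndarray,
    structure: sp.spmatrix,
    cfg: STDPConfig,
    d: int = -1,
) -> sp.csr_matrix:
    """Exact double-sum evaluation of the pair rule over a spike record.

    For every structural synapse (i pre, j post) and every spike pair,
    the signed lag s = t_i - t_j selects one exponential branch; the
    weight change is d * learning_rate * sum of branch values.  Intended
    for small records as the ground truth for the online trace
    implementation (the two are algebraically identical for exponential
    windows).  Does not include the activity-independent decay.
    """
    ids = np.asarray(spike_ids, dtype=np.int64)
    times = np.asarray(spike_times, dtype=float)
    by_neuron: dict[int, np.ndarray] = {}
    for i in np.unique(ids):
        by_neuron[int(i)] = times[ids == i]
    S = sp.csr_matrix(structure)
    coo = S.tocoo()
    data = np.zeros(len(coo.data))
    for k, (j, i) in enumerate(zip(coo.row, coo.col)):
        ti = by_neuron.get(int(i))
        tj = by_neuron.get(int(j))
        if ti is None or tj is None:
            continue
        s = ti[:, None] - tj[None, :]
        data[k] = d * cfg.learning_rate * float(np.sum(pair_kernel(s, cfg)))
    out = sp.coo_matrix((data, (coo.row, coo.col)), shape=S.shape).tocsr()
    return out


def nearest_cells(
    pmap: PlaceFieldMap, point, env_index: int = 0, radius: float | None = None
) -> np.ndarray:
    """Cells whose field centre lies within `radius` (default sigma) of a
    point, nearest first."""
    r = radius if radius is not None else pmap.sigma
    centers = pmap.centers[env_index]
    tree = cKDTree(centers)
    idx = tree.query_ball_point(np.asarray(point, float), r)
    idx = np.asarray(idx, dtype=np.int64)
    if len(idx) == 0:
        return idx
    d = np.linalg.norm(centers[idx] - np.asarray(point), axis=1)
    return idx[np.argsort(d)]


def point_geodesic(
    weights: sp.spmatrix,
    pmap: PlaceFieldMap,
    start,
    goal,
    env_index: int = 0,
) -> float:
    """Geodesic length between two continuous points via the cell graph:
    straight hop to the nearest cell at each end plus the graph geodesic
    between those cells."""
    centers = pmap.centers[env_index]
    s_cells = nearest_cells(pmap, start, env_index, 2 * pmap.sigma)
    g_cells = nearest_cells(pmap, goal, env_index, 2 * pmap.sigma)
    if len(s_cells) == 0 or len(g_cells) == 0:
        raise ValueError("start or goal has no place cells nearby")
    dist = geodesic_distances(weights, pmap, s_cells[:3], env_index)
    best = np.inf
    for r, sc in enumerate(s_cells[:3]):
        ds = np.linalg.norm(centers[sc] - np.asarray(start, float))
        for gc in g_cells[:3]:
            dg = np.linalg.norm(centers[gc] - np.asarray(goal, float))
            best = min(best, ds + dist[r, gc] + dg)
    return float(best)
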