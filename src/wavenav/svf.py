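"""The synaptic vector field (SVF) and its diagnostics.

After a wavefront has passed under reverse STDP, each cell's outgoing
synapses are stronger toward the wavefront source than away from it.  The
per-cell vector

    r_i = sum_j w_ji (x_j - x_i) / sum_j w_ji

(the weight-weighted centroid of cell i's postsynaptic partners, relative
to its own field centre) then points along the planned flow, converging on
the seeded target.  The field is anchored at the field centres of whichever
environment's coordinates are requested; rendering the same weights in a
different environment's coordinates scrambles the directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .environment import PlaceFieldMap

__all__ = ["VectorField", "compute_svf", "svf_diagnostics", "resultant_null", "thin_indices"]


@dataclass
class VectorField:
    anchors: np.ndarray     # (n, 2) field centres
    vectors: np.ndarray     # (n, 2) r_i
    env_index: int = 0

    @property
    def norms(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=1)

    def mean_resultant_length(self, indices=None) -> float:
        """Circular concentration of the vector *directions* (0 = random,
        1 = perfectly aligned); zero vectors are excluded.  `indices`
        restricts to a subset (e.g. a spatially thinned one)."""
        vec = self.vectors if indices is None else self.vectors[indices]
        n = np.linalg.norm(vec, axis=1)
        nz = n > 0
        if not nz.any():
            return 0.0
        units = vec[nz] / n[nz, None]
        return float(np.linalg.norm(units.mean(axis=0)))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "neuron_id": np.arange(len(self.anchors)),
                "x": self.anchors[:, 0],
                "y": self.anchors[:, 1],
                "dx": self.vectors[:, 0],
                "dy": self.vectors[:, 1],
                "env_id": self.env_index,
            }
        )


def compute_svf(
    weights: sp.spmatrix,
    pmap: PlaceFieldMap,
    env_index: int = 0,
    baseline: sp.spmatrix | np.ndarray | None = None,
) -> VectorField:
    """Per-cell synaptic vector field from the weight matrix.

    weights[j, i] is the synapse i -> j; cell i's vector averages over its
    outgoing synapses (column i).  With `baseline` given, the field is
    computed on the rectified weight *change* max(w - w_baseline, 0)
    ("delta mode"), which sharpens the field by discarding the symmetric
    baseline; default is the literal field of the raw weights.  Cells with
    zero total outflow get the zero vector.
    """
    W = sp.csr_matrix(weights, dtype=float)
    if baseline is not None:
        base = baseline.data if sp.issparse(baseline) else np.asarray(baseline)
        W = W.copy()
        W.data = np.maximum(W.data - base, 0.0)
    centers = pmap.centers[env_index]
    Wt = W.T.tocsr()  # row i = outgoing synapses of i
    out_sum = np.asarray(Wt.sum(axis=1)).ravel()
    wx = Wt @ centers[:, 0]
    wy = Wt @ centers[:, 1]
    vec = np.zeros_like(centers)
    nz = out_sum > 0
    vec[nz, 0] = wx[nz] / out_sum[nz] - centers[nz, 0]
    vec[nz, 1] = wy[nz] / out_sum[nz] - centers[nz, 1]
    return VectorField(anchors=centers.copy(), vectors=vec, env_index=env_index)


def alignment_score(
    field: VectorField,
    descent_dirs: np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """Median cosine between the field vectors and reference descent
    directions (unit vectors toward the target along the geodesic), over
    cells selected by `mask` with nonzero vectors.  NaN when no cell
    qualifies (e.g. the zero field)."""
    sel = field.norms > 0
    dn = np.linalg.norm(descent_dirs, axis=1)
    sel &= dn > 0
    if mask is not None:
        sel &= mask
    if not sel.any():
        return float("nan")
    cos = np.einsum("ij,ij->i", field.vectors[sel], descent_dirs[sel]) / (
        field.norms[sel] * dn[sel]
    )
    return float(np.median(cos))


def locate_attractor(field: VectorField, weights: sp.spmatrix, k: int | None = None) -> np.ndarray:
    """Attractor of the field: where the outward synaptic flow collapses.

    A wavefront source fires before all of its neighbours, so reverse
    STDP depresses *every* one of its outgoing synapses; source cells are
    the cells with the smallest mean outgoing weight.  The attractor is
    the centroid of the k lowest-outflow cells (k defaults to roughly the
    seeding-footprint size), which pools out the per-cell jitter.
    """
    W = sp.csr_matrix(weights)
    Wt = W.T.tocsr()
    out_sum = np.asarray(Wt.sum(axis=1)).ravel()
    deg = np.diff(Wt.indptr)
    mean_out = np.where(deg > 0, out_sum / np.maximum(deg, 1), np.inf)
    # low-out-degree boundary cells have noisy averages; keep the well
    # connected majority
    med_deg = np.median(deg[deg > 0])
    mean_out[deg < 0.6 * med_deg] = np.inf
    if k is None:
        k = max(5, len(mean_out) // 250)
    low = np.argsort(mean_out, kind="stable")[:k]
    return field.anchors[low].mean(axis=0)


def svf_diagnostics(
    field: VectorField,
    weights: sp.spmatrix,
    descent_dirs: np.ndarray | None = None,
    interior_mask: np.ndarray | None = None,
) -> dict:
    """Summary report: median-cosine alignment (when reference directions
    are supplied), attractor location, and mean resultant length."""
    rep = {
        "mean_resultant_length": field.mean_resultant_length(),
        "n_zero_vectors": int(np.sum(field.norms == 0)),
        "attractor": locate_attractor(field, weights).tolist(),
    }
    if descent_dirs is not None:
        rep["alignment"] = alignment_score(field, descent_dirs, interior_mask)
        if np.isnan(rep["alignment"]):
            rep["alignment_defined"] = False
    return rep


def thin_indices(
    anchors: np.ndarray,
    spacing: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Greedy spatially-thinned subset: no two kept anchors closer than
    `spacing`.  Cells further apart than the receptive-field footprint
    share no synaptic partners, so their field vectors are effectively
    independent — the subset on which direction statistics are valid."""
    from scipy.spatial import cKDTree

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.permutation(len(anchors))
    tree = cKDTree(anchors)
    taken = np.zeros(len(anchors), dtype=bool)
    blocked = np.zeros(len(anchors), dtype=bool)
    for i in order:
        if blocked[i]:
            continue
        taken[i] = True
        blocked[tree.query_ball_point(anchors[i], spacing)] = True
    return np.flatnonzero(taken)


def resultant_null(
    field: VectorField,
    indices: np.ndarray | None = None,
    n_perm: int = 500,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Null distribution of the mean resultant length under isotropy.

    Randomises the direction of every (sub-sampled) vector uniformly on
    the circle, keeping the vector count; the observed statistic sits
    inside this distribution exactly when the directions are
    indistinguishable from random — the state of a field rendered in a
    foreign environment's coordinates.  Pass `indices` from
    :func:`thin_indices` so the compared vectors are decorrelated.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    norms = field.norms if indices is None else field.norms[indices]
    m = int(np.sum(norms > 0))
    if m == 0:
        return np.zeros(n_perm)
    out = np.empty(n_perm)
    for k in range(n_perm):
        th = rng.uniform(0.0, 2 * np.pi, m)
        out[k] = np.hypot(np.cos(th).mean(), np.sin(th).mean())
    return out
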