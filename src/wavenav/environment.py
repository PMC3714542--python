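"""Maze geometry, place-field assignment and sensory drive.

Environments are simple polygons (optionally with holes) in continuous 2-D
metre coordinates, origin at the lower left with y pointing up.  Each place
cell is anchored to a field centre inside the navigable region; the sensory
drive to a cell is an isotropic Gaussian of the agent's distance to that
centre, identical in width and peak for every cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import unary_union

__all__ = [
    "Environment",
    "PlaceFieldMap",
    "make_environment",
    "assign_place_fields",
    "sensory_current",
    "BUILTIN_SHAPES",
]


def _edges_of(poly: Polygon) -> np.ndarray:
    """All boundary edges (outer ring + holes) as an (E, 2, 2) array."""
    rings = [np.asarray(poly.exterior.coords)]
    rings += [np.asarray(r.coords) for r in poly.interiors]
    segs = []
    for ring in rings:
        segs.append(np.stack([ring[:-1], ring[1:]], axis=1))
    return np.concatenate(segs, axis=0)


class Environment:
    """A connected navigable region bounded by polygon walls.

    Parameters
    ----------
    polygon : shapely.Polygon
        Simple polygon (holes allowed) delimiting the navigable region.
    name : str
        Label for reports ("open", "T", "ring", "A", "inf" or custom).
    """

    def __init__(self, polygon: Polygon, name: str = "custom"):
        if isinstance(polygon, shapely.MultiPolygon):
            raise ValueError("navigable region must be connected (got MultiPolygon)")
        if not polygon.is_valid:
            raise ValueError("invalid (e.g. self-intersecting) boundary polygon")
        if polygon.area <= 0:
            raise ValueError("degenerate polygon with zero area")
        self.polygon = polygon
        self.name = name
        self._edges = _edges_of(polygon)  # (E, 2, 2)
        self.prepared = shapely.prepared.prep(polygon)

    # -- queries ---------------------------------------------------------
    @property
    def area(self) -> float:
        return self.polygon.area

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.polygon.bounds

    def contains(self, xy) -> np.ndarray | bool:
        """Point-in-region test; vectorised over an (n, 2) array."""
        xy = np.asarray(xy, dtype=float)
        if xy.ndim == 1:
            return bool(shapely.contains_xy(self.polygon, xy[0], xy[1]))
        return shapely.contains_xy(self.polygon, xy[:, 0], xy[:, 1])

    def segment_inside(self, p, q) -> bool:
        """True when the straight segment p-q stays in the navigable region.

        Used to reject synapses that would tunnel through a wall.
        """
        return self.prepared.contains(LineString([tuple(p), tuple(q)]))

    def segments_inside(self, p: np.ndarray, q: np.ndarray) -> np.ndarray:
        """Vectorised `segment_inside` over (n, 2) endpoint arrays."""
        lines = shapely.linestrings(
            np.stack([np.asarray(p, float), np.asarray(q, float)], axis=1)
        )
        return shapely.contains(self.polygon, lines)

    # -- wall reflection -------------------------------------------------
    def _first_hit(self, p: np.ndarray, d: np.ndarray):
        """First wall crossing along p + t*d for t in (0, 1].

        Returns (t, unit_normal) or (None, None) when no wall is crossed.
        """
        a = self._edges[:, 0]
        e = self._edges[:, 1] - self._edges[:, 0]
        # solve p + t d = a + u e
        denom = d[0] * e[:, 1] - d[1] * e[:, 0]
        ok = np.abs(denom) > 1e-14
        ap = a - p
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (ap[:, 0] * e[:, 1] - ap[:, 1] * e[:, 0]) / denom
            u = (ap[:, 0] * d[1] - ap[:, 1] * d[0]) / denom
        hit = ok & (t > 1e-9) & (t <= 1.0) & (u >= -1e-9) & (u <= 1 + 1e-9)
        if not hit.any():
            return None, None
        idx = np.flatnonzero(hit)
        best = idx[np.argmin(t[idx])]
        n = np.array([e[best, 1], -e[best, 0]])
        n /= np.linalg.norm(n)
        return float(t[best]), n

    def reflect(self, p, q, max_bounces: int = 8):
        """Specular reflection of the displacement p -> q off the walls.

        The motion starts at `p` (inside) and aims at `q`; every wall hit
        mirrors the remaining displacement about the wall (angle of
        incidence = angle of reflection).  Returns the final position and
        the final direction unit vector (or the incoming direction when no
        wall was met).
        """
        p = np.asarray(p, dtype=float).copy()
        d = np.asarray(q, dtype=float) - p
        dist = np.linalg.norm(d)
        if dist == 0:
            return p, np.zeros(2)
        u = d / dist
        for _ in range(max_bounces):
            t, n = self._first_hit(p, d)
            if t is None:
                cand = p + d
                if self.contains(cand):
                    return cand, u
                return p, -u  # numerical corner case: stay put, turn back
            hit = p + (t - 1e-9 / max(np.linalg.norm(d), 1e-12)) * d
            rest = (1.0 - t) * d
            rest = rest - 2.0 * (rest @ n) * n
            u = rest / np.linalg.norm(rest) if np.linalg.norm(rest) > 0 else -u
            p = hit + 1e-9 * u
            d = rest
        return p, u

    def slide(self, p, q):
        """Wall-constrained move used by the agent: cancel the normal
        velocity component at a wall instead of mirroring it."""
        q = np.asarray(q, dtype=float)
        if self.contains(q):
            return q, None
        p = np.asarray(p, dtype=float)
        d = q - p
        t, n = self._first_hit(p, d)
        if t is None:
            return p, None  # outside but no crossing found: do not move
        hit = p + max(t - 1e-6, 0.0) * d
        rest = (1.0 - t) * d
        rest = rest - (rest @ n) * n
        cand = hit + rest
        if self.contains(cand):
            return cand, n
        return hit, n

    def __repr__(self):
        return f"Environment({self.name!r}, area={self.area:.3f})"

    # prepared geometries cannot be pickled; rebuild on load
    def __getstate__(self):
        state = self.__dict__.copy()
        state.pop("prepared", None)
        return state

    def __setstate__(self, state):
        self.__dict__.update(state)
        self.prepared = shapely.prepared.prep(self.polygon)


# ---------------------------------------------------------------------------
# built-in maze fixtures
# ---------------------------------------------------------------------------

def _t_maze(side: float = 1.0, width: float = 0.3) -> Polygon:
    """T-shaped corridor: vertical stem meeting a horizontal top bar
    (one junction, three arm endpoints)."""
    s, w = side, width
    x0 = (s - w) / 2
    y0 = s - w
    return Polygon(
        [
            (x0, 0),
            (x0 + w, 0),
            (x0 + w, y0),
            (s, y0),
            (s, s),
            (0, s),
            (0, y0),
            (x0, y0),
        ]
    )


def _ring_maze(side: float = 1.0, width: float = 0.3) -> Polygon:
    """Square annulus: a single loop with two routes between any two points."""
    s, w = side, width
    outer = [(0, 0), (s, 0), (s, s), (0, s)]
    inner = [(w, w), (w, s - w), (s - w, s - w), (s - w, w)]  # CW hole
    return Polygon(outer, [inner])


def _letter_a_maze(side: float = 1.0, half_width: float = 0.09) -> Polygon:
    """Corridor maze shaped like the letter 'A': two legs and a crossbar
    enclosing one hole."""
    s = side
    strokes = [
        LineString([(0.12 * s, 0.05 * s), (0.5 * s, 0.95 * s)]),
        LineString([(0.88 * s, 0.05 * s), (0.5 * s, 0.95 * s)]),
        LineString([(0.22 * s, 0.38 * s), (0.78 * s, 0.38 * s)]),
    ]
    poly = unary_union([ln.buffer(half_width * s, quad_segs=4) for ln in strokes])
    return poly


def _infinity_maze(side: float = 1.0, half_width: float = 0.085) -> Polygon:
    """Corridor maze shaped like '∞': two adjoining rings, hence two holes."""
    s = side
    c1 = Point(0.28 * s, 0.5 * s).buffer(0.22 * s, quad_segs=12).exterior
    c2 = Point(0.72 * s, 0.5 * s).buffer(0.22 * s, quad_segs=12).exterior
    poly = unary_union(
        [LineString(c1).buffer(half_width * s, quad_segs=4),
         LineString(c2).buffer(half_width * s, quad_segs=4)]
    )
    return poly


BUILTIN_SHAPES = {
    "open": lambda side=1.0: Polygon([(0, 0), (side, 0), (side, side), (0, side)]),
    "T": _t_maze,
    "ring": _ring_maze,
    "A": _letter_a_maze,
    "inf": _infinity_maze,
}


def make_environment(shape_spec, name: str | None = None, **kwargs) -> Environment:
    """Build an :class:`Environment` from a named shape or explicit geometry.

    Parameters
    ----------
    shape_spec : str | shapely.Polygon | sequence
        A built-in name ("open", "T", "ring", "A", "inf"), a shapely
        polygon, or a vertex list ``[outer_ring]`` / ``(outer_ring, holes)``.
    """
    if isinstance(shape_spec, str):
        if shape_spec not in BUILTIN_SHAPES:
            raise ValueError(
                f"unknown shape {shape_spec!r}; options: {sorted(BUILTIN_SHAPES)}"
            )
        poly = BUILTIN_SHAPES[shape_spec](**kwargs)
        return Environment(poly, name or shape_spec)
    if isinstance(shape_spec, Polygon):
        return Environment(shape_spec, name or "custom")
    # vertex list(s)
    if isinstance(shape_spec, tuple) and len(shape_spec) == 2:
        outer, holes = shape_spec
        poly = Polygon(outer, holes)
    else:
        poly = Polygon(shape_spec)
    return Environment(poly, name or "custom")


# ---------------------------------------------------------------------------
# place fields
# ---------------------------------------------------------------------------

@dataclass
class PlaceFieldMap:
    """Per-neuron preferred locations, one set per environment.

    centers[k, i] is the field centre of neuron i in environment k; fields
    have a common Gaussian width `sigma` (m) and peak drive `amplitude`
    (nA).  In the multi-environment case each neuron owns one independent
    centre per environment, so neighbourhood structure is uncorrelated
    across environments.
    """

    centers: np.ndarray            # (n_envs, n_cells, 2)
    sigma: float                   # receptive-field width, metres
    amplitude: float               # peak sensory current, nA
    grid_pitch: float              # metres, spacing used for assignment
    environments: list = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return self.centers.shape[1]

    @property
    def n_envs(self) -> int:
        return self.centers.shape[0]

    def footprint_count(self, env_index: int = 0, radius_factor: float = 2.0) -> float:
        """Mean number of cells whose centres fall within
        ``radius_factor * sigma`` of a centre (the field footprint)."""
        from scipy.spatial import cKDTree

        pts = self.centers[env_index]
        tree = cKDTree(pts)
        counts = tree.query_ball_point(pts, radius_factor * self.sigma,
                                       return_length=True)
        return float(np.mean(counts) - 1)

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for k in range(self.n_envs):
            for i, (x, y) in enumerate(self.centers[k]):
                rows.append((i, k, x, y))
        return pd.DataFrame(rows, columns=["neuron_id", "env_id", "x", "y"])


def _grid_points_inside(env: Environment, pitch: float, margin: float) -> np.ndarray:
    x0, y0, x1, y1 = env.bounds
    xs = np.arange(x0 + pitch / 2, x1, pitch)
    ys = np.arange(y0 + pitch / 2, y1, pitch)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inner = env.polygon.buffer(-margin) if margin > 0 else env.polygon
    if inner.is_empty:
        inner = env.polygon
    keep = shapely.contains_xy(inner, pts[:, 0], pts[:, 1])
    return pts[keep]


def assign_place_fields(
    env: Environment | list[Environment],
    n_cells: int,
    grid_pitch: float | None = None,
    jitter_sd: float | None = None,
    seed: int | np.random.Generator = 0,
    footprint_target: float = 36.0,
    amplitude: float = 20.0,
) -> PlaceFieldMap:
    """Assign field centres on a jittered regular grid, per environment.

    The grid pitch is tuned so the region holds at least `n_cells` grid
    points (surplus points are dropped at random); Gaussian jitter of
    standard deviation `jitter_sd` (default pitch/4) is added and redrawn
    until inside the region.  `sigma` is derived from the pitch so that a
    disc of radius 2*sigma covers about `footprint_target` cells.  With a
    list of environments, every environment receives its own independent
    jittered grid and the neuron -> centre pairing is an independent
    uniformly random permutation, mimicking uncorrelated place-field
    remapping across environments.
    """
    envs = env if isinstance(env, (list, tuple)) else [env]
    rng = np.random.default_rng(seed)

    all_centers = []
    pitches = []
    for e in envs:
        pitch = grid_pitch or float(np.sqrt(e.area / n_cells))
        margin = 0.25 * pitch
        pts = _grid_points_inside(e, pitch, margin)
        if grid_pitch is None:
            # tune the pitch until the region holds the requested count
            shrink = 0
            while len(pts) < n_cells and shrink < 40:
                pitch *= 0.985 * (len(pts) / n_cells) ** 0.5 if len(pts) else 0.9
                pts = _grid_points_inside(e, pitch, margin)
                shrink += 1
        if len(pts) < n_cells:
            raise ValueError(
                f"grid does not fit {n_cells} cells in {e.name!r}; "
                f"achieved {len(pts)}"
            )
        if len(pts) > n_cells:
            keep = rng.choice(len(pts), size=n_cells, replace=False)
            pts = pts[np.sort(keep)]
        jsd = (pitch / 4.0) if jitter_sd is None else jitter_sd
        if jsd > 0:
            out = np.ones(n_cells, dtype=bool)
            jittered = pts.copy()
            for _ in range(100):
                prop = pts[out] + rng.normal(0.0, jsd, size=(out.sum(), 2))
                ok = e.contains(prop)
                idx = np.flatnonzero(out)
                jittered[idx[ok]] = prop[ok]
                out[idx[ok]] = False
                if not out.any():
                    break
            # any still-failing points stay on their grid nodes
            pts = jittered
        # independent neuron -> centre pairing per environment
        perm = rng.permutation(n_cells)
        centers = np.empty_like(pts)
        centers[perm] = pts
        all_centers.append(centers)
        pitches.append(pitch)

    pitch = float(np.mean(pitches))
    sigma = pitch * float(np.sqrt(footprint_target / (4.0 * np.pi)))
    return PlaceFieldMap(
        centers=np.stack(all_centers),
        sigma=sigma,
        amplitude=amplitude,
        grid_pitch=pitch,
        environments=list(envs),
    )


def sensory_current(
    pmap: PlaceFieldMap,
    env_index: int,
    agent_pos,
    amplitude: float | None = None,
    floor: float = 1e-4,
) -> np.ndarray:
    """Per-neuron Gaussian sensory drive (nA) at the agent position.

    i_sens,i = A * exp(-||pos - c_i||^2 / (2 sigma^2)); values below
    `floor * A` are clamped to zero.
    """
    amp = pmap.amplitude if amplitude is None else amplitude
    d2 = np.sum((pmap.centers[env_index] - np.asarray(agent_pos)) ** 2, axis=1)
    cur = amp * np.exp(-d2 / (2.0 * pmap.sigma**2))
    cur[cur < floor * amp] = 0.0
    return cur
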