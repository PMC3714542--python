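"""Diagnostic plots: maze outline, spike raster, vector field, agent path.

All functions draw onto a supplied (or fresh) matplotlib Axes and return
it; callers save or show.  A single arrow scale can be fixed across
figures so fields in different environments are visually comparable.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_environment", "plot_raster", "plot_svf", "plot_trajectory"]


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots(figsize=(5, 5))
    return ax


def plot_environment(env, ax=None, **kwargs):
    """Maze walls (outer boundary and holes) as line plots."""
    ax = _axes(ax)
    kwargs.setdefault("color", "k")
    kwargs.setdefault("lw", 1.5)
    xs, ys = env.polygon.exterior.xy
    ax.plot(xs, ys, **kwargs)
    for ring in env.polygon.interiors:
        xs, ys = ring.xy
        ax.plot(xs, ys, **kwargs)
    ax.set_aspect("equal")
    return ax


def plot_raster(record, ax=None, **kwargs):
    """Spike raster: neuron id against spike time."""
    ax = _axes(ax)
    kwargs.setdefault("s", 2)
    ax.scatter(record.times, record.ids, **kwargs)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("neuron id")
    return ax


def plot_svf(field, env=None, ax=None, arrow_scale=None, **kwargs):
    """Vector field as arrows anchored at the field centres.

    `arrow_scale` is the quiver scale; pass the same value for several
    fields to keep their arrow lengths comparable (the scale used is
    returned via the axes attribute `svf_arrow_scale`).
    """
    ax = _axes(ax)
    if env is not None:
        plot_environment(env, ax=ax)
    if arrow_scale is None:
        typical = np.median(field.norms[field.norms > 0]) or 1.0
        arrow_scale = 30 * typical
    kwargs.setdefault("width", 0.003)
    ax.quiver(
        field.anchors[:, 0], field.anchors[:, 1],
        field.vectors[:, 0], field.vectors[:, 1],
        angles="xy", scale_units="xy", scale=arrow_scale, **kwargs
    )
    ax.svf_arrow_scale = arrow_scale
    ax.set_aspect("equal")
    return ax


def plot_trajectory(traj, env=None, ax=None, **kwargs):
    """Agent path with start (circle) and target (cross) markers."""
    ax = _axes(ax)
    if env is not None:
        plot_environment(env, ax=ax)
    kwargs.setdefault("lw", 1.0)
    ax.plot(traj.pos[:, 0], traj.pos[:, 1], **kwargs)
    ax.plot(*traj.start, "o", color="tab:green", ms=8)
    ax.plot(*traj.target, "x", color="tab:red", ms=10, mew=2)
    ax.set_aspect("equal")
    return ax
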