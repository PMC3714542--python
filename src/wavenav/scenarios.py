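"""Reproducible experiment presets covering the canonical demonstrations:
wavefront propagation and adaptation, vector-field navigation, competing
targets, noise, and dual-environment operation.

Each scenario executes the full pipeline (explore -> plan -> navigate as
required), writes its artifacts (spike raster, vector field, trajectories,
planning report, manifest with the config hash) into the output directory,
and returns the headline numbers as a dict.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .config import RunConfig, derive_seeds, validate_config
from .environment import assign_place_fields, make_environment
from .exploration import explore_and_connect
from .navigation import AgentParams, navigate
from .network import SpikingNetwork
from .oracles import descent_directions, geodesic_distances, point_geodesic
from .planner import TargetSet, measure_front_speed, run_planning, second_front_blocked
from .svf import (
    alignment_score,
    compute_svf,
    resultant_null,
    svf_diagnostics,
    thin_indices,
)

__all__ = ["SCENARIOS", "run_scenario", "build_network"]


def build_network(cfg: RunConfig, shapes=None):
    """Shared pipeline head: environments, fields, exploration, network."""
    seeds = derive_seeds(cfg.seed)
    shapes = shapes or [cfg.environment.shape]
    envs = [make_environment(s) for s in shapes]
    pmap = assign_place_fields(
        envs if len(envs) > 1 else envs[0],
        cfg.environment.n_cells,
        cfg.environment.grid_pitch,
        cfg.environment.jitter_sd,
        seed=seeds["fields"],
        footprint_target=cfg.environment.footprint_target,
        amplitude=cfg.environment.amplitude,
    )
    rng = np.random.default_rng(seeds["explore"])
    W = None
    for k in range(len(envs)):
        Wk, _ = explore_and_connect(envs[k], pmap, k, cfg.exploration, rng)
        W = Wk if W is None else W.maximum(Wk)
    net = SpikingNetwork(
        W,
        params=cfg.neuron,
        inhibition=cfg.inhibition,
        stdp=cfg.stdp,
        rng=np.random.default_rng(seeds["plan"]),
    )
    net.snapshot_baseline()
    return envs, pmap, net, seeds


def _writer(outdir):
    out = Path(outdir) if outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    def write(name, obj):
        if out is None:
            return
        path = out / name
        if name.endswith(".json"):
            path.write_text(json.dumps(obj, indent=2, default=float))
        else:
            obj.to_csv(path, index=False)

    return write


def _plan_report(result, pmap, net, env_index=0):
    stats = measure_front_speed(result, pmap, net._mask, env_index)
    return {
        "coverage": result.coverage,
        "multi_fire": result.multi_fire_count(net.n),
        "n_spikes": len(result.record),
        "delays": list(map(float, result.delays)),
        "basin_cells": result.basin_counts(),
        "front_speed": stats["v"],
        "front_time_distance_r": stats["pearson_r"],
    }


def _fig2(cfg, outdir):
    """Wavefront propagation and adaptation refractoriness in the T maze."""
    write = _writer(outdir)
    envs, pmap, net, seeds = build_network(cfg, ["T"])
    target = [0.15, 0.85]
    res = run_planning(net, pmap, TargetSet(locations=[target]), seed=seeds["plan"])
    report = _plan_report(res, pmap, net)
    block = second_front_blocked(net, pmap, target, gap=0.5 * cfg.neuron.tau_ca)
    report["reblock_coverage_at_half_tau_ca"] = block["second_coverage"]
    write("spikes.csv", res.record.to_dataframe())
    write("planning_report.json", report)
    return report


def _fig3(cfg, outdir):
    """Single-target planning plus navigation in the T maze."""
    write = _writer(outdir)
    envs, pmap, net, seeds = build_network(cfg, ["T"])
    env = envs[0]
    target, start = [0.15, 0.85], [0.5, 0.1]
    res = run_planning(net, pmap, TargetSet(locations=[target]), seed=seeds["plan"])
    field = compute_svf(net.W, pmap, 0)
    dist, pred = geodesic_distances(
        net._mask, pmap, res.seed_cells[0][:1], 0, return_predecessors=True
    )
    report = _plan_report(res, pmap, net)
    report["svf"] = svf_diagnostics(field, net.W, descent_directions(pmap, pred))
    traj = navigate(net, pmap, env, start, target, cfg.agent, seed=seeds["navigate"])
    geo = point_geodesic(net._mask, pmap, start, target)
    report["navigation"] = {
        "outcome": traj.outcome,
        "path_length": traj.path_length,
        "oracle_length": geo,
        "ratio": traj.path_length / geo,
    }
    write("svf.csv", field.to_dataframe())
    write("trajectory.csv", traj.to_dataframe())
    write("planning_report.json", report)
    return report


def _fig4(cfg, outdir):
    """Three competing targets: basins of attraction and path selection."""
    write = _writer(outdir)
    envs, pmap, net, seeds = build_network(cfg, ["open"])
    env = envs[0]
    tset = TargetSet(locations=[[0.2, 0.8], [0.8, 0.75], [0.6, 0.2]])
    res = run_planning(net, pmap, tset, seed=seeds["plan"])
    report = _plan_report(res, pmap, net)
    field = compute_svf(net.W, pmap, 0)
    write("svf.csv", field.to_dataframe())
    import pandas as pd

    write(
        "first_spikes.csv",
        pd.DataFrame(
            {
                "neuron_id": np.arange(net.n),
                "t_first": res.first_spike,
                "source_label": res.labels,
            }
        ),
    )
    write("planning_report.json", report)
    return report


def _fig5(cfg, outdir):
    """Noise injection: spurious wavefronts, with and without supralinear
    summation."""
    write = _writer(outdir)
    envs, pmap, net, seeds = build_network(cfg, ["open"])
    target = [0.5, 0.5]
    rate = 20.0  # forced spikes per neuron per second
    out = {}
    for mode in ("supralinear", "linear"):
        net.reset_synapses()
        net.p.supralinear = mode == "supralinear"
        res = run_planning(
            net, pmap, TargetSet(locations=[target]),
            noise_rate=rate, seed=seeds["plan"],
        )
        spurious = int(np.sum(res.labels == -1))
        out[mode] = {
            "coverage": res.coverage,
            "spurious_cells": spurious,
            "multi_fire": res.multi_fire_count(net.n),
        }
    net.p.supralinear = True
    write("noise_report.json", out)
    return out


def _fig6(cfg, outdir, navigate_too=False):
    """Two environments in one synaptic matrix: planning in one looks like
    noise in the other; optionally navigate in each (fig7)."""
    from dataclasses import replace as _rep

    # dual-map operating point: the union connectivity doubles each
    # cell's in-degree, so the adaptation increment and the tonic drive
    # are raised to keep single-spike fronts and a working bump
    cfg = _rep(
        cfg,
        neuron=_rep(cfg.neuron, di_ca=100.0),
        agent=_rep(cfg.agent, tonic_amp=6.0),
    )
    write = _writer(outdir)
    envs, pmap, net, seeds = build_network(cfg, ["A", "inf"])
    report = {}
    targets = {0: [0.5, 0.8], 1: [0.28, 0.72]}
    starts = {0: [0.2, 0.1], 1: [0.72, 0.72]}
    for k in (0, 1):
        net.reset_synapses()
        res = run_planning(
            net, pmap, TargetSet(locations=[targets[k]]), env_index=k,
            seed=seeds["plan"],
        )
        own = compute_svf(net.W, pmap, k)
        other = compute_svf(net.W, pmap, 1 - k)
        dist, pred = geodesic_distances(
            net._mask, pmap, res.seed_cells[0][:1], k, return_predecessors=True
        )
        idx = thin_indices(other.anchors, 2 * pmap.sigma, seed=1)
        null = resultant_null(other, idx, n_perm=300, seed=2)
        rep = {
            "coverage": res.coverage,
            "alignment_own": alignment_score(
                own, descent_directions(pmap, pred, env_index=k)
            ),
            "resultant_own": own.mean_resultant_length(),
            "resultant_other_thinned": other.mean_resultant_length(idx),
            "isotropy_null_95": float(np.percentile(null, 95)),
        }
        if navigate_too:
            traj = navigate(
                net, pmap, envs[k], starts[k], targets[k], cfg.agent,
                env_index=k, seed=seeds["navigate"],
            )
            rep["navigation_outcome"] = traj.outcome
        report[f"planned_in_{envs[k].name}"] = rep
    write("dualenv_report.json", report)
    return report


def _fig7(cfg, outdir):
    return _fig6(cfg, outdir, navigate_too=True)


def _calibration(cfg, outdir):
    """Open-arena reference run: front speed, kinematics fit and footprint."""
    write = _writer(outdir)
    envs, pmap, net, seeds = build_network(cfg, ["open"])
    res = run_planning(net, pmap, TargetSet(locations=[[0.5, 0.5]]), seed=seeds["plan"])
    stats = measure_front_speed(res, pmap, net._mask)
    report = {
        "front_speed": stats["v"],
        "pearson_r": stats["pearson_r"],
        "r2": stats["r2"],
        "coverage": res.coverage,
        "footprint_mean_cells": pmap.footprint_count(),
        "grid_pitch": pmap.grid_pitch,
        "sigma": pmap.sigma,
    }
    write("calibration.json", report)
    return report


SCENARIOS = {
    "fig2_tmaze": _fig2,
    "fig3_navigation": _fig3,
    "fig4_multitarget": _fig4,
    "fig5_noise": _fig5,
    "fig6_dualenv": _fig6,
    "fig7_dualnav": _fig7,
    "calibration": _calibration,
}


def run_scenario(name, config=None, seed=None, outdir=None) -> dict:
    """Run a named scenario preset; returns the report dict and (when
    `outdir` is given) writes artifacts plus a manifest."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; options {sorted(SCENARIOS)}")
    cfg = validate_config(config or RunConfig())
    if seed is not None:
        cfg.seed = int(seed)
    cfg.scenario = name
    report = SCENARIOS[name](cfg, outdir)
    if outdir:
        manifest = {
            "scenario": name,
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "config": cfg.to_dict(),
            "report": report,
        }
        (Path(outdir) / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=float)
        )
    return report
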