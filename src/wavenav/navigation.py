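"""Navigation phase: spikes steer a point-mass agent along the vector field.

With the plan written into the weights, plasticity is frozen (d = 0) and
the weak global inhibition is re-enabled.  Tonic sensory excitation keeps
the place cells around the agent's location near threshold; the stored
weight asymmetry makes the cells on the target side of the agent fire
sooner and more often, and every spike delivers an impulsive force pulling
the agent toward that cell's field centre:

    F(t) = a_F * sum over spikes of (x_j - x_a)

The agent is a damped point mass; force impulses become velocity kicks,
walls cancel the normal velocity component (sliding contact), and the run
ends when the agent enters the capture radius of the target or times out.
Spike-frequency adaptation retires the cells the agent has just passed, so
fresh cells ahead dominate the force and the motion keeps moving forward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .environment import Environment, PlaceFieldMap, sensory_current
from .network import SpikingNetwork
from .planner import TargetSet

__all__ = [
    "AgentParams",
    "NavTrajectory",
    "spike_force",
    "agent_step",
    "navigate",
    "multi_target_navigate",
]


@dataclass
class AgentParams:
    mass: float = 1.0            # inertia (scalar specialisation of H)
    damping: float = 8.0         # N s/m, linear viscous bias force
    a_f: float = 0.5             # force gain per spike
    max_speed: float | None = None  # m/s; default 20*sigma/s, so one burst
                                 # glide clears the adapted bump (~2 sigma)
    tonic_amp: float = 3.0       # nA, peak of the tonic sensory bump
    nav_noise_sd: float = 1.0    # nA, background current during navigation
    capture_radius: float | None = None  # m, default 2.5 sigma
    max_time: float = 40.0       # s
    stall_window: float = 8.0    # s without spikes -> abort (adaptation
                                 # recovery re-ignites the bump within ~5 s)


@dataclass
class NavTrajectory:
    t: np.ndarray
    pos: np.ndarray
    start: np.ndarray
    target: np.ndarray
    outcome: str                     # "reached" | "timeout" | "stalled"
    n_spikes: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def reached(self) -> bool:
        return self.outcome == "reached"

    @property
    def path_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.pos, axis=0), axis=1)))

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) > 1 else 0.0

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(
            {"t": self.t, "x": self.pos[:, 0], "y": self.pos[:, 1]}
        )
        if self.n_spikes is not None:
            df["n_spikes_this_step"] = self.n_spikes
        return df


def spike_force(spike_ids, pmap: PlaceFieldMap, env_index, agent_pos, a_f) -> np.ndarray:
    """Net force of this step's spikes: a_F * sum (x_j - x_a)."""
    if len(spike_ids) == 0:
        return np.zeros(2)
    centers = pmap.centers[env_index][np.asarray(spike_ids, dtype=np.int64)]
    return a_f * np.sum(centers - np.asarray(agent_pos, float), axis=0)


def agent_step(pos, vel, force, params: AgentParams, dt, env: Environment | None = None):
    """One Euler step of the damped point mass; impulsive forces are
    applied as velocity kicks (impulse / mass).  Wall contact removes the
    normal velocity component so the agent slides along the boundary."""
    vel = vel + force / params.mass                       # impulse per step
    vel = vel * max(0.0, 1.0 - params.damping / params.mass * dt)
    vmax = params.max_speed if params.max_speed is not None else np.inf
    speed = float(np.linalg.norm(vel))
    if speed > vmax:
        vel = vel * (vmax / speed)
    new = pos + vel * dt
    if env is not None:
        new2, normal = env.slide(pos, new)
        if normal is not None:
            vel = vel - (vel @ normal) * normal
        new = new2
        if not env.contains(new):
            raise RuntimeError("agent escaped the environment (wall handling)")
    return new, vel


def navigate(
    net: SpikingNetwork,
    pmap: PlaceFieldMap,
    env: Environment,
    start,
    target,
    params: AgentParams | None = None,
    env_index: int = 0,
    seed: int | np.random.Generator | None = None,
    record_every: int = 25,
) -> NavTrajectory:
    """Drive the agent from `start` toward `target` using the stored field.

    The network keeps whatever dynamical state and weights it has (the
    vector field must already be written); plasticity is off for the whole
    run and the weight matrix is bit-identical before and after.
    """
    params = params or AgentParams()
    if params.max_speed is None:
        params = replace(params, max_speed=20.0 * pmap.sigma)
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    net.set_phase("navigate")
    net.reset_state()
    net.rng = rng
    old_noise = net.p.noise_sd
    net.p.noise_sd = params.nav_noise_sd

    dt = net.p.dt
    capture = params.capture_radius or 2.5 * pmap.sigma
    pos = np.asarray(start, dtype=float).copy()
    vel = np.zeros(2)
    target = np.asarray(target, dtype=float)
    if not env.contains(pos):
        raise ValueError("start position outside the environment")

    n_steps = int(round(params.max_time / dt))
    stall_limit = int(round(params.stall_window / dt))
    ts, ps, ns = [0.0], [pos.copy()], [0]
    outcome = "timeout"
    quiet = 0
    try:
        for k in range(n_steps):
            sens = sensory_current(pmap, env_index, pos, amplitude=params.tonic_amp)
            spikes = net.step(sens)
            quiet = 0 if len(spikes) else quiet + 1
            F = spike_force(spikes, pmap, env_index, pos, params.a_f)
            pos, vel = agent_step(pos, vel, F, params, dt, env)
            if k % record_every == 0 or len(spikes):
                ts.append((k + 1) * dt)
                ps.append(pos.copy())
                ns.append(len(spikes))
            if np.linalg.norm(pos - target) <= capture:
                outcome = "reached"
                break
            if quiet >= stall_limit:
                outcome = "stalled"
                break
    finally:
        net.p.noise_sd = old_noise
    return NavTrajectory(
        t=np.asarray(ts),
        pos=np.asarray(ps),
        start=np.asarray(start, float),
        target=target,
        outcome=outcome,
        n_spikes=np.asarray(ns),
    )


def multi_target_navigate(
    net: SpikingNetwork,
    pmap: PlaceFieldMap,
    env: Environment,
    starts,
    targets: TargetSet,
    params: AgentParams | None = None,
    env_index: int = 0,
    seed: int | np.random.Generator | None = None,
) -> list[NavTrajectory]:
    """Navigate from each start; a run counts as arrived when it enters
    the capture radius of *any* target (the field decides which basin the
    start belongs to).  The reached target's index is stored in
    `meta['target_reached']`."""
    params = params or AgentParams()
    if params.max_speed is None:
        params = replace(params, max_speed=20.0 * pmap.sigma)
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    capture = params.capture_radius or 2.5 * pmap.sigma
    out = []
    for s in np.atleast_2d(np.asarray(starts, dtype=float)):
        traj = _navigate_any(
            net, pmap, env, s, targets, params, env_index, rng, capture
        )
        out.append(traj)
    return out


def _navigate_any(net, pmap, env, start, targets, params, env_index, rng, capture):
    dt = net.p.dt
    net.set_phase("navigate")
    net.reset_state()
    net.rng = rng
    old_noise = net.p.noise_sd
    net.p.noise_sd = params.nav_noise_sd
    pos = np.asarray(start, dtype=float).copy()
    vel = np.zeros(2)
    n_steps = int(round(params.max_time / dt))
    stall_limit = int(round(params.stall_window / dt))
    ts, ps = [0.0], [pos.copy()]
    outcome, reached_idx = "timeout", -1
    quiet = 0
    try:
        for k in range(n_steps):
            sens = sensory_current(pmap, env_index, pos, amplitude=params.tonic_amp)
            spikes = net.step(sens)
            quiet = 0 if len(spikes) else quiet + 1
            F = spike_force(spikes, pmap, env_index, pos, params.a_f)
            pos, vel = agent_step(pos, vel, F, params, dt, env)
            if k % 25 == 0:
                ts.append((k + 1) * dt)
                ps.append(pos.copy())
            d = np.linalg.norm(targets.locations - pos, axis=1)
            if d.min() <= capture:
                outcome, reached_idx = "reached", int(np.argmin(d))
                break
            if quiet >= stall_limit:
                outcome = "stalled"
                break
    finally:
        net.p.noise_sd = old_noise
    return NavTrajectory(
        t=np.asarray(ts),
        pos=np.asarray(ps),
        start=np.asarray(start, float),
        target=targets.locations[reached_idx] if reached_idx >= 0 else targets.locations[0],
        outcome=outcome,
        meta={"target_reached": reached_idx},
    )
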