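"""Planning phase: single-spike wavefronts write the vector field.

A brief suprathreshold current pulse fires the cluster of cells around
each target; with inhibition gated off and reverse STDP active (d = -1)
the resulting front expands at constant speed, each cell firing exactly
once, until the whole reachable network has been traversed (or the front
reaches the agent's own place cells, at which point the field between
agent and target is complete).  Targets with larger rewards launch their
fronts earlier; the initiation delay (R_max - R_k)/(C v) converts the
reward differential into an equivalent path-length handicap, which shifts
the basin boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .environment import PlaceFieldMap
from .network import SpikeRecord, SpikingNetwork
from .oracles import nearest_cells

__all__ = [
    "TargetSet",
    "WavefrontResult",
    "seed_wavefront",
    "reward_to_delays",
    "run_planning",
    "propagate_labels",
    "second_front_blocked",
    "measure_front_speed",
]


@dataclass
class TargetSet:
    """Targets with rewards, plus the reward-to-time conversion constants."""

    locations: np.ndarray           # (k, 2) metres
    rewards: np.ndarray | None = None  # reward units, default all equal
    cost_rate: float = 1.0          # reward units per metre of path
    front_speed: float | None = None  # m/s, measured or configured

    def __post_init__(self):
        self.locations = np.atleast_2d(np.asarray(self.locations, dtype=float))
        if self.rewards is None:
            self.rewards = np.ones(len(self.locations))
        self.rewards = np.asarray(self.rewards, dtype=float)
        if len(self.rewards) != len(self.locations):
            raise ValueError("one reward per target required")
        if (self.rewards <= 0).any():
            raise ValueError("rewards must be positive")

    def __len__(self):
        return len(self.locations)


@dataclass
class WavefrontResult:
    record: SpikeRecord
    first_spike: np.ndarray         # (n,) seconds, NaN if never fired
    labels: np.ndarray              # (n,) winning target index, -1 spurious/none
    seed_cells: list = field(default_factory=list)
    delays: np.ndarray | None = None
    terminated_by_agent: bool = False

    @property
    def coverage(self) -> float:
        return float(np.mean(np.isfinite(self.first_spike)))

    def multi_fire_count(self, n: int) -> int:
        return int(np.sum(self.record.spike_counts(n) > 1))

    def basin_counts(self) -> dict:
        lab, cnt = np.unique(self.labels[self.labels >= 0], return_counts=True)
        return {int(k): int(c) for k, c in zip(lab, cnt)}


def seed_wavefront(
    pmap: PlaceFieldMap,
    target_loc,
    env_index: int = 0,
    radius: float | None = None,
    min_cells: int = 3,
) -> np.ndarray:
    """Cells forming the "exciter" cluster at a target: all field centres
    within `radius` (default sigma) of the target location.  Fewer than
    `min_cells` cannot launch a cooperative front and is an error."""
    cells = nearest_cells(pmap, target_loc, env_index, radius)
    if len(cells) < min_cells:
        raise ValueError(
            f"only {len(cells)} cells in the seeding footprint "
            f"(need >= {min_cells} for cooperative propagation)"
        )
    return cells


def reward_to_delays(targets: TargetSet) -> np.ndarray:
    """Initiation delay per target: (max R - R_k) / (C v).

    The richest target launches at zero; poorer targets wait long enough
    that the head start exactly compensates the reward differential at the
    front speed v."""
    if targets.cost_rate <= 0:
        raise ValueError("cost rate C must be positive")
    v = targets.front_speed
    if v is None or v <= 0:
        raise ValueError("front speed v must be measured or configured > 0")
    return (targets.rewards.max() - targets.rewards) / (targets.cost_rate * v)


def propagate_labels(
    record: SpikeRecord,
    structure: sp.spmatrix,
    seed_labels: dict[int, int],
    n: int,
    window: float = 0.025,
) -> np.ndarray:
    """Causal source attribution of every spike.

    Processing first spikes in time order, a cell inherits the majority
    label among its structural presynaptic cells that fired inside the
    integration window before it (ties to the lower label).  Seeded cells
    carry their target's index; a cell with no labelled presynaptic
    activity in the window starts a new, spurious lineage labelled -1.
    """
    W = sp.csr_matrix(structure)
    labels = np.full(n, -2, dtype=np.int64)  # -2 = never fired
    first = record.first_spike_times(n)
    fired = np.flatnonzero(np.isfinite(first))
    order = fired[np.argsort(first[fired], kind="stable")]
    for i, lab in seed_labels.items():
        labels[i] = lab
    for j in order:
        if labels[j] != -2:
            continue
        sl = slice(W.indptr[j], W.indptr[j + 1])
        pre = W.indices[sl]
        t0 = first[j]
        recent = pre[
            np.isfinite(first[pre])
            & (first[pre] < t0)
            & (first[pre] >= t0 - window)
        ]
        cand = labels[recent]
        cand = cand[cand >= -1]
        if len(cand) == 0:
            labels[j] = -1
            continue
        vals, counts = np.unique(cand, return_counts=True)
        # majority vote; ties prefer a real target lineage over spurious,
        # then the lower target index
        order = np.lexsort((vals, vals < 0, -counts))
        labels[j] = int(vals[order[0]])
    labels[labels == -2] = -1
    never = ~np.isfinite(first)
    labels[never] = -1
    return labels


def _noise_schedule(
    n: int, rate: float, duration: float, dt: float, rng: np.random.Generator
) -> dict[int, np.ndarray]:
    """Poisson-timed forced spikes at uniformly random neurons
    (`rate` in spikes per neuron per second)."""
    if rate <= 0:
        return {}
    n_events = rng.poisson(rate * n * duration)
    steps = rng.integers(0, int(round(duration / dt)), size=n_events)
    cells = rng.integers(0, n, size=n_events)
    sched: dict[int, np.ndarray] = {}
    for s in np.unique(steps):
        sched[int(s)] = cells[steps == s]
    return sched


def run_planning(
    net: SpikingNetwork,
    pmap: PlaceFieldMap,
    targets: TargetSet,
    env_index: int = 0,
    agent_pos=None,
    delays: np.ndarray | None = None,
    noise_rate: float = 0.0,
    seed_amp: float = 60.0,
    seed_pulse: float = 0.001,
    quiescence: float = 0.05,
    max_duration: float = 5.0,
    seed: int | np.random.Generator | None = None,
    label_window: float = 0.025,
    stop_coverage: float | None = None,
) -> WavefrontResult:
    """Run the planning phase from a (possibly reset) baseline network.

    Seeds a wavefront at each target after its initiation delay, with the
    phase controller in "plan" (reverse STDP on, inhibition off).  The run
    ends when the agent's own place cells fire (if `agent_pos` is given)
    or after `quiescence` seconds without a spike once every seed has been
    injected ("whole-map" mode, for charting the full vector field).
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    net.set_phase("plan")
    net.reset_state()
    dt = net.p.dt

    if delays is None:
        delays = (
            reward_to_delays(targets)
            if len(set(targets.rewards.tolist())) > 1
            else np.zeros(len(targets))
        )
    delays = np.asarray(delays, dtype=float)

    seed_cells = [
        seed_wavefront(pmap, loc, env_index) for loc in targets.locations
    ]
    seed_labels = {}
    for k, cells in enumerate(seed_cells):
        for c in cells:
            seed_labels.setdefault(int(c), k)

    # seeding pulse as sensory drive to the footprint cells
    pulse_steps = max(1, int(round(seed_pulse / dt)))
    pulse = {}
    for k, cells in enumerate(seed_cells):
        start = int(round(delays[k] / dt))
        for s in range(start, start + pulse_steps):
            pulse.setdefault(s, []).append(cells)

    def i_sens(t):
        s = int(round(t / dt))
        if s in pulse:
            cur = np.zeros(net.n)
            for cells in pulse[s]:
                cur[cells] = seed_amp
            return cur
        return None

    noise_sched = _noise_schedule(net.n, noise_rate, max_duration, dt, rng)

    agent_cells = (
        nearest_cells(pmap, agent_pos, env_index, pmap.sigma)
        if agent_pos is not None
        else None
    )

    rec = SpikeRecord("wavefront")
    net.record = rec
    quiet = 0
    quiet_limit = int(round(quiescence / dt))
    last_seed_step = max(pulse)
    n_steps = int(round(max_duration / dt))
    fired_mask = np.zeros(net.n, dtype=bool)
    terminated_by_agent = False
    try:
        for k in range(n_steps):
            forced = noise_sched.get(k)
            spikes = net.step(i_sens(net.t), forced)
            if len(spikes) > 0.5 * net.n:
                raise RuntimeError("runaway activity during planning")
            quiet = 0 if len(spikes) else quiet + 1
            if len(spikes):
                fired_mask[spikes] = True
                if agent_cells is not None and fired_mask[agent_cells].any():
                    terminated_by_agent = True
                    break
                if (
                    stop_coverage is not None
                    and fired_mask.mean() >= stop_coverage
                ):
                    break
            if quiet >= quiet_limit and k > last_seed_step:
                break
    finally:
        net.record = None

    first = rec.first_spike_times(net.n)
    labels = propagate_labels(rec, net.W, seed_labels, net.n, label_window)
    return WavefrontResult(
        record=rec,
        first_spike=first,
        labels=labels,
        seed_cells=seed_cells,
        delays=delays,
        terminated_by_agent=terminated_by_agent,
    )


def measure_front_speed(
    result: WavefrontResult,
    pmap: PlaceFieldMap,
    weights: sp.spmatrix,
    env_index: int = 0,
) -> dict:
    """Front speed from the affine fit of first-spike time against the
    geodesic distance from the seed (single-target runs).  Returns the
    speed v (m/s), Pearson r and the fit R^2."""
    from .oracles import geodesic_distances

    seeds = result.seed_cells[0]
    dist = geodesic_distances(weights, pmap, seeds, env_index).min(axis=0)
    ok = np.isfinite(result.first_spike) & np.isfinite(dist)
    t, x = result.first_spike[ok], dist[ok]
    r = float(np.corrcoef(x, t)[0, 1])
    slope, intercept = np.polyfit(x, t, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((t - pred) ** 2))
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    return {
        "v": float(1.0 / slope) if slope > 0 else float("inf"),
        "pearson_r": r,
        "r2": 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan"),
        "n": int(ok.sum()),
    }


def second_front_blocked(
    net: SpikingNetwork,
    pmap: PlaceFieldMap,
    target_loc,
    gap: float,
    env_index: int = 0,
    **plan_kwargs,
) -> dict:
    """Probe adaptation refractoriness: run one front, wait `gap` seconds,
    re-seed at the same target and report the second front's coverage.
    Weights are reset to baseline between fronts so only the adaptation
    current carries history."""
    tset = TargetSet(locations=[target_loc])
    r1 = run_planning(net, pmap, tset, env_index, **plan_kwargs)
    net.advance_quiet(gap)
    net.reset_synapses()
    # second run must not clear the dynamical state: seed directly
    rec = SpikeRecord("wavefront-2")
    dt = net.p.dt
    cells = seed_wavefront(pmap, target_loc, env_index)
    pulse_steps = max(1, int(round(plan_kwargs.get("seed_pulse", 0.001) / dt)))
    amp = plan_kwargs.get("seed_amp", 60.0)
    net.record = rec
    quiet = 0
    quiet_limit = int(round(plan_kwargs.get("quiescence", 0.05) / dt))
    max_steps = int(round(plan_kwargs.get("max_duration", 5.0) / dt))
    try:
        for k in range(max_steps):
            cur = None
            if k < pulse_steps:
                cur = np.zeros(net.n)
                cur[cells] = amp
            spikes = net.step(cur)
            quiet = 0 if len(spikes) else quiet + 1
            if quiet >= quiet_limit and k > pulse_steps:
                break
    finally:
        net.record = None
    cov2 = float(np.mean(np.isfinite(rec.first_spike_times(net.n))))
    return {
        "first_coverage": r1.coverage,
        "second_coverage": cov2,
        "gap": gap,
        "gap_over_tau_ca": gap / net.p.tau_ca,
    }
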