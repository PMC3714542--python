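"""Adaptive leaky integrate-and-fire population with supralinear synaptic
summation, continuous global inhibition and gated spike-timing-dependent
plasticity.

All neurons are excitatory place cells.  Membrane dynamics between spikes:

    tau_m du/dt = -(u - u_r) + R_m (i_sens + i_syn + i_ns - i_inh - i_Ca)
    tau_Ca di_Ca/dt = -i_Ca

A spike is emitted when u crosses the threshold; u is reset and clamped for
an absolute refractory period, and the adaptation current i_Ca is
incremented, producing spike-frequency adaptation that blocks re-firing for
a time set by the increment size.  Synaptic input uses the supralinear
spatial summation

    i_syn = a_syn * tanh(b_syn * N_active) * sum_j w_j i_j

which favours many near-simultaneous weak inputs over a few strong ones, so
isolated spikes do not ignite activity but a coherent wavefront does.
Inhibition is a single continuous population variable driven by every
excitatory spike and gated per behavioural phase.

Internal units: seconds, metres, nA, mV.  Integration is forward Euler at a
fixed 0.2 ms step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

__all__ = [
    "NeuronParams",
    "InhibitionParams",
    "STDPConfig",
    "SpikeRecord",
    "SpikingNetwork",
    "PHASES",
    "supralinear_sum",
]

# behavioural phase -> (STDP polarity d, inhibition gate a_inh)
PHASES = {
    "explore": (+1, 1),
    "plan": (-1, 0),
    "navigate": (0, 1),
}


@dataclass
class NeuronParams:
    """Membrane, adaptation and synapse constants (times in s)."""

    c_m: float = 1.0            # nF
    r_m: float = 20.0           # MOhm  (so R_m * 1 nA = 20 mV)
    u_r: float = 0.0            # mV, rest and reset potential
    threshold: float = 10.0     # mV
    refractory: float = 0.002   # s
    u_min: float = -20.0        # mV, hyperpolarisation floor (reversal-like)
    tau_ca: float = 2.0         # s, adaptation decay
    di_ca: float = 30.0         # nA, adaptation increment per spike
    tau_syn: float = 0.025      # s, synaptic current decay
    syn_jump: float = 0.4       # nA, synaptic current per presynaptic spike
    noise_sd: float = 0.0       # nA, per-step background current i_ns
    a_syn: float = 10.0         # supralinear gain
    b_syn: float = 0.05         # supralinear steepness
    supralinear: bool = True
    linear_gain: float = 1.2    # gain of the plain-sum alternative
    active_floor: float = 0.01  # fraction of syn_jump counting as "active"
    dt: float = 2e-4            # s, Euler step

    @property
    def tau_m(self) -> float:
        """Membrane time constant in seconds (C_m [nF] * R_m [MOhm] = ms)."""
        return self.c_m * self.r_m * 1e-3

    def __post_init__(self):
        if self.threshold <= self.u_r:
            raise ValueError("threshold must exceed the resting potential")
        for name in ("tau_ca", "tau_syn", "refractory", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class InhibitionParams:
    """Continuous global inhibitory population (Dirac-driven current i_e,
    threshold-linear activity, binary gate)."""

    tau_e: float = 0.050        # s, decay of the excitatory drive i_e
    a_e: float = 0.10           # nA added to i_e per excitatory spike
    i_e0: float = 0.5           # nA, firing threshold of the population
    gain: float = 2.0           # nA of feedback per nA of supra-threshold drive


@dataclass
class STDPConfig:
    """Exponential-window pair rule with switchable polarity.

    a_plus scales the branch for pre-before-post lags (s <= 0, boundary
    included); a_minus the opposite branch.  a_plus > a_minus > 0 gives a
    net-potentiating window under d = +1; d = -1 reverses the rule so that
    a passing wavefront strengthens synapses pointing back at its source;
    d = 0 freezes the weights entirely (including the activity-independent
    decay, which would otherwise erode the stored field while it is being
    used).
    """

    a_plus: float = 1.0
    a_minus: float = 0.5
    tau_w: float = 0.020        # s, learning-window constant (both branches)
    learning_rate: float = 0.9  # overall scale of one pairing, in units of w0
    a_decay: float = 0.0        # 1/s, activity-independent drift (<= 0)
    w_min: float = 0.0
    w_max: float = 5.0

    def __post_init__(self):
        if not (self.a_plus > self.a_minus > 0):
            raise ValueError("require a_plus > a_minus > 0")
        if self.tau_w <= 0:
            raise ValueError("tau_w must be positive")
        if self.a_decay > 0:
            raise ValueError("a_decay must be <= 0")


def pair_kernel(s, cfg: STDPConfig):
    """Unit weight change of one spike pair at signed lag s = t_pre - t_post.

    s <= 0 (pre precedes post, boundary included) returns the potentiating
    branch +a_plus * exp(s / tau_w); s > 0 returns the depressing branch
    -a_minus * exp(-s / tau_w).  The full contribution of the pair to the
    synapse is d * learning_rate times this value.
    """
    s = np.asarray(s, dtype=float)
    out = np.where(
        s <= 0,
        cfg.a_plus * np.exp(s / cfg.tau_w),
        -cfg.a_minus * np.exp(-s / cfg.tau_w),
    )
    return out if out.ndim else float(out)


def supralinear_sum(currents, weights, a_syn=10.0, b_syn=0.05):
    """Supralinear spatial summation of one neuron's synaptic inputs.

    i_syn = a_syn * tanh(b_syn * N_active) * sum_j w_j i_j with N_active
    the number of inputs carrying positive current.  Per-input efficacy
    grows with the count of co-active inputs until the tanh saturates.
    """
    currents = np.asarray(currents, dtype=float)
    weights = np.asarray(weights, dtype=float)
    n_active = int(np.count_nonzero(currents > 0))
    return a_syn * np.tanh(b_syn * n_active) * float(weights @ currents)


class SpikeRecord:
    """Event log of one simulation epoch: (neuron_id, spike time)."""

    def __init__(self, epoch: str = ""):
        self.epoch = epoch
        self._ids: list[np.ndarray] = []
        self._times: list[np.ndarray] = []

    def append(self, ids: np.ndarray, t: float):
        if len(ids):
            self._ids.append(np.asarray(ids, dtype=np.int64))
            self._times.append(np.full(len(ids), t))

    @property
    def ids(self) -> np.ndarray:
        return np.concatenate(self._ids) if self._ids else np.empty(0, np.int64)

    @property
    def times(self) -> np.ndarray:
        return np.concatenate(self._times) if self._times else np.empty(0)

    def __len__(self):
        return sum(len(a) for a in self._ids)

    def first_spike_times(self, n: int) -> np.ndarray:
        """Earliest spike time per neuron (NaN where the neuron never fired)."""
        out = np.full(n, np.nan)
        ids, times = self.ids, self.times
        for i, t in zip(ids[::-1], times[::-1]):  # reversed: earlier wins
            out[i] = t
        return out

    def spike_counts(self, n: int) -> np.ndarray:
        return np.bincount(self.ids, minlength=n)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"neuron_id": self.ids, "time_s": self.times})


class SpikingNetwork:
    """The excitatory place-cell network plus its global inhibitory loop.

    Parameters
    ----------
    weights : scipy.sparse matrix, shape (n, n)
        w[j, i] is the synapse strength from presynaptic neuron i to
        postsynaptic neuron j.  The sparsity structure is fixed at
        construction; plasticity only changes values on existing synapses.
    """

    def __init__(
        self,
        weights: sp.spmatrix,
        params: NeuronParams | None = None,
        inhibition: InhibitionParams | None = None,
        stdp: STDPConfig | None = None,
        rng: np.random.Generator | int | None = None,
    ):
        self.p = params or NeuronParams()
        self.inh = inhibition or InhibitionParams()
        self.stdp = stdp or STDPConfig()
        self.rng = (
            rng if isinstance(rng, np.random.Generator)
            else np.random.default_rng(rng)
        )

        # own copy: plasticity must never mutate the caller's matrix
        W = sp.csr_matrix(weights, dtype=float).copy()
        if W.shape[0] != W.shape[1]:
            raise ValueError("weight matrix must be square")
        if (W.data < 0).any():
            raise ValueError("synaptic weights must be non-negative")
        W.eliminate_zeros()
        if W.diagonal().any():
            raise ValueError("self-synapses are not allowed")
        self.n = W.shape[0]
        self.W = W
        self.W_baseline = W.data.copy()
        self._mask = sp.csr_matrix(
            (np.ones_like(W.data), W.indices, W.indptr), shape=W.shape
        )
        # column view of the CSR data array, for presynaptic-side updates
        order = np.argsort(W.indices, kind="stable")
        self._col_order = order
        self._col_ptr = np.searchsorted(W.indices[order], np.arange(self.n + 1))
        self._rows_of_data = np.repeat(
            np.arange(self.n), np.diff(W.indptr)
        )

        # precomputed per-step decay factors
        dt = self.p.dt
        self._k_syn = np.exp(-dt / self.p.tau_syn)
        self._k_ca = np.exp(-dt / self.p.tau_ca)
        self._k_w = np.exp(-dt / self.stdp.tau_w)
        self._k_e = np.exp(-dt / self.inh.tau_e)
        self._refrac_steps = max(1, int(round(self.p.refractory / dt)))

        self.reset_state()
        self.set_phase("plan")
        self.record: SpikeRecord | None = None

    # -- state -----------------------------------------------------------
    def reset_state(self):
        """Zero all dynamical state (not the weights)."""
        n = self.n
        self.u = np.full(n, self.p.u_r)
        self.i_ca = np.zeros(n)
        self.syn_trace = np.zeros(n)       # per presynaptic source
        self.pre_trace = np.zeros(n)       # STDP eligibility, tau_w
        self.post_trace = np.zeros(n)
        self.refrac_left = np.zeros(n, dtype=np.int64)
        self.i_e = 0.0
        self.step_index = 0

    @property
    def t(self) -> float:
        return self.step_index * self.p.dt

    def set_phase(self, phase: str):
        """Map a behavioural phase onto the STDP polarity and the
        inhibition gate: explore (d=+1, gate on), plan (d=-1, gate off),
        navigate (d=0, gate on)."""
        if phase not in PHASES:
            raise ValueError(f"unknown phase {phase!r}")
        self.phase = phase
        self.d, self.gate = PHASES[phase]

    def snapshot_baseline(self):
        """Store the current weights as the reset target."""
        self.W_baseline = self.W.data.copy()

    def reset_synapses(self):
        """Return all synapses to the stored baseline (between planning
        episodes); the synaptic vector field becomes exactly zero again
        when the baseline is the symmetric post-exploration state."""
        if self.W_baseline is None:
            raise RuntimeError("no baseline snapshot available")
        self.W.data[:] = self.W_baseline

    # -- dynamics --------------------------------------------------------
    def i_inh_now(self) -> float:
        a = self.inh.gain * max(self.i_e - self.inh.i_e0, 0.0)
        return self.gate * a

    def _i_syn(self) -> np.ndarray:
        s = self.syn_trace
        lin = self.W @ s
        if not self.p.supralinear:
            return self.p.linear_gain * lin
        active = (s > self.p.active_floor * self.p.syn_jump).astype(float)
        n_active = self._mask @ active
        return self.p.a_syn * np.tanh(self.p.b_syn * n_active) * lin

    def step(self, i_sens=None, forced_spikes=None) -> np.ndarray:
        """Advance one Euler step; returns the indices that spiked.

        forced_spikes : array of neuron indices driven to spike this step
            regardless of membrane state (noise "spike currents" and
            wavefront seeding go through the full spike machinery:
            adaptation increment, synaptic jump, plasticity, inhibition).
        """
        p = self.p
        dt = p.dt
        t = self.t

        # exponential decays
        self.syn_trace *= self._k_syn
        self.i_ca *= self._k_ca
        self.pre_trace *= self._k_w
        self.post_trace *= self._k_w
        self.i_e *= self._k_e

        drive = self._i_syn()
        if i_sens is not None:
            drive = drive + i_sens
        if p.noise_sd > 0:
            drive = drive + self.rng.normal(0.0, p.noise_sd, self.n)
        drive = drive - self.i_inh_now() - self.i_ca

        free = self.refrac_left == 0
        du = (dt / p.tau_m) * (-(self.u - p.u_r) + p.r_m * drive)
        self.u[free] += du[free]
        np.maximum(self.u, p.u_min, out=self.u)
        if not np.isfinite(self.u).all():
            raise FloatingPointError("non-finite membrane potential")

        fired = free & (self.u >= p.threshold)
        if forced_spikes is not None and len(forced_spikes):
            fz = np.zeros(self.n, dtype=bool)
            fz[np.asarray(forced_spikes, dtype=np.int64)] = True
            fired |= fz & free
        spikes = np.flatnonzero(fired)

        if len(spikes):
            self.u[spikes] = p.u_r
            self.refrac_left[spikes] = self._refrac_steps
            self.i_ca[spikes] += p.di_ca
            self.syn_trace[spikes] += p.syn_jump
            self.i_e += self.inh.a_e * len(spikes)
            if self.record is not None:
                self.record.append(spikes, t)
            if self.d != 0:
                self._apply_stdp(spikes)
        if self.d != 0 and self.stdp.a_decay:
            # activity-independent drift, gated off with the pairing term
            # when plasticity is frozen
            np.clip(
                self.W.data + self.stdp.a_decay * dt,
                self.stdp.w_min,
                self.stdp.w_max,
                out=self.W.data,
            )
        self.refrac_left[self.refrac_left > 0] -= 1
        self.step_index += 1
        return spikes

    def _apply_stdp(self, spikes: np.ndarray):
        """Online trace update equivalent to summing the exponential pair
        kernel over all spike pairs.  A lag of exactly zero (same step) is
        assigned to the pre-before-post branch only."""
        c = self.stdp
        data = self.W.data
        scale = self.d * c.learning_rate
        # presynaptic spikes pair with *earlier* postsynaptic spikes
        # (strict s > 0): use post traces before this step's jumps
        for i in spikes:
            pos = self._col_order[self._col_ptr[i]:self._col_ptr[i + 1]]
            if len(pos):
                data[pos] += scale * (-c.a_minus) * self.post_trace[
                    self._rows_of_data[pos]
                ]
        self.pre_trace[spikes] += 1.0
        self.post_trace[spikes] += 1.0
        # postsynaptic spikes pair with pre spikes up to and including now
        indptr, indices = self.W.indptr, self.W.indices
        for j in spikes:
            sl = slice(indptr[j], indptr[j + 1])
            data[sl] += scale * c.a_plus * self.pre_trace[indices[sl]]
        np.clip(data, c.w_min, c.w_max, out=data)

    def run(
        self,
        duration: float,
        i_sens=None,
        forced_schedule=None,
        record: SpikeRecord | None = None,
        stop_when_quiet: float | None = None,
        spikes_guard: float | None = 0.5,
    ) -> SpikeRecord:
        """Run for `duration` seconds of simulated time.

        i_sens : None, array, or callable t -> array.
        forced_schedule : dict step_offset -> array of neuron ids to force.
        stop_when_quiet : stop early after this many seconds without any
            spike (and once all scheduled forcings have happened).
        spikes_guard : abort if a single step fires more than this fraction
            of the population (runaway activity).
        """
        n_steps = int(round(duration / self.p.dt))
        rec = record if record is not None else SpikeRecord(self.phase)
        self.record = rec
        quiet_steps = 0
        quiet_limit = (
            int(round(stop_when_quiet / self.p.dt)) if stop_when_quiet else None
        )
        last_forced = max(forced_schedule) if forced_schedule else -1
        try:
            for k in range(n_steps):
                forced = forced_schedule.get(k) if forced_schedule else None
                sens = i_sens(self.t) if callable(i_sens) else i_sens
                spikes = self.step(sens, forced)
                if spikes_guard and len(spikes) > spikes_guard * self.n:
                    raise RuntimeError(
                        f"runaway activity: {len(spikes)} spikes in one step"
                    )
                quiet_steps = 0 if len(spikes) else quiet_steps + 1
                if (
                    quiet_limit is not None
                    and quiet_steps >= quiet_limit
                    and k > last_forced
                ):
                    break
        finally:
            self.record = None
        return rec

    def advance_quiet(self, duration: float):
        """Fast-forward through an input-free quiescent interval by applying
        the closed-form exponential decays (valid because no spikes can
        occur without drive once activity has ceased)."""
        n_steps = int(round(duration / self.p.dt))
        if n_steps <= 0:
            return
        self.i_ca *= self._k_ca**n_steps
        if n_steps * self.p.dt > 10 * self.p.tau_m:
            # membrane tracks its quasi-steady value under the (slow)
            # adaptation current alone, bounded by the floor
            self.u = np.maximum(
                self.p.u_r - self.p.r_m * self.i_ca, self.p.u_min
            )
        else:
            self.u = self.p.u_r + (self.u - self.p.u_r) * np.exp(
                -n_steps * self.p.dt / self.p.tau_m
            )
        self.syn_trace *= self._k_syn**n_steps
        self.pre_trace *= self._k_w**n_steps
        self.post_trace *= self._k_w**n_steps
        self.i_e *= self._k_e**n_steps
        self.refrac_left = np.maximum(self.refrac_left - n_steps, 0)
        self.step_index += n_steps

    def copy_weights(self) -> sp.csr_matrix:
        return self.W.copy()
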