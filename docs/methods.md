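# Model and methods

This note documents the model equations, the parameter choices and their
rationale, the numerical conventions, and the limits of what the test
suite demonstrates.

## Network model

**Neurons.** All cells are excitatory adaptive leaky integrate-and-fire
units:

    τ_m du/dt = −(u − u_r) + R_m (i_sens + i_syn + i_ns − i_inh − i_Ca)
    τ_Ca di_Ca/dt = −i_Ca

with C_m = 1 nF, R_m = 20 MΩ (τ_m = 20 ms), rest/reset u_r = 0 mV, spike
threshold 10 mV, absolute refractory period 2 ms, and a hyperpolarisation
floor u_min = −20 mV (a reversal-potential-like bound; without it the
adaptation current would drive recently active cells hundreds of mV below
rest, and a re-seeded wavefront would be blocked by membrane charging
time rather than by adaptation).  A spike increments the adaptation
current i_Ca by dI_Ca; i_Ca leaks with τ_Ca (default 2 s, the 1–5 s
regime).  The background current i_ns is zero-mean Gaussian, drawn
per neuron per step; its scale is a per-phase setting (0 during noiseless
planning, 1 nA during navigation, 5 nA available for noise studies).

**Synapses.** A presynaptic spike makes that source's current jump by
`syn_jump` (0.4 nA) and decay with τ_syn = 25 ms.  Per postsynaptic cell,

    i_syn = a_syn · tanh(b_syn · N_active) · Σ_j w_j i_j ,

a_syn = 10, b_syn = 0.05, where N_active counts sources whose current
exceeds 1 % of the jump.  This supralinear spatial summation makes the
per-input efficacy grow with the number of co-active inputs: with the
default weights one or two coincident spikes cannot fire a cell but three
can, which is what lets a coherent front propagate while isolated noise
spikes die out.  A plain linear mode (`supralinear=False`, gain 1.2,
calibrated to the same three-coincidence ignition threshold) exists for
the noise-robustness comparison.

**Inhibition.** One continuous global variable: every excitatory spike
adds a_e to a drive i_e that decays with τ_e; the inhibitory feedback to
all cells is gain·max(i_e − I_e0, 0), gated by the behavioural phase.
It is a stand-in for a fast interneuron population whose only job is to
keep population activity bounded.

**Plasticity.** Pair-based STDP with exponential windows (τ_w = 20 ms):
a pre-before-post pair (lag s ≤ 0, boundary included) contributes
+A⁺·exp(s/τ_w), the opposite ordering −A⁻·exp(−s/τ_w), A⁺ = 1 > A⁻ = 0.5;
the whole rule is multiplied by the polarity d and a learning rate.
Phases map to (d, inhibition gate): explore (+1, on), plan (−1, off),
navigate (0, on).  Under d = −1 (reverse STDP) a passing front therefore
*weakens* synapses pointing along its motion and *strengthens* those
pointing back at its source, which is exactly the orientation that makes
the vector field converge on the seeded target.  The online
implementation keeps one pre- and one post-trace per neuron and is
algebraically identical to the all-pairs double sum for exponential
windows; the brute-force evaluation is retained as a test oracle and the
two agree to 1e-9 relative.  With d = 0 the weights — including the
optional activity-independent decay a ≤ 0 — are frozen exactly: a decay
that kept running while the agent navigates would erase the field it is
using.  Zero-lag pairs are assigned to the pre-before-post branch.

## Pipeline

**Place fields.** Field centres sit on a regular grid (pitch ≈
√(area/n)) with Gaussian jitter (σ_jitter = pitch/4), redrawn until
inside the region.  The receptive-field width is derived from the pitch
so that a 2σ disc covers ≈ 36 cells (the 25–50 band at n = 2000):
σ = pitch·√(36/4π) ≈ 1.7·pitch.  With several environments each neuron
receives one independent centre per environment through a uniformly
random permutation, so neighbourhoods are uncorrelated across
environments.

**Exploration.** The trajectory is a constant-speed (0.5 m/s) persistent
random walk whose heading decorrelates over one maze dimension, with
specular wall bounces.  Cells emit Poisson spikes at
rate_max·exp(−d²/2σ²) (peak 60 Hz).  Every ordered pair of spikes
within a synapse accumulates exp(−Δt/τ_e), τ_e = 20 ms; after the walk,
each cell keeps incoming synapses of one common strength w₀ = 1 from the
m = 12 presynaptic cells with the largest accumulated potential.  The
emitter is rate-based rather than full membrane dynamics because the
statistic consumes only spike timings and is insensitive to the
emission details; a 2400 s walk is used so that the ranking noise of the
pair potential is small enough for the learned sets to overlap the
m-nearest-neighbour reference at Jaccard ≥ 0.8.  Walls are respected
automatically: the walk never co-activates cells on opposite sides of a
barrier closely in time.

m = 12 rather than a smaller out-degree is an operating-point choice: the
front then ignites each cell with ~6 co-active inputs, well above the
3-coincidence threshold, giving clean single-spike fronts whose arrival
time tracks geodesic distance with r ≥ 0.98.  At m = 8 the front runs at
its own ignition threshold and becomes ragged and slow.

**dI_Ca = 30 nA.** The adaptation increment must exceed the largest
synaptic drive a cell can still receive after its refractory period
(~26 nA when all 12 inputs are recently active), otherwise cells fire
twice as the front passes.  It also sets the refractory window for
second fronts: re-seeding is blocked until i_Ca decays below the
front-level drive, i.e. for a time of order τ_Ca·ln(30/6) ≈ 1.6 τ_Ca.

**Planning.** Cells within σ of a target (≈ 9 cells) receive a 1 ms
suprathreshold pulse; with inhibition gated off and d = −1 the front
expands until the agent's own cells fire (plan-to-agent mode) or until
50 ms of silence (whole-map mode).  Multi-target planning seeds each
target after the delay (R_max − R_k)/(C·v); the front speed v is
measured from the affine fit of first-spike time against geodesic
distance, not assumed.  Each cell's basin label is inherited from the
majority label of its presynaptic cells that fired within τ_syn before
it (ties prefer real targets over noise lineages, then the lower target
index); cells with no labelled ancestry start a spurious (−1) lineage —
the unit of the noise analysis.  Noise "spike currents" are forced
threshold crossings with the full spike machinery.

**Learning rate 0.9.** One front passage changes the toward-source
weight to ≈ 1.4 w₀ and the away weight to ≈ 0.2–0.5 w₀ (lag-dependent),
a ~5–10× asymmetry.  This large single-shot change is what makes the
field readable by the navigation bump; clipping at w_min = 0 still never
engages (minimum weight 0.10).  The field is computed from the raw
weights (the literal vector-field expression); a delta mode
(w − w_baseline, rectified) is available and is the field that is
*exactly* zero after `reset_synapses`, since the raw baseline field
carries small nonzero vectors from neighbourhood jitter.

**Navigation.** Tonic Gaussian drive (peak 3 nA ≈ 6× rheobase) keeps the
bump cells near threshold; the asymmetric recurrent input decides which
fire first, and each spike applies an impulse a_F·(x_j − x_a)/mass to a
damped point mass (mass 1, damping 8 s⁻¹, a_F = 0.5).  Adaptation
retires cells after ~one spike, so motion proceeds as a relay: a burst
kicks the agent into fresh territory ahead, whose unadapted cells burst
next.  Two consequences shape the remaining agent parameters:

- a locomotor speed cap of 20σ/s (≈ 0.6–0.7 m/s at desk scale) — part of
  the bias-force term of the motion equation — prevents burst impulses
  from accumulating into target-overshooting speeds, while still letting
  one burst glide clear the ~2σ adapted zone;
- a stalled bump self-heals on the adaptation timescale (i_Ca back below
  drive in ~5 s), so the no-spike abort window is 8 s and temporary
  stalls cost time, not success.

Capture radius is 2.5σ (just beyond the footprint radius, matching the
lateral spread of a passing bump); wall contact removes the
normal velocity component (sliding).  Runs are stochastic by design
(1 nA background noise): distinct seeds give distinct microscopic paths
with the same macroscopic route.

**Dual environments.** Both environments' learned synapses live in one
matrix (union, w₀ each).  The doubled in-degree doubles the maximal
post-refractory drive, so the dual-map presets run at dI_Ca = 100 nA and
tonic 6 nA; all other constants are unchanged.  Fronts then remain
single-spike in the planned environment while appearing as sparse random
activity in the other's coordinates.

## Oracles and statistics

Geodesic distances use Dijkstra on the directed synapse graph with
Euclidean edge lengths (uniform baseline weights make hop cost purely
geometric); basins use argmin over per-target distance + v·delay.
Alignment is the median cosine between field vectors and the one-hop
descent direction of the geodesic, over cells ≥ 2σ from walls.  The
attractor is the centroid of the lowest mean-outgoing-weight cells
(sources have every outgoing synapse depressed), excluding
low-out-degree boundary cells.  Directional randomness of a field
rendered in a foreign environment's coordinates is tested against an
isotropy null: vectors on a 2σ-thinned subset (so they share no
synaptic partners) are compared with the resultant length of uniformly
re-oriented vectors — a Rayleigh-type test.  Anchor-permutation nulls
were rejected: permuting anchors makes every vector point at the global
centroid, a radial field whose resultant is biased low, and such a null
fails fields that are statistically indistinguishable from isotropic.

## Numerical conventions

Euler integration, dt = 0.2 ms everywhere; spike times are the step of
threshold crossing (no sub-step interpolation; safe against the 2 ms
refractory period).  Quiescent gaps are fast-forwarded with the exact
exponential decays, with the membrane set to its quasi-steady value
u_r − R_m·i_Ca for gaps ≫ τ_m.  Halving dt moves seeded-front spike
times by well under 0.5 ms.  Connection selection ties at rank m break
toward the lower presynaptic index; all pipelines are deterministic
given their seed, with per-stage seeds derived from one master seed.

## What the tests do and do not show

The synthetic environments exercise the mechanisms — single-spike
fronts, reverse-STDP field writing, multi-goal arbitration, crosstalk
between stored maps — under idealised conditions: place fields are
isotropic Gaussians of identical width on a near-uniform grid, sensory
drive bleeds through walls (only the learned connectivity respects
barriers), rewards map to initiation delays by a fixed formula rather
than being learned, and the motor plant is a point mass.  Passing tests
therefore demonstrate the computational mechanism, not performance on
real rodent data or real robots.  Known limitations: navigation is
stochastic with a heavy tail (a few runs per hundred stall near walls
and recover slowly); the dual-map regime needs its own adaptation
operating point; and with more than ~2 stored environments the crosstalk
analysis here makes no claims.
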