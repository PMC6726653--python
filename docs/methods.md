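# Methods

## Model and integration

The network is a conductance-based leaky integrate-and-fire model with two
populations (N_E = 10000 excitatory, N_I = 2000 inhibitory by default).
Synaptic input is a single-exponential conductance (decay τ_s = 2 ms) that
multiplies the driving force toward the excitatory (0 mV) or inhibitory
(-80 mV) reversal potential. All state variables are advanced by the
forward Euler method at Δt = 0.1 ms, evaluating every derivative at the
state at the start of the step (standard simultaneous Euler). The update
order within a step is:

1. delayed synaptic impulses due this step are added to the target
   conductances;
2. the membrane equation is integrated and the conductances decay;
3. external trigger kicks are applied;
4. threshold crossings emit spikes, reset v to V_r and enqueue one delayed
   impulse per outgoing synapse.

A transmission delay of 0 ms therefore acts on the next step — a spike can
never influence the step in which it was emitted. During the 1 ms
refractory period the membrane is held at V_r and skipped by the
integrator while conductances keep decaying and accumulating input; a
neuron can fire again at the earliest one refractory period after its last
spike. Initial conditions are v = V_L and g = 0 everywhere. The simulator
aborts with a diagnostic (step and neuron index) if the state becomes
non-finite.

The choice of simultaneous Euler (rather than updating the conductance
first and integrating the membrane with the decayed value) is load-bearing
for the weight calibration: with it, the measured peak-EPSP/G_E slope over
the physiological amplitude range is ~99, matching the linear conversion
G_E = V_EPSP/100 the wiring uses to ~1%; the sequential variant gives ~94.5.

## Calibration of the EPSP-to-conductance conversion

A single impulse g_E(0+) = G_E applied to a resting neuron produces a peak
depolarization. In the small-signal limit the closed form of the
double-exponential response gives a peak of 108.3 mV per unit G_E at the
excitatory parameters (τ_m = 20 ms, τ_s = 2 ms, 70 mV driving force); with
increasing amplitude the depolarization erodes its own driving force, so
the through-origin least-squares slope over a grid whose peaks reach
~14 mV comes out at ~99. The network builder uses the literal factor 100;
`calibrate_conversion` is a verification tool and an override source, not a
silent replacement. The grid default is G_E ∈ [0.005, 0.15] (30 points),
and the maximum relative deviation from linearity over that grid (~10%) is
reported rather than hidden.

## Wiring

The 0.1·N_E² excitatory-to-excitatory EPSP amplitudes are drawn from a
log-normal with σ = 1.0 and μ = log 0.2 + σ² (density mode 0.2 mV); draws
above 15 mV are rejected and redrawn, so the distribution is truncated,
not clipped. Amplitudes above 9 mV define strong synapses (≈0.2% of
draws, ~20500 synapses at full size). Strong synapses are wired as a
directed ring lattice (offsets assigned in rounds; a partial last round
fills from node 0) rewired edge-by-edge with probability β; weak synapses
use the same procedure at β = 1, which is a random network with the
lattice's out-degrees. Rewiring replaces only the target of an edge,
resampling uniformly until the proposal is neither a self-loop nor a
duplicate (pre, post) pair within its synapse class; duplicates across
classes are permitted (conductances add). Amplitudes are assigned to the
edges of their class by a uniform random permutation. E→I, I→E and I→I
connections are independent Bernoulli wirings (probabilities 0.1, 0.5,
0.5) with fixed weights 0.018, 0.002, 0.0025. Delays are uniform (1–3 ms
for E→E, 0–2 ms otherwise), rounded to the Δt grid. Six named RNG streams
(amplitudes, strong topology, weak topology, delays, Bernoulli wiring,
assignment), all derived from one master seed under a domain key disjoint
from the simulator's, make the build bit-reproducible and each component
independently so.

The batch rewiring resolves collisions iteratively: all selected edges
propose targets at once, proposals colliding with fixed edges or with an
earlier proposal are redrawn. This is deterministic given the generator
and equivalent in distribution to sequential resampling.

## External trigger

The trigger signal is a per-neuron Poisson train of instantaneous kicks
A_s = V_thr - V_L + 1 = 21 mV during the first 100 ms, so each kick fires
a resting neuron. The Poisson rate Λ is a free parameter of the drive with
default 5 Hz per excitatory neuron (≈5000 ignition spikes); because every
kick forces a spike and the network then settles into its self-sustained
attractor, the post-trigger statistics are insensitive to Λ over a wide
range. Kicks target the excitatory population by default (configurable to
all neurons) and are skipped for refractory neurons.

## Analysis conventions

- **Population rate**: spikes per Δt bin, scaled to Hz per neuron
  (10³·S/(Δt·N)); the counting identity sum(rate)·Δt·N/10³ = total spikes
  holds exactly. Smoothing is a unit-area Gaussian kernel, width 10 ms
  read as σ (an FWHM reading is available), truncated at ±4σ, reflective
  boundaries.
- **Activate period**: fraction of bins with r_E above θ; θ is not fixed
  by the source material, default 10 Hz (above the baseline rate of the
  irregular regime, below burst peaks).
- **Multiscale entropy**: sample entropy h = -log(C_{m+1}/C_m) with m = 2
  and absolute tolerance r = 1.0 (never rescaled by the SD — rescaling the
  series changes h, and a test asserts that). Both template sets use the
  N - m start points (Richman–Moorman convention), Chebyshev distance,
  strict inequality, self-matches excluded, no Theiler window. The input
  is the smoothed excitatory rate block-averaged to 1 ms bins over
  [500, 9500] ms, then coarse-grained by non-overlapping block means at
  scale factors 1…300 (≥30 points remain at τ = 300). Undefined entropies
  (no template matches) are NaN sentinels, excluded from across-trial
  aggregates.
- **Surrogates**: IAAFT (impose amplitude spectrum, restore value multiset
  by rank ordering; 50 iterations; the returned iterate is value-exact).
  Per trial the surrogate entropy at each scale is the mean over 10
  surrogates, and original vs surrogate profiles are compared by a paired
  t-test across trials at each scale (two-tailed flags at 10⁻² and 10⁻³,
  no multiple-testing correction across scales; per-surrogate pairing is
  available behind a flag).
- **Topology**: all graph metrics binarize and symmetrize the directed
  synapses. C_i is the triangle count through node i (diag(A³)/2), the
  average clustering coefficient takes 2C_i/(k_i(k_i-1)) as 0 for degree
  < 2, and the characteristic path length averages BFS distances over
  reachable ordered pairs, excluding (and counting) unreachable pairs —
  at small β the strong network is a sparse ring whose giant component
  dominates, and infinite distances would make the mean undefined. β
  sweeps rebuild the network from the same seed so only the rewiring draw
  varies, and normalize by the β = 0 lattice.

## Performance

Synapses are grouped per presynaptic neuron into a CSR incidence
structure; delivery of one spike is a flat loop (numba-compiled, with a
pure-numpy fallback of identical semantics) over its outgoing synapses
into a circular (delay-slot × neuron) buffer of pending conductance
increments. A full-size 10 s run costs ~1-2 minutes on one CPU; wiring the
10⁷-synapse network costs ~30 s, dominated by the duplicate-free rewiring
of the weak class.

## What the simulations show — and what they do not

At full size the model self-sustains irregular low-rate activity after the
trigger: at β = 1.0 (strong network random) r_E ≈ 1.8 Hz, r_I ≈ 16 Hz with
E-I rate correlation ≈ 0.99; at β = 0.2 (strong network near the lattice)
rates roughly double, the activity intermittently enters high-rate
"activate periods", and the multiscale-entropy profile develops structure
at large scale factors that is absent at β = 1.0. These β trends — more
clustering, more activate periods, more slow-time-scale complexity at low
β, with CC(0.2)/CC(0) ≈ 0.52 and PL(β)/PL(0) ≈ 0 across 0.2 ≤ β ≤ 1 — are
the robust, reproducible content of the model.

The absolute activity level is less robust. The self-sustained attractor
sits near a fluctuation-driven balance and reported rates for this
parameter set in the literature range over a factor of a few; our
implementation lands at the low end (1.8 Hz excitatory at β = 1.0), and
because the entropy tolerance r = 1.0 Hz is absolute, the β = 1.0 rate
fluctuations (SD ≈ 0.09 Hz after smoothing) fall below it, collapsing the
β = 1.0 entropy profile toward zero. Quantities that are ratios,
correlations or trends are insensitive to this; quantities pinned to an
absolute rate or entropy level are not, and should be read with that
caveat.

## Scaled-down networks

`make_fixture(scale)` shrinks both populations while keeping every
density, distribution and threshold. Two finite-size effects follow.
First, clustering in the strong subnetwork requires at least two full
lattice rounds (strong count ≥ 2·N_E), which the 9 mV threshold only
provides near full size; tests of the clustering machinery at small N
lower the threshold instead. Second, the spontaneous low-rate regime
itself is a full-scale property: per-neuron input counts scale with N, so
at one-tenth scale the inhibitory population (which needs ~10× more
excitatory drive to reach threshold) stays silent while the excitatory
runaway attractor remains reachable, and the reduced network either dies
out or saturates at the refractory-limited rate (~830 Hz). Reduced-scale
simulations are therefore smoke tests of the machinery, not quantitative
stand-ins for the full model, and passing them says nothing about
spontaneous-activity statistics at full size.

## Known limitations

- No synaptic plasticity, no exact event-time integration, no alternative
  weight distributions or topologies beyond the configuration ranges.
- The rewiring duplicate-avoidance is per class; a strong and a weak
  synapse may share an ordered pair.
- The sample-entropy template definition follows the standard
  Richman–Moorman convention; sources that build m+1-element vectors for
  C_m differ by an index convention at the series tail.
- The characteristic path length convention (unreachable pairs excluded)
  is one of several in use; it is documented and the excluded-pair count
  is always reported alongside.
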