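"""Euler-integrated simulation of the conductance-based LIF network.

Per time step (dt, default 0.1 ms):

1. deliver delayed synaptic impulses due this step (each E->E transmission
   fails independently with its synapse's failure probability);
2. Euler-update the membrane potential and conductances of non-refractory
   neurons, evaluating all derivatives at the state at the start of the step;
3. apply external Poisson trigger kicks of size A_s (only inside the trigger
   window, excitatory population by default);
4. neurons at or above threshold emit a spike, reset to V_r, start their
   refractory period, and enqueue one delayed impulse per outgoing synapse.

During refractoriness the membrane is held at V_r while conductances keep
decaying and accumulating input.  Synapses are grouped per presynaptic neuron
into a CSR incidence structure so delivery is a flat loop over the outgoing
synapses of the neurons that spiked.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np

from .network import SynapseTable

try:  # pragma: no cover - numba is an optional accelerator
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = ["SimulationConfig", "SpikeRaster", "run", "deliver_spike"]


@dataclass
class SimulationConfig:
    """Integration, neuron and external-drive parameters.

    ``A_s`` defaults to V_thr - V_L + 1 (= 21 mV), so a single external kick
    fires a neuron from rest.  ``lambda_ext`` is the Poisson rate (Hz) of
    trigger kicks per targeted neuron inside ``trigger_window``.
    """

    dt: float = 0.1                 # ms
    duration: float = 10000.0       # ms
    refractory: float = 1.0         # ms
    V_L: float = -70.0              # mV
    V_E: float = 0.0                # mV
    V_I: float = -80.0              # mV
    V_r: float = -60.0              # mV
    V_thr: float = -50.0            # mV
    tau_m_E: float = 20.0           # ms
    tau_m_I: float = 10.0           # ms
    tau_s: float = 2.0              # ms
    A_s: float | None = None        # mV, default V_thr - V_L + 1
    lambda_ext: float = 5.0         # Hz per neuron, trigger drive
    trigger_window: tuple[float, float] = (0.0, 100.0)  # ms
    kick_population: str = "E"      # "E" or "all"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.A_s is None:
            self.A_s = self.V_thr - self.V_L + 1.0
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (self.V_I < self.V_L < self.V_r < self.V_thr < self.V_E):
            raise ValueError("require V_I < V_L < V_r < V_thr < V_E")
        if self.refractory < self.dt:
            raise ValueError("refractory period must be at least dt")
        if self.kick_population not in ("E", "all"):
            raise ValueError("kick_population must be 'E' or 'all'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["trigger_window"] = list(d["trigger_window"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "trigger_window" in d:
            d["trigger_window"] = tuple(d["trigger_window"])
        return cls(**d)


@dataclass
class SpikeRaster:
    """Spike events of one run: (time, neuron id) pairs plus provenance."""

    times: np.ndarray           # ms, on the dt grid, ascending
    ids: np.ndarray             # int32 neuron indices
    n_E: int
    n_I: int
    dt: float
    duration: float
    seed: int
    config: SimulationConfig | None = None
    counters: dict = field(default_factory=dict)
    traces: dict | None = None

    def __len__(self) -> int:
        return self.times.size

    def population_events(self, population: str) -> tuple[np.ndarray, np.ndarray]:
        """Times and ids of one population ('E' or 'I')."""
        if population == "E":
            m = self.ids < self.n_E
        elif population == "I":
            m = self.ids >= self.n_E
        else:
            raise ValueError(f"unknown population {population!r}")
        return self.times[m], self.ids[m]

    def per_neuron_rate(self, window: tuple[float, float] | None = None) -> np.ndarray:
        """Mean firing rate (Hz) of every neuron over ``window`` ms."""
        lo, hi = window if window is not None else (0.0, self.duration)
        m = (self.times >= lo) & (self.times < hi)
        counts = np.bincount(self.ids[m], minlength=self.n_E + self.n_I)
        return counts * 1e3 / (hi - lo)


def deliver_spike(p_fail: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent Bernoulli transmission over one spike's outgoing synapses.

    Returns the boolean delivered mask (True = the impulse reaches its
    target); entry j fails with probability ``p_fail[j]``.
    """
    p_fail = np.asarray(p_fail, dtype=float)
    return rng.random(p_fail.size) >= p_fail


if _HAVE_NUMBA:

    @njit(cache=True)
    def _deliver_fail(spikers, indptr, posts, ws, dsteps, pfail, u, buf, t, D):
        delivered = 0
        k = 0
        for si in range(spikers.size):
            i = spikers[si]
            for s in range(indptr[i], indptr[i + 1]):
                if u[k] >= pfail[s]:
                    buf[(t + dsteps[s]) % D, posts[s]] += ws[s]
                    delivered += 1
                k += 1
        return delivered

    @njit(cache=True)
    def _deliver_all(spikers, indptr, posts, ws, dsteps, buf, t, D):
        delivered = 0
        for si in range(spikers.size):
            i = spikers[si]
            for s in range(indptr[i], indptr[i + 1]):
                buf[(t + dsteps[s]) % D, posts[s]] += ws[s]
                delivered += 1
        return delivered

else:  # pragma: no cover - numpy fallback, identical semantics

    def _gather(spikers, indptr):
        return np.concatenate(
            [np.arange(indptr[i], indptr[i + 1]) for i in spikers]
        ) if spikers.size else np.empty(0, dtype=np.int64)

    def _deliver_fail(spikers, indptr, posts, ws, dsteps, pfail, u, buf, t, D):
        syn = _gather(spikers, indptr)
        ok = u >= pfail[syn]
        syn = syn[ok]
        np.add.at(buf, ((t + dsteps[syn]) % D, posts[syn]), ws[syn])
        return int(ok.sum())

    def _deliver_all(spikers, indptr, posts, ws, dsteps, buf, t, D):
        syn = _gather(spikers, indptr)
        np.add.at(buf, ((t + dsteps[syn]) % D, posts[syn]), ws[syn])
        return syn.size


def _csr_incidence(table: SynapseTable):
    """Outgoing synapses grouped by presynaptic neuron."""
    n = table.n_neurons
    order = np.argsort(table.pre, kind="stable")
    posts = table.post[order].astype(np.int64)
    ws = table.weight[order].astype(np.float64)
    # a delay of 0 still acts on the next step: delivery precedes integration
    dsteps = np.maximum(table.delay_steps[order].astype(np.int64), 1)
    pfail = table.p_fail[order].astype(np.float64)
    counts = np.bincount(table.pre, minlength=n)
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    return indptr, posts, ws, dsteps, pfail


def run(network: SynapseTable, sim: SimulationConfig | None = None,
        seed: int | None = None, trace_neurons: tuple[int, ...] = (),
        init_v: float | np.ndarray | None = None) -> SpikeRaster:
    """Simulate the network and return its :class:`SpikeRaster`.

    ``seed`` overrides ``sim.seed``; separate RNG streams drive the
    transmission failures and the external Poisson kicks.  ``trace_neurons``
    records (v, g_E, g_I) of the listed neurons every step.  ``init_v``
    overrides the default initial membrane potential V_L.

    Raises ``FloatingPointError`` with the step and neuron index if the state
    becomes non-finite.
    """
    sim = sim or SimulationConfig()
    seed = sim.seed if seed is None else seed
    # domain key 1: disjoint from the wiring streams (domain 0) per seed
    rng_fail, rng_ext = (np.random.default_rng(s)
                         for s in np.random.SeedSequence([1, seed]).spawn(2))

    n_E, n_I = network.n_E, network.n_I
    n = n_E + n_I
    dt = sim.dt
    if abs(network.dt - dt) > 1e-12:
        raise ValueError("network delay grid and simulation dt disagree")
    n_steps = int(round(sim.duration / dt))
    refr_steps = int(round(sim.refractory / dt))

    indptr, posts, ws, dsteps, pfail = _csr_incidence(network)
    D = int(dsteps.max()) + 1 if dsteps.size else 2
    buf_E = np.zeros((D, n))  # pending increments to g_E, by arrival slot
    buf_I = np.zeros((D, n))

    v = np.full(n, sim.V_L, dtype=np.float64)
    if init_v is not None:
        v[:] = init_v
    g_E = np.zeros(n)
    g_I = np.zeros(n)
    refr = np.zeros(n, dtype=np.int64)

    inv_tau_m = np.empty(n)
    inv_tau_m[:n_E] = 1.0 / sim.tau_m_E
    inv_tau_m[n_E:] = 1.0 / sim.tau_m_I
    g_decay = 1.0 - dt / sim.tau_s

    t_lo, t_hi = sim.trigger_window
    p_kick = -np.expm1(-sim.lambda_ext * dt * 1e-3)
    n_kick = n_E if sim.kick_population == "E" else n

    trace_neurons = tuple(int(i) for i in trace_neurons)
    traces = None
    if trace_neurons:
        traces = {key: np.empty((n_steps, len(trace_neurons)))
                  for key in ("v", "g_E", "g_I")}
        tr_idx = np.asarray(trace_neurons)

    step_list: list[np.ndarray] = []
    id_list: list[np.ndarray] = []
    emitted = 0
    syn_events = 0
    delivered = 0

    with np.errstate(over="ignore", invalid="ignore"):
        for t in range(n_steps):
            row = t % D
            g_E += buf_E[row]
            buf_E[row] = 0.0
            g_I += buf_I[row]
            buf_I[row] = 0.0

            v += dt * (-(v - sim.V_L) * inv_tau_m
                       - g_E * (v - sim.V_E) - g_I * (v - sim.V_I))
            held = np.flatnonzero(refr)
            if held.size:
                v[held] = sim.V_r
            g_E *= g_decay
            g_I *= g_decay

            t_ms = t * dt
            if t_lo <= t_ms < t_hi and p_kick > 0:
                kicks = np.flatnonzero(
                    (rng_ext.random(n_kick) < p_kick) & (refr[:n_kick] == 0))
                if kicks.size:
                    v[kicks] += sim.A_s

            if traces is not None:
                traces["v"][t] = v[tr_idx]
                traces["g_E"][t] = g_E[tr_idx]
                traces["g_I"][t] = g_I[tr_idx]

            sp = np.flatnonzero(v >= sim.V_thr)
            if sp.size:
                v[sp] = sim.V_r
                refr[sp] = refr_steps
                step_list.append(np.full(sp.size, t, dtype=np.int64))
                id_list.append(sp.astype(np.int32))
                emitted += sp.size
                cut = int(np.searchsorted(sp, n_E))
                sp_e, sp_i = sp[:cut], sp[cut:]
                if sp_e.size:
                    n_ev = int((indptr[sp_e + 1] - indptr[sp_e]).sum())
                    u = rng_fail.random(n_ev)
                    delivered += _deliver_fail(sp_e, indptr, posts, ws,
                                               dsteps, pfail, u, buf_E, t, D)
                    syn_events += n_ev
                if sp_i.size:
                    d = _deliver_all(sp_i, indptr, posts, ws, dsteps,
                                     buf_I, t, D)
                    delivered += d
                    syn_events += d

            if refr_steps and held.size:
                refr[held] -= 1

            if t % 1000 == 999 and not np.all(np.isfinite(v)):
                bad = int(np.flatnonzero(~np.isfinite(v))[0])
                raise FloatingPointError(
                    f"non-finite membrane potential at step {t} "
                    f"(t = {t_ms:.1f} ms), neuron {bad}")

    if step_list:
        times = np.concatenate(step_list) * dt
        ids = np.concatenate(id_list)
    else:
        times = np.empty(0)
        ids = np.empty(0, dtype=np.int32)

    return SpikeRaster(
        times=times, ids=ids, n_E=n_E, n_I=n_I, dt=dt,
        duration=sim.duration, seed=seed, config=sim,
        counters={
            "emitted_spikes": emitted,
            "synaptic_events": syn_events,
            "delivered": delivered,
            "failed": syn_events - delivered,
        },
        traces=traces,
    )
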