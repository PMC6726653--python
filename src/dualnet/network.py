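"""Wiring of the dual-topology spiking network.

Excitatory-to-excitatory synapses carry EPSP amplitudes drawn from a capped
log-normal distribution.  Amplitudes above a threshold (default 9 mV) define
the *strong* subnetwork, wired as a Watts-Strogatz ring lattice rewired with
probability ``beta``; the remaining *weak* synapses are wired by the same
procedure at ``beta = 1`` (a random network).  E->I, I->E and I->I connections
are independent Bernoulli wirings with fixed weights.  Synaptic transmission
on E->E synapses fails stochastically with probability ``a / (a + V_EPSP)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "NetworkConfig",
    "SynapseTable",
    "SYNAPSE_CLASSES",
    "sample_epsp_amplitudes",
    "epsp_to_weight",
    "transmission_failure_prob",
    "build_ring_lattice",
    "rewire",
    "build_dual_network",
    "build_strong_network",
]

#: synapse-class codes used in :class:`SynapseTable.syn_class`
SYNAPSE_CLASSES = {"strong_EE": 0, "weak_EE": 1, "EI": 2, "IE": 3, "II": 4}
CLASS_NAMES = {v: k for k, v in SYNAPSE_CLASSES.items()}


@dataclass
class NetworkConfig:
    """Structural parameters of the dual-topology network.

    Defaults reproduce the full-size configuration: 10000 excitatory and 2000
    inhibitory neurons, 0.1*N_E**2 E->E synapses with log-normal EPSPs
    (sigma = 1, mode 0.2 mV, capped at 15 mV), strong/weak split at 9 mV.
    """

    N_E: int = 10000
    N_I: int = 2000
    ee_connection_count: int | None = None  # default 0.1 * N_E**2
    sigma: float = 1.0
    mu: float | None = None  # default log(0.2) + sigma**2  (mode = 0.2 mV)
    epsp_cap: float = 15.0
    strong_threshold: float = 9.0
    beta: float = 1.0
    p_EI: float = 0.1
    p_IE: float = 0.5
    p_II: float = 0.5
    G_EI: float = 0.018
    G_IE: float = 0.002
    G_II: float = 0.0025
    failure_a: float = 0.1
    conversion_factor: float = 100.0  # mV of peak EPSP per unit conductance
    delay_ee_range: tuple[float, float] = (1.0, 3.0)
    delay_other_range: tuple[float, float] = (0.0, 2.0)
    dt: float = 0.1  # ms, grid for delay quantization
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ee_connection_count is None:
            self.ee_connection_count = int(round(0.1 * self.N_E**2))
        if self.mu is None:
            self.mu = float(np.log(0.2) + self.sigma**2)
        self.validate()

    def validate(self) -> None:
        if self.N_E < 2 or self.N_I < 0:
            raise ValueError("need N_E >= 2 and N_I >= 0")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must lie in [0, 1], got {self.beta}")
        if self.ee_connection_count > self.N_E * (self.N_E - 1):
            raise ValueError("ee_connection_count exceeds N_E*(N_E-1)")
        if not self.epsp_cap > self.strong_threshold > 0:
            raise ValueError("require epsp_cap > strong_threshold > 0")
        for name in ("p_EI", "p_IE", "p_II"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        for name in ("delay_ee_range", "delay_other_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must be a non-negative interval")
        if self.failure_a <= 0:
            raise ValueError("failure_a must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["delay_ee_range"] = list(d["delay_ee_range"])
        d["delay_other_range"] = list(d["delay_other_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        for key in ("delay_ee_range", "delay_other_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SynapseTable:
    """Column-oriented table of all synapses in one wired network.

    All arrays have equal length.  ``delay_steps`` is the transmission delay
    in units of ``dt``; ``epsp`` is the EPSP amplitude in mV for E->E rows and
    0 elsewhere; ``p_fail`` is nonzero only for E->E rows.
    """

    pre: np.ndarray          # int32 neuron indices
    post: np.ndarray         # int32 neuron indices
    weight: np.ndarray       # float32 conductance increments, ms^-1
    delay_steps: np.ndarray  # int16 multiples of dt
    p_fail: np.ndarray       # float32 in [0, 1]
    syn_class: np.ndarray    # int8 codes, see SYNAPSE_CLASSES
    epsp: np.ndarray         # float32 mV (0 for non-EE rows)
    n_E: int
    n_I: int
    dt: float
    config: NetworkConfig | None = None

    def __len__(self) -> int:
        return self.pre.size

    @property
    def n_neurons(self) -> int:
        return self.n_E + self.n_I

    @property
    def delay_ms(self) -> np.ndarray:
        return self.delay_steps * self.dt

    def class_mask(self, *names: str) -> np.ndarray:
        codes = [SYNAPSE_CLASSES[n] for n in names]
        return np.isin(self.syn_class, codes)

    def class_counts(self) -> dict[str, int]:
        return {
            name: int(np.count_nonzero(self.syn_class == code))
            for name, code in SYNAPSE_CLASSES.items()
        }

    def save(self, path: str | Path) -> None:
        """Write as compressed columnar arrays plus a JSON config sidecar."""
        path = Path(path)
        meta = {"n_E": self.n_E, "n_I": self.n_I, "dt": self.dt}
        if self.config is not None:
            meta["config"] = self.config.to_dict()
        np.savez_compressed(
            path,
            pre=self.pre, post=self.post, weight=self.weight,
            delay_steps=self.delay_steps, p_fail=self.p_fail,
            syn_class=self.syn_class, epsp=self.epsp,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path: str | Path) -> "SynapseTable":
        with np.load(path) as z:
            meta = json.loads(z["meta"].tobytes().decode())
            cfg = meta.get("config")
            return cls(
                pre=z["pre"], post=z["post"], weight=z["weight"],
                delay_steps=z["delay_steps"], p_fail=z["p_fail"],
                syn_class=z["syn_class"], epsp=z["epsp"],
                n_E=int(meta["n_E"]), n_I=int(meta["n_I"]),
                dt=float(meta["dt"]),
                config=NetworkConfig.from_dict(cfg) if cfg else None,
            )

    def to_edgelist(self, path: str | Path) -> None:
        """Plain-text edge list: ``pre post weight delay_ms p_fail class``."""
        with open(path, "w") as fh:
            fh.write("# pre post weight delay_ms p_fail class\n")
            names = np.array([CLASS_NAMES[c] for c in range(len(CLASS_NAMES))])
            cols = zip(self.pre, self.post, self.weight,
                       self.delay_ms, self.p_fail, names[self.syn_class])
            for pre, post, w, d, pf, cl in cols:
                fh.write(f"{pre} {post} {w:.8g} {d:.4f} {pf:.8g} {cl}\n")


# ---------------------------------------------------------------------------
# elementary operations


def sample_epsp_amplitudes(n: int, config: NetworkConfig,
                           rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` EPSP amplitudes (mV) from the capped log-normal.

    Values above ``config.epsp_cap`` are rejected and redrawn (not clipped),
    so the output follows the log-normal truncated to ``(0, epsp_cap]``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    out = rng.lognormal(config.mu, config.sigma, size=n)
    bad = out > config.epsp_cap
    while np.any(bad):
        out[bad] = rng.lognormal(config.mu, config.sigma, size=int(bad.sum()))
        bad = out > config.epsp_cap
    return out


def epsp_to_weight(epsp, calibration_factor: float = 100.0):
    """Convert EPSP amplitude (mV) to a conductance increment (ms^-1).

    The default factor 100 is the linear conversion G_E = V_EPSP / 100; an
    alternative factor can be measured with :mod:`dualnet.calibration`.
    """
    epsp = np.asarray(epsp, dtype=float)
    if np.any(epsp < 0):
        raise ValueError("EPSP amplitudes must be non-negative")
    return epsp / calibration_factor


def transmission_failure_prob(epsp, a: float = 0.1):
    """Failure probability a / (a + V_EPSP) of an E->E synaptic transmission.

    Larger EPSPs transmit more reliably; the probability decreases
    monotonically from 1/2 at V_EPSP = a toward 0.
    """
    epsp = np.asarray(epsp, dtype=float)
    if np.any(epsp <= 0) or a <= 0:
        raise ValueError("epsp and a must be positive")
    return a / (a + epsp)


def build_ring_lattice(n_nodes: int, n_edges: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic directed ring lattice with ``n_edges`` edges.

    Edges are placed in rounds: round k adds i -> (i+k) mod n_nodes for every
    node i; the last round may be partial and is filled from node 0 upward.
    Returns ``(pre, post)`` int32 arrays with no duplicates or self-loops.
    """
    if n_nodes < 2:
        raise ValueError("need at least two nodes")
    if not 0 <= n_edges <= n_nodes * (n_nodes - 1):
        raise ValueError(
            f"n_edges={n_edges} infeasible for {n_nodes} nodes")
    full, rem = divmod(n_edges, n_nodes)
    nodes = np.arange(n_nodes, dtype=np.int32)
    pre = np.tile(nodes, full)
    offsets = np.repeat(np.arange(1, full + 1, dtype=np.int32), n_nodes)
    post = (pre + offsets) % n_nodes
    if rem:
        pre_p = nodes[:rem]
        post_p = (pre_p + full + 1) % n_nodes
        pre = np.concatenate([pre, pre_p])
        post = np.concatenate([post, post_p])
    return pre, post.astype(np.int32)


def rewire(pre: np.ndarray, post: np.ndarray, beta: float, n_nodes: int,
           rng: np.random.Generator) -> np.ndarray:
    """Watts-Strogatz rewiring of directed edge targets.

    Each edge independently has its target replaced, with probability
    ``beta``, by a node drawn uniformly at random; proposals creating a
    self-loop or duplicating an existing (pre, post) pair are redrawn.
    Sources and the edge count are preserved.  Returns the new ``post``.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must lie in [0, 1], got {beta}")
    pre = np.asarray(pre)
    post = np.asarray(post).copy()
    m = pre.size
    if m == 0 or beta == 0.0:
        return post
    move = rng.random(m) < beta
    pre64 = pre.astype(np.int64)
    out_deg = np.bincount(pre, minlength=n_nodes)
    if np.any(out_deg > n_nodes - 1):
        raise ValueError("a source has more edges than available targets")
    accepted = np.sort(pre64[~move] * n_nodes + post[~move])
    unresolved = np.flatnonzero(move)
    while unresolved.size:
        prop = rng.integers(0, n_nodes, size=unresolved.size)
        keys = pre64[unresolved] * n_nodes + prop
        ok = prop != pre[unresolved]
        # collision with already-fixed edges (kept + accepted proposals)
        pos = np.searchsorted(accepted, keys)
        pos_c = np.minimum(pos, max(accepted.size - 1, 0))
        if accepted.size:
            ok &= accepted[pos_c] != keys
        # duplicates among this batch: first occurrence (stable order) wins
        order = np.argsort(keys, kind="stable")
        sk = keys[order]
        dup_sorted = np.zeros(sk.size, dtype=bool)
        dup_sorted[1:] = sk[1:] == sk[:-1]
        dup = np.empty_like(dup_sorted)
        dup[order] = dup_sorted
        ok &= ~dup
        take = unresolved[ok]
        post[take] = prop[ok]
        accepted = np.sort(np.concatenate([accepted, keys[ok]]))
        unresolved = unresolved[~ok]
    return post


def _quantized_delays(n: int, lo: float, hi: float, dt: float,
                      rng: np.random.Generator,
                      min_steps: int = 0) -> np.ndarray:
    """Uniform delays in [lo, hi] ms, rounded to the nearest dt grid point."""
    d = rng.uniform(lo, hi, size=n)
    steps = np.rint(d / dt).astype(np.int16)
    return np.maximum(steps, min_steps)


def _bernoulli_pairs(n_pre: int, n_post: int, p: float,
                     rng: np.random.Generator,
                     exclude_diagonal: bool = False
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Ordered pairs (i, j) drawn by independent Bernoulli(p) per pair."""
    if p <= 0:
        empty = np.empty(0, dtype=np.int32)
        return empty, empty.copy()
    mask = rng.random(n_pre * n_post) < p
    idx = np.flatnonzero(mask)
    pre = (idx // n_post).astype(np.int32)
    post = (idx % n_post).astype(np.int32)
    if exclude_diagonal:
        keep = pre != post
        pre, post = pre[keep], post[keep]
    return pre, post


def _spawn_streams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    # domain key 0 = topology/wiring; the simulator uses domain 1, so a shared
    # master seed never reuses a bit stream across build and simulation
    children = np.random.SeedSequence([0, seed]).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


_STREAMS = ("amplitudes", "topology_strong", "topology_weak",
            "delays", "bernoulli", "assignment")


def build_strong_network(config: NetworkConfig, beta: float | None = None,
                         seed: int | None = None
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Wire only the strong (EPSP > threshold) E->E subnetwork.

    Shares RNG streams with :func:`build_dual_network`, so for the same seed
    the amplitudes (hence the strong-edge count) are identical and only the
    rewiring draw changes with ``beta``.  Returns ``(pre, post, epsp)``.
    """
    beta = config.beta if beta is None else beta
    seed = config.seed if seed is None else seed
    rngs = _spawn_streams(seed, _STREAMS)
    epsp = sample_epsp_amplitudes(config.ee_connection_count, config,
                                  rngs["amplitudes"])
    strong = epsp[epsp > config.strong_threshold]
    pre, post = build_ring_lattice(config.N_E, strong.size)
    post = rewire(pre, post, beta, config.N_E, rngs["topology_strong"])
    strong = strong[rngs["assignment"].permutation(strong.size)]
    return pre, post, strong


def build_dual_network(config: NetworkConfig,
                       seed: int | None = None) -> SynapseTable:
    """Wire the complete network and return its :class:`SynapseTable`.

    Steps: draw the E->E EPSP amplitudes; split at the strong threshold;
    wire the strong class as a rewired ring lattice at ``config.beta`` and
    the weak class by the same procedure at beta = 1; assign amplitudes to
    edges by random permutation within class; convert amplitudes to weights
    and failure probabilities; wire E->I, I->E, I->I by Bernoulli coupling
    with fixed weights; draw delays uniformly per class on the dt grid.
    """
    seed = config.seed if seed is None else seed
    rngs = _spawn_streams(seed, _STREAMS)
    N_E, N_I = config.N_E, config.N_I
    dt = config.dt

    epsp = sample_epsp_amplitudes(config.ee_connection_count, config,
                                  rngs["amplitudes"])
    strong_vals = epsp[epsp > config.strong_threshold]
    weak_vals = epsp[epsp <= config.strong_threshold]

    pre_s, post_s = build_ring_lattice(N_E, strong_vals.size)
    post_s = rewire(pre_s, post_s, config.beta, N_E, rngs["topology_strong"])
    pre_w, post_w = build_ring_lattice(N_E, weak_vals.size)
    post_w = rewire(pre_w, post_w, 1.0, N_E, rngs["topology_weak"])

    strong_vals = strong_vals[rngs["assignment"].permutation(strong_vals.size)]
    weak_vals = weak_vals[rngs["assignment"].permutation(weak_vals.size)]

    pre_ei, post_ei = _bernoulli_pairs(N_E, N_I, config.p_EI, rngs["bernoulli"])
    post_ei = post_ei + N_E
    pre_ie, post_ie = _bernoulli_pairs(N_I, N_E, config.p_IE, rngs["bernoulli"])
    pre_ie = pre_ie + N_E
    pre_ii, post_ii = _bernoulli_pairs(N_I, N_I, config.p_II, rngs["bernoulli"],
                                       exclude_diagonal=True)
    pre_ii = pre_ii + N_E
    post_ii = post_ii + N_E

    counts = [pre_s.size, pre_w.size, pre_ei.size, pre_ie.size, pre_ii.size]
    pre = np.concatenate([pre_s, pre_w, pre_ei, pre_ie, pre_ii]).astype(np.int32)
    post = np.concatenate([post_s, post_w, post_ei, post_ie, post_ii]).astype(np.int32)
    syn_class = np.repeat(np.arange(5, dtype=np.int8), counts)

    ee_epsp = np.concatenate([strong_vals, weak_vals])
    weight = np.concatenate([
        epsp_to_weight(ee_epsp, config.conversion_factor),
        np.full(counts[2], config.G_EI),
        np.full(counts[3], config.G_IE),
        np.full(counts[4], config.G_II),
    ]).astype(np.float32)
    p_fail = np.zeros(pre.size, dtype=np.float32)
    n_ee = counts[0] + counts[1]
    p_fail[:n_ee] = transmission_failure_prob(ee_epsp, config.failure_a)
    epsp_col = np.zeros(pre.size, dtype=np.float32)
    epsp_col[:n_ee] = ee_epsp

    lo, hi = config.delay_ee_range
    d_ee = _quantized_delays(n_ee, lo, hi, dt, rngs["delays"])
    lo, hi = config.delay_other_range
    d_other = _quantized_delays(pre.size - n_ee, lo, hi, dt, rngs["delays"])
    delay_steps = np.concatenate([d_ee, d_other]).astype(np.int16)

    return SynapseTable(
        pre=pre, post=post, weight=weight, delay_steps=delay_steps,
        p_fail=p_fail, syn_class=syn_class, epsp=epsp_col,
        n_E=N_E, n_I=N_I, dt=dt, config=config,
    )
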