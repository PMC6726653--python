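"""Population-rate and spike-train statistics of a simulated raster.

The population rate in a bin of width ``bin_ms`` holding S spikes from a
population of N neurons is r = 10^3 S / (bin_ms * N) Hz (per-neuron rate).
Smoothing uses a unit-area Gaussian kernel, so the mean rate is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from .simulator import SpikeRaster

__all__ = [
    "RateSeries",
    "population_rate",
    "gaussian_smooth",
    "activate_period_rate",
    "rate_power_spectrum",
    "ei_rate_correlation",
    "coherent_pair_rate",
    "bin_spike_trains",
]


@dataclass
class RateSeries:
    """A uniformly sampled population-rate series (Hz per neuron)."""

    values: np.ndarray
    bin_ms: float
    population: str = ""
    smoothing: str = "none"

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Left edge (ms) of every bin."""
        return np.arange(self.values.size) * self.bin_ms

    def window(self, lo: float, hi: float) -> "RateSeries":
        """Restrict to bins whose left edge lies in [lo, hi)."""
        i0 = int(np.ceil(lo / self.bin_ms - 1e-9))
        i1 = int(np.ceil(hi / self.bin_ms - 1e-9))
        return replace(self, values=self.values[i0:i1])

    def rebin(self, bin_ms: float) -> "RateSeries":
        """Block-average to a coarser bin width (must be a multiple)."""
        k = bin_ms / self.bin_ms
        ki = int(round(k))
        if abs(k - ki) > 1e-9 or ki < 1:
            raise ValueError("new bin width must be a multiple of the old")
        if ki == 1:
            return replace(self)
        nb = self.values.size // ki
        vals = self.values[: nb * ki].reshape(nb, ki).mean(axis=1)
        return replace(self, values=vals, bin_ms=bin_ms)


def population_rate(raster: SpikeRaster, population: str = "E",
                    bin_ms: float | None = None) -> RateSeries:
    """Population rate time series of one population.

    Default bin width is the simulation step dt, the convention under which
    S is the spike count per step.  The counting identity
    mean(rate) * N * duration = 10^3 * total spikes holds exactly.
    """
    bin_ms = raster.dt if bin_ms is None else bin_ms
    n_pop = {"E": raster.n_E, "I": raster.n_I}.get(population)
    if n_pop is None:
        raise ValueError(f"unknown population {population!r}")
    times, _ = raster.population_events(population)
    n_bins = int(np.floor(raster.duration / bin_ms + 1e-9))
    idx = np.minimum((times / bin_ms).astype(np.int64), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(np.float64)
    rate = 1e3 * counts / (bin_ms * n_pop)
    return RateSeries(rate, bin_ms, population=population)


def gaussian_smooth(series: RateSeries, width_ms: float = 10.0,
                    interpret: str = "sigma") -> RateSeries:
    """Convolve with a unit-area Gaussian window of temporal width ``width_ms``.

    ``interpret`` reads the width as the Gaussian sigma (default) or as its
    FWHM.  The kernel is truncated at +-4 sigma with reflective boundaries.
    """
    if width_ms <= 0:
        raise ValueError("width must be positive")
    sigma_ms = width_ms / 2.3548200450309493 if interpret == "fwhm" else width_ms
    sigma_bins = sigma_ms / series.bin_ms
    vals = gaussian_filter1d(series.values, sigma_bins, mode="reflect",
                             truncate=4.0)
    return replace(series, values=vals,
                   smoothing=f"gaussian_{interpret}={width_ms}ms")


def activate_period_rate(series: RateSeries, theta: float = 10.0,
                         window: tuple[float, float] | None = None) -> float:
    """Fraction of time the rate exceeds ``theta`` Hz (the activate period)."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    s = series if window is None else series.window(*window)
    if len(s) == 0:
        raise ValueError("empty evaluation window")
    return float(np.mean(s.values > theta))


def rate_power_spectrum(series: RateSeries, nperseg: int = 1024
                        ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Welch power spectrum of the rate series in dB/Hz.

    Returns (frequency Hz, power dB/Hz, estimator metadata).
    """
    if len(series) < 256:
        raise ValueError("series too short for a Welch estimate")
    fs = 1e3 / series.bin_ms
    nperseg = min(nperseg, len(series))
    f, pxx = signal.welch(series.values, fs=fs, window="hann",
                          nperseg=nperseg)
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(pxx)
    meta = {"estimator": "welch", "window": "hann", "nperseg": nperseg,
            "noverlap": nperseg // 2, "fs_hz": fs}
    return f, db, meta


def ei_rate_correlation(r_E: RateSeries, r_I: RateSeries,
                        window: tuple[float, float] | None = None) -> float:
    """Pearson correlation between the E and I population-rate series.

    Returns NaN (flagged sentinel) if either series has zero variance.
    """
    if abs(r_E.bin_ms - r_I.bin_ms) > 1e-12:
        raise ValueError("series must share the same binning")
    a = (r_E if window is None else r_E.window(*window)).values
    b = (r_I if window is None else r_I.window(*window)).values
    if a.size != b.size:
        raise ValueError("series must have equal length")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def bin_spike_trains(raster: SpikeRaster, neurons: np.ndarray,
                     bin_ms: float = 10.0) -> np.ndarray:
    """Per-neuron binned spike counts, shape (len(neurons), n_bins)."""
    neurons = np.asarray(neurons)
    n_bins = int(np.floor(raster.duration / bin_ms + 1e-9))
    lookup = np.full(raster.n_E + raster.n_I, -1, dtype=np.int64)
    lookup[neurons] = np.arange(neurons.size)
    rows = lookup[raster.ids]
    m = rows >= 0
    cols = np.minimum((raster.times[m] / bin_ms).astype(np.int64), n_bins - 1)
    out = np.zeros((neurons.size, n_bins))
    np.add.at(out, (rows[m], cols), 1.0)
    return out


def coherent_pair_rate(raster: SpikeRaster, pairs: np.ndarray,
                       corr_threshold: float = 0.5, bin_ms: float = 10.0,
                       denominator: str = "pairs"
                       ) -> tuple[float, np.ndarray, int]:
    """Fraction of neuron pairs whose binned trains are strongly correlated.

    ``pairs`` is an (n, 2) array of neuron indices (e.g. the endpoints of
    strong synapses).  Pairs involving a silent neuron have undefined
    correlation and are excluded (their count is returned).  ``denominator``
    selects the convention: "pairs" divides by the number of listed pairs
    with defined correlation, "all_ordered" by N_E * (N_E - 1).

    Returns ``(fraction, indices of qualifying pairs, n_excluded)``.
    """
    pairs = np.atleast_2d(np.asarray(pairs))
    if pairs.size == 0:
        raise ValueError("pairs must be non-empty")
    neurons = np.unique(pairs)
    trains = bin_spike_trains(raster, neurons, bin_ms)
    trains = trains - trains.mean(axis=1, keepdims=True)
    norms = np.sqrt((trains**2).sum(axis=1))
    lookup = np.full(raster.n_E + raster.n_I, -1, dtype=np.int64)
    lookup[neurons] = np.arange(neurons.size)
    a, b = lookup[pairs[:, 0]], lookup[pairs[:, 1]]
    valid = (norms[a] > 0) & (norms[b] > 0)
    corr = np.zeros(pairs.shape[0])
    corr[valid] = ((trains[a[valid]] * trains[b[valid]]).sum(axis=1)
                   / (norms[a[valid]] * norms[b[valid]]))
    qualify = np.flatnonzero(valid & (corr > corr_threshold))
    n_excluded = int((~valid).sum())
    if denominator == "pairs":
        denom = int(valid.sum())
    elif denominator == "all_ordered":
        denom = raster.n_E * (raster.n_E - 1)
    else:
        raise ValueError("denominator must be 'pairs' or 'all_ordered'")
    frac = qualify.size / denom if denom else float("nan")
    return frac, qualify, n_excluded
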