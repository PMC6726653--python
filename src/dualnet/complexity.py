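"""Multiscale entropy of rate time series.

Sample entropy h(r, m) = -log(C_{m+1}(r) / C_m(r)) where C_m(r) is the
fraction of template pairs (i != j) of m consecutive samples whose Chebyshev
distance is strictly below the tolerance r.  Following the Richman-Moorman
convention both C_m and C_{m+1} are counted over the same N - m template
start points.  The tolerance is an *absolute* value (default r = 1.0 Hz),
never rescaled by the series SD, so entropy depends on the physical rate
fluctuation amplitude.

Multiscale entropy evaluates h on coarse-grained series: non-overlapping
block means of length tau (the scale factor, in units of the base bin,
default 1 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .activity import RateSeries

__all__ = ["MSEConfig", "MSEProfile", "coarse_grain", "sample_entropy",
           "mse_profile"]


@dataclass
class MSEConfig:
    """Parameters of the multiscale-entropy analysis."""

    m: int = 2                      # embedding dimension
    r: float = 1.0                  # absolute tolerance (Hz)
    scales: tuple[int, ...] = tuple(range(1, 301))
    base_bin_ms: float = 1.0        # width of scale factor 1
    window: tuple[float, float] = (500.0, 9500.0)  # ms

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r <= 0:
            raise ValueError("r must be positive")
        if any(int(s) != s or s < 1 for s in self.scales):
            raise ValueError("scales must be integers >= 1")
        self.scales = tuple(int(s) for s in self.scales)

    def to_dict(self) -> dict:
        return {"m": self.m, "r": self.r, "scales": list(self.scales),
                "base_bin_ms": self.base_bin_ms, "window": list(self.window)}

    @classmethod
    def from_dict(cls, d: dict) -> "MSEConfig":
        d = dict(d)
        if "scales" in d:
            d["scales"] = tuple(d["scales"])
        if "window" in d:
            d["window"] = tuple(d["window"])
        return cls(**d)


@dataclass
class MSEProfile:
    """Sample entropy per (trial, scale), with across-trial aggregates."""

    scales: np.ndarray
    h: np.ndarray        # shape (n_trials, n_scales), NaN = undefined

    @property
    def mean(self) -> np.ndarray:
        return np.nanmean(self.h, axis=0)

    @property
    def sd(self) -> np.ndarray:
        return np.nanstd(self.h, axis=0, ddof=1) if self.h.shape[0] > 1 \
            else np.zeros(self.h.shape[1])

    def peak_scale(self) -> int:
        """Scale factor at which the trial-mean profile is maximal."""
        mean = self.mean
        if np.all(np.isnan(mean)):
            raise ValueError("profile is undefined at every scale")
        return int(self.scales[np.nanargmax(mean)])


def coarse_grain(series: np.ndarray, tau: int) -> np.ndarray:
    """Non-overlapping block means of length ``tau`` (remainder dropped)."""
    x = np.asarray(series, dtype=float)
    tau = int(tau)
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if tau > x.size:
        raise ValueError(f"tau={tau} exceeds the series length {x.size}")
    if tau == 1:
        return x.copy()
    nb = x.size // tau
    return x[: nb * tau].reshape(nb, tau).mean(axis=1)


def sample_entropy(series: np.ndarray, m: int = 2, r: float = 1.0,
                   chunk: int = 1024) -> float:
    """Sample entropy of one series; NaN when no template pair matches.

    Pairs are counted over the N - m templates common to lengths m and m+1
    with strict Chebyshev distance < r and self-matches (i == j) excluded.
    """
    x = np.asarray(series, dtype=float)
    if m < 1:
        raise ValueError("m must be >= 1")
    if r <= 0:
        raise ValueError("r must be positive")
    n_templates = x.size - m
    if n_templates < 2:
        raise ValueError(f"series of length {x.size} too short for m={m}")
    xm = sliding_window_view(x, m)[:n_templates]
    xm1 = sliding_window_view(x, m + 1)
    b = 0  # length-m matches (unordered)
    a = 0  # length-(m+1) matches
    for i0 in range(0, n_templates, chunk):
        i1 = min(i0 + chunk, n_templates)
        # distances from templates [i0:i1) to all templates j > i
        d = np.abs(xm[i0:i1, None, 0] - xm[None, i0:, 0])
        for q in range(1, m):
            np.maximum(d, np.abs(xm[i0:i1, None, q] - xm[None, i0:, q]),
                       out=d)
        rows = np.arange(i1 - i0)
        upper = rows[:, None] < np.arange(n_templates - i0)[None, :]
        hit_m = (d < r) & upper
        b += int(hit_m.sum())
        np.maximum(d, np.abs(xm1[i0:i1, None, m] - xm1[None, i0:, m]),
                   out=d)
        a += int(((d < r) & upper).sum())
    if b == 0 or a == 0:
        return float("nan")
    return float(-np.log(a / b))


def mse_profile(trials, config: MSEConfig | None = None) -> MSEProfile:
    """Multiscale-entropy profile of one or more rate series.

    Each trial (a :class:`RateSeries`, assumed already smoothed) is
    block-averaged to the base bin, restricted to the evaluation window,
    coarse-grained at every scale factor and scored with sample entropy.
    Undefined entropies are kept as NaN per (trial, scale) and excluded from
    the across-trial mean/SD.
    """
    config = config or MSEConfig()
    if not trials:
        raise ValueError("need at least one trial")
    scales = np.asarray(config.scales)
    h = np.empty((len(trials), scales.size))
    for ti, trial in enumerate(trials):
        if isinstance(trial, RateSeries):
            base = trial.rebin(config.base_bin_ms).window(*config.window)
            x = base.values
        else:
            x = np.asarray(trial, dtype=float)
        for si, tau in enumerate(scales):
            y = coarse_grain(x, tau)
            if y.size < config.m + 2:
                h[ti, si] = np.nan
                continue
            h[ti, si] = sample_entropy(y, config.m, config.r)
    return MSEProfile(scales=scales, h=h)
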