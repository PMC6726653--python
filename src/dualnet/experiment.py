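"""Experiment configuration, scaled fixtures and the beta-sweep driver.

``reproduce_sweep`` ties the full pipeline together: per rewiring
probability it wires a network, simulates a number of trials, computes
rates, activate-period fractions, multiscale entropy, optional surrogate
comparisons and strong-network topology, and writes everything as CSV plus
a machine-readable summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .activity import (activate_period_rate, ei_rate_correlation,
                       gaussian_smooth, population_rate)
from .complexity import MSEConfig, mse_profile
from .graph import beta_sweep_metrics
from .io import config_hash, read_raster, write_raster
from .network import NetworkConfig, SynapseTable, build_dual_network
from .simulator import SimulationConfig, SpikeRaster, run
from .surrogate import surrogate_mse_comparison

__all__ = ["ExperimentConfig", "load_config", "dump_config", "make_fixture",
           "trial_summary", "reproduce_sweep", "smoothed_rates"]

#: full-size reference populations used by the scale factor of make_fixture
FULL_N_E = 10000
FULL_N_I = 2000


@dataclass
class ExperimentConfig:
    """Complete description of one beta-sweep experiment."""

    network: NetworkConfig = field(default_factory=NetworkConfig)
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    mse: MSEConfig = field(default_factory=MSEConfig)
    betas: tuple[float, ...] = (1.0, 0.8, 0.6, 0.4, 0.2)
    n_trials: int = 10
    seed: int = 0
    theta: float = 10.0            # Hz, activate-period threshold
    smooth_width_ms: float = 10.0  # Gaussian sigma of the rate smoothing
    eval_window: tuple[float, float] = (500.0, 9500.0)  # ms
    n_surrogates: int = 0          # 0 disables the surrogate comparison
    surrogate_iters: int = 50
    run_graph: bool = True
    out_dir: str = "sweep_out"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["network"] = self.network.to_dict()
        d["sim"] = self.sim.to_dict()
        d["mse"] = self.mse.to_dict()
        d["betas"] = list(self.betas)
        d["eval_window"] = list(self.eval_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(
                f"unknown configuration key(s): {', '.join(sorted(unknown))}")
        for key, sub in (("network", NetworkConfig),
                         ("sim", SimulationConfig), ("mse", MSEConfig)):
            if key in d:
                sub_d = d[key]
                sub_known = set(sub.__dataclass_fields__)
                sub_unknown = set(sub_d) - sub_known
                if sub_unknown:
                    raise ValueError(
                        f"unknown key(s) in '{key}': "
                        f"{', '.join(sorted(sub_unknown))}")
                d[key] = sub.from_dict(sub_d)
        for key in ("betas", "eval_window"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        for b in cfg.betas:
            if not 0.0 <= b <= 1.0:
                raise ValueError(f"beta must lie in [0, 1], got beta={b}")
        if cfg.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        return cfg


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse a JSON experiment configuration; unknown keys are rejected."""
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: not valid JSON ({exc})") from exc
    return ExperimentConfig.from_dict(raw)


def dump_config(config: ExperimentConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def make_fixture(scale: float, seed: int = 0, beta: float = 1.0,
                 duration: float = 10000.0,
                 **net_overrides) -> tuple[SynapseTable, SimulationConfig]:
    """Scaled-down network preserving the full-size densities.

    ``scale`` multiplies both population sizes; the E->E synapse count stays
    at 0.1 * N_E'^2 and all probabilities, distributions and thresholds are
    unchanged, so edge densities match the full configuration.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must lie in (0, 1]")
    n_e = int(round(scale * FULL_N_E))
    n_i = int(round(scale * FULL_N_I))
    if n_e < 50:
        raise ValueError(
            f"scale {scale} gives N_E={n_e} < 50; the strong subnetwork "
            "would be too sparse to stay connected")
    net_cfg = NetworkConfig(N_E=n_e, N_I=n_i, beta=beta, seed=seed,
                            **net_overrides)
    table = build_dual_network(net_cfg)
    sim_cfg = SimulationConfig(duration=duration, seed=seed)
    return table, sim_cfg


def smoothed_rates(raster: SpikeRaster, smooth_width_ms: float = 10.0):
    """Smoothed E and I population-rate series at the raster's dt binning."""
    r_e = gaussian_smooth(population_rate(raster, "E"), smooth_width_ms)
    r_i = gaussian_smooth(population_rate(raster, "I"), smooth_width_ms)
    return r_e, r_i


def trial_summary(raster: SpikeRaster, theta: float = 10.0,
                  smooth_width_ms: float = 10.0,
                  window: tuple[float, float] = (500.0, 9500.0)) -> dict:
    """Rates, E-I correlation and activate fraction of one trial."""
    r_e, r_i = smoothed_rates(raster, smooth_width_ms)
    return {
        "r_E_mean": float(np.mean(r_e.window(*window).values)),
        "r_I_mean": float(np.mean(r_i.window(*window).values)),
        "ei_corr": ei_rate_correlation(r_e, r_i, window),
        "activate_fraction": activate_period_rate(r_e, theta, window),
        "n_spikes": int(len(raster)),
    }


def reproduce_sweep(config: ExperimentConfig,
                    resume: bool = True) -> dict:
    """Run the full beta sweep and write its results bundle.

    Per (beta, trial) the trial seed is ``config.seed + trial index`` and the
    raster is stored as text; with ``resume`` an existing raster file is read
    back instead of re-simulated, so interrupted sweeps continue where they
    stopped.  A failing trial is recorded in the summary and the sweep
    continues.  Returns the summary dictionary (also written as JSON).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    resolved = config.to_dict()
    chash = config_hash(resolved)
    dump_config(config, out / "config.json")

    rate_rows, mse_rows = [], []
    summary: dict = {"config_hash": chash, "betas": {}}
    for beta in config.betas:
        beta_key = f"{beta:g}"
        trials = []
        trial_info = []
        for trial in range(config.n_trials):
            tseed = config.seed + trial
            rpath = out / f"raster_beta{beta_key}_trial{trial}.txt"
            try:
                if resume and rpath.exists():
                    raster = read_raster(rpath)
                else:
                    net_cfg = NetworkConfig(**{
                        **config.network.to_dict(), "beta": beta,
                        "seed": tseed})
                    table = build_dual_network(net_cfg)
                    sim_cfg = SimulationConfig(**{
                        **config.sim.to_dict(), "seed": tseed})
                    raster = run(table, sim_cfg)
                    write_raster(raster, rpath)
            except Exception as exc:  # record and continue with other trials
                trial_info.append({"trial": trial, "seed": tseed,
                                   "error": f"{type(exc).__name__}: {exc}"})
                continue
            info = trial_summary(raster, config.theta,
                                 config.smooth_width_ms, config.eval_window)
            info.update({"trial": trial, "seed": tseed})
            trial_info.append(info)
            rate_rows.append({"beta": beta, **info})
            r_e, _ = smoothed_rates(raster, config.smooth_width_ms)
            trials.append(r_e)

        beta_summary: dict = {"trials": trial_info}
        if trials:
            profile = mse_profile(trials, config.mse)
            for ti in range(profile.h.shape[0]):
                for si, tau in enumerate(profile.scales):
                    mse_rows.append({"beta": beta, "trial": ti,
                                     "tau": int(tau),
                                     "h": float(profile.h[ti, si])})
            beta_summary["mse_peak_tau"] = profile.peak_scale()
            beta_summary["mse_mean"] = [float(x) for x in profile.mean]
            if config.n_surrogates > 0 and len(trials) >= 2:
                surr_rng = np.random.default_rng(
                    np.random.SeedSequence([2, config.seed]))
                cmp_df = surrogate_mse_comparison(
                    trials, config.mse, config.n_surrogates,
                    config.surrogate_iters, surr_rng)
                cmp_df.insert(0, "beta", beta)
                cmp_df.to_csv(out / f"surrogate_beta{beta_key}.csv",
                              index=False)
                beta_summary["surrogate_sig_taus_1e2"] = [
                    int(t) for t in cmp_df.loc[cmp_df.sig_1e2, "tau"]]
        summary["betas"][beta_key] = beta_summary

    if rate_rows:
        pd.DataFrame(rate_rows).to_csv(out / "rates.csv", index=False)
    if mse_rows:
        pd.DataFrame(mse_rows).to_csv(out / "mse.csv", index=False)
    if config.run_graph:
        gdf, _ = beta_sweep_metrics(config.network, list(config.betas),
                                    seed=config.seed)
        gdf.to_csv(out / "graph.csv", index=False)
        summary["graph"] = gdf.to_dict(orient="records")

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
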