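"""Plain-text raster files with an embedded configuration snapshot.

Format: '#'-prefixed header lines (a format tag, a JSON metadata line holding
the simulation config, seed and a config hash), one ``time_ms neuron_id``
line per spike.  Times are written at 0.1 us precision and snapped back to
the dt grid on read, so a write/read round trip reproduces the raster
exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .simulator import SimulationConfig, SpikeRaster

__all__ = ["write_raster", "read_raster", "config_hash"]

_FORMAT_TAG = "# dualnet raster v1"


def config_hash(d: dict) -> str:
    """Short stable hash of a resolved configuration dictionary."""
    blob = json.dumps(d, sort_keys=True).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def write_raster(raster: SpikeRaster, path: str | Path) -> None:
    cfg = raster.config.to_dict() if raster.config else None
    meta = {
        "n_E": raster.n_E, "n_I": raster.n_I, "dt": raster.dt,
        "duration": raster.duration, "seed": raster.seed,
        "config": cfg, "counters": raster.counters,
        "config_hash": config_hash(cfg or {}),
    }
    with open(path, "w") as fh:
        fh.write(_FORMAT_TAG + "\n")
        fh.write("# meta: " + json.dumps(meta, sort_keys=True) + "\n")
        fh.write("# time_ms neuron_id\n")
        for t, i in zip(raster.times, raster.ids):
            fh.write(f"{t:.4f} {i}\n")


def read_raster(path: str | Path) -> SpikeRaster:
    path = Path(path)
    meta = None
    times: list[float] = []
    ids: list[int] = []
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _FORMAT_TAG:
            raise ValueError(f"{path}: not a dualnet raster (bad format tag)")
        for ln, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# meta: "):
                    meta = json.loads(line[len("# meta: "):])
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 'time_ms neuron_id'")
            try:
                times.append(float(parts[0]))
                ids.append(int(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: unparsable spike line") from exc
    if meta is None:
        raise ValueError(f"{path}: missing '# meta:' header line")
    dt = float(meta["dt"])
    t = np.asarray(times, dtype=np.float64)
    t = np.rint(t / dt) * dt  # snap to the integration grid
    cfg = meta.get("config")
    return SpikeRaster(
        times=t, ids=np.asarray(ids, dtype=np.int32),
        n_E=int(meta["n_E"]), n_I=int(meta["n_I"]), dt=dt,
        duration=float(meta["duration"]), seed=int(meta["seed"]),
        config=SimulationConfig.from_dict(cfg) if cfg else None,
        counters=dict(meta.get("counters") or {}),
    )
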