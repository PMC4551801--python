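"""Config parsing and plain-text serialisation of runs, sweeps and snapshots.

All normative outputs are comma-separated text with floats written at full
double precision, so every file round-trips exactly and is diffable.  Config
files are flat YAML mappings; every experiment writes a JSON metadata file
sufficient to re-run it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import GameParams
from .simulate import ObservableSeries, RunConfig
from .sweep import SweepGrid, SweepSpec

__all__ = [
    "load_config",
    "dump_config",
    "write_timeseries",
    "read_timeseries",
    "export_snapshot",
    "read_snapshot",
    "write_sweep",
    "read_sweep",
    "write_metadata",
]

log = logging.getLogger("limres")

_RUN_KEYS = {
    "kind", "L", "b", "c", "mcs", "seed", "snapshots", "steady_window",
    "parent_weight", "replacement", "reward", "sucker", "punishment", "consumption",
}
_SWEEP_KEYS = {
    "kind", "L", "b_values", "c_values", "replicates", "base_seed", "mcs",
    "steady_window", "parent_weight", "replacement",
    "reward", "sucker", "punishment", "consumption",
}
_SWEEP_ONLY = {"b_values", "c_values", "replicates", "base_seed"}


def _auto_seed() -> int:
    seed = int(np.random.SeedSequence().generate_state(1)[0] & 0x7FFFFFFF)
    log.warning("no seed supplied; auto-generated seed=%d (record it to reproduce)", seed)
    return seed


def _game_params(cfg: dict, L_default: int = 100) -> GameParams:
    return GameParams(
        L=int(cfg.get("L", L_default)),
        b=float(cfg.get("b", 1.1)),
        c=float(cfg.get("c", 1.01)),
        reward=float(cfg.get("reward", 1.0)),
        sucker=float(cfg.get("sucker", 0.0)),
        punishment=float(cfg.get("punishment", 0.0)),
        consumption=float(cfg.get("consumption", 1.0)),
        parent_weight=cfg.get("parent_weight", "net"),
        replacement=cfg.get("replacement", "synchronous"),
    )


def load_config(path) -> RunConfig | SweepSpec:
    """Read a flat YAML config and build a validated RunConfig or SweepSpec.

    A mapping containing any of b_values/c_values/replicates/base_seed (or
    ``kind: sweep``) describes a sweep; anything else a single run.  Unknown
    keys raise a ValueError naming the key; out-of-range values propagate
    the underlying validation error, which also names the key.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a flat mapping")
    is_sweep = cfg.get("kind") == "sweep" or bool(_SWEEP_ONLY & cfg.keys())
    allowed = _SWEEP_KEYS if is_sweep else _RUN_KEYS
    unknown = sorted(cfg.keys() - allowed)
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(unknown)}")

    if is_sweep:
        template = RunConfig(
            params=_game_params(cfg),
            mcs_total=int(cfg.get("mcs", 1024)),
            seed=0,
            steady_window=cfg.get("steady_window"),
        )
        return SweepSpec(
            b_values=tuple(float(x) for x in cfg.get("b_values", (1.1,))),
            c_values=tuple(float(x) for x in cfg.get("c_values", (1.01,))),
            replicates=int(cfg.get("replicates", 100)),
            base_seed=int(cfg["base_seed"]) if "base_seed" in cfg else _auto_seed(),
            run_template=template,
        )
    return RunConfig(
        params=_game_params(cfg),
        mcs_total=int(cfg.get("mcs", 1024)),
        seed=int(cfg["seed"]) if "seed" in cfg else _auto_seed(),
        snapshot_checkpoints=tuple(int(t) for t in cfg.get("snapshots", ())),
        steady_window=cfg.get("steady_window"),
    )


def dump_config(config: RunConfig | SweepSpec, path) -> None:
    """Write a config back to canonical flat YAML (inverse of load_config)."""
    if isinstance(config, SweepSpec):
        t = config.run_template
        out = {
            "kind": "sweep",
            "L": t.params.L,
            "b_values": [float(x) for x in config.b_values],
            "c_values": [float(x) for x in config.c_values],
            "replicates": config.replicates,
            "base_seed": config.base_seed,
            "mcs": t.mcs_total,
            "steady_window": t.steady_window,
            "parent_weight": t.params.parent_weight,
            "replacement": t.params.replacement,
        }
    else:
        p = config.params
        out = {
            "kind": "run",
            "L": p.L,
            "b": p.b,
            "c": p.c,
            "mcs": config.mcs_total,
            "seed": config.seed,
            "snapshots": list(config.snapshot_checkpoints),
            "steady_window": config.steady_window,
            "parent_weight": p.parent_weight,
            "replacement": p.replacement,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)


def write_timeseries(series: ObservableSeries, path) -> None:
    """One CSV row per step: mcs,mean_cp,std_cp,deaths (full float precision)."""
    df = pd.DataFrame(
        {
            "mcs": np.arange(len(series)),
            "mean_cp": series.mean_cp,
            "std_cp": series.std_cp,
            "deaths": series.deaths.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_timeseries(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def export_snapshot(grid: np.ndarray, path, format: str = "matrix") -> None:
    """Write one CP grid: L comma-separated rows, or a grayscale image.

    The matrix text is the normative form and round-trips bit-exactly; the
    image maps CP 0 -> black, 1 -> white, one pixel per site.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2:
        raise ValueError(f"snapshot must be 2-D, got shape {grid.shape}")
    if format == "matrix":
        np.savetxt(path, grid, fmt="%.17g", delimiter=",")
    elif format == "image":
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        plt.imsave(path, grid, cmap="gray", vmin=0.0, vmax=1.0)
    else:
        raise ValueError(f"unknown snapshot format {format!r}")


def read_snapshot(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", ndmin=2)


def write_sweep(grid: SweepGrid, path) -> None:
    """Long-format CSV: one row per (b, c, metric) with mean, stderr, n."""
    pd.DataFrame(grid.to_records()).to_csv(path, index=False, float_format="%.17g")


def read_sweep(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_metadata(path, config: RunConfig | SweepSpec, extra: dict | None = None) -> None:
    """JSON metadata sufficient to re-run the experiment exactly."""
    try:
        from importlib.metadata import version

        pkg_version = version("limres")
    except Exception:  # pragma: no cover - not installed
        pkg_version = "unknown"
    from datetime import datetime, timezone

    payload = {
        "package": "limres",
        "version": pkg_version,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": asdict(config),
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return str(obj)
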