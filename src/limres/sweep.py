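"""Replicated parameter sweeps over the (b, c) plane.

Each grid cell runs several independent seeded realisations, summarises the
steady state of each, and aggregates mean and standard error per cell.  Cell
seeds are derived from (base_seed, b index, c index, replicate) alone, so
cells are independent of evaluation order and of the rest of the grid:
adding rows or columns never changes existing cells' random streams.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .model import GameParams
from .simulate import RunConfig, run_simulation, summarize_steady

__all__ = ["SweepSpec", "SweepGrid", "cell_seed", "run_cell", "run_sweep", "argmax_over_c"]

METRICS = ("mean_cp", "std_cp", "deaths_per_mcs")


def cell_seed(base_seed: int, b_index: int, c_index: int, replicate: int) -> int:
    """Deterministic per-replicate seed, independent of grid shape and order."""
    ss = np.random.SeedSequence((base_seed, b_index, c_index, replicate))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass(frozen=True)
class SweepSpec:
    """A (b, c) grid of replicated runs sharing one run template.

    ``run_template`` supplies L, Monte Carlo length, steady window and any
    non-default payoff entries; its own b, c and seed are overridden per
    cell and replicate.
    """

    b_values: tuple[float, ...]
    c_values: tuple[float, ...]
    replicates: int
    base_seed: int
    run_template: RunConfig

    def __post_init__(self) -> None:
        for name, vals in (("b_values", self.b_values), ("c_values", self.c_values)):
            if len(vals) == 0:
                raise ValueError(f"{name} must be non-empty")
            if any(y <= x for x, y in zip(vals, vals[1:])):
                raise ValueError(f"{name} must be strictly increasing")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")


@dataclass
class SweepGrid:
    """Per-cell replicate means and standard errors of the steady summaries.

    All metric arrays have shape (len(b_values), len(c_values)); ``sem`` is
    the standard error of the replicate mean (0 when replicates == 1).
    """

    b_values: np.ndarray
    c_values: np.ndarray
    replicates: int
    mean: dict[str, np.ndarray]
    sem: dict[str, np.ndarray]
    seeds: np.ndarray  # shape (nb, nc, replicates)

    def row(self, b: float, metric: str) -> np.ndarray:
        bi = _index_of(self.b_values, b, "b")
        return self.mean[metric][bi]

    def to_records(self):
        """Long-format rows (b, c, metric, mean, stderr, n) for serialisation."""
        rows = []
        for bi, b in enumerate(self.b_values):
            for ci, c in enumerate(self.c_values):
                for m in METRICS:
                    rows.append(
                        {
                            "b": float(b),
                            "c": float(c),
                            "metric": m,
                            "mean": float(self.mean[m][bi, ci]),
                            "stderr": float(self.sem[m][bi, ci]),
                            "n": self.replicates,
                        }
                    )
        return rows


def _index_of(values: np.ndarray, x: float, name: str) -> int:
    hits = np.flatnonzero(np.isclose(values, x, rtol=0.0, atol=1e-12))
    if len(hits) != 1:
        raise KeyError(f"{name} = {x} not present in the grid")
    return int(hits[0])


def run_cell(spec: SweepSpec, b_index: int, c_index: int):
    """Run all replicates of one (b, c) cell; returns (summaries, seeds)."""
    b = spec.b_values[b_index]
    c = spec.c_values[c_index]
    params = dc_replace(spec.run_template.params, b=float(b), c=float(c))
    summaries, seeds = [], []
    for r in range(spec.replicates):
        seed = cell_seed(spec.base_seed, b_index, c_index, r)
        config = dc_replace(spec.run_template, params=params, seed=seed)
        series = run_simulation(config)
        summaries.append(summarize_steady(series))
        seeds.append(seed)
    return summaries, seeds


def run_sweep(spec: SweepSpec) -> SweepGrid:
    """Run every cell of the grid and aggregate replicate statistics."""
    nb, nc = len(spec.b_values), len(spec.c_values)
    mean = {m: np.empty((nb, nc)) for m in METRICS}
    sem = {m: np.empty((nb, nc)) for m in METRICS}
    seeds = np.empty((nb, nc, spec.replicates), dtype=np.int64)
    for bi in range(nb):
        for ci in range(nc):
            summaries, cell_seeds = run_cell(spec, bi, ci)
            seeds[bi, ci] = cell_seeds
            for m in METRICS:
                vals = np.array([getattr(s, m) for s in summaries])
                mean[m][bi, ci] = vals.mean()
                sem[m][bi, ci] = (
                    vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
                )
    return SweepGrid(
        b_values=np.asarray(spec.b_values, dtype=float),
        c_values=np.asarray(spec.c_values, dtype=float),
        replicates=spec.replicates,
        mean=mean,
        sem=sem,
        seeds=seeds,
    )


def argmax_over_c(
    grid: SweepGrid, b: float, metric: str = "mean_cp", minimize: bool = False
) -> float:
    """The c value extremising a metric along one b row; ties -> smaller c.

    ``metric`` is one of mean_cp, std_cp, deaths_per_mcs.
    """
    if metric not in METRICS:
        raise KeyError(f"unknown metric {metric!r}; choose from {METRICS}")
    row = grid.row(b, metric)
    idx = int(np.argmin(row) if minimize else np.argmax(row))  # first hit = smallest c
    return float(grid.c_values[idx])
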