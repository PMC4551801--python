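"""Seeded Monte Carlo driver: time series, snapshots, steady-state summaries.

A run starts from a fresh uniform-random lattice, iterates full Monte Carlo
steps, and records the population mean and standard deviation of the
characteristic parameter plus the death count after every step.  "Steady
state" is operationalised as a time average over a final window (default the
last 10% of steps, at least 100): once deaths cease the lattice is frozen
and the average is exact, while under persistent turnover it estimates the
stationary level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import GameParams, LatticeState, init_lattice, mcs_step

__all__ = [
    "RunConfig",
    "ObservableSeries",
    "SteadySummary",
    "default_steady_window",
    "run_simulation",
    "summarize_steady",
]


def default_steady_window(mcs_total: int) -> int:
    """Last 10% of the run, at least 100 steps, never longer than the run."""
    return min(mcs_total, max(100, mcs_total // 10))


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one simulation exactly."""

    params: GameParams
    mcs_total: int = 1024
    seed: int = 0
    snapshot_checkpoints: tuple[int, ...] = ()
    steady_window: int | None = None

    def __post_init__(self) -> None:
        if self.mcs_total < 1:
            raise ValueError(f"mcs_total must be >= 1, got {self.mcs_total}")
        window = self.window
        if not 1 <= window <= self.mcs_total:
            raise ValueError(
                f"steady_window must lie in [1, mcs_total], got {self.steady_window}"
            )
        bad = [t for t in self.snapshot_checkpoints if not 0 <= t <= self.mcs_total]
        if bad:
            raise ValueError(f"snapshot checkpoints outside [0, mcs_total]: {bad}")

    @property
    def window(self) -> int:
        return (
            self.steady_window
            if self.steady_window is not None
            else default_steady_window(self.mcs_total)
        )


@dataclass
class ObservableSeries:
    """Per-step observables; index t = 0 is the initial state (deaths[0] = 0)."""

    mean_cp: np.ndarray
    std_cp: np.ndarray
    deaths: np.ndarray
    reseeded: np.ndarray
    snapshots: dict[int, np.ndarray] = field(default_factory=dict)
    config: RunConfig | None = None

    def __len__(self) -> int:
        return len(self.mean_cp)

    @property
    def cumulative_deaths(self) -> np.ndarray:
        return np.cumsum(self.deaths)


@dataclass(frozen=True)
class SteadySummary:
    """Time averages over the final steady window of one run."""

    mean_cp: float
    std_cp: float
    deaths_per_mcs: float
    seed: int


def run_simulation(config: RunConfig) -> ObservableSeries:
    """Run one seeded simulation and record observables each step.

    Deterministic: the same config (including seed) always yields
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    state = init_lattice(config.params, rng)
    T = config.mcs_total

    mean_cp = np.empty(T + 1)
    std_cp = np.empty(T + 1)
    deaths = np.zeros(T + 1, dtype=np.int64)
    reseeded = np.zeros(T + 1, dtype=np.int64)
    mean_cp[0] = state.cp.mean()
    std_cp[0] = state.cp.std()

    checkpoints = set(config.snapshot_checkpoints)
    snapshots: dict[int, np.ndarray] = {}
    if 0 in checkpoints:
        snapshots[0] = state.cp.copy()

    for t in range(1, T + 1):
        state, stats = mcs_step(state, config.params, rng)
        mean_cp[t] = stats.mean_cp
        std_cp[t] = stats.std_cp
        deaths[t] = stats.deaths
        reseeded[t] = stats.reseeded
        if t in checkpoints:
            snapshots[t] = state.cp.copy()

    return ObservableSeries(
        mean_cp=mean_cp,
        std_cp=std_cp,
        deaths=deaths,
        reseeded=reseeded,
        snapshots=snapshots,
        config=config,
    )


def summarize_steady(series: ObservableSeries, steady_window: int | None = None) -> SteadySummary:
    """Average the observables over the last ``steady_window`` steps.

    The window never includes t = 0 (the pre-update initial state).
    """
    if steady_window is None:
        steady_window = (
            series.config.window if series.config is not None else default_steady_window(len(series) - 1)
        )
    n_steps = len(series) - 1
    if not 1 <= steady_window <= n_steps:
        raise ValueError(
            f"steady_window must lie in [1, {n_steps}], got {steady_window}"
        )
    sl = slice(len(series) - steady_window, len(series))
    seed = series.config.seed if series.config is not None else -1
    return SteadySummary(
        mean_cp=float(series.mean_cp[sl].mean()),
        std_cp=float(series.std_cp[sl].mean()),
        deaths_per_mcs=float(series.deaths[sl].mean()),
        seed=seed,
    )
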