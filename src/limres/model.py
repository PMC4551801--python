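"""Core lattice model: payoffs, resource sharing, and death-birth replacement.

The model lives on an L x L square lattice with periodic boundaries.  Each
site holds one individual described by a single heritable number, its
*characteristic parameter* (CP) ``p`` in [0, 1], the tendency to cooperate.
One Monte Carlo step (MCS) has three phases:

1. **Payoff.**  Every individual plays a continuous-strategy prisoner's
   dilemma with its four von Neumann neighbours.  Against a neighbour with
   CP ``p_j``, the focal individual with CP ``p_i`` earns the expected payoff

       P_ij = p_i p_j R + (1 - p_i) p_j T + p_i (1 - p_j) S
              + (1 - p_i)(1 - p_j) P

   With the rescaled matrix R = 1, S = 0, T = b, P = 0 (b > 1 the temptation
   to defect) this is P_ij = p_i p_j + (1 - p_i) p_j b: lower CP always pays
   better against a given neighbour, which is the engine of the dilemma.

2. **Resource distribution.**  The environment supplies a fixed global
   budget G_sys = c L^2 per step (c is the per-capita investment rate).  It
   is split in proportion to payoff, G_i = G_sys P_i / P_sys, and each
   individual consumes one unit, leaving the net resource H_i = G_i - 1.

3. **Death-birth replacement.**  Every individual with H_i < 0 dies and its
   site is refilled by the offspring of a surviving neighbour, chosen with
   probability proportional to that neighbour's resource; offspring inherit
   the parent CP exactly.  A dead site with no surviving neighbour is
   reseeded with a fresh uniform CP.

There is no imitation or mutation channel: once a step produces zero deaths
the lattice is frozen forever.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GameParams",
    "LatticeState",
    "PayoffField",
    "ResourceField",
    "UpdateResult",
    "StepStats",
    "init_lattice",
    "pair_payoff",
    "payoff_field",
    "distribute_resource",
    "select_parent",
    "death_birth_step",
    "mcs_step",
]

# the four von Neumann displacements (up, down, left, right) as (shift, axis)
_NEIGHBOR_SHIFTS = ((1, 0), (-1, 0), (1, 1), (-1, 1))


def _neighbor_stack(a: np.ndarray) -> np.ndarray:
    """Stack the four periodic von Neumann translates of ``a``, shape (4, L, L)."""
    return np.stack([np.roll(a, shift, axis=axis) for shift, axis in _NEIGHBOR_SHIFTS])


@dataclass(frozen=True)
class GameParams:
    """Parameters of the limited-resource lattice game.

    Parameters
    ----------
    L
        Lattice side length; the population has ``L * L`` sites.
    b
        Temptation to defect, the payoff T a defector extracts from a full
        cooperator.  ``b > 1`` creates the social dilemma; the interesting
        range is (1, 2].
    c
        Environment (resource) rate: investment per individual and per step.
        The global budget each step is ``G_sys = c * L**2``.
    reward, sucker, punishment
        Remaining payoff-matrix entries R, S, P.  Defaults (1, 0, 0) are the
        standard rescaling; with ``b > 1`` the ranking T > R > P >= S holds.
    consumption
        Per-individual consumption subtracted from the allocated resource
        each step (default 1, the survival threshold).
    parent_weight
        ``"net"`` weights parent selection by surviving neighbours' net
        resource H (default); ``"gross"`` uses the allocated resource G.
    replacement
        ``"synchronous"`` (default) marks all deaths from one resource
        snapshot and refills them in parallel from pre-update neighbours;
        ``"sequential"`` refills dead sites one at a time in random order,
        letting freshly placed offspring act as (zero-weight) parents.
    """

    L: int
    b: float = 1.1
    c: float = 1.01
    reward: float = 1.0
    sucker: float = 0.0
    punishment: float = 0.0
    consumption: float = 1.0
    parent_weight: str = "net"
    replacement: str = "synchronous"

    def __post_init__(self) -> None:
        if not isinstance(self.L, (int, np.integer)) or self.L < 2:
            raise ValueError(f"L must be an integer >= 2, got {self.L!r}")
        if not self.c > 0:
            raise ValueError(f"c must be positive, got {self.c!r}")
        if not np.isfinite(self.b):
            raise ValueError(f"b must be finite, got {self.b!r}")
        if self.parent_weight not in ("net", "gross"):
            raise ValueError(
                f"parent_weight must be 'net' or 'gross', got {self.parent_weight!r}"
            )
        if self.replacement not in ("synchronous", "sequential"):
            raise ValueError(
                "replacement must be 'synchronous' or 'sequential', "
                f"got {self.replacement!r}"
            )

    @property
    def n_sites(self) -> int:
        return self.L * self.L

    @property
    def total_resource(self) -> float:
        """Global per-step resource budget G_sys = c * L**2."""
        return self.c * self.n_sites


@dataclass
class LatticeState:
    """CP grid plus a Monte Carlo time index; boundary is periodic."""

    cp: np.ndarray
    mcs: int = 0

    def __post_init__(self) -> None:
        self.cp = np.asarray(self.cp, dtype=float)
        if self.cp.ndim != 2 or self.cp.shape[0] != self.cp.shape[1]:
            raise ValueError(f"cp must be a square 2-D array, got shape {self.cp.shape}")
        if np.any(self.cp < 0) or np.any(self.cp > 1):
            raise ValueError("all characteristic parameters must lie in [0, 1]")

    @property
    def L(self) -> int:
        return self.cp.shape[0]


@dataclass(frozen=True)
class PayoffField:
    """Per-site total payoffs P_i (summed over the four neighbours) and P_sys."""

    payoff: np.ndarray
    total: float


@dataclass(frozen=True)
class ResourceField:
    """Allocated resource G_i, net resource H_i = G_i - consumption, and G_sys."""

    allocated: np.ndarray
    net: np.ndarray
    total_budget: float


@dataclass(frozen=True)
class UpdateResult:
    """Outcome of one death-birth phase."""

    new_state: LatticeState
    deaths: int
    reseeded: int


@dataclass(frozen=True)
class StepStats:
    """Observables of one full MCS, measured on the post-update lattice."""

    mean_cp: float
    std_cp: float
    deaths: int
    reseeded: int


def init_lattice(params: GameParams, rng: np.random.Generator) -> LatticeState:
    """Draw the initial lattice: i.i.d. Uniform(0, 1) CPs (mean 0.5)."""
    cp = rng.random((params.L, params.L))
    return LatticeState(cp=cp, mcs=0)


def pair_payoff(p_i, p_j, params: GameParams):
    """Expected payoff of the focal individual i against neighbour j.

    Asymmetric in its arguments: the focal side is always the first one.
    Accepts scalars or broadcastable arrays.
    """
    p_i = np.asarray(p_i, dtype=float)
    p_j = np.asarray(p_j, dtype=float)
    if np.any(p_i < 0) or np.any(p_i > 1) or np.any(p_j < 0) or np.any(p_j > 1):
        raise ValueError("strategies must lie in [0, 1]")
    out = (
        p_i * p_j * params.reward
        + (1.0 - p_i) * p_j * params.b
        + p_i * (1.0 - p_j) * params.sucker
        + (1.0 - p_i) * (1.0 - p_j) * params.punishment
    )
    return out[()] if out.ndim == 0 else out


def payoff_field(state: LatticeState, params: GameParams) -> PayoffField:
    """Total payoff P_i of every site against its four periodic neighbours."""
    p = state.cp
    nsum = _neighbor_stack(p).sum(axis=0)  # sum of the four neighbour CPs
    # Sum of pair_payoff over neighbours collapses to a function of nsum only.
    payoff = (
        p * nsum * params.reward
        + (1.0 - p) * nsum * params.b
        + p * (4.0 - nsum) * params.sucker
        + (1.0 - p) * (4.0 - nsum) * params.punishment
    )
    return PayoffField(payoff=payoff, total=float(payoff.sum()))


def distribute_resource(fieldv: PayoffField, params: GameParams) -> ResourceField:
    """Split the global budget G_sys = c L^2 in proportion to payoff.

    If the whole lattice earns zero payoff (only reachable from an all-p=0
    state under the default matrix), the budget is split equally so that
    conservation still holds and no division by zero occurs.
    """
    g_sys = params.total_resource
    if fieldv.total > 0:
        allocated = g_sys * fieldv.payoff / fieldv.total
    else:
        allocated = np.full_like(fieldv.payoff, params.c)
    net = allocated - params.consumption
    return ResourceField(allocated=allocated, net=net, total_budget=g_sys)


def _neighbor_coords(i: int, j: int, L: int):
    return [((i + s) % L, j) if ax == 0 else (i, (j + s) % L) for s, ax in _NEIGHBOR_SHIFTS]


def select_parent(
    dead_site: tuple[int, int],
    state: LatticeState,
    resources: ResourceField,
    params: GameParams,
    rng: np.random.Generator,
) -> float:
    """Pick the CP that refills one dead site (scalar reference implementation).

    Surviving neighbours (H >= 0 on the pre-update snapshot) compete with
    probability proportional to their resource (net H by default, gross G
    via ``params.parent_weight``); offspring copy the parent CP exactly.
    With survivors but all-zero weights the choice is uniform among
    survivors; with no survivors a fresh Uniform(0, 1) CP is drawn.
    """
    i, j = dead_site
    if resources.net[i, j] >= 0:
        raise ValueError(f"site {dead_site} is alive (H >= 0); nothing to replace")
    coords = _neighbor_coords(i, j, state.L)
    alive = [resources.net[a, b_] >= 0 for a, b_ in coords]
    if not any(alive):
        return float(rng.random())
    source = resources.net if params.parent_weight == "net" else resources.allocated
    weights = np.array(
        [source[a, b_] if ok else 0.0 for (a, b_), ok in zip(coords, alive)]
    )
    if weights.sum() <= 0:
        weights = np.array([1.0 if ok else 0.0 for ok in alive])
    k = rng.choice(4, p=weights / weights.sum())
    a, b_ = coords[k]
    return float(state.cp[a, b_])


def _death_birth_synchronous(
    state: LatticeState,
    resources: ResourceField,
    params: GameParams,
    rng: np.random.Generator,
) -> UpdateResult:
    p = state.cp
    H = resources.net
    dead = H < 0
    n_dead = int(dead.sum())
    if n_dead == 0:
        return UpdateResult(new_state=state, deaths=0, reseeded=0)

    Hn = _neighbor_stack(H)
    pn = _neighbor_stack(p)
    alive_n = Hn >= 0
    source_n = Hn if params.parent_weight == "net" else _neighbor_stack(resources.allocated)
    w = np.where(alive_n, source_n, 0.0)
    has_survivor = alive_n.any(axis=0)
    wsum = w.sum(axis=0)
    # survivors present but all weights zero -> uniform among survivors
    fallback = has_survivor & (wsum <= 0.0)
    w = np.where(fallback[None, :, :], alive_n.astype(float), w)
    wsum = w.sum(axis=0)

    cum = np.cumsum(w, axis=0)
    r = rng.random(p.shape) * wsum
    k = np.minimum((cum <= r[None, :, :]).sum(axis=0), 3)
    chosen = np.take_along_axis(pn, k[None, :, :], axis=0)[0]
    fresh = rng.random(p.shape)

    new_cp = np.where(dead, np.where(has_survivor, chosen, fresh), p)
    reseeded = int((dead & ~has_survivor).sum())
    return UpdateResult(
        new_state=LatticeState(cp=new_cp, mcs=state.mcs),
        deaths=n_dead,
        reseeded=reseeded,
    )


def _death_birth_sequential(
    state: LatticeState,
    resources: ResourceField,
    params: GameParams,
    rng: np.random.Generator,
) -> UpdateResult:
    # Dead set is fixed from the snapshot, but sites refill one at a time in
    # random order; a refilled site rejoins the survivor pool with H = 0.
    H = resources.net.copy()
    G = resources.allocated.copy()
    cp = state.cp.copy()
    L = state.L
    dead_idx = np.argwhere(H < 0)
    n_dead = len(dead_idx)
    if n_dead == 0:
        return UpdateResult(new_state=state, deaths=0, reseeded=0)
    order = rng.permutation(n_dead)
    reseeded = 0
    # `work` and `res` alias the arrays mutated below, so each iteration sees
    # the lattice as updated by earlier replacements.
    work = LatticeState(cp=cp, mcs=state.mcs)
    res = ResourceField(allocated=G, net=H, total_budget=resources.total_budget)
    for t in order:
        i, j = map(int, dead_idx[t])
        coords = _neighbor_coords(i, j, L)
        if not any(H[a, b_] >= 0 for a, b_ in coords):
            reseeded += 1
        cp[i, j] = select_parent((i, j), work, res, params, rng)
        H[i, j] = 0.0
        G[i, j] = params.consumption
    return UpdateResult(
        new_state=LatticeState(cp=cp, mcs=state.mcs),
        deaths=n_dead,
        reseeded=reseeded,
    )


def death_birth_step(
    state: LatticeState,
    resources: ResourceField,
    params: GameParams,
    rng: np.random.Generator,
) -> UpdateResult:
    """Replace every site with negative net resource.

    All deaths are marked from the same resource snapshot.  In the default
    synchronous mode every replacement draws its parent from the pre-update
    CP field, so a dead site can never parent another and survivors are
    bit-identical across the step.
    """
    if params.replacement == "sequential":
        return _death_birth_sequential(state, resources, params, rng)
    return _death_birth_synchronous(state, resources, params, rng)


def mcs_step(
    state: LatticeState, params: GameParams, rng: np.random.Generator
) -> tuple[LatticeState, StepStats]:
    """One full Monte Carlo step: payoff -> resource -> death-birth."""
    fieldv = payoff_field(state, params)
    resources = distribute_resource(fieldv, params)
    result = death_birth_step(state, resources, params, rng)
    new_cp = result.new_state.cp
    new_state = LatticeState(cp=new_cp, mcs=state.mcs + 1)
    stats = StepStats(
        mean_cp=float(new_cp.mean()),
        std_cp=float(new_cp.std()),  # population std: the lattice is the population
        deaths=result.deaths,
        reseeded=result.reseeded,
    )
    return new_state, stats
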