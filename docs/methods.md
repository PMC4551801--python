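# Methods

## Model

The population is an `L × L` square lattice with periodic boundaries, one
individual per site, each described by a continuous characteristic
parameter (CP) `p ∈ [0, 1]` that serves simultaneously as its mixed
prisoner's-dilemma strategy and as its heritable "gene".  One Monte Carlo
step (MCS) applies three phases to the whole lattice:

1. **Payoff.** `P_i = Σ_j P_ij` over the four von Neumann neighbours, with
   `P_ij = p_i p_j R + (1 − p_i) p_j T + p_i (1 − p_j) S + (1 − p_i)(1 − p_j) P`.
   The default matrix is the rescaled `R = 1, S = 0, T = b, P = 0`; the
   general entries are exposed (`reward`, `sucker`, `punishment`) but not
   used by any shipped experiment.  Because the four pair payoffs depend on
   the neighbours only through the sum of their CPs, the field is computed
   vectorised from one neighbour-sum array; tests pin it to a naive
   double-loop oracle on small lattices.

2. **Resource.** `G_i = G_sys P_i / P_sys` with `G_sys = c L²`, then
   `H_i = G_i − consumption` (consumption defaults to 1, the survival
   threshold).  Conservation `Σ G_i = G_sys` holds to 1e−9 relative and is
   property-tested.  If `P_sys = 0` (reachable only from an all-defector
   lattice under the default matrix) the budget is split equally, which
   preserves conservation and avoids a division by zero.

3. **Death-birth.**  Death is strict: `H_i < 0` dies, `H_i = 0` survives.
   All deaths are marked synchronously from one resource snapshot; each
   dead site is refilled by copying the CP of one of its four neighbours
   that survived (`H ≥ 0` on the same snapshot), chosen with probability
   proportional to its net resource `H` (all surviving weights zero →
   uniform among survivors).  A dead site whose four neighbours all died is
   reseeded with a fresh Uniform(0, 1) draw.  Offspring copy the parent CP
   exactly; there is no mutation, so a step with zero deaths freezes the
   lattice permanently (property-tested).

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `L` | lattice side | 100 | experiments here use 50 (see below) |
| `b` | temptation to defect (T) | 1.1 | dilemma requires b > 1 |
| `c` | resource rate (investment per capita) | 1.01 | budget `c·L²` per MCS |
| `consumption` | survival threshold | 1 | `H_i = G_i − consumption` |
| `mcs_total` | Monte Carlo steps | 1024 | matches the longest snapshot time |
| `steady_window` | averaging window | last 10 %, ≥ 100 | see below |
| `parent_weight` | selection weight | `"net"` (H) | `"gross"` (G) switchable |
| `replacement` | update scheme | `"synchronous"` | `"sequential"` switchable |

## Design choices where the model description is open

- **Initial CPs** are i.i.d. Uniform(0, 1).  This matches the reported
  initial mean of ≈ 0.5 and the near-0.5 long-run mean when selection is
  weak, and is the natural maximum-entropy choice on [0, 1].
- **Selection weight.**  "Proportional to their resources" could mean the
  allocated resource G or the net resource H.  The default is H restricted
  to survivors (all weights then ≥ 0, and H is the quantity that defines
  survival); G is available via `parent_weight="gross"` so both readings
  can be compared.  The death set itself is identical under either reading.
- **Synchrony.**  The three phases are sequential lattice-wide passes, so
  deaths are determined synchronously and all replacements read pre-update
  CPs; a dead neighbour can never be a parent within the step.  The
  alternative `replacement="sequential"` processes dead sites in random
  order and lets an already-refilled site act as a parent carrying net
  resource 0 (it has not played yet).  Survivors are untouched either way.
- **Steady state** is operationalised as a time average over the final
  window (default last 10 % of steps, at least 100).  A convergence test
  would be ill-posed here: for moderate `c` a low death churn persists
  indefinitely (see Limitations), so the dynamics are stationary rather
  than convergent.
- **"Number of dead individuals"** is reported as deaths per MCS averaged
  over the steady window; the cumulative count is also derivable from the
  recorded series (`ObservableSeries.cumulative_deaths`).
- **Reproducibility.**  One `numpy` PCG64 generator per run, seeded from the
  run config.  Sweep replicate seeds derive from
  `SeedSequence((base_seed, b_index, c_index, replicate))`, so every cell's
  stream depends only on its identity: cells can be computed in any order,
  and growing the grid never perturbs existing cells.

## Numerical and degenerate-input choices

- The vectorised death-birth phase draws one uniform field per lattice for
  parent choice and one for reseeding, regardless of how many sites died;
  this keeps the stream layout fixed and the step O(L²).
- Direction choice uses an inverse-CDF scan over the four cumulative
  weights; zero-weight directions can never be selected (also holds at the
  r = 0 boundary).
- Floats are serialised with `%.17g` and parsed in round-trip mode, so every
  CSV artifact reproduces the in-memory doubles bit-exactly.
- `L < 2`, `c ≤ 0`, strategies outside [0, 1], windows longer than the run,
  and selection on a living site all raise `ValueError` with the offending
  quantity named.

## Problem sizes used in tests and the acceptance script

The full-scale reference conditions (L=100, 100 replicates per point) are
scaled to L=50 with 10 replicates of 1024 MCS and a 100-step steady window.  At
this scale the three headline observables are stable across seeds: steady
mean CP ≈ 0.93–0.94 at (b=1.1, c=1.01), ≈ 0.46 at (b=1.9, c=1.9), and an
optimal resource rate of 1.15 on the 0.05-spaced grid at b=1.9.  Spot
checks at L=100 give the same values to within replicate scatter.

## What the synthetic dynamics do and do not show

All data are self-generated by the model; there is no external input.  The
simulations therefore validate the implementation and the model's internal
claims (resource conservation, selection law, frozen-lattice behaviour,
parameter-plane shape), not any empirical ecological system: real
populations have vacancies, noisy payoffs, mutation and non-lattice
contact structure, all deliberately outside this model.

## Known limitations

- A uniform-CP lattice with `c ≥ 1` is absorbing, and any zero-death step
  freezes the lattice; long-run behaviour can depend on freezing time for
  large `c`.
- The lattice does *not* freeze for moderate `c` (e.g. 1.9): a full
  cooperator whose neighbours all defect earns payoff 0, hence `G = 0` and
  `H = −1` at any `c`, so parasite–host geometry sustains a small death
  churn forever.  The abundant-resource steady mean CP consequently sits
  slightly below 0.5 (≈ 0.46 at b=1.9, ≈ 0.49 at b=1.1) rather than exactly
  at the neutral initial mean — "trends to 0.5" is accurate, equality is
  not, and the corresponding three-standard-error check in the test suite
  documents this gap by failing.
- Sweeps run serially; cell independence makes them embarrassingly
  parallel, but no parallel executor is shipped.
- `std_cp` is the population (divide-by-L²) standard deviation: the lattice
  is the whole population, not a sample.
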