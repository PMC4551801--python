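# limres — cooperation on a lattice with limited resource

`limres` simulates a continuous-strategy spatial prisoner's dilemma in which
the environment, not the payoff matrix alone, decides who survives.  It is
aimed at researchers in evolutionary game theory and spatial population
dynamics who want a small, fully reproducible reference implementation of
resource-limited death-birth dynamics.

## The model

Individuals occupy an `L × L` square lattice with periodic boundaries.  Each
carries a heritable *characteristic parameter* (CP) `p ∈ [0, 1]`, its
tendency to cooperate.  One Monte Carlo step (MCS) has three phases:

1. **Payoff.**  Against each of its four von Neumann neighbours the focal
   individual earns the expected prisoner's-dilemma payoff

   ```
   P_ij = p_i p_j R + (1 − p_i) p_j T + p_i (1 − p_j) S + (1 − p_i)(1 − p_j) P
   ```

   with the rescaled matrix `R = 1, S = 0, T = b, P = 0` (so
   `P_ij = p_i p_j + (1 − p_i) p_j b`), and `P_i = Σ_j P_ij`.  For `b > 1`
   a lower CP always earns more against any given neighbour.

2. **Resource distribution.**  A fixed global budget `G_sys = c L²`
   (`c` = investment per individual) is split in proportion to payoff,
   `G_i = G_sys · P_i / P_sys`; after unit consumption the net resource is
   `H_i = G_i − 1`.

3. **Death-birth update.**  Every individual with `H_i < 0` dies and its
   site is refilled by the offspring of a surviving neighbour, chosen with
   probability proportional to its resource; offspring inherit the parent
   CP exactly.  A dead site with no surviving neighbour gets a fresh
   uniform CP.

Because parasites (low CP next to high CP) earn the most and their hosts
the least, scarcity first culls cooperators who failed to cluster — and then
starves the parasites they fed, so clustered cooperators take over the
lattice.  Scarce resource plus low temptation (`c` just above 1, `b ≈ 1.1`)
drives the population mean CP close to 1; abundant resource (`c ≈ 1.9`)
leaves selection weak and the mean near its initial 0.5; at large `b` there
is an interior resource rate (near `c ≈ 1.2`) that maximises cooperation.

## Worked example

```
limres run --L 50 --b 1.1 --c 1.01 --mcs 1024 --seed 7 \
           --snapshots 0,1,8,1024 --out-prefix example
```

prints (to standard error)

```
INFO run: L=50 b=1.1 c=1.01 mcs=1024 seed=7
INFO done: steady mean_cp=0.9389 std_cp=0.1642 deaths/mcs=388.64 (window=102)
```

The steady mean CP of 0.94 is the near-full-cooperation plateau under
scarce resource: starting from a uniform-random lattice (mean 0.50), the
mean first dips (low-CP advantage), then recovers as cooperator clusters
monopolise the resource.  `deaths/mcs` is the persistent turnover rate at
steady state, averaged over the final window of 102 steps.  The command
writes `example_timeseries.csv` (columns `mcs,mean_cp,std_cp,deaths`), one
CP-matrix CSV per snapshot checkpoint, and `example_meta.json` with every
parameter and seed needed to re-run it.

The same pipeline is available as a library:

```python
from limres import GameParams, RunConfig, run_simulation, summarize_steady

config = RunConfig(params=GameParams(L=50, b=1.1, c=1.01), mcs_total=1024, seed=7)
summary = summarize_steady(run_simulation(config))
print(summary.mean_cp)   # 0.938…
```

Parameter-plane sweeps with replicate aggregation:

```
limres sweep --b-range 1.0:2.0:0.05 --c-range 1.0:2.0:0.05 \
             --reps 100 --base-seed 1 --out-prefix plane
```

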