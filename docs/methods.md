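# Methods

## Model

The simulator evolves a discrete-time Markov chain on a fully connected set
of `L` cities. The state is an `L × L` matrix `n[j, x]`: people of origin
`x` currently living in city `j`. Each origin group has its own
column-stochastic transition kernel per step; `w[i, j]` is the probability
that an individual in city `j` moves to city `i`. Total population is
conserved by construction — there is no demography (births, deaths, aging),
only redistribution.

The kernel's stay branch is

    w_jj = 1 − δ + δ (e/β_t)^β_t (n_j/K_j)^β_t exp(−n_j/K_j)

and the move branch (i ≠ j), normalised per column by `C`,

    w_ij = C (Σ_{x≠k} n_i^(x) + γ n_i^(k))^β_t d_ij^(−α) exp(−n_i/K_i).

Assumptions worth making explicit:

- **Synchronous updates.** All `L` kernels for step `t` are computed from
  the state at `t` before anyone moves — standard Markov-chain semantics.
- **Single shared exponent.** One `β_t` per step enters both branches.
- **Homogeneous, static `K`.** Every city has the same characteristic size,
  constant in time. Heterogeneous or dynamic `K` is out of scope.
- **Fully connected geography.** Any city is reachable from any other in
  one step; distance only reweights, it never disconnects.

## Parameters

| name | meaning | units | default |
|------|---------|-------|---------|
| `delta` | max emigrating fraction per step | — | 0.2 |
| `alpha` | distance-deterrence exponent | — | 1 |
| `gamma` | social-tie weight on own-origin people | — | 50 |
| `tau_beta` | mindset timescale | steps | 120 |
| `T` | simulation length | steps | 5000 |
| `n0` | initial natives per city | persons | 3000 |
| `K` | characteristic city size (via the map) | persons | 5000 |
| `epsilon` | extinction threshold at the final step | persons | 1 |
| `L` | number of cities | — | 10 |

`gamma = 1` is the neutral value (the tie numerator collapses to total
destination population); the default 50 is the benchmark configuration the
package's experiments are built around. With `tau_beta = 120` the exponent
`β_t = 1 − e^(−t/τ_β)` is within 1% of 1 after ~550 steps, so a 5,000-step
run spends most of its time in the fully-weighted regime — the interesting
dynamics are in how the early distance-only transient sets the basin the
system settles into.

## Numerical conventions

- `τ_β = 0` is defined as `β_t ≡ 1` for all `t` (the instantaneous-mindset
  limit; the exponential form is undefined there).
- `0^0 := 1`: at `β = 0` the population factor is identically 1, including
  for empty destinations, so the kernel reduces exactly to the
  distance-and-environment-only form. For `β > 0`, `0^β = 0`.
- `(e/β)^β → 1` as `β → 0` (limit value used at `β = 0`). The stay-branch
  bonus `(e/β)^β (n/K)^β e^{−n/K}` is evaluated in log space,
  `exp(β(1 + ln(n/K) − ln β) − n/K)`, which is stable for arbitrarily small
  `β` and gives the empty-city value 0 without special-casing.
- **Degenerate columns.** If every off-diagonal raw weight of a column is
  zero (e.g. all other cities empty while `β > 0`), the would-be emigrant
  fraction has nowhere admissible to go: the stay probability is forced to
  1 and the column becomes an identity column, conserving mass.
- `β_t` is evaluated at the current step index (`t = 0` for the first
  kernel).
- Kernel columns sum to 1 within 1e−12; the kernel is invariant under any
  uniform rescaling of map coordinates because the normalisation constant
  absorbs the global `d^(−α)` scale.
- No flooring or truncation of small populations during a run; extinction
  is a *measurement* applied at the final step only (strict inequality:
  population `> ε` survives). Deterministic flows never reach exactly
  zero, so "fewer than one whole person" (`ε = 1`) is the operational
  reading of an extinct city; the stochastic mode can use `ε = 0`.
- Quartiles in boxplot summaries use linear interpolation between order
  statistics; whiskers extend to the most extreme points within 1.5 IQR of
  the quartiles, everything beyond is an outlier. The whisker/outlier split
  depends on this quartile rule, which is why it is pinned here.

## Update modes

The default mode propagates *expected flows*: `n'[i,k] = Σ_j w_k[i,j]
n[j,k]` with real-valued populations, giving smooth, bit-reproducible
trajectories; per-origin totals are conserved to ~1e−9 relative (float
roundoff only). The production path factorises the update into one matrix
product per step rather than materialising all `L` kernels; a test pins it
to the explicit kernel-propagation path at 1e−12.

The *stochastic* mode instead deals each (city, origin) cell's integer
individuals to destinations with a multinomial draw from that cell's
column. Totals are then conserved exactly as integers and runs are
reproducible under a seed. It is the agent-level counterpart of the same
chain (its single-step mean is the expected flow); ensemble experiments use
the deterministic mode, attributing across-run variability entirely to the
random maps.

## Synthetic maps

Every simulation runs on a randomly generated map: `L` points uniform on
the unit square, all with the same `K`, resampled until every pairwise
distance is at least `d_min = 0.05` (the inverse-distance factor diverges
for coincident cities, and scale invariance makes the domain size
irrelevant — only the shape of the point pattern matters). This emulates an
abstract, spatially disordered settlement system. It does **not** emulate
real geography: no clustering, no rivers/coasts, no heterogeneous carrying
capacities, no empirically calibrated distances. Passing tests therefore
demonstrate the model's internal mechanics and qualitative trends on
disordered maps, not predictive validity for any real migration system.

## Experiments and problem sizes

- **Legacy effect** (`legacy_effect`): several `τ_β` values run on one
  shared map; final states are compared by the maximum absolute per-city
  total-population difference, with 10 persons as the threshold for calling
  two final states different (the underlying claim is qualitative; the
  threshold makes it testable).
- **Survival vs K** (`k_sweep`): mean surviving-city count per `K`, fresh
  random map per run. The package default is 100 maps per `K` cell — the
  scale at which the decreasing trend (Spearman ρ ≤ 0 across
  K ∈ {4000…12000}) is already unambiguous; larger ensembles sharpen the
  curve but do not change its direction.
- **Diversity vs γ** (`gamma_diversity`): surviving-city Simpson indices
  pooled across runs and across the K grid, grouped by the run's
  surviving-city count (with a single survivor, `S = L` by construction,
  so survival count must be conditioned on). The trend test uses 30
  realizations per (γ, K) cell and only inspects groups with at least 30
  pooled cities, allowing a 0.05 noise margin on median comparisons.
- Per-run seeds are derived from `(master_seed, cell index, replicate)`
  via a seed sequence, recorded in every summary, and kept below 2^31; any
  run can be replayed in isolation and aggregation is order-independent.

## Known limitations

- Directions of the ensemble trends, not exact curve values, are the
  stable surface: single-map trajectories and per-cell statistics depend
  on the particular random maps drawn.
- The γ grids are configurable defaults ({1, 10, 50}), not canonical
  values.
- Deterministic mode moves fractional people; interpret small populations
  as expectations, not counts.
- `K` heterogeneity, time-varying `K`, births/deaths, and real-world
  calibration are all out of scope by design.
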