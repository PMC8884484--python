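# chase

A Markov-chain simulator of human migration between cities, driven by four
interacting forces: **CH**anging mindset, **A**gglomeration, **S**ocial
ties, and the **E**nvironment.

## The model

The system is `L` cities placed at random on a plane; city `j` starts with
`n0` natives and can comfortably support a characteristic population `K_j`.
People carry their origin label forever (no births or deaths). The
probability that an individual of origin `k` moves from city `j` to city
`i` during step `t` is

```
w_jj = 1 - δ + δ (e/β_t)^β_t (n_j/K_j)^β_t exp(-n_j/K_j)          (stay)
w_ij = C (Σ_{x≠k} n_i^(x) + γ n_i^(k))^β_t d_ij^(-α) exp(-n_i/K_i)  (move, i≠j)
```

where `n_j = Σ_x n_j^(x)` is city `j`'s total population, `d_ij` the
Euclidean distance, and `C` normalises each column to sum to one. The
pieces:

- `δ` — the maximum fraction of a city that can emigrate in one step;
- `(n_i)^β_t` — agglomeration: bigger destinations mean more opportunity;
- `γ` — social ties: people of one's own origin at a destination count
  `γ`-fold (`γ = 1` is neutral — the numerator is then just the total
  population);
- `exp(-n_i/K_i)` — Ricker-style environmental pressure: over-full cities
  repel;
- `β_t = 1 - e^(-t/τ_β)` — the mindset schedule: right after a shock people
  weigh only distance (`β ≈ 0`); as they settle, opportunities and ties
  enter their decisions (`β → 1`) on a timescale `τ_β`. `τ_β = 0` pins
  `β_t = 1` throughout.

The stay-branch factor `(e/β)^β (n/K)^β e^{-n/K}` peaks at exactly 1 (at
`n = βK`), so `1 - δ ≤ w_jj ≤ 1` always. At the end of a run each city gets
an inverse Simpson diversity index `S_j = 1/Σ_x (p_j^(x))²` — 1 when
everyone shares one origin, `L` when all origins are equally represented, 0
for an empty city — and a city *survives* if its final population exceeds
the extinction threshold `ε` (default 1 person).

## Worked example

```python
from chase import ModelParameters, generate_map, run, city_diversity

cmap = generate_map(L=10, K_value=5000.0, seed=7)   # 10 random cities
params = ModelParameters()   # δ=0.2, α=1, γ=50, τ_β=120, T=5000, n0=3000
res = run(cmap, params, record="final")
div = city_diversity(res.final_state, params.epsilon)
print(f"total population : {res.total_population():.1f}")
print(f"surviving cities : {div.count_surviving}")
print(f"diversity (S)    : {[round(float(s), 2) for s in div.surviving_S()]}")
```

prints

```
total population : 30000.0
surviving cities : 5
diversity (S)    : [9.37, 9.75, 9.54, 9.67, 9.27]
```

All 30,000 people are still accounted for after 5,000 steps (the kernels
are column-stochastic, so mass is conserved to machine precision), the ten
initial cities have consolidated into five, and with the slow mindset
schedule and strong ties of the benchmark each survivor ends up housing a
broad mix of origins (`S` between 9.2 and 9.8 out of a maximum of 10).

The same is available from a shell:

```bash
chase simulate --seed 7 --out out/run7        # trajectory.csv, metrics.csv, run.json
chase sweep-k --seed 1 --n-maps 100 --out out/sweep   # surviving cities vs K
chase diversity --seed 1 --out out/div        # diversity vs γ, grouped by survival
chase legacy --seed 1 --out out/legacy        # final states across τ_β on one map
```

Ensemble experiments derive every per-run seed from the master seed, record
them all, and are exactly reproducible; any single run can be replayed from
its recorded seed.

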