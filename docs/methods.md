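# Methods

Technical notes for `feednet`: what each iteration simulates, the equations
and default parameters, the numerical contracts the tests enforce, and the
model's limitations.

## 1. Framing

One iteration = one pen of 200 steers observed at its baseline marketing
endpoint **EP1** and three hypothetical extensions **EP2/EP3/EP4** at +14,
+28, +42 days on feed (DOF). For each later endpoint and each sale basis
(live, dressed-cash, grid) the model computes a **partial budget**:

```
ΔNR_pen  = TR_EPι − TC_EPι − TR_EP1
ΔNR_head = ΔNR_pen / (Hd_EPι + Rem_total_EPι)
```

where `TR` is total revenue (pen sale plus any removal salvage), `TC` is the
*added* cost of the extra feeding period (opportunity cost + feed/yardage +
health), and the denominator is animals marketed (surviving head plus
removals sold along the way). Costs before EP1 are out of scope, so ΔNR is
the value of waiting, not profit.

## 2. Stochastic inputs, in draw order

Each iteration `i` owns the RNG stream `PCG64(SeedSequence((master_seed, i)))`
and consumes it in a **frozen order** (changing this order is a breaking
change; the dual-path equivalence and restart-invariance tests pin it):

| # | Draw | Distribution / default |
|---|------|------------------------|
| 1 | EP1 final body weight, hot carcass weight | correlated normals, FBW 667 ± 11.4 kg, HCW 431 ± 8.62 kg |
| 2 | live & carcass daily gain | correlated normals, 1.32 ± 0.06 and 1.00 ± 0.04 kg/d |
| 3 | YG cumulative-logit thresholds (4) | correlated logistics, locations −3.59/−1.72/0.15/2.29, scales ≈ 0.17 |
| 4 | QG cumulative-logit thresholds (3) | correlated logistics, locations −3.67/0.82/4.62, scales 0.332/0.322/0.362 |
| 5 | YG shift coefficients β (EP2/3/4) | correlated logistics |
| 6 | QG shift coefficients β (EP2/3/4) | correlated logistics |
| 7 | health events ×3 intervals | Poisson; morbidity / mortality / removal per interval, in that order |
| 8 | dry-matter intake | normal, 10.5 ± 0.58 kg/animal/d |
| 9 | corn price | log-normal, 6.00 ± 1.10 $/bu |
| 10 | live fed-cattle prices (4 EPs) | log-normals, each 152 ± 25.1 $/cwt, correlated across EPs |
| 11 | QG grid pick | uniform over grids 1–3 |
| 12 | interest rate pick | uniform over 5/7/9 %/yr |

Log-normal draws are moment-matched: `σ² = ln(1 + sd²/mean²)`,
`μ = ln(mean) − σ²/2`, so the arithmetic mean and SD equal the stated values
and the median is `mean/√(1+cv²)` (149.97 $/cwt for live price).

**Correlation machinery.** Correlated non-normal draws use a Gaussian
copula: standard normals are correlated through the Cholesky factor of the
target correlation matrix, mapped to uniforms by the normal CDF, then through
the target family's quantile function (logistic:
`loc + scale·ln(u/(1−u))`). This keeps every stated marginal exact while
imposing the dependence structure. The Cholesky product is applied by
explicit column accumulation (not BLAS `@`) so scalar and batched paths are
bitwise identical.

## 3. Biology

- Weights extend linearly: `W_EPι = W_EP1 + gain × extra_DOF`, the same drawn
  gains reused across a pen's endpoints (no quadratic growth term).
- Heavyweight carcass fraction: `1 − Φ((476 − HCW)/38.6)` — the within-pen
  HCW spread is a fixed 38.6 kg normal; 476 kg is the grid's heavy threshold.
- Grade proportions: thresholds are cumulative log odds ordered
  best-grade-first; differencing the logistic CDF gives the pen's proportion
  vector (Prime, Choice, Select, sub-Select; YG5…YG1). Later endpoints add
  the drawn β to every threshold (proportional odds), moving mass toward
  higher grades. Simulated threshold vectors that lose strict ordering are
  redrawn (≤100 attempts) then sorted as a last resort; repairs are counted
  and logged.

## 4. Health ledger

Events per 14-day interval are Poisson with per-animal-day rates
(morbidity 0.29, removal 0.18, mortality 0.09 per 1,000 animal-days,
stored ÷1000). Expected exposure is `head × 14`; realized animal-days charge
fallouts for half the interval: `HdDays = head×14 − (mort + rem)×7`. Events
carry over: the head count entering each interval is reduced by prior
mortalities and removals, and cumulative totals feed costs and revenue. If a
draw would exceed the remaining head count, removals are truncated first,
then mortalities. With no fallouts, cumulative exposure is exactly
2,800 / 5,600 / 8,400 animal-days at EP2/3/4.

## 5. Markets and prices

- Dressed base price = live price ÷ 0.63 (fixed dressing percentage).
- Feed-and-yardage price ($/dry US ton): `FYP = 26.80 + 71.64·corn − 2.97·corn²`.
- Removal (railer) salvage price: `0.92 × (−27.18 + 1.30 × live price)`,
  evaluated at the prior endpoint's live price and the prior endpoint's HCW.
- Grid adjustment ($/cwt): `QG·γ_QG + YG·γ_YG + heavy_frac × (−16.50)` —
  dot products of the pen's grade proportion vectors with the premium/
  discount vectors of the drawn grid. The three shipped QG grids span
  Choice-Select spreads of −5 / −17.5 / −30 $/cwt; YG premiums are
  (5, 2, 0, −10, −14) for YG1…YG5. The sub-Select discount follows the
  quadratic `−14.61 + P + 0.004·P²` in the Select discount `P`, rounded to
  the nearest $0.25 (−19.50 / −31.00 / −41.00).

## 6. Economics

With `cwt = 45.4 kg`, `ton = 907 kg`, and `ifrac = rate × extra_DOF / 365`:

- Revenue: live `head × FBW × price / 45.4`; dressed `head × HCW × base /
  45.4`; grid the dressed form with `base + grid_adjustment`.
- Opportunity cost: `TR_EP1(basis) × ifrac` — interest forgone on the
  baseline revenue while waiting (hence basis-specific).
- Feed & yardage: `FYP/907 × DMI × realized animal-days × (1 + ifrac/2)`
  (feed financed for half the period on average).
- Health: `23.60 × morbidity + 40.50 × mortality` (cumulative counts).
- Degenerate-world identity (tested): with all SDs zero, gains zero, rates
  zero, and hence equal prices across endpoints,
  `ΔNR_head = −(OC + FYC)/200` exactly.
- Currency conservation (tested on every iteration): the per-head figure
  times animals marketed equals the reconstructed `TR − TC − TR_EP1` to 1e−6.

## 7. Engine and convergence

`run_simulation` returns one row per iteration (~115 columns: inputs,
per-endpoint biology, grade vectors, health totals, costs, ΔNR per basis).
Two code paths share the same draws: the default vectorized path and a
scalar per-pen reference path (`vectorized=False`) that serves as its oracle;
their outputs are bitwise identical. Per-iteration streams also make runs
restartable: `run(n=100)` equals `run(n=60)` stacked with
`run(n=40, start=60)`.

`run_to_convergence` starts at 135,000 iterations and adds blocks of 45,000
until, for all nine ΔNR series, every percentile in
(0.5, 2.5, 10, 25, 75, 90, 97.5, 99.5) changes by <1% relative (denominator
floored at $0.01; the median is excluded since it sits near zero). Throughput
is roughly 2,000 iterations/s on one CPU core, so a 360,000-iteration run
completes in a few minutes.

## 8. Placeholder correlation matrices and limitations

The originally estimated within-variable correlation matrices (live prices
across endpoints; YG/QG thresholds; shift coefficients) were published only
as supplementary material and are **not** shipped. Defaults are clearly
labelled placeholders in the YAML and warned about at load: AR(1) ρ = 0.95
for the 4-endpoint price block, exponential-decay ρ = 0.8 adjacent for grade
threshold/β blocks, ρ = 0.9 for the 2×2 weight and gain blocks.

Consequences:

- Medians of marginal quantities (prices, grade proportions at edge
  categories, opportunity costs) are insensitive and reproduce reference
  values; distribution **tails and spreads are placeholder-sensitive** and
  should not be quoted without supplying the estimated matrices.
- Known artifact: the median of an *interior* cumulative-logit category
  (e.g. YG 3) shrinks slightly (~0.35 pp at adjacent ρ = 0.8) below its
  closed-form value, because the category proportion is a concave function
  of two imperfectly correlated thresholds. With near-parallel threshold
  jitter (ρ ≥ ~0.95) the shrinkage vanishes.

Other limitations: pen-level resolution only (no individual animals); linear
growth over the 42-day horizon; fixed dressing percentage; no price
seasonality; 14-day interval granularity for health events; removal salvage
uses prior-endpoint weight/price as an approximation.
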