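# feednet

Stochastic pen-level simulation of the **marginal economics of extending
days-on-feed for feedlot steers**.

A feedlot manager holding a 200-head pen of steers at its planned marketing
endpoint (EP1) can instead feed the pen 14, 28, or 42 more days (EP2-EP4).
Longer feeding adds carcass weight and shifts Quality and Yield Grade
distributions upward, but also accrues feed, yardage, interest
(opportunity-cost), and health-event costs, exposes the pen to heavier-carcass
discounts, and gambles on where fed-cattle and corn prices move. `feednet`
quantifies that trade-off by Monte-Carlo simulation: each iteration draws one
pen's biology, health path, and market conditions, then computes the
**net-return difference versus selling at EP1** (Δ net return, $/animal
marketed) under three sale bases — live weight, dressed (carcass) cash, and a
quality/yield grid.

The model is a partial budget: only what changes after EP1 is counted, so the
output is the distribution of the gain or loss from *waiting*, not overall
profitability.

## Model in one paragraph

Each iteration simulates: EP1 final body weight and hot carcass weight
(correlated normals) extended linearly by drawn live/carcass daily gains; a
heavyweight-carcass fraction from a normal tail above 476 kg; Yield and
Quality Grade pen proportions from correlated logistic draws on
cumulative-logit thresholds, shifted at later endpoints by drawn
proportional-odds coefficients; Poisson morbidity, mortality, and
pen-removal counts per 14-day interval with head-count and animal-day
carry-over; log-normal corn and fed-cattle prices (the four endpoint prices
correlated, dressed base = live / 0.63); feed-and-yardage price from a corn
regression; one of three Choice-Select-spread grids and one of three interest
rates per iteration; and finally revenues, added costs, and the per-animal
net-return difference for EP2/3/4 under each sale basis. Full equations and
assumptions: [docs/methods.md](docs/methods.md).

## Worked example

```python
from feednet import load_defaults, summaries
from feednet.engine import run_simulation

params, corrs = load_defaults()
results = run_simulation(params, corrs, n=20_000, master_seed=7)

print(summaries.percentile_table(results, percentiles=(2.5, 25, 50, 75, 97.5)).round(2))
```

```
                    2.5     25.0   50.0    75.0    97.5
basis   endpoint
live    EP2      -238.30  -85.02  -6.74   71.39  238.06
        EP3      -348.74 -125.87 -12.40  100.04  331.92
        EP4      -426.36 -153.98 -17.66  119.09  411.56
dressed EP2      -231.66  -75.16   5.23   85.99  258.56
        EP3      -334.25 -105.70  10.88  127.35  370.18
        EP4      -403.12 -123.34  17.67  160.65  465.28
grid    EP2      -245.80  -89.37  -8.78   71.87  244.46
        EP3      -370.79 -140.34 -24.50   92.64  334.37
        EP4      -478.42 -195.13 -53.28   91.18  395.53
```

Median net-return differences are negative on the live and grid bases
(waiting usually loses money, and the grid compounds losses at later
endpoints through carcass discounts) but positive and growing on the
dressed-cash basis, where added carcass weight is paid for directly.

```python
print(summaries.opportunity_cost_by_rate(results, basis="live").round(2))
```

```
               median  p2.5  p97.5      n
interest_rate
0.05             4.22  3.09   5.87  20127
0.07             5.90  4.27   8.14  19806
0.09             7.63  5.53  10.54  20067
```

Other surfaces: `summaries.categorize` (five net-return categories),
`summaries.grid_frequency`, `summaries.describe_by_category`, and
`summaries.plot_dnr_distributions` (needs the `plots` extra).

## Command line

```bash
feednet run --n 100000 --seed 1 --out results.csv     # one fixed-size run
feednet converge --seed 1 --out results.csv           # grow until percentiles stabilize
feednet summarize --in results.csv --out summaries/   # percentile/category tables
feednet run --n 1000 --seed 1 --out r.csv --reference # slow scalar oracle path
```

All runs are deterministic given `--seed`; each iteration has its own RNG
stream, so extending a run (the `converge` loop) never changes earlier
iterations, and the vectorized and reference paths produce bitwise-identical
tables.

## Configuration

Every parameter (means/SDs, rates, grids, regression coefficients,
correlation matrices) lives in `src/feednet/data/default_params.yaml` and can
be overridden from a YAML file via `--config` or
`feednet.params.load_overrides`. **Note:** the shipped within-variable
correlation matrices (endpoint-to-endpoint prices, grade thresholds) are
labelled placeholders — the originally estimated matrices were published only
as supplementary material. Distribution tails are sensitive to them; medians
and the reproduction targets below are not. Supply your own matrices for
faithful tail spreads.

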