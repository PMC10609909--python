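# cambium

Process-based simulation of conifer cambial activity: how many xylem cells a
tree's radial file produces in a growing season, and when.

Tree rings are built by the cambium, a thin meristem whose cells divide
through the G1→S→G2→M cycle during the growing season.  This package
simulates one radial file of cambial cells, forced by a single daily
environmental variable — the integral growth rate Gr(t) ∈ [0, 1] produced
upstream from temperature, moisture and photoperiod — and regulated
internally by a growth inhibitor (an auxin/cytokinin- or sugar/enzyme-balance
analogue) whose concentration gradient maintains the cambial zone.  It is
written for dendroecologists and tree-ring modellers who need annual cell
production and within-season division kinetics without manual year-to-year
recalibration.

## Model

One season starts with a single initial cell (diameter `D_init`) holding the
whole seasonal inhibitor supply `Inht_i`.  Cells change phase when their
diameter reaches critical sizes `D_S < D_G2 < D_M < D_div`; growth in S/G2/M
runs at the constant rate `V0`, growth in G1 follows a Gompertz function of
the cell's inhibitor concentration `C = Inht/D`:

    v = exp(−exp(−c·C))             (optimal conditions)
    v = exp(−exp(−c·S·C))           (division flagged by a stress window)
    v = (D_div − D_init)/d          (first division of the initial cell)

A division splits the mother into two half-size G1 daughters and partitions
her inhibitor asymmetrically: the share α goes to the daughter closer to the
initial cell, 1−α to the distal one.  A cell whose concentration falls below
`C_min` (checked at birth and at the division diameter) loses the ability to
divide and is exported to the enlargement zone; the season's export count is
the **cell production**, the tree-ring cell-count proxy.  A division is
stress-flagged when the daily growth rate declined strictly for three or
more consecutive days immediately before it.  The season ends when the
environmental season ends or when no cell in the row retains a divisible
concentration.

The seasonal supply itself is predicted from the distribution of the daily
growth rates:

    Inht_i = 1.184 + 9.44·sd(Gr_i) + 2.0209·median(Gr_i) − 3.4693·mad(Gr_i)
             − 16.5541·min(Gr_i) − 1.4214·max(Gr_i) − 0.3408·skew(Gr_{i−1})

and can be refit per study by ordinary least squares from per-season
training pairs.  A calibration harness inverts the simulator for observed
cell counts (monotone bisection), scores calibration/verification splits
(R² as squared Pearson correlation), and tunes parameters on an "average
growth season".  A synthetic-data generator provides seasons and full
multi-year studies with known ground truth.

## Worked example

```python
from cambium import (FixtureConfig, ParameterSet, gen_growth_series,
                     predict_supply, season_stats, simulate_season)

# a noise-free sine-arch season over DOY 127-285
cfg = FixtureConfig(n_years=1, seed=7, ar_sigma=0.0, dips_range=(0, 0),
                    peak_sd=0.0, bounds_jitter_sd=0.0,
                    baseline_range=(0.0225, 0.0225),
                    drought_depth_range=(0.0, 0.0))
season = gen_growth_series(cfg)[1963]

stats = season_stats(season)          # sd=0.2963 median=0.6875 mad=0.2373
supply = predict_supply(stats, 0.0)   # SupplyPrediction(value=2.7927, ...)
result = simulate_season(season, ParameterSet(), supply.value)
print(result.production, result.simulated_season_length,
      result.termination_reason)
# 19 130.034 supply_consumed
```

The regression assigns this season a supply of 2.79 relative units; the
simulator turns it into 19 exported cells (the magnitude of observed larch
production, low tens per year) over a simulated season of 130.0 days — about
29 days shorter than the 159-day environmental season, because the supply is
exhausted first.  The first division happens at day 7.5 (the initial cell's
linear first cycle); each division is logged with its phase timings at
0.001-day resolution, e.g. the second division:

    appearance 7.500  G1 9.933  S 0.294  G2 0.441  M 0.735  cycle 11.404
    inhibitor received 2.314  concentration at M 0.2436  cell 0.p  mother 0

The same workflow is available from the shell:

```bash
cambium synth --out fx --years 40 --seed 1
cambium reconstruct --series fx/series.csv --regression fx/regression.json --out rec
cambium fit-regression --series fx/series.csv --observed fx/production.csv --out fit
cambium report --series fx/series.csv --observed fx/production.csv \
    --calibration-years 1989-2002 --verification-years 1963-1988 --out rep
```

## Documentation

`docs/methods.md` describes the model assumptions, every tunable parameter
with units and defaults, what the synthetic generator does and does not
emulate, and the numerical choices (event solving, tie-breaks, degenerate
inputs) in detail.
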