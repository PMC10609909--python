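# Methods

## Model

The package simulates the cell-division activity of one radial file of
conifer cambium over a growing season.  The governing hypothesis is that a
growth inhibitor — a stand-in for the auxin/cytokinin or sugar/enzyme
balance — is deposited once per season in the initial cell and thereafter
only redistributed: every division hands the share α of the mother's
inhibitor amount to the proximal daughter (the one nearer the initial cell)
and 1−α to the distal one, so amounts are conserved exactly and a declining
concentration gradient forms away from the initial cell.  Division ability
is concentration-gated: a cell whose inhibitor concentration `C = Inht/D`
(amount per micron of radial diameter) is below `C_min` at birth, or when it
reaches the division diameter, is exported to the enlargement zone instead
of dividing.  The number of exports per season is the annual cell
production, the quantity compared against anatomical cell counts.

Phase identity is purely size-based: a cell is in G1, S, G2 or M according
to its diameter relative to the critical sizes `D_S < D_G2 < D_M < D_div`,
and transitions fire exactly when the diameter crosses a threshold.  Growth
is piecewise linear: rate `V0` in S/G2/M, and in G1 a Gompertz function of
the cell's own current concentration, `v = exp(−exp(−c·C))`, which is small
for inhibitor-poor cells (asymptote `e^{−1} ≈ 0.368` at `C = 0` times
nothing — the function's floor — rising towards 1 μm/day as `C` grows).
The environment enters three ways: the daily integral growth rate series
delimits the season; a strictly-decreasing run of three or more daily steps
immediately before a division flags that division (and its daughters' G1
regime) as stress-induced; and the seasonal inhibitor supply is predicted
from the season's rate distribution (below).  The cell cycle itself is
otherwise internal — consistent with the observation that cambial kinetics
track the environment mainly through the supply and the stress windows.

The dormant initial cell is special on two counts.  Its first cycle runs at
the fixed linear rate `(D_div − D_init)/d_init`, carrying it from its small
post-dormancy diameter to its first division in `d_init` days regardless of
concentration.  And it never exports: when its concentration falls below
`C_min` at the division diameter it simply stops, and the row can only
drain.  After each of its divisions the proximal daughter *is* the initial
cell (position 0) and uses the ordinary G1→M machinery from half size.

A season terminates when the environmental season ends, or at the end of
the first day on which no cell in the row — initial included — has a
concentration of at least `C_min`.  Because amounts are conserved, "supply
consumed" can only mean exhaustion of divisibility, not of substance; once
no cell can ever divide again, cells still growing toward the division
diameter would only be exported later, so the day-end check is the natural
cut.  The simulated season length is the time of the last in-row event
(reported at 0.001-day resolution), or the environmental length if that is
reached first.

## Parameters

| name | meaning | units | default |
|---|---|---|---|
| `D_S` | G1→S critical diameter | μm | 8.5 |
| `D_G2` | S→G2 critical diameter | μm | 8.7 |
| `D_M` | G2→M critical diameter | μm | 9.0 |
| `D_div` | division diameter | μm | 9.5 |
| `C_min` | minimum divisible concentration | rel. units/μm | 0.03 |
| `V0` | S/G2/M growth rate | μm/day | 0.68 |
| `c` | G1 Gompertz rate parameter | rel. units | 0.071 |
| `D_init` | initial-cell diameter after dormancy | μm | 2.0 |
| `S_stress` | stress coefficient in the G1 exponent | rel. units | 100 |
| `alpha` | proximal daughter's inhibitor share | — | 0.8286 |
| `d_init` | duration of the initial cell's first cycle | days | 7.5 |
| `stress_mode` | `literal` or `reciprocal` (below) | — | `literal` |
| `g1_env_coupling` | `none` or `multiplicative` (below) | — | `none` |

The diameters, `C_min`, `V0`, `c`, `S_stress` and `alpha` are the published
season-invariant values for Siberian larch.  `d_init` has no published
value; 7.5 days makes the first cycle's linear rate exactly 1 μm/day and
places the first division in the second week of the season, consistent with
the reported kinetics; it is a configuration parameter, not a fitted one.

Two model ambiguities are exposed as switches rather than silently
resolved.  **Stress direction**: as written, the stressed G1 rate multiplies
the exponent argument by `S_stress = 100`, which *raises* the rate towards
its asymptote — yet stress is described as slowing cambial growth.  The
default (`literal`) is faithful to the equation; `reciprocal` divides by
`S_stress` instead and slows stressed cells, and the direction-sensitive
property test asserts each mode under its own sign.  **Environmental
coupling**: the G1 rate equation contains no daily-rate term, although the
simulated G1 kinetics are reported to track the external rate; the default
(`none`) is again literal, and `multiplicative` scales the G1 rate by the
day's growth rate for users who want the coupled variant.

## Seasonal supply regression

The supply placed in the initial cell is a linear function of the current
season's daily-rate distribution and the previous season's asymmetry:

    Inht_i = 1.184 + 9.44·sd + 2.0209·median − 3.4693·mad
             − 16.5541·min − 1.4214·max − 0.3408·skew(previous season)

Statistical conventions are configurable because the published coefficients
were fitted under a fixed but unrecorded convention: `sd` uses the sample
(n−1) denominator, `mad` is the raw median absolute deviation (a
normal-consistency factor can be applied via `mad_scale`), and `skew` is the
population moment coefficient `g1 = m3/m2^1.5`, defined as 0 for constant
sequences.  The first season of a record has no predecessor; its
previous-season skewness defaults to 0 and is configurable.  A nonpositive
predicted supply is returned unchanged but flagged; the season simulator
treats any supply ≤ `C_min·D_init` as "no growth possible" and reports zero
production without stepping.  Refitting uses ordinary least squares
(statsmodels) and requires at least seven seasons with a full-rank design.

## Numerical scheme

Within a day every cell advances independently — cells interact only
through the division-time inhibitor split — so the engine resolves each
cell's events analytically: phase-boundary crossing times are solved
exactly as `(threshold − diameter)/rate`, and the G1 rate is held constant
between re-evaluations at day boundaries, phase entries and births.  The
day is the natural re-evaluation grid because the forcing is daily.
Daughters born mid-day continue advancing for the remainder of that day.
Division, export and phase times are exact to floating precision and
reported rounded to 0.001 days.  The engine is deterministic: identical
inputs give byte-identical division logs.

The test suite checks this event-driven integration against a naive
fixed-step integrator (dt = 0.0005 days, same model semantics, thresholds
checked after every step) on five generated seasons; productions agree
within one cell and event times within 0.01 days.  Ties break as follows:
a concentration exactly equal to `C_min` retains division ability ("reaches
the threshold" is read strictly); a supply exactly equal to `C_min·D_init`
counts as degenerate (production 0).  Lineage IDs are dotted path strings —
initial cell `0`, daughters appending `.p`/`.d` — so logs are comparable
across engines and runs.  After an export, distal cells shift down one
position so the row stays contiguous with the initial cell at 0.

Supply inversion (`infer_supply_for_production`) exploits the monotone
trend of production in supply: the upper bracket doubles until the target
production is reached, then bisection finds the smallest sufficient supply
to 1e-4 relative precision.  Production is an integer step function whose
jumps can exceed one cell (a newly divisible subtree exports several
descendants), so some targets are unattainable on a given season; these
return the closest achievable production with an `unattained` flag rather
than an error.  Average-season calibration uses a deterministic bounded
start grid followed by Nelder–Mead polish; the grid stage is essential
because the production term of the objective is piecewise constant and a
purely local simplex can stall on a plateau.  If the initial configuration
already meets the targets it is returned unchanged.  R² is the squared
Pearson correlation throughout, matching the convention in which the
reported R and R² values are consistent (r = 0.715 ↔ R² ≈ 0.51).

## Synthetic data

No forcing or anatomical series are deposited for the study system
("data available on request"), so the generator supplies the study
conditions: ~40 seasons over average bounds DOY 127–285 (a 159-day season)
with a few days of inter-annual jitter; a sine-arch daily-rate curve with a
small nonzero edge level, because the upstream season is bounded where the
rate crosses a critical value, not where it vanishes; a mid-summer drought
depression of year-varying severity (0–55% deep), the bimodal curve shape
characteristic of semi-arid sites, which is also the main source of
realistic inter-annual variability in the supply; AR(1) daily noise
(σ = 0.04, ρ = 0.6); and zero to three injected strictly-decreasing stress
dips of 3–6 days per season.  Under these defaults the regression assigns
supplies of roughly 1.8–3.4 relative units and the simulator produces
11–24 cells per year (mean ≈ 19), matching the observed low-tens magnitude
(series mean 22.7 cells).

The generator does **not** emulate actual station climate, the upstream
temperature/moisture/photoperiod partial rates, autocorrelation between
consecutive seasons' shapes, or measurement error in anatomical counts
beyond two simple observation-noise models (±1-cell rounding error or
Poisson resampling).  Recovery tests passing on these fixtures therefore
demonstrate that the pipeline is self-consistent — supplies and
coefficients are recoverable when the data really were generated by the
model — not that the model fits any particular forest.  With the stated
supply noise (sd = 0.15 × mean supply over 40 seasons) the refit regression
recovers the noise-free supplies with R² ≈ 0.95 and coefficients within
three standard errors; the simulated-vs-observed production R² under that
noise is intrinsically bounded well below 1 because the observations
themselves inherit the noise.

Problem sizes used by the tests — 40-year fixtures for recovery, five
seasons for the fixed-step cross-check, 20-point supply grids for
monotonicity — keep the full suite under ten seconds while exercising
multi-generation division trees end to end.

## Known limitations

- Everything after export is out of scope: cell enlargement, wall
  thickening and lignification are not modelled, so simulated season
  lengths end with the last division-zone event and are systematically
  shorter than environmental seasons (the same direction as reported for
  the original study, where the difference averaged 35.5 days).
- Phloem-side production is ignored; all daughters are treated as
  xylem-bound.
- The upstream environmental model is consumed as a daily-rate CSV, never
  recomputed from climate.
- The literal stress mode follows the published equation even though its
  direction is biologically doubtful; choose `reciprocal` for
  direction-consistent experiments.
- Production is non-decreasing in supply in all tested conditions, but the
  step structure means inversion targets between steps are unattainable;
  calibration against observed counts should expect exact hits only on
  attainable values.
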