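# raincross

Two-stage analysis of the association between cumulative precipitation
and diarrheal mortality across climate zones.

Diarrheal disease transmission responds to both ends of the
precipitation distribution: heavy rain mobilises enteric pathogens and
contaminates drinking water, while prolonged dry spells concentrate
pathogens and degrade water, sanitation and hygiene. `raincross`
implements the standard epidemiological design for quantifying this at
multi-country scale from daily death counts and weather series, for
researchers working with national vital-statistics data (which are
typically not publicly shareable — hence the package ships a
synthetic-data generator with known ground truth, so the entire pipeline
is testable end to end without any restricted data).

## The model

**Stage 1 — per location (time-stratified case-crossover).** For each
within-country climatic region, daily deaths follow a conditional
quasi-Poisson model

    ln E[Y_t] = alpha_c + f(rain_t; beta) + s(temp_t, l; theta) + I(month_t; gamma)

with strata c = year × quarterly months × day of week (intercepts
profiled out exactly), `f` a natural cubic spline of the prior 28-day
precipitation sum (knots at the 50th/90th percentiles), `s` a
temperature exposure–lag cross-basis over lags 0–28 (knots at the
33rd/67th temperature percentiles; lag knots log-spaced), and eleven
month indicators. The covariance of beta is scaled by the Pearson
dispersion.

**Stage 2 — pooling (multilevel multivariate meta-regression).**
Location coefficient vectors are combined under

    beta_ij = X_ij gamma + g_j,   g_j ~ N(0, Psi)

with climate-zone fixed effects and a country-level random coefficient
block, Psi estimated by REML. Outputs: pooled exposure–response curves
per climate, Cochran's Q and I², a Wald test for the climate effect,
BLUP curves per country–climate, the minimum-risk precipitation (MMP,
searched between the minimum and the 90th percentile), and percent
changes in risk at the 5th/95th percentiles relative to the MMP.

See `docs/methods.md` for the full specification and design choices.

## Worked example

Run the numbered drivers in order (each writes under `results/`):

```bash
python analysis/01_simulate.py        # synthetic 29-location, 8-country study
python analysis/02_fit_locations.py   # stage-1 case-crossover fits
python analysis/03_pool.py            # REML meta-regression
python analysis/04_risk.py            # curves, MMP, percent changes
python analysis/05_sensitivity.py     # five sensitivity families
```

The simulated study uses 10 years of daily data per location with known
truth curves: tropical log-linear (RR 1.18 at P95 vs minimum), arid and
temperate U-shaped (vertices at P73 / P64). Step 04 prints:

```
climate     MMP mm MMP pct      dry %chg (95% CI)      wet %chg (95% CI)
tropical         0     0.0                     --     +22.0 (12.9, 31.7)
arid            55    76.0      +7.7 (-5.6, 22.9)       +7.9 (0.9, 15.3)
temperate      111    64.4      +4.7 (-4.1, 14.4)      +5.7 (-2.3, 14.4)
```

Reading: the tropical pooled curve is monotone increasing, so the
minimum-risk precipitation is the lowest observed 28-day sum and
mortality risk at the wet extreme (95th percentile) is ~22% above it —
recovering the generated truth of +18% within its confidence interval.
The arid and temperate curves are U-shaped with minimum risk near the
73rd/64th percentile vertices of their truths, and elevated risk at both
the dry and wet extremes. Step 03 additionally reports heterogeneity
(Q, I²) and the climate Wald test; step 05 shows the exposure-window
sensitivity (7/14/21-day sums attenuate the cumulative effect, as
expected for a 28-day generative window).

The same pipeline runs from the command line on any standard input table
(`location_id, country, climate, date, deaths, precip_mm, temp_c`):

```bash
raincross simulate --countries 8 --years 10 --seed 1 --out study.csv
raincross all --table study.csv --outdir out/
```

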