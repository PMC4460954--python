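# otochron

Otolith-increment biochronologies for fish populations: from per-fish,
per-transect increment widths to crossdated, standardized master growth
chronologies, and on to a climate–growth correlation screen with PCA and
regression diagnostics.

Fish ear stones (otoliths) accrete one growth increment per year, and
increment width tracks somatic growth.  Borrowing the toolkit of
dendrochronology, a sample of long-lived fish can therefore be turned
into an annually resolved population growth record and screened against
environmental drivers — ENSO state, sea-surface temperature and
salinity, decadal oscillations, rainfall.  `otochron` implements that
workflow for the kind of study where juveniles and adults occupy
different habitats (estuaries vs coastal reefs) and the two life stages
are analysed as separate chronologies.

The package is aimed at sclerochronologists and fisheries ecologists who
want a scripted, testable version of the classic
COFECHA-plus-regional-curve workflow, together with a synthetic-data
generator that produces realistic collections with known ground truth.

## The method

For each measurement transect of each fish, increment widths `w(a)` by
age are dated backwards from the year of capture, then detrended with a
cubic smoothing spline whose amplitude frequency response is 0.5 at a
22-year wavelength, and standardized by division:

    index(t) = w(t) / spline(t)

These high-frequency indices drive crossdating quality control: each
series is correlated against the leave-one-out master (the mean of all
other series), low correlations are flagged (default critical r =
0.3665, the classic 99% one-tailed level), and a lagged change-point
scan localizes series mis-dated by a missed or doubled increment.

Chronology construction uses a regional-curve-style standardization
that keeps low-frequency common variation: divide each series by the
population mean width-at-age curve, average transects within a fish,
split into adult (ages ≥ 8) and juvenile (ages 1–9) stages, and average
across fish per calendar year subject to sample-depth rules (adult:
every retained year has ≥ 20 fish; juvenile: the longest contiguous run
with ≥ 10 fish).  Chronology quality is summarized by the mean pairwise
correlation among fish-level series (rbar) and the expressed population
signal

    EPS = n·rbar / (n·rbar + (1 − rbar)),

the expected squared correlation between the finite-sample chronology
and the hypothetical population chronology.

The environmental screen correlates a chronology with
January–March monthly values of five climate factors (15 variables,
Pearson, two-sided, fixed significance threshold α = 0.03 to account
for the multiplicity), groups collinear predictors (|r| ≥ 0.5),
combines each group by PCA on the correlation matrix, and fits OLS
models of the chronology on PC1 scores or single (optionally
fourth-root transformed) predictors, reporting adjusted R², the overall
model p, Durbin–Watson, Shapiro–Wilk and Breusch–Pagan diagnostics.

## Worked example

```python
import numpy as np
import otochron as oc

# a synthetic study: 36 fish aged 24-52, captured 1996-2005,
# 3 transects each, forced by a shared environmental signal
climate, signal = oc.simulate_climate(range(1935, 2006), seed=1)
fish, truth = oc.simulate_fish(oc.SimulationConfig(seed=1), signal)

chron, staged, stats = oc.build_stage_chronology(fish, "adult")
print(chron.span, len(chron.index))
print(round(stats.rbar, 3), round(stats.eps, 3))

common = chron.index.index.intersection(signal.index)
print(round(np.corrcoef(chron.index.loc[common], signal.loc[common])[0, 1], 3))

screen = oc.run_screen(chron, climate)
key = next(iter(screen.pca))
print(int(screen.records["significant"].sum()),
      round(100 * screen.pca[key].explained_fraction[0], 1),
      round(screen.models[f"{key}:PC1"].adj_r2, 3))
```

prints

```
(1968, 2000) 33
0.06 0.672
0.807
8 54.5 0.52
```

— an adult chronology spanning 1968–2000 (33 years with ≥ 20 fish), a
weak but real common signal (rbar 0.06, EPS 0.67), a chronology that
recovers the true environmental forcing with r = 0.81, and a screen in
which 8 of 15 variables are significant, the collinear
ENSO/salinity/decadal-oscillation group's PC1 explains 54.5% of their
variance, and the PC1 regression reaches adjusted R² = 0.52.

The same workflow is scriptable from the shell:

```
otochron simulate --seed 1 --out-dir run/
otochron prep --increments run/increments.csv --out-dir run/
otochron crossdate --standardized run/standardized.csv --out-dir run/
otochron chronology --increments run/increments.csv --stage adult --out-dir run/
otochron screen --chronology run/chronology_adult.csv --climate run/climate.csv --out-dir run/
otochron report --out-dir run/
```

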