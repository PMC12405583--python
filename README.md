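# dcturnover

Quantitative analysis of conventional dendritic cell (cDC) turnover in the
small intestine, for immunologists and modellers working with in-vivo cell
tracking data.  The package implements the estimators and mechanistic models
needed to turn label-dilution time courses — photoconversion (Dendra2),
BrdU/EdU pulse-chase — and tissue point patterns into turnover rates,
half-replacement times, egress rates and cluster statistics, together with
seeded synthetic-data generators so every analysis runs without any
experimental download.

## What it computes

**Empirical kinetics** (`dcturnover.kinetics`).  For a photoconverted tissue
compartment the fraction of labelled (Dred+) cells declines as unlabelled
cells arrive.  A linear fit `y(t) = b + s t` gives the daily turnover rate
`|s|` (pp/day), the half-replacement time `T50 = (b − 50)/|s|` and the
extrapolated complete turnover `2 T50`.  Fast compartments (migratory lymph
node cDCs) are fit with `y(t) = A e^{−rt}`, half-life `ln 2 / r`, and the
replaced fraction at time `t` is `100 (1 − 2^{−t/T50})`.  A BrdU chase
declining by `s` pp/day from a fitted peak `P` at the first chase point gives
a tissue egress rate `100 s / P` percent of the population per day.

**Mechanistic models** (`dcturnover.models`).  Three nested models of tissue
influx, local proliferation and efflux at steady state:

| model | structure | proliferation | exit |
|---|---|---|---|
| M1 | well-mixed ODE | constant `p0` | constant rate `m > p0` |
| M2 | transport equation in residence age `a` | `p(a) = k a` | forced at `a_max` |
| M3 | transport equation | `p(a) = k a` | hazard `µ` plus forced at `a_max` |

The steady-state age density is `n*(a) = c exp(k a²/2 − µ a)` and the
labelled fraction after photoconversion with efficiency `η` is the tail mass
`100 η ∫_min(t,a_max)^{a_max} n* da / ∫_0^{a_max} n* da` (M1:
`100 η e^{−(m−p0)t}`).  A method-of-characteristics solver (unit CFL,
first-order upwind) reproduces the closed forms to < 1e−3 pp; fitting is a
deterministic grid search plus Nelder–Mead refinement, with model comparison
by residual sum of squares.

**Spatial clustering** (`dcturnover.spatial`).  cDC1 positions in tissue
sections are clustered as connected components of the Delaunay triangulation
after removing edges ≥ 40 µm, with cluster-size histograms, the fraction of
cells in proximity to another cell, and marker (Ki67) positivity by
cluster-size bin.

**Synthetic data** (`dcturnover.synthetic`).  Seeded generators for every
input above, with defaults set to the reported study parameters (16.8 pp/day
decline from 98.7%, half-lives 9.5/6.3/10.1 h, BrdU peak 20.0% declining
5.26 pp/day, Ki67 probabilities 0.476/0.735 by cluster size).

All fits are scikit-learn style estimators (`LinearTurnoverRegressor`,
`ExponentialDecayRegressor`, `TurnoverModel`, `DelaunayThresholdClustering`,
...) that compose with sklearn tooling; the module-level functions are thin
wrappers accepting `LabelTimeCourse` tables.

## Worked example

```python
from dcturnover import (gen_linear_photoconversion, fit_linear_turnover,
                        compare_models)

tc = gen_linear_photoconversion(seed=1)          # noisy SI LP default series
fit = fit_linear_turnover(tc)
print(f"slope {fit.slope:+.2f} pp/day, T50 {fit.t50:.2f} d, "
      f"complete {fit.complete_turnover_time:.2f} d, r^2 {fit.r_squared:.4f}")

rank = compare_models(tc.to_days(), ["M1", "M2", "M3"])
print(rank[["model", "sse"]])
```

prints

```
slope -17.22 pp/day, T50 2.89 d, complete 5.78 d, r^2 0.9972
     model        sse
rank
0       M3  16.381421
1       M2  36.227323
2       M1  80.530415
```

i.e. with replicate noise of 2 pp the default series still yields a
half-replacement time of ~2.9 days (about 17% of the compartment replaced
daily, complete turnover in under 6 days), and the mixed model M3 — most
cells leaving at a fixed residence time, a minority earlier — fits the
near-linear decline better than either the purely random-exit model M1 or
the strict fixed-residence model M2.

The same pipeline is available from the shell:

```bash
dcturnover simulate --scenario photoconversion-si --seed 1 --out tc.csv
dcturnover fit-kinetics --input tc.csv --method linear --out fit.json
dcturnover fit-model --input tc.csv --models M1,M2,M3 --out models.json
```

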