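# Methods

## Scope and data model

The package analyses label-dilution kinetics of conventional dendritic cells
(cDCs) in the small-intestinal lamina propria (SI LP) and the draining
mesenteric lymph node (MLN), plus spatial cluster statistics of cDC1s in
tissue sections.  The common input is a `LabelTimeCourse`: percent-labelled
measurements (photoconverted Dred+, BrdU+ or EdU+) at a few time points in a
few biological replicates, with an explicit unit (`days` or `hours`; the
internal canonical unit is days and every conversion is explicit).
Photoconversion conserves Dred+ % + Dred− % = 100, so every estimator accepts
either channel; fitting the complement mirrors slope and intercept exactly.

Replicates are pooled — each measurement is one least-squares point — rather
than fitting per-time means.  With balanced replication the two choices give
identical point estimates for linear fits; pooling matches how the underlying
scatter plots are drawn and keeps unbalanced designs unbiased toward
oversampled time points.

## Empirical estimators

**Linear turnover.**  Ordinary least squares of percent labelled on time.
Derived quantities: daily turnover rate `|slope|` (pp/day), half-replacement
time `T50 = (intercept − 50)/|slope|`, and the extrapolated complete-turnover
time `2 T50`.  The doubling convention (rather than `intercept/|slope|`) is
deliberate: T50 measures replacement of half the compartment, so doubling it
extrapolates the same constant rate to full replacement and is consistent
with the reported pair (2.9 d, 5.8 d), which `intercept/|slope|` is not for
any intercept near 100.  A non-declining series, or one starting below 50%,
yields a *flagged undefined* T50 (`NaN` + `t50_defined=False`), not an
exception, so batch analyses continue.  Fitted slopes below 1e−10 pp/day are
truncated to exact zero — measurement percentages are O(100) over a span of
days, so anything smaller is floating-point residue.

**Exponential replacement.**  Nonlinear least squares of `A e^{−rt}` with the
amplitude free (photoconversion efficiency at t = 0 is below 100%),
initialised from a log-linear regression on the positive observations and
retried from two deterministic alternative starts before declaring failure.
Requires ≥ 3 distinct positive time points.  Outputs carry the input time
unit; `half_life = ln 2 / r`, and the replaced fraction at time t is
`100 (1 − e^{−rt})`.

**BrdU egress.**  The BrdU+ fraction declines linearly during chase as
labelled cells leave the tissue.  The absolute slope (pp/day) divided by the
*fitted value at the first chase time point* (24 h) converts the decline into
percent of the whole population leaving per day.  Using the first chase point
as denominator (rather than an extrapolated t = 0 intercept) is an assumption;
with the default series the two differ by well under the reporting precision.
An increasing chase series is returned flagged non-physical.

**Maturation profile.**  EdU+ percentages across the ordered bins M1–M4
(surface-MHCII quartiles of CCR7− cDCs) and CCR7+ are summarised by per-bin
means and two flags: non-strict monotone rise across M1–M4, and a drop of the
CCR7+ mean below M4 — the signature of proliferation increasing with tissue
maturation and shutting down in pre-migratory cells.

## Mechanistic models

Three nested models of a tissue compartment at demographic steady state, all
with constant cell influx `c` (a pure scale parameter, fixed at 1 since label
fractions are scale-free) and photoconversion efficiency `η` (default 0.99,
from the measured >98%; optionally profiled within [0.95, 1]):

* **M1** — well-mixed ODE: constant per-capita proliferation `p0` (default
  0.1/day, a doubling time of about one week) and exit rate `m`; requires
  `m > p0`; steady state `N* = c/(m − p0)`; labelled fraction
  `100 η e^{−(m−p0)t}`.
* **M2** — transport equation in residence age `a` with proliferation
  increasing with time in the tissue, `p(a) = k a` (default
  `k = 0.1/day²`), and forced exit at the maximal residence time `a_max`.
* **M3** — M2 plus a constant age-independent early-exit hazard `µ`; `µ = 0`
  recovers M2 exactly, and `k = 0` with large `a_max` approaches M1 with
  `p0 = 0`.  The constant-hazard form is the simplest early-exit mechanism
  consistent with "some cells leave before the maximal residence time"; age-
  dependent hazards would not be identifiable from 4 time points.

Daughters of labelled cells inherit the label (the fluorescent protein is
histone-fused) and are booked at the parent's residence age — proliferation
is a source term `p(a) n` along characteristics, not a boundary influx.
Label dilution below flow-cytometric detection after many divisions is not
modelled.  Under these conventions the steady-state density is
`n*(a) = c exp(k a²/2 − µ a)` on `[0, a_max]`, and the labelled fraction
t days after conversion is the tail mass of cells aged ≥ t.  The `k = 0`
limit of M2 gives an exactly linear decline `100 η (1 − t/a_max)` — the
phenomenology seen in the SI LP data.

**Numerics.**  The density integrals `∫ exp(k a²/2 − µ a) da` are evaluated
in closed form via the Dawson function (`scipy.special.dawsn`), a stable
rewriting of the imaginary error function that cannot overflow for any
physically sensible exponent; `scipy.integrate.quad` serves as the
independent oracle in the tests.  The forward solver marches the transport
equation on a uniform age grid (default spacing `Δa = 0.005` day; spacings
above `a_max/50` are rejected) with the method of characteristics at unit
CFL: each step shifts the density one node and multiplies by the exact
integrated growth factor, which preserves the steady state to machine
precision (total-population drift ~1e−15 relative).  The labelled front lies
exactly on a grid node, so the tail quadrature is split there and stays
second-order accurate; certified accuracy against the closed forms is
< 1e−3 pp at the default spacing.  M1 is integrated with `solve_ivp`
(rtol 1e−10) as a genuine numerical route against its closed form.

**Fitting.**  SSE between the closed-form label fraction and the pooled
observations is minimised over the free parameters (M1: `m`; M2: `a_max`;
M3: `a_max, µ`; optionally `η`, which enters linearly and is profiled out
analytically).  Proliferation parameters stay fixed at their defaults unless
scanned explicitly (`scan_proliferation_rates`).  The optimiser is fully
deterministic: a coarse grid (`a_max ∈ [0.5, 15]` d step 0.05; `m, µ ∈ [0, 2]`
/day step 0.01) followed by bounded Nelder–Mead refinement from the grid
optimum — no random restarts, no seed dependence.  For M3 the refined M2
optimum (`µ = 0`) seeds a second simplex, so `SSE(M3) ≤ SSE(M2)` holds
exactly on every dataset, as nesting demands.  Model comparison sorts by SSE
(rounded at 1e−9 to make ties well-defined) breaking ties toward fewer free
parameters; per-configuration failures are captured per row instead of
aborting the batch.  An all-identical time course produces a degenerate-fit
warning and `converged=False` with the flat SSE surface reported as-is.

## Spatial clustering

Clusters are connected components of the Delaunay triangulation after
deleting edges of length ≥ the threshold (default 40 µm).  This is the
"Delaunay cluster features" semantics of QuPath and is *not* equivalent to
all-pairs distance thresholding: two cells closer than the threshold are not
joined when the triangulation does not carry their edge.  "In proximity" is
operationalised as membership in a cluster of size ≥ 2.  For fewer than three
points, or exactly collinear input where no triangulation exists, the
complete graph is used; exactly coincident points are merged with a warning
(sizes count distinct positions).  Coincidentally cocircular configurations
admit several valid triangulations and any is accepted; test fixtures jitter
coordinates by 1e−6 µm to stay in general position.  The analysis is strictly
2-D (sections are 10 µm slices) and no tissue-boundary masking is applied.
The test-suite oracle is an exhaustive empty-circumcircle triangulation over
all triples, valid for the ≤ 12-point fixtures it checks.

## Synthetic data

Generators are seeded (`numpy.random.default_rng`), bit-reproducible, and
default to the reported study parameters so the acceptance checks run off
default configurations:

* linear photoconversion: intercept 98.7%, slope −16.8 pp/day (total cDC;
  −22.3 / −14.4 for cDC1 / cDC2), times 0–3 days, 3 replicates;
* exponential photoconversion: half-lives 9.5 / 6.3 / 10.1 h per migratory
  MLN subset, times 0–24 h, amplitude `100 η`;
* BrdU chase: peak 20.0% at 24 h declining 5.26 pp/day at 24/48/72 h;
* maturation bins: noise-free means (2, 3.5, 5, 6.5, 1)% for
  (M1..M4, CCR7+) — the bin means are published only graphically, so these
  values emulate the rising-then-collapsing pattern, not exact magnitudes;
* point patterns: cluster sizes 1–10 with `P(s) ∝ 0.52^(s−1)` (chosen once so
  that ~77% of cells sit in clusters of ≥ 2 and sizes reach 10), members
  Gaussian (sd 5 µm) around centres separated by ≥ 3× the threshold so the
  generated partition is recoverable by construction; Ki67 probability 0.476
  for cells in clusters of 1–2, 0.735 for ≥ 5, and 0.60 (interpolated) for
  3–4.

Replicate noise is Gaussian on the percent scale, default sd 2 pp (the
magnitude of replicate scatter in this kind of flow-cytometry data; per-
replicate noise is published only graphically, so this is a stated assumption,
with a binomial cells-per-sample option for realism).  Values are clipped to
[0, 100] and the clip count is recorded in `meta`.  What the generators do
*not* emulate: inter-animal heteroscedasticity, photoconversion-efficiency
variation between experiments, time-point-dependent cell yields, and any
correlation structure between replicates — so passing tests demonstrate
correctness of the estimators under the stated noise model, not robustness to
every artefact of real data.

## Problem sizes and determinism

The default test and acceptance workloads use 4–6 time points × 3 replicates
for fits, 200 seeds for the noisy a_max-recovery experiment, 1000 seeds for
the slope-unbiasedness check, 20 random parameter sets per model for the
solver-vs-closed-form oracle, and ~5000 cells for the spatial marker
statistics — sizes matched to the study design, at which the whole suite
completes in well under a minute.  Every stochastic step takes an explicit
seed; fitting itself is seed-free by construction.

The noisy recovery experiment targets M2's `a_max` (a single identified
parameter).  M3's `(a_max, µ)` pair is only weakly identified from four time
points under noise — the two parameters trade off against each other — so M3
recovery is asserted noise-free, where both return within 1%.

## Known limitations

* The mechanistic models treat the MLN empirically (exponential fits only);
  no mechanistic two-compartment SI→MLN coupling is implemented.
* M1's "age density" is a plotting surrogate: the well-mixed model has no
  residence-age structure.
* The Delaunay oracle equivalence is exhaustive only up to 12 points;
  larger patterns rely on scipy's qhull triangulation.
* Cluster-size-dependent marker probabilities are piecewise-constant in the
  generator; real Ki67 dependence on cluster size is presumably smoother.
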