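# Methods

## Model family and assumptions

The package implements three nested deterministic ODE models of a
well-mixed culture sharing glutamine `A` (mM), ammonium `W` (mM) and a
composite alternative-energy pool `R` (mM):

* **Monoculture** (states A, W, R, X): one population converts Gln to
  NH4+ (rate k1, yield c1), recycles NH4+ back to Gln at the cost of R
  (rate k2, yield c2), consumes R independently (k3), secretes NH4+ from
  other sources (h), grows Monod-style on Gln (r1, K1) and on R (r2, K2),
  and dies at d1 per mM NH4+ plus a background d2. Every flux is
  proportional to the live-cell count, so an empty well is inert and all
  states remain nonnegative for nonnegative initial data.
* **Merged coculture** (A, W, R, X, Y): the union of the CAF and
  cancer-cell monoculture terms over the shared metabolites. Cancer
  cells cannot grow on the alternative pool: their r2 is fixed at 0 a
  priori, which makes their K2 inert (it is kept in the container so one
  type serves both cell types, and it is pinned during fitting).
* **Stress coculture**: adds a dimensionless crowding/stress variable L
  with dL/dt = g·X·Y, L(0) = 0, and a -m·L² loss term in both growth
  equations. The quadratic dependence makes stress increasingly harmful
  at high levels, producing the concave late-time decline of the mixed
  population. In this variant the two growth rates revert to their
  monoculture values.
* **Normalized coculture**: the merged model with the CAF NH4+→Gln
  conversion disabled (caf.k2 = 0) — the counterfactual in which a
  therapy returns the fibroblasts to their normal, non-recycling
  phenotype.

Key structural properties, all covered by tests: R is nonincreasing and
L nondecreasing along every trajectory; with unit yields (c1 = c2 = 1)
and no basal production (h = 0) the total A + W is conserved exactly;
the coculture right-hand side restricted to one population reproduces
the corresponding monoculture model.

Everything is kept in natural units — mM, cells, hours — so the packaged
published constants drop in verbatim. One printed unit in the coculture
growth-rate table is dimensionally inconsistent (h⁻² for a specific
growth rate); it is treated as 1/h, which the growth equation forces.
Likewise the source equations typeset the cell count inconsistently in
two conversion terms (lowercase x); the conversion flux is implemented
uniformly as W·R·X, which the published unit of k2, 1/(cell·mM·h),
requires.

## Parameters

The packaged tables (`glnrecycle/tables/*.yaml`, checksum-guarded in the
test suite) carry the published point estimates and 95% intervals for
both cell types, the two coculture growth-rate overrides
(caf.r1 = 5×10⁻³/h, cc.r1 = 6×10⁻²/h), and the stress constants
(g = 7×10⁻⁷ /(h·cell²), m = 10⁻¹¹/h). Initial conditions follow the
experimental design: 8×10⁴ cells seeded per well (1:1 for cocultures),
R(0) = 20 mM (chosen to match the order of magnitude of the dosed
substrates; R is not observable and is a lumped quantity), Gln doses
{0, 1, 2, 4} mM, NH4Cl doses {0, 5, 10, 25} mM, observations at
0/24/48/72 h.

## Numerical integration

The default solver is an in-package batched adaptive Dormand–Prince
4(5) stepper compiled with numba (rtol 10⁻⁸, atol 10⁻¹⁰, RMS error norm,
safety factor 0.9, step factor clamped to [0.2, 10]). It integrates all
scenarios of an experiment in a single compiled pass, which keeps one
objective evaluation under 0.1 ms and makes the Nelder–Mead and
bootstrap loops cheap; scipy's `solve_ivp` backends (RK45, DOP853 and
the stiff Radau/LSODA fallbacks) are selectable via `method=` and agree
with the default path to ~10⁻¹⁰ relative in tests, alongside an
independent fixed-step Euler oracle. Output times are hit exactly by
step clamping. Components are clipped to zero only within solver
tolerance; any deeper negative excursion raises an integration error
naming the scenario rather than being silently clipped. The dynamics at
the published constants are only mildly stiff; the implicit fallbacks
exist for harsher parameter regimes. A `reset_R=(t, value)` hook on
`simulate` supports the medium-replenishment thought experiment.

## Objective and fitting

The objective sums squared residuals over all scenarios and streams of
one experiment. Because raw counts (~10⁴–10⁵ cells) would dominate raw
concentrations (~0.1–25 mM) in an unscaled sum, each stream is first
divided by a scale weight — 10⁴ cells for counts, 1 mM for
concentrations — making the two kinds of residual comparable;
`unweighted_weights()` restores the literal unscaled sum for
sensitivity to this choice. Fitting uses Nelder–Mead (scipy, adaptive
coefficients) over log-transformed free constants, which enforces
positivity without constraints. The initial simplex perturbs each
coordinate by ×1.05; optional restarts re-inflate the simplex at the
best vertex (×1.005 edges) to escape premature collapse, and a fit is
reported unconverged if the evaluation budget (10⁵ by default) is
exhausted. A solver failure during a trial evaluation returns a large
finite penalty (10¹²) so the simplex retreats instead of crashing.
Initial conditions during fitting are the nominal design values (doses
as dosed, R0 = 20 mM, 8×10⁴ cells); zero-dose scenarios present in a
dataset participate in the joint fit.

## Error model, bootstrap, sensitivity

Measurement error is additive, Gaussian, centred and grouped per cell
type (ε_CAF, ε_CC independent), estimated from the weighted residuals by
the unbiased sample variance; per-stream grouping is available. The
parametric bootstrap simulates data at the fitted constants, adds
per-group noise, truncates negative observations at zero (a physical
constraint), refits each of 300 replicates starting from the fitted
values, and reports percentile 95% intervals — chosen over a
normal-approximation interval because replicate distributions of rate
constants are skewed on the natural scale. Replicate refits use a
looser simplex tolerance than the primary fit since they start at the
optimum. The run is driven by a single seed and is bit-reproducible;
more than 10% failed refits aborts with a diagnostic. Sensitivity is
ranked by normalized interval width (bounds divided by the point
estimate): recomputed from the published intervals, the Gln growth rate
r1 and the NH4+ kill rate d1 rank among the five narrowest of twelve
for both cell types, i.e. they are the constants the data pin down most
tightly. Zero-valued estimates are flagged rather than divided.

## Synthetic data

The generator emulates the experimental design only: it simulates each
dosing scenario, samples the observation grid, adds independent
Gaussian noise per replicate in weighted units, truncates each
replicate at zero, averages three replicates per observation (matching
triplicate-averaged assays), and rounds averaged counts to whole cells
(noiseless records pass through exactly so zero-noise datasets equal
the model output bit-for-bit). The default σ = 0.2 in weighted units
(0.2 mM / 0.2×10⁴ cells) is a realistic assay-scale error of a few
percent of the mid-range signal. Noise is measurement error only — no
process noise, no plate or edge effects, no proportional
(heteroscedastic) error, no replicate-level reporting. Passing recovery
and coverage tests on these data therefore validates the estimation
machinery under the model's own assumptions; they cannot certify the
model against real cultures, whose raw tables are not redistributable
here. Where a reference raw dataset is needed (the published-parameter
refit checks), a synthetic stand-in is generated noiselessly at the
published constants under the published design and is labelled as such.

## Scaling of the statistical checks

The test suite's calibration experiments are scaled to desk size as the
package's own test design: the coverage check runs 100 seeded synthetic
experiments with 50-replicate bootstraps freeing the three sensitive
constants (r1, d1, k1) for the CAF parameter set, and asserts ≥85/100
coverage of the true r1; the sigma-recovery check uses 200 seeded
draws. Zero-truncation slightly deflates residual-variance estimates
for observations near zero (e.g. Gln in ammonium-only wells); the
calibration tests account for this by evaluating concentrations well
above the truncation region or by the documented tolerance bands.

## Known limitations

* R is a lumped, unobserved pool; its initial value is a convention, so
  k2, k3, r2, K2 are only identified jointly with that convention.
* The ODEs assume a well-mixed environment; no spatial structure.
* Cell counts are continuous (no demographic stochasticity).
* The stress constants g, m are taken as given alongside the published
  tables; fitting them is possible but not exercised by default.
* Nelder–Mead is local: recovery from starts far beyond ×2 perturbation
  is not guaranteed, and no global or gradient-based optimizer is
  provided by design.
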