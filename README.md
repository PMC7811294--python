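# glnrecycle

Deterministic ODE models of the bidirectional glutamine/ammonium exchange
between breast cancer cells (CC) and cancer-associated fibroblasts (CAF),
with joint least-squares fitting, parametric-bootstrap confidence
intervals, sensitivity ranking, and end-to-end scenario suites.

## The problem

Glutaminolysis fuels tumor growth but dumps ammonium (NH4+), a toxic
waste, into the shared medium. Tumor-educated fibroblasts can recycle
NH4+ back into glutamine (Gln) at the cost of an alternative chemical
energy pool, detoxifying the microenvironment and feeding the cancer
cells. This package models that symbiosis for monocultures and 1:1
cocultures observed over 72 h, and asks what the coculture gains — and
what a "renormalization" therapy that switches the recycling off would
cost the tumor.

## The model

State variables: Gln `A` (mM), NH4+ `W` (mM), alternative energy `R`
(mM, seeded at 20 mM, never replenished), live cell counts `X` (CAF) and
`Y` (CC). Each cell type carries twelve constants
(k1, c1, k2, c2, h, k3, r1, K1, r2, K2, d1, d2):

```
dA/dt = -k1·A·X + c2·k2·W·R·X
dW/dt =  c1·k1·A·X - k2·W·R·X + h·X
dR/dt = -k2·W·R·X - k3·R·X
dX/dt = (r1·A/(K1+A) + r2·R/(K2+R) - d1·W - d2)·X
```

Cells convert Gln to NH4+ at rate k1 (yield c1) and NH4+ back to Gln at
rate k2 (yield c2), burning R; growth is Monod in each substrate and
NH4+ kills at rate d1 per mM. Cancer cells cannot grow on R (r2 = 0).
The coculture model is the union of the two equation sets over the shared
(A, W, R); an optional stress factor `L` with dL/dt = g·X·Y adds a
-m·L² death term to both populations, capturing the sharp decline of the
mixed population after 48 h. Published fitted constants for both cell
types, the coculture growth-rate overrides, and the stress constants ship
as packaged tables.

Fitting minimizes `F(θ) = Σ_k |u(t_k;θ) - w(t_k)|²` over all dosing
scenarios of one cell type jointly (Nelder–Mead over log-transformed free
constants; counts are scaled to units of 10⁴ cells by default so they do
not drown out the millimolar concentrations). Confidence intervals come
from a parametric bootstrap: simulate at the fitted constants, add
per-cell-type Gaussian measurement noise estimated from the residuals,
refit, and take 95% percentile intervals over the replicates.

## Worked example

Generate a synthetic CAF experiment at the published constants (the full
dosing design: Gln 0/1/2/4 mM and NH4Cl 0/5/10/25 mM, triplicate-averaged
noise), refit the three most sensitive constants, and bootstrap their
intervals:

```python
import glnrecycle as gr

caf = gr.caf_params()
design = gr.DesignSpec(cell_type="CAF", noise=0.2)
data = gr.generate(design, caf, seed=11)

result = gr.fit(data, caf, free=("r1", "d1", "k1"), restarts=1)
boot = gr.bootstrap_ci(result, data, n_replicates=300, seed=5)
for name in result.free:
    print(f"{name:>3}: {boot.estimates[name]:.3e}  "
          f"95% CI [{boot.ci_low[name]:.3e}, {boot.ci_high[name]:.3e}]")
```

prints

```
 r1: 2.472e-02  95% CI [2.435e-02, 2.509e-02]
 d1: 1.282e-03  95% CI [1.258e-03, 1.307e-03]
 k1: 4.115e-07  95% CI [3.990e-07, 4.234e-07]
```

— the maximal growth rate on Gln (r1, 1/h), the NH4+ kill rate (d1,
1/(mM·h)) and the glutaminolysis rate (k1, 1/(cell·h)) are each recovered
within a few percent of the generating values (2.5e-2, 1.3e-3, 4.13e-7),
and every interval covers its truth. The coculture suite tracks
composition:

```python
comp = gr.run_coculture_suite(variant="coculture_merged")["composition"]
print(comp[comp.scenario_id == "nh4_5"][["time_h", "cells_total", "pct_cc"]]
      .to_string(index=False))
```

```
 time_h  cells_total    pct_cc
    0.0 80000.000000 50.000000
   24.0 72094.642517 47.634816
   48.0 72719.185100 48.068055
   72.0 73565.233835 48.258083
```

Under 5 mM NH4+ the mixed population holds its 1:1 composition (the
cancer-cell share stays near 50%) — the buffering behavior the model was
built to explain.

A CLI mirrors the library: `glnrecycle simulate|synth|fit|bootstrap|
suite|report --help`.

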