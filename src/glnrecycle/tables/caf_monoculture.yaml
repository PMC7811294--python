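# Fitted kinetic constants for patient-derived breast-tumor CAFs grown alone
# (triple-negative tumor fibroblasts educated with cancer-cell extracellular
# vesicles), with percentile 95% confidence intervals.
cell_type: CAF
parameters:
  k1: {value: 4.13e-7, ci: [4.03e-7, 4.21e-7], unit: "1/(cell*h)", role: "conversion rate of Gln to NH4+"}
  c1: {value: 0.9, ci: [0.85, 0.92], unit: "dimensionless", role: "efficacy of NH4+ production"}
  k2: {value: 4.5e-8, ci: [4.06e-8, 4.89e-8], unit: "1/(cell*mM*h)", role: "conversion rate of NH4+ to Gln"}
  c2: {value: 0.28, ci: [0.28, 0.29], unit: "dimensionless", role: "efficacy of Gln production"}
  h: {value: 1.6e-8, ci: [1.33e-8, 1.89e-8], unit: "mM/(cell*h)", role: "natural production rate of NH4+"}
  k3: {value: 2.1e-7, ci: [1.83e-7, 2.3e-7], unit: "1/(cell*h)", role: "consumption rate of alternative energy"}
  r1: {value: 2.5e-2, ci: [2.39e-2, 2.60e-2], unit: "1/h", role: "maximal growth rate on Gln"}
  K1: {value: 0.63, ci: [0.53, 0.72], unit: "mM", role: "half-maximal Gln concentration"}
  r2: {value: 3.45e-6, ci: [3.05e-6, 3.84e-6], unit: "1/h", role: "maximal growth rate on alternative energy"}
  K2: {value: 7.3, ci: [6.1, 8.5], unit: "mM", role: "half-maximal alternative energy concentration"}
  d1: {value: 1.3e-3, ci: [1.27e-3, 1.34e-3], unit: "1/(mM*h)", role: "NH4+ induced cell death rate"}
  d2: {value: 7.0e-5, ci: [6.33e-5, 7.67e-5], unit: "1/h", role: "background cell death rate"}
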