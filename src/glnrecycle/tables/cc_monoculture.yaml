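# Fitted kinetic constants for MDA-MB-231 breast cancer cells grown alone,
# with percentile 95% confidence intervals.  Cancer cells cannot grow on the
# alternative energy pool: r2 is fixed to 0 a priori and K2 is an inert
# placeholder (the growth term r2*R/(K2+R) vanishes identically).
cell_type: CC
parameters:
  k1: {value: 7.5e-8, ci: [7.21e-8, 7.89e-8], unit: "1/(cell*h)", role: "conversion rate of Gln to NH4+"}
  c1: {value: 1.9, ci: [1.67, 2.18], unit: "dimensionless", role: "efficacy of NH4+ production"}
  k2: {value: 2.4e-8, ci: [2.35e-8, 2.41e-8], unit: "1/(cell*mM*h)", role: "conversion rate of NH4+ to Gln"}
  c2: {value: 0.15, ci: [0.14, 0.16], unit: "dimensionless", role: "efficacy of Gln production"}
  h: {value: 5.3e-7, ci: [5.1e-7, 5.6e-7], unit: "mM/(cell*h)", role: "natural production rate of NH4+"}
  k3: {value: 2.6e-10, ci: [1.92e-10, 3.37e-10], unit: "1/(cell*h)", role: "consumption rate of alternative energy"}
  r1: {value: 5.6e-2, ci: [5.4e-2, 5.8e-2], unit: "1/h", role: "maximal growth rate on Gln"}
  K1: {value: 1.97, ci: [1.93, 2.00], unit: "mM", role: "half-maximal Gln concentration"}
  r2: {value: 0.0, ci: null, unit: "1/h", role: "maximal growth rate on alternative energy (fixed 0)"}
  K2: {value: 1.0, ci: null, unit: "mM", role: "half-maximal alternative energy concentration (inert, r2 = 0)"}
  d1: {value: 1.7e-3, ci: [1.6e-3, 1.75e-3], unit: "1/(mM*h)", role: "NH4+-induced cell death rate"}
  d2: {value: 1.1e-2, ci: [9.4e-3, 1.3e-2], unit: "1/h", role: "background cell death rate"}
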