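# Constants of the stress-factor coculture extension: a dimensionless
# crowding/stress variable L produced jointly by both populations
# (dL/dt = g*X*Y, L(0)=0) kills both cell types at rate m*L^2.  In this
# variant the two growth rates revert to their monoculture values.
parameters:
  g: {value: 7.0e-7, unit: "1/(h*cell^2)", role: "stress production rate"}
  m: {value: 1.0e-11, unit: "1/h", role: "stress kill coefficient"}
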