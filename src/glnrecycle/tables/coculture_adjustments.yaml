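# The merged coculture model keeps every monoculture constant except the two
# maximal growth rates on Gln, which are refit jointly on the coculture data
# (the two populations are assumed to influence each other's proliferation).
# "ratio" is the change relative to the monoculture value.
overrides:
  caf.r1: {value: 5.0e-3, ci: [4.6e-3, 5.4e-3], unit: "1/h", ratio: 0.1}
  cc.r1: {value: 6.0e-2, ci: [5.95e-2, 6.03e-2], unit: "1/h", ratio: 1.08}
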