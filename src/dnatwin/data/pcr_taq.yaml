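kind: pcr
name: taq
mean_efficiency: 0.9
efficiency_sigma: 0.0051
# observed substitution accrual per nucleotide per cycle for Taq-family polymerase
substitution_rate_taq: 1.09e-4
fidelity_relative_to_taq: 1.0
pattern_weights:
  "A>G/T>C": 0.61
  "C>T/G>A": 0.20
  "A>T/T>A": 0.13
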