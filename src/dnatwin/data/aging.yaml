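kind: aging
name: aging
# substitution accrual per nucleotide per half-life of decay
substitution_rate_per_half_life: 1.64e-4
deletion_rate: 0.0
pattern_weights:
  "C>T/G>A": 0.77
  "C>A/G>T": 0.07
  "C>G/G>C": 0.06
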