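kind: synthesis
name: electrochemical
# lognormal sigma of the normalized initial coverage distribution
coverage_sigma: 1.30
coverage_sigma_gc_constrained: 0.58
deletion:
  # observed mean deletion rate (nt^-1); realized rate is calibrated to this
  mean_rate: 0.0135
  terminal_rate: 0.05
  shape: exponential
  # electrochemical synthesis proceeds 3'->5': the profile rises in synthesis
  # direction and is reversed along the forward read
  direction: synthesis_3to5
run_law:
  # continuation probability calibrated so the mean run length *measured from
  # mapped reads* is ~2.6: chance mergers of adjacent independent deletions at
  # the high-rate 5' end produce many length-2 runs that dilute the law's runs
  continuation_probability: 0.55
  run_probability: 0.05
  burst_feedback: 3.0
substitution_rate: 0.0
insertion_rate: 1.0e-4
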