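kind: synthesis
name: material_deposition
coverage_sigma: 0.27
coverage_sigma_gc_constrained: 0.30
deletion:
  mean_rate: 5.8e-4
  shape: flat
  direction: read
run_law:
  continuation_probability: 0.375
  run_probability: 0.05
  burst_feedback: 1.0
substitution_rate: 0.0
insertion_rate: 1.0e-4
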