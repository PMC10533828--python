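"""Sequencing-by-synthesis errors: direction- and cycle-dependent substitutions.

Sequences an error-free pool with the iSeq 100 preset, so every error in the
reads comes from the sequencer model, then measures the substitution rate by
read direction and shows the cycle dependence of the forward profile.
"""

import numpy as np

import dnatwin as dt

refs = dt.generate_reference_pool(500, 150, seed=1)
pool = dt.pool_from_references(refs, [100] * 500)
reads = dt.sequence(pool, dt.sequencing_params("iseq100", read_count=30_000), seed=2)
mappings = dt.map_reads(reads, refs, read_length=150)
report = dt.error_rates(mappings, refs)

for direction, target in (("forward", 1.1e-3), ("reverse", 2.5e-3)):
    ms = [m for m in mappings if m.direction == direction]
    rate = sum(m.n_substitutions() for m in ms) / sum(m.aligned_ref_nt for m in ms)
    print(f"{direction:8s} substitution rate: {rate:.2e} nt^-1 (preset {target:.1e})")

fwd = report.positional.query("direction == 'forward' and type == 'sub'")
early = fwd[fwd.position <= 10].rate.mean()
mid = fwd[(fwd.position >= 20) & (fwd.position <= 30)].rate.mean()
late = fwd[fwd.position >= 140].rate.mean()
print(f"\nforward rate by cycle: 1-10 {early:.1e} | 20-30 {mid:.1e} | 140-150 {late:.1e}")
print(
    "\nReverse reads are ~2x noisier than forward reads, and the rate dips to a"
    "\nminimum near cycle 25 (when the base-caller's phasing and color-matrix"
    "\ncorrections kick in) before climbing again over the run."
)
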