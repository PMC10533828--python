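"""Synthesis presets: deletion rates, burst runs, and coverage skew.

Synthesizes a small pool with each provider preset, sequences it without
sequencing errors, maps the reads back, and prints the measured deletion
statistics next to the preset's nominal values.
"""

import dnatwin as dt

refs = dt.generate_reference_pool(500, 150, seed=1)

for preset, nominal in (("electrochemical", 13.5e-3), ("material_deposition", 0.58e-3)):
    params = dt.synthesis_params(preset, mean_coverage=50)
    pool = dt.synthesize(refs, params, seed=2)
    reads = dt.sequence(pool, dt.error_free_sequencing_params(15_000), seed=3)
    mappings = dt.map_reads(reads, refs, read_length=150)
    report = dt.error_rates(mappings, refs)

    print(f"\n{preset} synthesis ({len(reads)} read pairs mapped)")
    print(f"  deletion rate : {report.rates['del']:.2e} nt^-1 (preset {nominal:.2e})")
    print(f"  insertion rate: {report.rates['ins']:.2e} nt^-1")
    ge2 = {l: f for l, f in report.run_length_histogram.items() if l >= 2}
    if ge2:
        mean_run = sum(l * f for l, f in ge2.items()) / sum(ge2.values())
        print(f"  mean deletion-run length (runs >= 2): {mean_run:.2f} bases")
    sigma = dt.fit_lognormal_coverage(dt.normalized_coverage(pool))
    print(f"  coverage lognormal sigma: {sigma:.2f} "
          f"(preset {params.coverage_sigma})")

print(
    "\nThe electrochemical process deletes ~20x more bases, concentrated at the"
    "\n5' end and clustered into multi-base runs; material deposition is nearly"
    "\nerror-free but both show the lognormal coverage skew that drives dropout."
)
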