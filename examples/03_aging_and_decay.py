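"""Accelerated aging: first-order decay plus slow deamination damage.

Ages a pool for increasing numbers of half-lives, tracking both the loss of
molecules (the dominant effect) and the slow accrual of C>T/G>A
substitutions in the survivors, then fits the decay constant back from the
surviving-copy counts.
"""

import numpy as np

import dnatwin as dt

refs = dt.generate_reference_pool(500, 150, seed=1)
half_lives = [0.0, 1.0, 2.0, 4.0, 8.0]
survival, sub_rates = [], []

for h in half_lives:
    pool = dt.pool_from_references(refs, [2000] * 500)
    aged = dt.age(pool, dt.aging_params(half_lives=h), seed=int(10 + h))
    survival.append(aged.total_count / pool.total_count)
    reads = dt.sequence(aged, dt.error_free_sequencing_params(8_000), seed=int(20 + h))
    report = dt.error_rates(dt.map_reads(reads, refs, read_length=150), refs)
    sub_rates.append(report.rates["sub"])
    print(f"  {h:3.0f} half-lives: {100 * survival[-1]:6.2f}% DNA left, "
          f"substitution rate {report.rates['sub']:.2e} nt^-1")

fit = dt.fit_decay(np.maximum(survival, 1e-12), half_lives)
slope = np.polyfit(half_lives, sub_rates, 1)[0]
print(f"\nfitted half-life: {fit['tau']:.3f} (simulated in units of tau, so ideal = 1)")
print(f"substitution accrual: {slope:.2e} nt^-1 per half-life (preset 1.64e-4)")
print(
    "\nEight half-lives destroy 99.6% of the molecules yet add fewer errors than"
    "\n15 Taq PCR cycles: decay costs coverage, not fidelity, so storage density"
    "\nis limited by dropout rather than by mutations."
)
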