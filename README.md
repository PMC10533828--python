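# dnatwin

A stochastic **digital twin of the DNA data storage channel**, plus the
analysis toolkit that measures errors and biases back from sequencing reads.

Archiving digital data in synthetic DNA pushes an oligonucleotide pool
through a chain of noisy processes — array synthesis, PCR amplification,
long-term storage (decay), dilution, and sequencing-by-synthesis.  Each step
introduces substitutions, deletions and insertions at characteristic rates
and base biases, and, just as importantly, skews the *coverage distribution*
(copies per designed sequence), which drives **sequence dropout**: designed
sequences that vanish from the readout entirely.  Choosing how much
error-correction redundancy to encode requires knowing these rates and
biases for a concrete workflow — which usually means costly sequencing
experiments.  `dnatwin` replaces those experiments with a parameterized
simulation faithful enough to plan redundancy and compare error-correction
schemes, and it ships the measurement side too, so simulated FASTQ and real
FASTQ go through the identical analysis.

It is a library first (with an `examples/` directory of narrative scripts),
plus a thin `dnatwin` CLI for shell use.

## The model in brief

An oligonucleotide pool is a collection of sequence variants with integer
copy counts, attributed to their designed reference.  The stages:

- **Synthesis** — per-reference counts `round(c̄·X/E[X])`, `X ~ LogN(0, σ²)`
  (σ = 1.30 electrochemical, 0.27 material deposition, unconstrained pools);
  positional deletion profiles (exponential, >5 %/nt at the 5′ end, mean
  13.5×10⁻³ nt⁻¹ for electrochemical; flat 0.58×10⁻³ nt⁻¹ for material
  deposition) with burst runs (mean run length 2.6 nt over runs ≥ 2) and
  within-copy clustering; insertions at 10⁻⁴ per site.
- **PCR** — a branching binomial process: per cycle each copy duplicates
  with its reference's efficiency `ε_i = clip((1+ε̄)·relᵢ − 1, 0, 1)`,
  `relᵢ ~ N(1, σ)` drawn once per reference (σ ≈ 0.0051); new copies gain
  substitutions so the pool accrues 1.09×10⁻⁴ nt⁻¹cycle⁻¹ (Taq; divided by
  the polymerase fidelity, e.g. 280 for Q5), 61 % A→G/T→C.
- **Aging** — copies survive `h` half-lives with probability `2^(−h)`
  (`c(t)/c(0) = e^(−kt)`, `k = ln2/τ`); survivors gain 1.64×10⁻⁴ nt⁻¹ per
  half-life, 77 % C→T/G→A (deamination).
- **Dilution / sequencing** — pure random subsampling; paired reads carry
  direction- and cycle-dependent substitution profiles (iSeq 100 preset:
  1.1×10⁻³ forward, 2.5×10⁻³ reverse, minimum near cycle 25).

The analysis half maps reads to references by global alignment
(Needleman–Wunsch, match +1 / mismatch −1 / gap −1, < 85 % similarity
filtered), derives per-type / per-position / per-pattern rates, deletion
run-length and errors-per-read histograms with their independence
references (`Geom(1−rate)`, `Binom(L, rate)`), lognormal coverage fits,
per-reference amplification efficiencies
`(1+ε_i)/(1+ε̄) = (x_i(c)/x_i(0))^(1/c)`, decay fits, and dropout (all-reads
or error-free-only).

## Worked example

Characterize PCR as an error source by re-amplifying an error-free pool and
measuring the substitution accrual from mapped reads
(`examples/02_pcr_titration.py`):

```text
   15 cycles: substitution rate 1.65e-03 nt^-1
   30 cycles: substitution rate 3.32e-03 nt^-1
   45 cycles: substitution rate 4.85e-03 nt^-1
   60 cycles: substitution rate 6.60e-03 nt^-1
   75 cycles: substitution rate 8.11e-03 nt^-1
   90 cycles: substitution rate 9.65e-03 nt^-1

regression slope: 1.069e-04 nt^-1 cycle^-1 (Taq preset: 1.09e-4)
substitution bias: A>G/T>C 60%, C>T/G>A 20%, A>T/T>A 13%
```

The regression slope is the polymerase's effective error rate — the
simulated titration recovers the configured 1.09×10⁻⁴ nt⁻¹cycle⁻¹ within
Monte-Carlo noise, with the A→G/T→C transition dominance intact.  The other
examples walk through synthesis profiles and coverage skew (`01`), decay
(`03`), sequencing inhomogeneities (`04`), the storage-density case study
(`05`), and a full workflow ending in paired FASTQ (`06`).

The same loop in code:

```python
import dnatwin as dt

refs = dt.generate_reference_pool(500, 150, seed=1)          # designed pool
pool = dt.synthesize(refs, dt.synthesis_params("electrochemical",
                                               mean_coverage=50), seed=2)
reads = dt.sequence(pool, dt.sequencing_params("iseq100",
                                               read_count=20_000), seed=3)
report = dt.error_rates(dt.map_reads(reads, refs, read_length=150), refs)
print(report.rates)        # {'sub': ..., 'del': ~0.0135, 'ins': ...}
```

## Command line

```bash
dnatwin run --config workflow.yaml --refs refs.fasta --seed 1 --out out/
dnatwin analyze --r1 out/reads_R1.fastq.gz --r2 out/reads_R2.fastq.gz \
                --refs refs.fasta --out report/
dnatwin scenario best_case --seed 1 --scale 0.17 --out scen/
```

Workflow YAML is an ordered list of steps with preset names and overrides
(see `dnatwin.parse_workflow_config` or `examples/06_workflow_and_fastq.py`).

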