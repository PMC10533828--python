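# Methods

`dnatwin` is a stochastic simulator ("digital twin") of the DNA data storage
channel — synthesis, PCR, accelerated aging, dilution, and Illumina-style
sequencing-by-synthesis — together with the analysis toolkit that measures
error rates and coverage biases back from sequencing reads.  This note
documents the model, its parameters and defaults, the numerical choices, and
what the closed-loop tests do and do not establish.

## Pool representation

An oligonucleotide pool is a collection of *variants*: distinct sequences
with integer copy counts, each attributed to the designed reference it
descends from.  References whose copies all disappear are retained with zero
count, so sequence dropout is always measurable.  The attribution is
simulator bookkeeping only: the analysis half of the package re-derives the
read-to-reference mapping by alignment, exactly as it must for real FASTQ
data.

Exponential amplification outgrows any per-molecule representation, so a
pool carries a `scale` factor: the number of physical molecules represented
by one tracked count.  PCR thins the tracked counts binomially once they
exceed `max_molecules` (default 10^6) and raises `scale` by the inverse
thinning fraction, which preserves all expected values; the extra sampling
noise this introduces is only relative to the tracked size, i.e. it appears
exactly in the regime where physical sampling noise is negligible.  Dilution
always resolves a pool back to `scale = 1` — individually tracked molecules
— which is what dilution to desk-scale copy numbers means physically.

## Error generators

**Substitutions.**  Each position of each copy substitutes independently
with probability `rate(position) * base_multiplier(base)`; the replacement is
drawn from a 4x4 row-stochastic conditional matrix with zero diagonal.  The
matrix and multipliers are built from pooled pattern fractions as reported in
the field (e.g. "A>G/T>C: 61% of substitutions"): each pooled weight is split
equally over its two directed substitutions, the residual is spread uniformly
over unnamed off-diagonal cells, row sums become per-base rate multipliers
(normalized to mean 1 over an equal base composition) and rows are normalized
into the conditional.  The multipliers are necessary: a pattern carrying more
than 25% of substitutions is impossible under equal per-base substitution
rates, so which base substitutes must itself be biased.  With this
construction the sampled pattern fractions equal the configured weights on
base-balanced input while the overall mean rate stays at the configured
value.

**Deletions.**  Copies are scanned in read coordinates.  At each position a
deletion *event* initiates with the profile probability; an event deletes one
base, extends into a run of two or more with probability `run_probability`,
and each further base continues with probability `q`
(`continuation_probability`), so runs of length >= 2 average `2 + q/(1-q)`
bases.  After a copy's first event all subsequent initiation probabilities
are multiplied by `burst_feedback`, reproducing the observed clustering of
deletions in a subset of reads (a copy that has suffered mass-transfer
trouble once is likely to suffer it again).

The positional profile is *calibrated*: because runs and burst feedback add
deletions on top of initiations, the initiation profile is rescaled — via an
exact dynamic program over (position, suffered-before) states solved with
Brent's method — so that the realized mean deletion rate equals the preset's
nominal rate.  The calibration is evaluated in the kernel's scan direction,
since burst feedback makes the expectation order-dependent.

**Run-law parameters.**  The electrochemical preset uses
`q = 0.55, run_probability = 0.05, burst_feedback = 3`.  `q` was calibrated
against the *measured* statistic, not the closed-form law: at the
electrochemical rates (up to ~5%/nt near the 5' end) adjacent *independent*
deletions frequently merge into apparent length-2 runs in the alignment, and
these chance mergers dilute the observed mean run length.  With the
closed-form choice (`q = 0.375`, law mean 2.6) the observed mean saturates
near 2.35; `q = 0.55` puts the observed mean at ~2.5-2.6 bases, at the cost
of a slightly high share of deletions in runs (~18% vs the reported 10-14%).
The material-deposition preset keeps `q = 0.375`: at its rate chance mergers
are negligible and the observed mean equals the law mean of 2.6.
`burst_feedback = 3` enriches reads with >= 3 deletion events relative to a
binomial null (over-dispersion is asserted in the property suite); it is a
free clustering parameter, not a measured constant.

**Insertions.**  A copy of length L has L+1 insertion sites (both ends
included); each receives one uniformly random base with the configured
probability (presets: 1e-4 per site at synthesis, part of the 5e-5 indel
rate at sequencing).

All generators conserve total copy count, are the identity at rate zero, and
may merge copies with identical outcomes.

## Process steps

**Synthesis** draws per-reference counts as
`round(mean_coverage * X / E[X])` with `X ~ lognormal(0, sigma^2)`, so the
normalized coverage has unit mean and lognormal shape `sigma` (presets:
1.30 electrochemical / 0.27 material deposition unconstrained; 0.58 / 0.30
GC-constrained), then passes every copy through the deletion, insertion and
substitution generators.  The electrochemical deletion profile is
exponential in synthesis direction — solved so its positional mean is
13.5e-3 nt^-1 and its terminal (5'-end) value 0.05 nt^-1 — and synthesis
proceeds 3'->5', so the profile is reversed along the forward read.  The
material-deposition profile is flat at 0.58e-3 nt^-1.  Profiles are
constructed at the payload length so the mean anchor refers to the positions
actually synthesized.

**PCR** draws one relative efficiency `rel ~ N(1, efficiency_sigma)` per
reference per step (redrawing each cycle would average the bias away and
contradict the persistent skew); the per-copy duplication probability is
`clip((1 + mean_eff) * rel - 1, 0, 1)` (clipped, not redrawn — negligible at
the preset sigma of 0.0051).  Each cycle, every variant gains
`Binomial(count, eff)` new copies; only new copies mutate, and mutated
copies become new single-copy variants.  The configured substitution rate
(Taq preset: 1.09e-4 nt^-1 cycle^-1, divided by `fidelity_relative_to_taq`,
Q5 = 280) is the *observed accrual per cycle*: because a random molecule's
lineage experiences on average `eff/(1+eff)` duplications per cycle, new
copies mutate at `rate * (1+eff)/eff` per duplication so that a titration
measured from reads recovers exactly the configured slope.  Substitution
events per variant are Poisson (the small-rate limit of per-position
Bernoulli trials; per-copy multi-hits are drawn from the same Poisson
allocation, so double substitutions in one cycle are represented).

**Aging** keeps each copy with probability `2^(-half_lives)` and applies
substitutions to survivors at `half_lives * 1.64e-4 nt^-1` through a
C>T/G>A-dominated deamination matrix (77% / 7% C>A/G>T / 6% C>G/G>C).
Substitutions are applied to survivors only — non-survivors are never
observed — and rare aging deletions (preset rate 0) would be single-base
Poisson events.

**Dilution** subsamples to a target physical mean coverage (binomial per
variant at `scale = 1`, Poisson at large scale) and refuses to "dilute up".

**Sequencing** samples oligos with replacement proportionally to counts
(sampling, like dilution and decay, is pure random subsampling); each
sampled oligo emits a forward read (its first `read_length` bases) and a
reverse read (the reverse complement's first `read_length` bases), which
then pass through direction-specific cycle-dependent substitution profiles
plus a small indel rate.  The iSeq 100 preset scales a stored per-cycle
shape curve (elevated over the first ~20 cycles, minimum near cycle 25,
slow linear rise) to mean rates of 1.1e-3 (forward) and 2.5e-3 (reverse);
the shape is a data file, not code.  Molecules shorter than `read_length`
yield shorter reads.

**Workflows** execute ordered step lists with sub-seeds derived from the
master seed and the step index alone (`SeedSequence(seed, spawn_key=(i,))`),
so appending steps never perturbs earlier ones and identical configurations
are byte-reproducible.

## Read mapping and error analysis

Reads are globally aligned (Needleman-Wunsch; match +1, mismatch -1, gap -1
— the paper-style "custom script" convention fixed here for
reproducibility) to their best-scoring reference; ties break to the lowest
reference index; similarity is matches over alignment columns, and reads
under 85% similarity are discarded and counted.  Reverse reads are
reverse-complemented first and keep their direction for stratified
statistics.  Deletions are reported at the first deleted reference base of
their run; insertions at the preceding reference base.

For speed, candidates are proposed by a unique-16-mer index and scored with
a banded dynamic program (band = length difference + 16); full-length reads
whose Hamming distance to a candidate is <= 8 take an ungapped fast path.
`exhaustive=True` aligns against every reference with the full matrix; the
test suite asserts the heuristic equals the exhaustive result, and the full
program is itself verified against a brute-force enumeration oracle on
short instances.

Reads cut off at the sequencer's cycle cap are right-censored: trailing
reference gaps reflect bases the sequencer never reached, and for capped
reads the global alignment must balance each insertion with a gap whose
position is ambiguous — so capped reads have one trailing deleted base per
insertion removed from both the event list and the aligned-nucleotide
denominator.  Without this censoring, insertion-truncation artifacts would
inflate the material-deposition deletion rate by ~17%.  A side effect is a
small (~1.5%) undercount of genuine deletions in reads that carry both an
insertion and a deletion, and terminal insertions may be invisible or scored
as substitutions (~10% undercount of the insertion rate); both are below
the tolerances of the quantities the package reports.

Derived statistics: per-type rates are events per aligned reference
nucleotide (deletion rate counts deleted bases); deletions-per-read counts a
run as one event; independence references are `Geom(1 - mean rate)` for run
lengths and `Binomial(read length, mean rate)` for errors per read.
Coverage bias is the maximum-likelihood lognormal shape of normalized
coverage, excluding zero-coverage references (they are dropout, reported
separately).  Amplification efficiencies are estimated per reference as
`(x_post/x_pre)^(1/cycles)` after excluding references under 10 reads; in
the deterministic-expectation limit the estimator is exact up to the common
mean-growth normalization.  Decay is fitted by least squares on the
log-ratio against time, `tau = ln2 / k`.

## Scenarios and problem sizes

The storage case study (synthesis at coverage 200, 20 cycles with
efficiency sigma 0.0051, dilution to the storage coverage, one half-life,
30 more cycles, iSeq sequencing; best case = material deposition + fidelity
280, worst case = electrochemical + Taq) is run at a desk scale of 2000 of
the full 12000 references; dropout fractions are per-reference quantities,
so their expectations are scale-invariant.  Sequencing depth defaults to 30
read pairs per reference — the depth is not pinned by the source material,
so it is exposed as a sensitivity parameter.  The acceptance script uses
2000-reference pools with 1e5 reads per titration point, 12000 references
for the coverage and efficiency fits, and three replicate seeds for the
case-study endpoint; these sizes put Monte-Carlo error comfortably inside
each quantity's tolerance.

## What the closed loop does and does not show

The synthetic-data generator *is* the study conditions: closed-loop tests
demonstrate that the analysis toolkit recovers the configured rates, biases,
run statistics and coverage shapes through the full simulate -> sequence ->
map -> analyze pipeline, and that the composed workflow reproduces the
published endpoint numbers.  They do not validate the presets against new
wet-lab data: real pools add sequence-dependent effects (GC content,
homopolymers), plateau-phase PCR kinetics, primer/adapter chemistry and
quality-score structure, all deliberately out of scope.  FASTQ qualities are
a constant character; nanopore and photochemical processes are extension
points, not presets.

## Known limitations

- Substitution events inside PCR/aging use a Poisson approximation per
  variant; at the preset rates the per-copy-per-cycle event probability is
  ~3.5e-2 or less, where the approximation error is far below sampling noise.
- Thinned (scaled) pools lose per-molecule granularity; statistics that
  depend on rare single molecules should dilute first (as the scenarios do).
- The mapper's k-mer prefilter can drop reads sharing no exact 16-mer with
  any reference; at the modeled error rates this is rarer than the 85%
  similarity filter itself.
- `estimate_efficiencies` returns estimates normalized to the realized pool
  mean growth, which differs from the configured mean efficiency by O(sigma^2);
  the fitted spread is unaffected.
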