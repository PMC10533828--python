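"""The five channel stages: synthesis, PCR, aging, dilution, sequencing.

Each stage consumes and produces an :class:`~dnatwin.pools.OligoPool` (or a
:class:`~dnatwin.seqio.ReadSet` for sequencing) and draws all randomness from
an explicit seed.  ``run_workflow`` composes stages into user-defined
workflows with counter-based sub-seeds, so the random stream of one step does
not depend on the steps that follow it.

PCR is a branching binomial process: each cycle, every copy duplicates with
its reference's amplification efficiency, and newly synthesized copies acquire
polymerase substitutions.  Because the configured substitution rate is the
*observed* per-cycle accrual (the quantity a titration experiment measures),
the per-duplication rate applied to new copies is
``rate * (1 + eff) / eff``: a random molecule's lineage experiences on average
``eff / (1 + eff)`` duplications per cycle, so the pool-mean error rate then
grows by exactly ``rate`` each cycle.

Exponential amplification quickly exceeds what can be tracked molecule by
molecule; above ``max_molecules`` tracked copies the pool is binomially
thinned and its ``scale`` factor raised so physical totals stay unbiased.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import seqio
from .errors import (
    PositionalRateProfile,
    RunLengthLaw,
    SubstitutionMatrix,
    calibrate_initiation_profile,
    uniform_substitution_matrix,
)
from ._kernels import deletion_scan, insertion_scan, substitution_scan
from .pools import (
    OligoPool,
    ReferencePool,
    decode_sequence,
    encode_sequence,
    reverse_complement,
)

_CHUNK_COPIES = 250_000  # per-copy expansion chunk size (memory guard)


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class SynthesisParams:
    """Synthesis stage: initial coverage skew plus synthesis errors."""

    mean_coverage: float = 200.0
    coverage_sigma: float = 0.0  # lognormal sigma of normalized coverage
    deletion_profile: PositionalRateProfile | None = None  # nominal observed rates
    run_law: RunLengthLaw = field(default_factory=RunLengthLaw)
    substitution_rate: float = 0.0
    substitution_matrix: SubstitutionMatrix | None = None
    insertion_rate: float = 1e-4
    provider_preset: str = "custom"

    def __post_init__(self) -> None:
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if self.coverage_sigma < 0:
            raise ValueError("coverage_sigma must be non-negative")

    def without_errors(self) -> "SynthesisParams":
        """The same coverage model with all error generators disabled."""
        return replace(
            self,
            deletion_profile=None,
            substitution_rate=0.0,
            insertion_rate=0.0,
        )


@dataclass
class PCRParams:
    """PCR stage: cycles, efficiency bias, and polymerase substitutions."""

    cycles: int = 15
    mean_efficiency: float = 0.9
    efficiency_sigma: float = 0.0  # sigma of the relative-efficiency normal
    substitution_rate_taq: float = 1.09e-4  # observed accrual, nt^-1 cycle^-1
    fidelity_relative_to_taq: float = 1.0  # Taq = 1, Q5 = 280
    matrix: SubstitutionMatrix | None = None
    max_molecules: float | None = 1e6  # tracked-copy cap before thinning

    def __post_init__(self) -> None:
        if self.cycles < 0:
            raise ValueError("cycles must be >= 0")
        if not 0 <= self.mean_efficiency <= 1:
            raise ValueError("mean_efficiency must lie in [0, 1]")
        if self.fidelity_relative_to_taq < 1:
            raise ValueError("fidelity_relative_to_taq must be >= 1")

    @property
    def substitution_rate(self) -> float:
        """Effective observed substitution accrual per cycle."""
        return self.substitution_rate_taq / self.fidelity_relative_to_taq


@dataclass
class AgingParams:
    """Storage stage: first-order decay plus deamination substitutions."""

    half_lives: float = 1.0
    substitution_rate_per_half_life: float = 1.64e-4
    matrix: SubstitutionMatrix | None = None
    deletion_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.half_lives < 0:
            raise ValueError("half_lives must be >= 0")

    @property
    def survival_probability(self) -> float:
        return 2.0 ** (-self.half_lives)


@dataclass
class SequencingParams:
    """Paired-end sequencing-by-synthesis with cycle-dependent substitutions."""

    read_count: int = 100_000
    read_length: int = 150
    forward_profile: PositionalRateProfile | None = None
    reverse_profile: PositionalRateProfile | None = None
    matrix_forward: SubstitutionMatrix | None = None
    matrix_reverse: SubstitutionMatrix | None = None
    indel_rate: float = 5e-5

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")


# ---------------------------------------------------------------------------
# shared helpers


def _subseed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def draw_synthesis_counts(
    n_references: int, mean_coverage: float, coverage_sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-reference initial copy counts with lognormal coverage skew.

    Counts are ``round(mean_coverage * X / E[X])`` with ``X`` lognormal(0,
    sigma^2), so the normalized coverage distribution has unit mean and
    lognormal shape ``sigma``.
    """
    if coverage_sigma == 0:
        return np.full(n_references, int(round(mean_coverage)), dtype=np.int64)
    x = rng.lognormal(0.0, coverage_sigma, n_references)
    x /= np.exp(coverage_sigma**2 / 2.0)
    return np.round(mean_coverage * x).astype(np.int64)


def _collapse(
    seqs: np.ndarray,
    lengths: np.ndarray,
    ref_of_row: np.ndarray,
    agg: dict[tuple[int, str], int],
) -> None:
    for row in range(seqs.shape[0]):
        key = (int(ref_of_row[row]), decode_sequence(seqs[row, : lengths[row]]))
        agg[key] = agg.get(key, 0) + 1


def synthesize(refs: ReferencePool, params: SynthesisParams, seed=0) -> OligoPool:
    """Synthesize a physical pool from the designed references.

    Coverage bias enters through a skewed initial count distribution; each
    copy then passes through the deletion (positional profile + burst-run
    law), insertion, and substitution generators of the synthesis preset.
    The deletion initiation profile is calibrated so that the *realized* mean
    deletion rate, including run and burst contributions, matches the
    profile's nominal mean.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(refs)
    counts = draw_synthesis_counts(n, params.mean_coverage, params.coverage_sigma, rng)
    length = refs.payload_length

    del_profile = None
    if params.deletion_profile is not None and params.deletion_profile.mean_rate > 0:
        # window the profile to the payload length before calibrating, so the
        # nominal mean refers to the positions that actually get synthesized
        window = PositionalRateProfile(
            params.deletion_profile.rates[:length], params.deletion_profile.direction
        )
        init = calibrate_initiation_profile(window, params.run_law)
        del_profile = init.in_read_coordinates(length)
    matrix = params.substitution_matrix or uniform_substitution_matrix()
    flat_sub = np.full(length, params.substitution_rate)

    ref_codes = np.stack([encode_sequence(s) for s in refs.sequences])
    agg: dict[tuple[int, str], int] = {}
    errors_off = (
        del_profile is None and params.insertion_rate == 0 and params.substitution_rate == 0
    )
    if errors_off:
        live = counts > 0
        return OligoPool(
            ref_ids=list(refs.ids),
            sequences=[refs.sequences[i] for i in np.flatnonzero(live)],
            counts=counts[live],
            ref_index=np.flatnonzero(live).astype(np.int32),
        )

    ref_of_copy = np.repeat(np.arange(n, dtype=np.int32), counts)
    total = ref_of_copy.size
    for start in range(0, total, _CHUNK_COPIES):
        block_refs = ref_of_copy[start : start + _CHUNK_COPIES]
        seqs = ref_codes[block_refs].copy()
        lengths = np.full(seqs.shape[0], length, dtype=np.int32)
        if del_profile is not None:
            seqs, lengths = deletion_scan(
                seqs,
                lengths,
                del_profile,
                params.run_law.continuation_probability,
                params.run_law.run_probability,
                params.run_law.burst_feedback,
                _subseed(rng),
            )
        if params.insertion_rate > 0:
            seqs, lengths = insertion_scan(seqs, lengths, params.insertion_rate, _subseed(rng))
        if params.substitution_rate > 0:
            prof = np.full(seqs.shape[1], params.substitution_rate)
            substitution_scan(
                seqs, lengths, prof, matrix.base_multipliers, matrix.row_cumulative(),
                _subseed(rng),
            )
        _collapse(seqs, lengths, block_refs, agg)

    ref_index = np.fromiter((k[0] for k in agg), dtype=np.int32, count=len(agg))
    sequences = [k[1] for k in agg]
    var_counts = np.fromiter(agg.values(), dtype=np.int64, count=len(agg))
    return OligoPool(
        ref_ids=list(refs.ids), sequences=sequences, counts=var_counts, ref_index=ref_index
    )


# ---------------------------------------------------------------------------
# point-substitution machinery on counted variants (PCR / aging)


def _variant_weights(sequences: list[str], matrix: SubstitutionMatrix) -> np.ndarray:
    mult = matrix.base_multipliers
    return np.fromiter(
        (mult[encode_sequence(s)].sum() for s in sequences),
        dtype=float,
        count=len(sequences),
    )


def _mutate_selected_copies(
    sequences: list[str],
    ref_index: np.ndarray,
    weights: np.ndarray,
    eligible: np.ndarray,
    event_intensity: float,
    matrix: SubstitutionMatrix,
    rng: np.random.Generator,
) -> tuple[list[str], list[int], list[float], np.ndarray]:
    """Apply point substitutions to copies drawn from counted variants.

    ``eligible`` gives, per variant, the number of copies exposed to
    mutation; each exposed copy accrues substitution events with intensity
    ``event_intensity`` per unit of sequence weight (``weights`` caches the
    per-variant sum of base multipliers).  The number of events per variant
    is Poisson — the small-rate limit of independent per-position trials —
    and events landing on the same copy are applied sequentially.  Returns
    the new single-copy variants (with their weights) and the per-variant
    count of copies removed from their parent.
    """
    mult = matrix.base_multipliers
    cond_cum = np.cumsum(matrix.conditional, axis=1)
    lam = eligible * event_intensity * weights
    n_events = rng.poisson(lam)
    new_seqs: list[str] = []
    new_refs: list[int] = []
    new_weights: list[float] = []
    removed = np.zeros(len(sequences), dtype=np.int64)
    for v in np.flatnonzero(n_events):
        k = int(n_events[v])
        n_copies = int(eligible[v])
        if n_copies == 0:
            continue
        copy_ids = rng.integers(0, n_copies, size=k)
        ids, per_copy = np.unique(copy_ids, return_counts=True)
        parent = encode_sequence(sequences[v])
        for m in per_copy:
            codes = parent.copy()
            for _ in range(int(m)):
                w = mult[codes]
                cum = np.cumsum(w)
                pos = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
                pos = min(pos, codes.size - 1)
                b = codes[pos]
                codes[pos] = int(np.searchsorted(cond_cum[b], rng.random(), side="right"))
            new_seqs.append(decode_sequence(codes))
            new_refs.append(int(ref_index[v]))
            new_weights.append(float(mult[codes].sum()))
        removed[v] = ids.size
    return new_seqs, new_refs, new_weights, removed


def pcr(pool: OligoPool, params: PCRParams, seed=0) -> OligoPool:
    """Amplify the pool by a branching binomial process.

    Each reference draws one relative efficiency ``N(1, sigma)`` for the whole
    step; its per-copy duplication probability is
    ``clip((1 + mean_eff) * rel - 1, 0, 1)``.  Per cycle and per variant, new
    copies are Binomial(count, efficiency); new copies acquire substitutions
    (observed accrual ``substitution_rate_taq / fidelity`` per cycle) and
    mutated copies become new variants.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_refs = pool.n_references
    rel = rng.normal(1.0, params.efficiency_sigma, n_refs)
    eff = np.clip((1.0 + params.mean_efficiency) * rel - 1.0, 0.0, 1.0)

    rate = params.substitution_rate
    if params.mean_efficiency > 0 and rate > 0:
        per_duplication = rate * (1.0 + params.mean_efficiency) / params.mean_efficiency
    else:
        per_duplication = 0.0
    matrix = params.matrix or uniform_substitution_matrix()

    sequences = list(pool.sequences)
    counts = pool.counts.copy()
    ref_index = pool.ref_index.copy()
    weights = _variant_weights(sequences, matrix) if per_duplication > 0 else None
    scale = pool.scale
    cap = None if params.max_molecules is None else int(params.max_molecules)

    for _ in range(params.cycles):
        p = eff[ref_index]
        new = rng.binomial(counts, p)
        if per_duplication > 0 and new.sum() > 0:
            new_seqs, new_refs, new_weights, removed = _mutate_selected_copies(
                sequences, ref_index, weights, new, per_duplication, matrix, rng
            )
            new = new - removed
            counts = counts + new
            if new_seqs:
                sequences.extend(new_seqs)
                counts = np.concatenate(
                    [counts, np.ones(len(new_seqs), dtype=np.int64)]
                )
                ref_index = np.concatenate(
                    [ref_index, np.asarray(new_refs, dtype=np.int32)]
                )
                weights = np.concatenate([weights, new_weights])
        else:
            counts = counts + new

        total = counts.sum()
        if cap is not None and total > cap:
            thin = cap / total
            counts = rng.binomial(counts, thin)
            scale /= thin
            live = counts > 0
            if not live.all():
                sequences = [s for s, keep in zip(sequences, live) if keep]
                counts = counts[live]
                ref_index = ref_index[live]
                if weights is not None:
                    weights = weights[live]

    return OligoPool(
        ref_ids=list(pool.ref_ids),
        sequences=sequences,
        counts=counts,
        ref_index=ref_index,
        scale=scale,
        efficiencies=eff,
    )


def age(pool: OligoPool, params: AgingParams, seed=0) -> OligoPool:
    """Decay the pool for ``half_lives`` half-lives and add aging damage.

    Each copy survives with probability ``2^(-half_lives)``; survivors accrue
    substitutions at ``half_lives * substitution_rate_per_half_life`` through
    the aging matrix (C>T/G>A-dominated deamination in the presets).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.binomial(pool.counts, params.survival_probability)
    sequences = list(pool.sequences)
    ref_index = pool.ref_index.copy()

    sub_rate = params.half_lives * params.substitution_rate_per_half_life
    if sub_rate > 0 and counts.sum() > 0:
        matrix = params.matrix or uniform_substitution_matrix()
        new_seqs, new_refs, _new_weights, removed = _mutate_selected_copies(
            sequences, ref_index, _variant_weights(sequences, matrix), counts,
            sub_rate, matrix, rng
        )
        counts = counts - removed
        if new_seqs:
            sequences.extend(new_seqs)
            counts = np.concatenate([counts, np.ones(len(new_seqs), dtype=np.int64)])
            ref_index = np.concatenate([ref_index, np.asarray(new_refs, dtype=np.int32)])

    if params.deletion_rate > 0 and counts.sum() > 0:
        # single-base deletion events at Poisson-distributed counts per variant
        # (aging deletions are rare and show no burst behaviour)
        lengths = np.fromiter((len(s) for s in sequences), dtype=float, count=len(sequences))
        n_events = rng.poisson(counts * lengths * params.deletion_rate)
        new_seqs: list[str] = []
        new_refs: list[int] = []
        removed = np.zeros(len(sequences), dtype=np.int64)
        for v in np.flatnonzero(n_events):
            n_copies = int(counts[v])
            if n_copies == 0:
                continue
            copy_ids = rng.integers(0, n_copies, size=int(n_events[v]))
            ids, per_copy = np.unique(copy_ids, return_counts=True)
            for m in per_copy:
                s = sequences[v]
                for _ in range(min(int(m), len(s))):
                    pos = int(rng.integers(0, len(s)))
                    s = s[:pos] + s[pos + 1 :]
                new_seqs.append(s)
                new_refs.append(int(ref_index[v]))
            removed[v] = ids.size
        counts = counts - removed
        if new_seqs:
            sequences.extend(new_seqs)
            counts = np.concatenate([counts, np.ones(len(new_seqs), dtype=np.int64)])
            ref_index = np.concatenate([ref_index, np.asarray(new_refs, dtype=np.int32)])

    live = counts > 0
    return OligoPool(
        ref_ids=list(pool.ref_ids),
        sequences=[s for s, keep in zip(sequences, live) if keep],
        counts=counts[live],
        ref_index=ref_index[live],
        scale=pool.scale,
    )


def dilute(pool: OligoPool, target_mean_coverage: float, seed=0) -> OligoPool:
    """Randomly subsample the pool down to a target physical mean coverage.

    Dilution only removes molecules.  The result is always at ``scale = 1``:
    a scaled pool is resolved back to individually tracked molecules, which is
    exactly what dilution to desk-scale copy numbers means physically.
    """
    if target_mean_coverage <= 0:
        raise ValueError("target_mean_coverage must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    target_total = target_mean_coverage * pool.n_references
    current = float(pool.counts.sum()) * pool.scale
    if target_total > current + 1e-9:
        raise ValueError(
            f"cannot dilute up: target {target_total:.0f} exceeds pool of {current:.0f}"
        )
    p = target_total / current
    if pool.scale == 1.0:
        counts = rng.binomial(pool.counts, p)
    else:
        lam = pool.counts.astype(float) * pool.scale * p
        counts = rng.poisson(lam)
    live = counts > 0
    return OligoPool(
        ref_ids=list(pool.ref_ids),
        sequences=[s for s, keep in zip(pool.sequences, live) if keep],
        counts=counts[live],
        ref_index=pool.ref_index[live],
        scale=1.0,
    )


def error_free_sequencing_params(read_count: int, read_length: int = 150) -> SequencingParams:
    """Sequencing with the error generators disabled (sampling only)."""
    return SequencingParams(
        read_count=read_count,
        read_length=read_length,
        forward_profile=PositionalRateProfile(np.zeros(read_length)),
        reverse_profile=PositionalRateProfile(np.zeros(read_length)),
        indel_rate=0.0,
    )


def sequence(pool: OligoPool, params: SequencingParams, seed=0) -> seqio.ReadSet:
    """Sample read pairs from the pool and apply sequencing errors.

    ``read_count`` oligos are drawn with replacement, with probability
    proportional to copy counts.  Each sampled oligo yields a forward read
    (its first ``read_length`` bases) and a reverse read (the first
    ``read_length`` bases of its reverse complement); each direction then
    passes through its own cycle-dependent substitution profile and matrix,
    plus rare sequencing indels.  Molecules shorter than ``read_length`` give
    naturally shorter reads.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if pool.counts.sum() == 0:
        raise ValueError("cannot sequence an empty pool")
    total = float(pool.counts.sum())
    probs = pool.counts / total
    idx = rng.choice(len(pool.sequences), size=params.read_count, p=probs)
    true_ref = pool.ref_index[idx]

    L = params.read_length
    r1, r2 = [], []
    for direction in ("forward", "reverse"):
        if direction == "forward":
            molecules = [pool.sequences[i][:L] for i in idx]
            profile = params.forward_profile
            matrix = params.matrix_forward or uniform_substitution_matrix()
        else:
            molecules = [reverse_complement(pool.sequences[i])[:L] for i in idx]
            profile = params.reverse_profile
            matrix = params.matrix_reverse or uniform_substitution_matrix()
        out_reads = r1 if direction == "forward" else r2

        for start in range(0, len(molecules), _CHUNK_COPIES):
            block = molecules[start : start + _CHUNK_COPIES]
            width = max(len(s) for s in block)
            seqs = np.zeros((len(block), width), dtype=np.uint8)
            lengths = np.zeros(len(block), dtype=np.int32)
            for i, s in enumerate(block):
                c = encode_sequence(s)
                seqs[i, : c.size] = c
                lengths[i] = c.size
            if params.indel_rate > 0:
                half = params.indel_rate / 2.0
                seqs, lengths = deletion_scan(
                    seqs, lengths, np.full(width, half), 0.0, 0.0, 1.0, _subseed(rng)
                )
                seqs, lengths = insertion_scan(seqs, lengths, half, _subseed(rng))
                np.minimum(lengths, L, out=lengths)  # the sequencer stops at L cycles
                seqs = seqs[:, : max(L, 1)]
            if profile is not None and profile.rates[:L].max() > 0:
                prof = profile.in_read_coordinates(min(L, seqs.shape[1]))
                if prof.size < seqs.shape[1]:
                    prof = np.pad(prof, (0, seqs.shape[1] - prof.size))
                substitution_scan(
                    seqs, lengths, prof, matrix.base_multipliers, matrix.row_cumulative(),
                    _subseed(rng),
                )
            for i in range(seqs.shape[0]):
                out_reads.append(decode_sequence(seqs[i, : lengths[i]]))

    return seqio.ReadSet(r1=r1, r2=r2, true_ref=[int(i) for i in true_ref])


# ---------------------------------------------------------------------------
# workflow composition


@dataclass
class WorkflowResult:
    pool: OligoPool
    reads: seqio.ReadSet | None
    log: list[dict]


_STEP_PARAM_TYPES = {
    "synthesize": SynthesisParams,
    "pcr": PCRParams,
    "age": AgingParams,
    "dilute": None,  # takes target_mean_coverage
    "sequence": SequencingParams,
}


def _pool_summary(pool: OligoPool) -> dict:
    per_ref = pool.counts_per_reference()
    return {
        "total_count": float(pool.total_count),
        "tracked_count": pool.tracked_count,
        "scale": pool.scale,
        "n_variants": len(pool.sequences),
        "mean_coverage": float(pool.mean_coverage),
        "dropout_fraction": float((per_ref == 0).mean()),
    }


def run_workflow(
    config: list[tuple[str, object]],
    refs: ReferencePool,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> WorkflowResult:
    """Execute an ordered list of ``(step_name, params)`` stages.

    Steps are validated before anything runs.  Every step receives a
    sub-seed derived from the master seed and the step index alone
    (counter-based), so appending steps never perturbs earlier ones.
    Optionally writes gzipped paired FASTQ, a JSON-lines provenance log and
    a TSV pool snapshot to ``outdir``.
    """
    for name, params in config:
        if name not in _STEP_PARAM_TYPES:
            raise ValueError(f"unknown workflow step {name!r}")
        expected = _STEP_PARAM_TYPES[name]
        if expected is not None and not isinstance(params, expected):
            raise TypeError(f"step {name!r} needs {expected.__name__}, got {type(params).__name__}")
        if name == "dilute" and not isinstance(params, (int, float)):
            raise TypeError("step 'dilute' needs a numeric target mean coverage")
    if config and config[0][0] != "synthesize":
        raise ValueError("workflows must start with a 'synthesize' step")

    pool: OligoPool | None = None
    reads: seqio.ReadSet | None = None
    log: list[dict] = []
    for i, (name, params) in enumerate(config):
        sub = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        if name == "synthesize":
            pool = synthesize(refs, params, sub)
        elif name == "pcr":
            pool = pcr(pool, params, sub)
        elif name == "age":
            pool = age(pool, params, sub)
        elif name == "dilute":
            pool = dilute(pool, float(params), sub)
        elif name == "sequence":
            reads = sequence(pool, params, sub)
        entry = {"step": i, "name": name, **_pool_summary(pool)}
        if name == "sequence":
            entry["read_pairs"] = len(reads)
        log.append(entry)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if reads is not None:
            seqio.write_fastq(reads, outdir / "reads")
        with open(outdir / "run_log.jsonl", "w") as fh:
            for entry in log:
                fh.write(json.dumps(entry) + "\n")
        with open(outdir / "pool_snapshot.tsv", "w") as fh:
            fh.write("reference_id\tvariant_sequence\tcount\n")
            for s, c, r in zip(pool.sequences, pool.counts, pool.ref_index):
                fh.write(f"{pool.ref_ids[r]}\t{s}\t{int(c)}\n")
    return WorkflowResult(pool=pool, reads=reads, log=log)
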