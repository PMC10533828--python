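"""Error generators: substitutions, deletions with burst runs, insertions.

Generators operate on *batches*: lists of ``(sequence, count)`` pairs, i.e.
groups of identical copies.  Every generator conserves the total copy count
and may merge copies that end up with identical sequences.

Three small value types parameterize the generators:

``PositionalRateProfile``
    per-position error probabilities, declared either in read coordinates or
    in synthesis coordinates (electrochemical synthesis proceeds 3'->5', so
    its profile must be reversed before being applied along a forward read).

``SubstitutionMatrix``
    where substitutions go.  Built from the pooled substitution patterns the
    field reports (e.g. "A>G/T>C transitions: 61% of substitutions").  Because
    a pattern share above 25% cannot be realized with equal per-base
    substitution rates, the matrix carries both a row-stochastic conditional
    P(observed | true, substitution) and per-base rate multipliers (mean 1
    on base-balanced sequences), so that sampled substitutions reproduce the
    configured pattern fractions while the overall mean rate stays at the
    configured value.

``RunLengthLaw``
    burst behaviour of deletions: the probability that a deletion event
    extends into a run of consecutive deletions, the run-continuation
    probability, and a within-copy feedback multiplier applied after a copy's
    first deletion event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from ._kernels import deletion_scan, insertion_scan, substitution_scan
from .pools import decode_sequence, encode_sequence

Batch = list[tuple[str, int]]

_BASES = "ACGT"

#: the six complement-pooled substitution patterns
POOLED_PATTERNS = ("A>G/T>C", "C>T/G>A", "A>T/T>A", "A>C/T>G", "C>A/G>T", "C>G/G>C")


def _rng_seed(seed: int | np.random.Generator) -> int:
    """A 31-bit seed for the numba kernels, derived from seed or Generator."""
    if isinstance(seed, np.random.Generator):
        return int(seed.integers(0, 2**31 - 1))
    return int(np.random.default_rng(seed).integers(0, 2**31 - 1))


@dataclass
class PositionalRateProfile:
    """Per-position error probability curve with a declared direction."""

    rates: np.ndarray
    direction: str = "read"  # "read" or "synthesis_3to5"

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim != 1 or self.rates.size == 0:
            raise ValueError("profile must be a non-empty 1-D array")
        if (self.rates < 0).any() or (self.rates > 1).any():
            raise ValueError("rates must lie in [0, 1]")
        if self.direction not in ("read", "synthesis_3to5"):
            raise ValueError(f"unknown profile direction {self.direction!r}")

    @property
    def mean_rate(self) -> float:
        return float(self.rates.mean())

    def __len__(self) -> int:
        return self.rates.size

    def in_read_coordinates(self, length: int) -> np.ndarray:
        """The first ``length`` positions, oriented along the forward read."""
        if length > self.rates.size:
            raise ValueError("profile shorter than the requested sequence length")
        window = self.rates[:length]
        if self.direction == "synthesis_3to5":
            # synthesis position L is the molecule's 5' end, i.e. read start
            return window[::-1].copy()
        return window.copy()

    def scaled(self, factor: float) -> "PositionalRateProfile":
        return PositionalRateProfile(np.clip(self.rates * factor, 0.0, 1.0), self.direction)

    def to_dict(self) -> dict:
        return {"rates": self.rates.tolist(), "direction": self.direction}

    @classmethod
    def from_dict(cls, d: dict) -> "PositionalRateProfile":
        return cls(np.asarray(d["rates"], dtype=float), d.get("direction", "read"))


def make_positional_profile(
    mean_rate: float,
    terminal_rate: float | None = None,
    length: int = 150,
    shape: str = "flat",
    direction: str = "read",
) -> PositionalRateProfile:
    """Construct a flat or exponential positional profile.

    ``flat`` ignores ``terminal_rate`` and returns a constant profile.
    ``exponential`` returns ``r(i) = a * exp(b * i)`` with ``a`` and ``b``
    solved numerically so that the positional mean equals ``mean_rate`` and
    the final position equals ``terminal_rate``.
    """
    if shape == "flat":
        if not 0 <= mean_rate <= 1:
            raise ValueError("mean_rate must lie in [0, 1]")
        return PositionalRateProfile(np.full(length, mean_rate), direction)
    if shape != "exponential":
        raise ValueError(f"unknown profile shape {shape!r}")
    if terminal_rate is None:
        raise ValueError("exponential profiles need a terminal_rate")
    if not 0 <= mean_rate <= terminal_rate <= 1:
        raise ValueError("need 0 <= mean_rate <= terminal_rate <= 1")
    if mean_rate == terminal_rate or mean_rate == 0:
        return PositionalRateProfile(np.full(length, mean_rate), direction)

    i = np.arange(1, length + 1, dtype=float)
    ratio = mean_rate / terminal_rate  # mean of exp(b*(i-L)) over i

    def f(b: float) -> float:
        return np.exp(b * (i - length)).mean() - ratio

    # f(0+) = 1 - ratio > 0; f decreases towards 1/length for large b
    b = brentq(f, 1e-12, 10.0)
    rates = terminal_rate * np.exp(b * (i - length))
    return PositionalRateProfile(rates, direction)


@dataclass
class SubstitutionMatrix:
    """Conditional replacement distribution plus per-base rate multipliers."""

    conditional: np.ndarray  # 4x4 row-stochastic, zero diagonal
    base_multipliers: np.ndarray  # per true base, mean 1 on balanced input
    pattern_weights: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.conditional = np.asarray(self.conditional, dtype=float)
        self.base_multipliers = np.asarray(self.base_multipliers, dtype=float)
        if self.conditional.shape != (4, 4):
            raise ValueError("conditional must be 4x4")
        if not np.allclose(np.diag(self.conditional), 0.0):
            raise ValueError("conditional diagonal must be zero")
        if not np.allclose(self.conditional.sum(axis=1), 1.0):
            raise ValueError("conditional rows must sum to 1")
        if (self.base_multipliers < 0).any():
            raise ValueError("base multipliers must be non-negative")

    def row_cumulative(self) -> np.ndarray:
        return np.cumsum(self.conditional, axis=1)

    def sequence_weight(self, codes: np.ndarray) -> float:
        """Sum of base multipliers along a sequence (expected events per unit rate)."""
        return float(self.base_multipliers[codes].sum())

    def to_dict(self) -> dict:
        return {"pattern_weights": dict(self.pattern_weights)}

    @classmethod
    def from_dict(cls, d: dict) -> "SubstitutionMatrix":
        return substitution_matrix_from_patterns(d.get("pattern_weights", {}))


def uniform_substitution_matrix() -> SubstitutionMatrix:
    return substitution_matrix_from_patterns({})


def _parse_pattern(pattern: str) -> list[tuple[int, int]]:
    pairs = []
    for part in pattern.replace("->", ">").split("/"):
        src, dst = part.strip().split(">")
        src, dst = src.strip().upper(), dst.strip().upper()
        if src not in _BASES or dst not in _BASES or src == dst:
            raise ValueError(f"malformed substitution pattern {pattern!r}")
        pairs.append((_BASES.index(src), _BASES.index(dst)))
    return pairs


def substitution_matrix_from_patterns(pattern_weights: dict) -> SubstitutionMatrix:
    """Build a SubstitutionMatrix from pooled pattern fractions.

    Each pooled pattern (e.g. ``"A>G/T>C": 0.61``) is split equally over its
    directed substitutions; the residual weight is spread uniformly over all
    off-diagonal cells not named by any pattern.  Row sums become per-base
    rate multipliers (scaled to mean 1 over an equal base composition) and
    rows are normalized into the conditional replacement distribution, so that
    sampling on base-balanced input reproduces the pattern fractions.
    """
    weights = np.zeros((4, 4), dtype=float)
    named = np.zeros((4, 4), dtype=bool)
    total = 0.0
    for pattern, w in pattern_weights.items():
        if w < 0:
            raise ValueError("pattern weights must be non-negative")
        pairs = _parse_pattern(pattern)
        total += w
        for src, dst in pairs:
            if named[src, dst]:
                raise ValueError(f"substitution {pattern!r} named twice")
            weights[src, dst] += w / len(pairs)
            named[src, dst] = True
    if total > 1.0 + 1e-9:
        raise ValueError("pattern weights must sum to at most 1")
    residual = max(0.0, 1.0 - total)
    free = ~named & ~np.eye(4, dtype=bool)
    if free.any() and residual > 0:
        weights[free] = residual / free.sum()

    row_sums = weights.sum(axis=1)
    conditional = np.full((4, 4), 1.0 / 3.0)
    np.fill_diagonal(conditional, 0.0)
    for b in range(4):
        if row_sums[b] > 0:
            conditional[b] = weights[b] / row_sums[b]
    grand = weights.sum()
    multipliers = (
        4.0 * row_sums / grand if grand > 0 else np.ones(4, dtype=float)
    )
    return SubstitutionMatrix(conditional, multipliers, dict(pattern_weights))


@dataclass
class RunLengthLaw:
    """Burst-deletion law: run starts, run continuation, within-copy feedback."""

    continuation_probability: float = 0.375
    run_probability: float = 0.055
    burst_feedback: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.continuation_probability < 1:
            raise ValueError("continuation_probability must lie in [0, 1)")
        if not 0 <= self.run_probability <= 1:
            raise ValueError("run_probability must lie in [0, 1]")
        if self.burst_feedback < 1:
            raise ValueError("burst_feedback must be >= 1")

    @property
    def mean_run_length(self) -> float:
        """Mean length of runs of two or more consecutive deletions."""
        q = self.continuation_probability
        return 2.0 + q / (1.0 - q)

    @property
    def deletions_per_event(self) -> float:
        """Expected deleted bases per deletion event (runs included)."""
        return 1.0 + self.run_probability / (1.0 - self.continuation_probability)

    @classmethod
    def from_mean_run_length(
        cls, mean_run_length: float, run_probability: float = 0.055, burst_feedback: float = 1.0
    ) -> "RunLengthLaw":
        if mean_run_length < 2:
            raise ValueError("mean run length over runs >= 2 cannot be below 2")
        q = (mean_run_length - 2.0) / (mean_run_length - 1.0)
        return cls(q, run_probability, burst_feedback)

    def to_dict(self) -> dict:
        return {
            "continuation_probability": self.continuation_probability,
            "run_probability": self.run_probability,
            "burst_feedback": self.burst_feedback,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunLengthLaw":
        return cls(**d)


# ---------------------------------------------------------------------------
# batch plumbing


def _batch_to_codes(batch: Batch) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expand a batch into per-copy code rows (one row per physical copy)."""
    total = sum(c for _, c in batch)
    width = max((len(s) for s, _ in batch), default=0)
    seqs = np.zeros((total, width), dtype=np.uint8)
    lengths = np.zeros(total, dtype=np.int32)
    row = 0
    for s, c in batch:
        if c == 0:
            continue
        codes = encode_sequence(s)
        seqs[row : row + c, : codes.size] = codes
        lengths[row : row + c] = codes.size
        row += c
    return seqs, lengths, width


def _codes_to_batch(seqs: np.ndarray, lengths: np.ndarray) -> Batch:
    agg: dict[str, int] = {}
    for row in range(seqs.shape[0]):
        s = decode_sequence(seqs[row, : lengths[row]])
        agg[s] = agg.get(s, 0) + 1
    return list(agg.items())


def _profile_array(rate, length: int) -> np.ndarray:
    if isinstance(rate, PositionalRateProfile):
        return rate.in_read_coordinates(length)
    rate = float(rate)
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0, 1]")
    return np.full(length, rate)


def apply_substitutions(
    batch: Batch,
    rate,
    matrix: SubstitutionMatrix | None = None,
    seed: int | np.random.Generator = 0,
) -> Batch:
    """Substitute each position of each copy independently.

    ``rate`` is a scalar per-nucleotide probability or a
    ``PositionalRateProfile`` in read coordinates; the replacement base is
    drawn from the matrix row of the true base, with the matrix's per-base
    multipliers biasing which bases substitute.
    """
    if matrix is None:
        matrix = uniform_substitution_matrix()
    seqs, lengths, width = _batch_to_codes(batch)
    if seqs.shape[0] == 0 or width == 0:
        return list(batch)
    profile = _profile_array(rate, width)
    substitution_scan(
        seqs, lengths, profile, matrix.base_multipliers, matrix.row_cumulative(), _rng_seed(seed)
    )
    return _codes_to_batch(seqs, lengths)


def apply_deletions(
    batch: Batch,
    profile,
    run_law: RunLengthLaw | None = None,
    seed: int | np.random.Generator = 0,
) -> Batch:
    """Delete bases according to a positional profile and a burst-run law.

    Positions are scanned in read coordinates (a synthesis-direction profile
    is reversed first).  The profile gives the probability of *initiating* a
    deletion event at each position; events may extend into runs and raise
    the copy's subsequent initiation probability by ``burst_feedback``.
    """
    if run_law is None:
        run_law = RunLengthLaw(run_probability=0.0)
    seqs, lengths, width = _batch_to_codes(batch)
    if seqs.shape[0] == 0 or width == 0:
        return list(batch)
    prof = _profile_array(profile, width)
    out, out_lengths = deletion_scan(
        seqs,
        lengths,
        prof,
        run_law.continuation_probability,
        run_law.run_probability,
        run_law.burst_feedback,
        _rng_seed(seed),
    )
    return _codes_to_batch(out, out_lengths)


def apply_insertions(
    batch: Batch,
    rate: float,
    seed: int | np.random.Generator = 0,
) -> Batch:
    """Insert a uniformly random base at each of the L+1 gaps with prob ``rate``."""
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0, 1]")
    seqs, lengths, width = _batch_to_codes(batch)
    if seqs.shape[0] == 0:
        return list(batch)
    out, out_lengths = insertion_scan(seqs, lengths, float(rate), _rng_seed(seed))
    return _codes_to_batch(out, out_lengths)


# ---------------------------------------------------------------------------
# calibration of deletion initiation profiles


def expected_deletion_fraction(
    init_profile: np.ndarray, run_law: RunLengthLaw
) -> float:
    """Exact expected fraction of deleted bases per copy under the generator.

    Dynamic program over (position, suffered-an-event-before) states; used to
    calibrate an initiation profile so that the *realized* mean deletion rate
    (which exceeds the initiation rate because of runs and burst feedback)
    matches a target.
    """
    r = np.asarray(init_profile, dtype=float)
    L = r.size
    q = run_law.continuation_probability
    p_run = run_law.run_probability
    f = run_law.burst_feedback

    def run_length_pmf(max_len: int) -> tuple[np.ndarray, float, float]:
        # P(run length = l) for l = 1..max_len-1, plus lumped tail mass/mean
        pmf = np.zeros(max_len + 1)
        pmf[1] = 1.0 - p_run
        for l in range(2, max_len + 1):
            pmf[l] = p_run * (1.0 - q) * q ** (l - 2)
        tail = 1.0 - pmf.sum()
        return pmf, max(tail, 0.0), float(max_len)

    E = {True: np.zeros(L + 2 + L), False: np.zeros(L + 2 + L)}
    for flag in (True, False):
        for i in range(L - 1, -1, -1):
            u = min(1.0, r[i] * (f if flag else 1.0))
            cont = E[flag][i + 1] if not flag else E[True][i + 1]
            remaining = L - i
            pmf, tail, tail_len = run_length_pmf(remaining)
            ev = 0.0
            for l in range(1, remaining + 1):
                if pmf[l] == 0.0:
                    continue
                ev += pmf[l] * (l + E[True][i + l])
            ev += tail * tail_len  # runs hitting the end delete everything left
            E[flag][i] = (1.0 - u) * cont + u * ev
    return E[False][0] / L


def calibrate_initiation_profile(
    profile: PositionalRateProfile,
    run_law: RunLengthLaw,
    target_mean_rate: float | None = None,
) -> PositionalRateProfile:
    """Scale a profile so the realized mean deletion rate hits a target.

    The profile's own mean is used as the target when none is given: the
    returned initiation profile is scaled down to compensate for the extra
    deletions contributed by runs and burst feedback.
    """
    if target_mean_rate is None:
        target_mean_rate = profile.mean_rate
    if target_mean_rate == 0:
        return profile.scaled(0.0)
    base = profile.rates / profile.rates.mean()
    # burst feedback makes the realized rate depend on scan order, so the
    # expectation is evaluated in read coordinates (the kernel's direction)
    scan_order = base[::-1] if profile.direction == "synthesis_3to5" else base

    def realized(scale: float) -> float:
        return expected_deletion_fraction(scan_order * scale * target_mean_rate, run_law)

    lo, hi = 1e-6, 1.0
    while realized(hi) < target_mean_rate:
        hi *= 2.0
        if hi > 1e3:
            raise ValueError("cannot reach the target deletion rate")
    scale = brentq(lambda s: realized(s) - target_mean_rate, lo, hi, xtol=1e-10)
    return PositionalRateProfile(
        np.clip(base * scale * target_mean_rate, 0.0, 1.0), profile.direction
    )
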