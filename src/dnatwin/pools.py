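"""In-memory model of designed reference pools and evolving oligonucleotide pools.

An oligonucleotide pool is represented as a collection of *variants*: distinct
sequences with an integer copy number, each attributed to the designed
reference sequence it descends from.  The reference attribution is known by
construction during simulation and is used only for bookkeeping (coverage,
dropout); the analysis toolkit deliberately ignores it and re-derives the
mapping by alignment, as one must for real sequencing data.

Copy counts are tracked as integers.  Because exponential amplification can
push physical pool sizes far beyond what is practical to track molecule by
molecule, a pool carries a ``scale`` factor: the number of physical molecules
represented by one tracked count.  All sampling steps operate on tracked
counts, and physical totals are ``tracked * scale``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

DNA_ALPHABET = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(DNA_ALPHABET)}
_CODE_TO_BASE = np.frombuffer(DNA_ALPHABET.encode(), dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _c in _BASE_TO_CODE.items():
    _ENCODE_LUT[ord(_b)] = _c


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string as a uint8 code array (A=0, C=1, G=2, T=3)."""
    codes = _ENCODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if codes.max(initial=0) == 255:
        bad = int(np.argmax(codes == 255))
        raise ValueError(f"non-ACGT character in sequence: {seq[bad]!r}")
    return codes


def decode_sequence(codes: np.ndarray) -> str:
    return _CODE_TO_BASE[codes].tobytes().decode()


@dataclass
class ReferencePool:
    """The designed sequences: unique ids and their ground-truth payloads."""

    ids: list[str]
    sequences: list[str]
    gc_constrained: bool = False
    gc_target: float | None = None
    gc_tolerance: float = 1e-9

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences must have the same length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("reference ids must be unique")
        for seq in self.sequences:
            if not seq:
                raise ValueError("reference sequences must be non-empty")
            if set(seq) - set(DNA_ALPHABET):
                raise ValueError(f"non-ACGT characters in sequence {seq!r}")
        if self.gc_constrained:
            if self.gc_target is None:
                raise ValueError("gc_constrained pools must declare gc_target")
            for seq in self.sequences:
                gc = (seq.count("G") + seq.count("C")) / len(seq)
                if abs(gc - self.gc_target) > self.gc_tolerance + 0.5 / len(seq):
                    raise ValueError(f"sequence violates GC constraint: GC={gc:.3f}")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def payload_length(self) -> int:
        return len(self.sequences[0])

    @property
    def entries(self) -> list[tuple[str, str]]:
        return list(zip(self.ids, self.sequences))


@dataclass
class OligoPool:
    """A physical pool: per-reference variant sequences with copy counts.

    ``sequences``, ``counts`` and ``ref_index`` are parallel arrays describing
    the variants.  References with zero total count simply have no live
    variants; they are retained via ``ref_ids`` so dropout stays measurable.
    """

    ref_ids: list[str]
    sequences: list[str]
    counts: np.ndarray  # int64, per-variant copy counts (tracked units)
    ref_index: np.ndarray  # int32, variant -> index into ref_ids
    scale: float = 1.0  # physical molecules per tracked count
    efficiencies: np.ndarray | None = None  # per-reference, set by the last PCR

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.ref_index = np.asarray(self.ref_index, dtype=np.int32)
        if not (len(self.sequences) == self.counts.size == self.ref_index.size):
            raise ValueError("variant arrays must be parallel")
        if (self.counts < 0).any():
            raise ValueError("copy counts must be non-negative")

    @property
    def n_references(self) -> int:
        return len(self.ref_ids)

    @property
    def tracked_count(self) -> int:
        return int(self.counts.sum())

    @property
    def total_count(self) -> float | int:
        """Physical number of molecules (tracked counts times scale)."""
        total = self.counts.sum() * self.scale
        return int(round(total)) if self.scale == 1.0 else float(total)

    @property
    def mean_coverage(self) -> float:
        return self.counts.sum() * self.scale / self.n_references

    def counts_per_reference(self, physical: bool = False) -> np.ndarray:
        """Total copies per reference, including zeros for dropped-out references."""
        per_ref = np.bincount(
            self.ref_index, weights=self.counts.astype(float), minlength=self.n_references
        )
        if physical:
            return per_ref * self.scale
        return per_ref.astype(np.int64)

    def variants(self, ref_id: str) -> list[tuple[str, int]]:
        """All (sequence, tracked count) variants attributed to one reference."""
        idx = self.ref_ids.index(ref_id)
        mask = self.ref_index == idx
        return [
            (self.sequences[i], int(self.counts[i])) for i in np.flatnonzero(mask)
        ]

    def merged(self) -> "OligoPool":
        """Merge identical (reference, sequence) variants, summing counts."""
        agg: dict[tuple[int, str], int] = {}
        for seq, cnt, ref in zip(self.sequences, self.counts, self.ref_index):
            if cnt == 0:
                continue
            key = (int(ref), seq)
            agg[key] = agg.get(key, 0) + int(cnt)
        refs = np.fromiter((k[0] for k in agg), dtype=np.int32, count=len(agg))
        seqs = [k[1] for k in agg]
        cnts = np.fromiter(agg.values(), dtype=np.int64, count=len(agg))
        return OligoPool(
            ref_ids=self.ref_ids,
            sequences=seqs,
            counts=cnts,
            ref_index=refs,
            scale=self.scale,
            efficiencies=self.efficiencies,
        )


@dataclass
class CoverageVector:
    """Per-reference coverage normalized to its mean (mean of values is 1)."""

    ids: list[str]
    values: np.ndarray  # normalized coverage, mean 1
    counts: np.ndarray = field(default=None)  # raw counts backing the values

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("coverage values must be non-negative")
        if self.counts is None:
            self.counts = self.values.copy()
        self.counts = np.asarray(self.counts, dtype=float)

    def __len__(self) -> int:
        return self.values.size


def generate_reference_pool(
    n_sequences: int,
    length: int,
    gc_constraint: float | None = None,
    seed: int | np.random.Generator = 0,
    id_prefix: str = "seq",
) -> ReferencePool:
    """Generate ``n_sequences`` unique random sequences of the given length.

    With ``gc_constraint`` given, every sequence carries exactly
    ``round(gc_constraint * length)`` G/C bases: the base composition is fixed
    and shuffled (constructive sampling), rather than filtering random draws,
    so runtime is deterministic.
    """
    if n_sequences < 1 or length < 1:
        raise ValueError("n_sequences and length must be >= 1")
    if gc_constraint is not None and not 0.0 < gc_constraint < 1.0:
        raise ValueError("gc_constraint must lie in (0, 1)")

    # sequence-space feasibility (log-scale to avoid overflow)
    if gc_constraint is None:
        log_space = length * math.log(4.0)
    else:
        n_gc = round(gc_constraint * length)
        log_space = (
            math.lgamma(length + 1)
            - math.lgamma(n_gc + 1)
            - math.lgamma(length - n_gc + 1)
            + length * math.log(2.0)
        )
    if math.log(max(n_sequences, 1)) > log_space:
        raise ValueError("requested number of unique sequences exceeds sequence space")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def draw_block(n: int) -> np.ndarray:
        if gc_constraint is None:
            return rng.integers(0, 4, size=(n, length), dtype=np.uint8)
        n_gc = round(gc_constraint * length)
        block = np.empty((n, length), dtype=np.uint8)
        # G/C positions get code 1 or 2, A/T positions 0 or 3; then shuffle columns per row
        gc_part = rng.integers(0, 2, size=(n, n_gc), dtype=np.uint8) + 1  # C=1, G=2
        at_part = rng.integers(0, 2, size=(n, length - n_gc), dtype=np.uint8) * 3  # A=0, T=3
        block[:, :n_gc] = gc_part
        block[:, n_gc:] = at_part
        perm = rng.random((n, length)).argsort(axis=1)
        return np.take_along_axis(block, perm, axis=1)

    seen: set[bytes] = set()
    sequences: list[str] = []
    while len(sequences) < n_sequences:
        block = draw_block(n_sequences - len(sequences))
        for row in block:
            key = row.tobytes()
            if key in seen:
                continue
            seen.add(key)
            sequences.append(decode_sequence(row))
            if len(sequences) == n_sequences:
                break

    ids = [f"{id_prefix}_{i:06d}" for i in range(n_sequences)]
    return ReferencePool(
        ids=ids,
        sequences=sequences,
        gc_constrained=gc_constraint is not None,
        gc_target=gc_constraint,
    )


def pool_from_references(refs: ReferencePool, counts) -> OligoPool:
    """Build a pristine pool: one variant per reference at the given copy count."""
    counts = np.asarray(counts, dtype=np.int64)
    if counts.size != len(refs):
        raise ValueError("need exactly one count per reference")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    live = counts > 0
    return OligoPool(
        ref_ids=list(refs.ids),
        sequences=[s for s, keep in zip(refs.sequences, live) if keep],
        counts=counts[live],
        ref_index=np.flatnonzero(live).astype(np.int32),
    )


def normalized_coverage(pool: OligoPool) -> CoverageVector:
    """Per-reference coverage divided by the pool mean coverage."""
    per_ref = pool.counts_per_reference(physical=False).astype(float)
    total = per_ref.sum()
    if total <= 0:
        raise ValueError("cannot normalize coverage of an empty pool")
    mean = total / pool.n_references
    return CoverageVector(ids=list(pool.ref_ids), values=per_ref / mean, counts=per_ref)


def coverage_from_counts(ids: list[str], counts) -> CoverageVector:
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("cannot normalize an all-zero coverage vector")
    return CoverageVector(ids=list(ids), values=counts / counts.mean(), counts=counts)
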