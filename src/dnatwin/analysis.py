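"""Measure error rates and biases from sequencing reads.

This is the characterization half of the toolkit: reads (simulated or real)
are globally aligned to their best-matching reference, filtered by a
similarity threshold, and the resulting mappings are condensed into error
rates by type, position, involved bases and read direction, independence
statistics (deletion run lengths vs. a geometric law, errors per read vs. a
binomial law), coverage-bias fits, amplification-efficiency estimates, decay
fits, and sequence-dropout measures.

The mapper never consults the simulator's lineage bookkeeping: reference
assignment is re-derived from sequence alone, as it must be for real data.

Alignment convention (fixed, part of the analysis contract): global
Needleman-Wunsch with match +1, mismatch -1, gap -1; the best reference is
the highest-scoring one, ties broken by lowest reference index; similarity is
matches over alignment columns.  A k-mer prefilter proposes candidate
references and a banded dynamic program scores them; on small instances this
is verified against exhaustive full-matrix alignment in the test suite.

Reads truncated by the sequencer at its read length are right-censored: a
trailing run of reference gaps in their alignment reflects bases the
sequencer never reached, not deletions, and is excluded from both the event
list and the aligned-nucleotide denominator.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._align import OP_DEL, OP_INS, OP_MATCH, hamming, nw_align
from .errors import POOLED_PATTERNS
from .pools import (
    CoverageVector,
    ReferencePool,
    encode_sequence,
    reverse_complement,
)
from .seqio import ReadSet

_KMER = 16
_HAMMING_MAX = 8  # beyond this many mismatches, suspect indels and run the DP
_BAND_PAD = 16


@dataclass(slots=True)
class ReadMapping:
    """One read's alignment against its best-scoring reference."""

    read_index: int
    ref_index: int
    direction: str  # "forward" or "reverse"
    similarity: float
    aligned_ref_nt: int  # reference positions covered (denominator share)
    # events: ("sub", ref_pos, true, observed) / ("del", ref_pos, run_length)
    #         / ("ins", ref_pos_before, observed); ref positions are 1-based,
    #         deletions are reported at the first deleted base of their run
    events: list = field(default_factory=list)

    @property
    def error_free(self) -> bool:
        return not self.events

    def n_substitutions(self) -> int:
        return sum(1 for e in self.events if e[0] == "sub")

    def n_deleted_bases(self) -> int:
        return sum(e[2] for e in self.events if e[0] == "del")

    def n_deletion_events(self) -> int:
        return sum(1 for e in self.events if e[0] == "del")

    def n_insertions(self) -> int:
        return sum(1 for e in self.events if e[0] == "ins")


class _ReferenceIndex:
    """Exact-match table plus k-mer lookup for candidate selection."""

    def __init__(self, refs: ReferencePool, read_length: int | None):
        self.refs = refs
        self.codes = [encode_sequence(s) for s in refs.sequences]
        self.exact: dict[str, int] = {}
        for i, s in enumerate(refs.sequences):
            key = s if read_length is None else s[:read_length]
            self.exact.setdefault(key, i)
        self.kmers: dict[str, int] = {}
        ambiguous: set[str] = set()
        for i, s in enumerate(refs.sequences):
            for off in range(0, len(s) - _KMER + 1):
                km = s[off : off + _KMER]
                prev = self.kmers.get(km)
                if prev is None:
                    self.kmers[km] = i
                elif prev != i:
                    ambiguous.add(km)
        for km in ambiguous:
            del self.kmers[km]

    def candidates(self, read: str) -> list[int]:
        hits: Counter[int] = Counter()
        for stride in (_KMER + 1, 1):
            for off in range(0, max(1, len(read) - _KMER + 1), stride):
                ref = self.kmers.get(read[off : off + _KMER])
                if ref is not None:
                    hits[ref] += 1
            if hits:
                break
        if not hits:
            return []
        ranked = hits.most_common()
        best = ranked[0][1]
        return sorted(i for i, c in ranked if c >= max(1, best // 2))[:4]


def _events_from_ops(
    ops: np.ndarray, read: np.ndarray, ref: np.ndarray, censor_tail: bool
) -> tuple[list, int, int, int]:
    """Walk a traceback and extract events, matches, columns, covered ref nt."""
    n_ops = ops.size
    if censor_tail:
        while n_ops > 0 and ops[n_ops - 1] == OP_DEL:
            n_ops -= 1
    events: list = []
    i = j = 0
    matches = 0
    run_start = -1
    run_len = 0
    for t in range(n_ops):
        op = ops[t]
        if op != OP_DEL and run_len:
            events.append(("del", run_start, run_len))
            run_len = 0
        if op == OP_MATCH:
            if read[i] == ref[j]:
                matches += 1
            else:
                events.append(("sub", j + 1, "ACGT"[ref[j]], "ACGT"[read[i]]))
            i += 1
            j += 1
        elif op == OP_DEL:
            if run_len == 0:
                run_start = j + 1
            run_len += 1
            j += 1
        else:  # OP_INS
            events.append(("ins", j, "ACGT"[read[i]]))
            i += 1
    if run_len:
        events.append(("del", run_start, run_len))
    return events, matches, n_ops, j


def map_reads(
    reads: ReadSet,
    refs: ReferencePool,
    min_similarity: float = 0.85,
    read_length: int | None = None,
    exhaustive: bool = False,
) -> list[ReadMapping]:
    """Align every read to its best-scoring reference and extract error events.

    Reverse reads are reverse-complemented before alignment and keep their
    direction for stratified statistics.  Reads below ``min_similarity``
    (and reads sharing no k-mer with any reference, unless ``exhaustive``)
    are discarded; the returned mappings expose the survivors.

    ``read_length`` is the sequencer's cycle cap, used to right-censor
    truncated reads; by default it is inferred as the longest read seen.
    """
    if len(refs) == 0:
        raise ValueError("reference pool is empty")
    if read_length is None:
        lengths = [len(s) for s in reads.r1 + reads.r2]
        read_length = max(lengths) if lengths else 0
    index = _ReferenceIndex(refs, read_length)
    mappings: list[ReadMapping] = []

    jobs = [(i, s, "forward") for i, s in enumerate(reads.r1)]
    jobs += [(i, reverse_complement(s), "reverse") for i, s in enumerate(reads.r2)]

    for read_idx, seq, direction in jobs:
        if not seq:
            continue
        exact = index.exact.get(seq)
        if exact is not None and len(refs.sequences[exact]) == len(seq):
            mappings.append(
                ReadMapping(read_idx, exact, direction, 1.0, len(seq), [])
            )
            continue
        read = encode_sequence(seq)
        cand = (
            list(range(len(refs)))
            if exhaustive
            else index.candidates(seq)
        )
        if not cand:
            continue
        best_score = None
        best_ref = -1
        best_payload = None  # (ops, ref_codes) or ("hamming", mismatch_positions)
        for ci in cand:
            ref = index.codes[ci]
            if not exhaustive and read.size == ref.size:
                d = hamming(read, ref)
                if d <= _HAMMING_MAX:
                    score = read.size - 2 * d
                    if best_score is None or score > best_score:
                        best_score, best_ref, best_payload = score, ci, ("hamming", ref)
                    continue
            band = read.size + ref.size if exhaustive else abs(read.size - ref.size) + _BAND_PAD
            score, ops, _ = nw_align(read, ref, band)
            if best_score is None or score > best_score:
                best_score, best_ref, best_payload = score, ci, ("ops", ops, ref)
        if best_payload is None:
            continue
        censor = len(seq) == read_length
        if best_payload[0] == "hamming":
            ref = best_payload[1]
            mism = np.flatnonzero(read != ref)
            events = [
                ("sub", int(p) + 1, "ACGT"[ref[p]], "ACGT"[read[p]]) for p in mism
            ]
            matches, columns, covered = read.size - mism.size, read.size, read.size
        else:
            _, ops, ref = best_payload
            events, matches, columns, covered = _events_from_ops(ops, read, ref, censor)
            if censor:
                # A read cut off at the sequencer's cycle cap never reaches the
                # reference tail.  Each insertion shifts one more reference
                # base out of the window, and the balancing gap the global
                # alignment must open is a truncation artifact, not a
                # deletion: discard the last deleted bases, one per insertion.
                n_ins = sum(1 for e in events if e[0] == "ins")
                n_delb = sum(e[2] for e in events if e[0] == "del")
                excess = min(n_ins, n_delb)
                k = len(events) - 1
                while excess > 0 and k >= 0:
                    if events[k][0] == "del":
                        take = min(excess, events[k][2])
                        if take == events[k][2]:
                            events.pop(k)
                        else:
                            events[k] = ("del", events[k][1], events[k][2] - take)
                        excess -= take
                        columns -= take
                        covered -= take
                    k -= 1
        similarity = matches / columns if columns else 0.0
        if similarity < min_similarity:
            continue
        mappings.append(
            ReadMapping(read_idx, best_ref, direction, similarity, covered, events)
        )
    return mappings


# ---------------------------------------------------------------------------
# aggregate statistics


def _pooled_pattern(true: str, obs: str) -> str:
    for pattern in POOLED_PATTERNS:
        if f"{true}>{obs}" in pattern.split("/"):
            return pattern
    raise ValueError(f"not a substitution: {true}>{obs}")


@dataclass
class AnalysisReport:
    """Condensed error statistics for one set of mapped reads."""

    n_reads: int
    aligned_nt: int
    rates: dict  # per-type mean rates, nt^-1 ("sub", "del", "ins")
    positional: pd.DataFrame  # per reference position, by direction and type
    pattern_fractions: dict  # pooled substitution pattern -> fraction
    run_length_histogram: dict  # deletion run length -> frequency
    errors_per_read: dict  # type -> {count: frequency}; "del" counts runs once
    read_length: int

    def rate(self, kind: str) -> float:
        return self.rates[kind]


def error_rates(
    mappings: list[ReadMapping], refs: ReferencePool
) -> AnalysisReport:
    """Per-type, per-position, and per-pattern error rates from mappings.

    Rates are events per aligned reference nucleotide.  Deletion rate counts
    deleted bases; the per-read deletion histogram counts any run of
    consecutive deletions as a single event.
    """
    if not mappings:
        raise ValueError("no mappings to analyze")
    L = refs.payload_length
    aligned_nt = 0
    n_sub = n_del_bases = n_ins = 0
    pos_counts = {
        (d, t): np.zeros(L, dtype=np.int64)
        for d in ("forward", "reverse")
        for t in ("sub", "del", "ins")
    }
    pos_cov = {d: np.zeros(L, dtype=np.int64) for d in ("forward", "reverse")}
    patterns: Counter[str] = Counter()
    run_lengths: Counter[int] = Counter()
    per_read: dict[str, Counter[int]] = {t: Counter() for t in ("sub", "del", "ins")}

    for m in mappings:
        aligned_nt += m.aligned_ref_nt
        pos_cov[m.direction][: m.aligned_ref_nt] += 1
        subs = dels = ins = 0
        for e in m.events:
            if e[0] == "sub":
                _, pos, true, obs = e
                n_sub += 1
                subs += 1
                patterns[_pooled_pattern(true, obs)] += 1
                pos_counts[(m.direction, "sub")][pos - 1] += 1
            elif e[0] == "del":
                _, pos, run = e
                n_del_bases += run
                dels += 1
                run_lengths[run] += 1
                pos_counts[(m.direction, "del")][pos - 1 : pos - 1 + run] += 1
            else:
                _, pos, _obs = e
                n_ins += 1
                ins += 1
                pos_counts[(m.direction, "ins")][max(pos - 1, 0)] += 1
        per_read["sub"][subs] += 1
        per_read["del"][dels] += 1
        per_read["ins"][ins] += 1

    rows = []
    for d in ("forward", "reverse"):
        cov = np.maximum(pos_cov[d], 1)
        for t in ("sub", "del", "ins"):
            rate = pos_counts[(d, t)] / cov
            for p in range(L):
                if pos_cov[d][p]:
                    rows.append((d, t, p + 1, rate[p], int(pos_cov[d][p])))
    positional = pd.DataFrame(
        rows, columns=["direction", "type", "position", "rate", "coverage"]
    )

    total_patterns = sum(patterns.values())
    pattern_fractions = {
        p: patterns.get(p, 0) / total_patterns if total_patterns else 0.0
        for p in POOLED_PATTERNS
    }
    total_runs = sum(run_lengths.values())
    run_hist = {
        k: v / total_runs for k, v in sorted(run_lengths.items())
    } if total_runs else {}
    per_read_freq = {
        t: {k: v / len(mappings) for k, v in sorted(c.items())}
        for t, c in per_read.items()
    }
    return AnalysisReport(
        n_reads=len(mappings),
        aligned_nt=aligned_nt,
        rates={
            "sub": n_sub / aligned_nt,
            "del": n_del_bases / aligned_nt,
            "ins": n_ins / aligned_nt,
        },
        positional=positional,
        pattern_fractions=pattern_fractions,
        run_length_histogram=run_hist,
        errors_per_read=per_read_freq,
        read_length=L,
    )


def independence_stats(report: AnalysisReport, kind: str = "del") -> dict:
    """Empirical pmfs next to their error-independence references.

    Under independence, run lengths of consecutive errors follow
    ``Geom(1 - mean rate)`` and errors per read follow
    ``Binom(read length, mean rate)``.  Deletions-per-read counts a run of
    consecutive deletions as one event.
    """
    rate = report.rates[kind]
    if kind == "del":
        empirical_runs = report.run_length_histogram
    else:
        empirical_runs = {}
    max_run = max(empirical_runs.keys(), default=1)
    support = np.arange(1, max(max_run, 5) + 1)
    # Geom(1 - rate): P(n) = rate^(n-1) * (1 - rate)
    geom_pmf = stats.geom.pmf(support, 1.0 - rate)

    per_read = report.errors_per_read[kind]
    max_count = max(per_read.keys(), default=0)
    counts = np.arange(0, max(max_count, 5) + 1)
    binom_pmf = stats.binom.pmf(counts, report.read_length, rate)
    return {
        "rate": rate,
        "run_length_empirical": empirical_runs,
        "run_length_geometric": dict(zip(support.tolist(), geom_pmf.tolist())),
        "per_read_empirical": per_read,
        "per_read_binomial": dict(zip(counts.tolist(), binom_pmf.tolist())),
    }


# ---------------------------------------------------------------------------
# coverage, efficiency, decay, dropout


def fit_lognormal_coverage(coverage: CoverageVector) -> float:
    """Maximum-likelihood lognormal shape parameter of normalized coverage.

    Zero-coverage references cannot enter a lognormal fit; they are dropout
    and are reported separately by :func:`dropout_rate`.
    """
    vals = coverage.values[coverage.values > 0]
    if vals.size < 2:
        raise ValueError("need at least two positive coverage values")
    log_vals = np.log(vals)
    return float(np.sqrt(np.mean((log_vals - log_vals.mean()) ** 2)))


@dataclass
class EfficiencyEstimate:
    """Per-reference relative amplification efficiencies and their spread."""

    ids: list[str]
    relative_efficiency: np.ndarray  # (1 + eff_i) / (1 + mean eff)
    sigma: float  # std of a normal fitted to the estimates
    n_excluded: int


def estimate_efficiencies(
    pre: CoverageVector,
    post: CoverageVector,
    cycles: int,
    min_reads: int = 10,
) -> EfficiencyEstimate:
    """Relative amplification efficiencies from pre/post coverage fold change.

    For each reference, ``(x_post / x_pre) ** (1 / cycles)`` estimates the
    relative efficiency ``(1 + eff_i) / (1 + mean_eff)``; references with
    fewer than ``min_reads`` observations in either dataset are excluded (the
    fold change is too noisy at low coverage).
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    if pre.ids != post.ids:
        raise ValueError("pre and post coverage vectors must be aligned by id")
    ok = (pre.counts >= min_reads) & (post.counts >= min_reads) & (pre.values > 0)
    n_excluded = int((~ok).sum())
    ratio = post.values[ok] / pre.values[ok]
    est = ratio ** (1.0 / cycles)
    sigma = float(est.std(ddof=0)) if est.size else float("nan")
    return EfficiencyEstimate(
        ids=[i for i, keep in zip(pre.ids, ok) if keep],
        relative_efficiency=est,
        sigma=sigma,
        n_excluded=n_excluded,
    )


def fit_decay(concentrations, times) -> dict:
    """First-order decay fit: c(t)/c(0) = exp(-k t), with tau = ln2 / k.

    Least squares on the log-ratio against time; concentrations are
    normalized to the first time point if no exact t=0 sample is present.
    """
    c = np.asarray(concentrations, dtype=float)
    t = np.asarray(times, dtype=float)
    if c.size != t.size or c.size < 2:
        raise ValueError("need matching concentrations and times, at least two points")
    if (c <= 0).any():
        raise ValueError("concentrations must be positive")
    c0 = c[t == 0][0] if (t == 0).any() else c[np.argmin(t)]
    y = np.log(c / c0)
    slope, _intercept = np.polyfit(t, y, 1)
    k = -slope
    return {"k": float(k), "tau": float(np.log(2) / k) if k != 0 else float("inf")}


def dropout_rate(
    mappings: list[ReadMapping],
    refs: ReferencePool,
    error_free_only: bool = False,
) -> float:
    """Fraction of designed references absent from the mapped reads.

    With ``error_free_only``, a reference only counts as present if at least
    one of its reads is error-free (what a code without within-sequence
    redundancy can use).
    """
    if len(refs) == 0:
        raise ValueError("reference pool is empty")
    present: set[int] = set()
    for m in mappings:
        if error_free_only and not m.error_free:
            continue
        present.add(m.ref_index)
    return 1.0 - len(present) / len(refs)


def pool_dropout(pool, error_free_only: bool = False, refs: ReferencePool | None = None) -> float:
    """Dropout measured on a pool's counts instead of mapped reads."""
    if error_free_only:
        if refs is None:
            raise ValueError("error_free_only pool dropout needs the references")
        present = {
            int(r)
            for s, c, r in zip(pool.sequences, pool.counts, pool.ref_index)
            if c > 0 and s == refs.sequences[int(r)]
        }
        return 1.0 - len(present) / pool.n_references
    per_ref = pool.counts_per_reference()
    return float((per_ref == 0).mean())
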