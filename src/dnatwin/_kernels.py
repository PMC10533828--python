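"""Numba kernels for per-copy mutation machinery.

Sequences are handled as uint8 code matrices (A=0, C=1, G=2, T=3) with a
parallel length vector, so the kernels work on ragged batches.  Each kernel
seeds numba's internal RNG from an explicit integer, which makes every run
bit-reproducible for a given seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def deletion_scan(
    seqs: np.ndarray,
    lengths: np.ndarray,
    profile: np.ndarray,
    continuation_p: float,
    run_p: float,
    burst_feedback: float,
    seed: int,
):
    """Positional deletions with burst runs and within-copy clustering.

    For every copy, positions are scanned in read coordinates.  At position
    ``i`` a deletion event starts with probability ``profile[i]`` (times
    ``burst_feedback`` once the copy has already suffered an event).  An event
    deletes one base; with probability ``run_p`` it extends into a run of
    consecutive deletions whose length beyond two continues with probability
    ``continuation_p`` per extra base (mean run length over runs >= 2 is
    ``2 + q/(1-q)``).
    """
    np.random.seed(seed)
    n, width = seqs.shape
    out = np.zeros((n, width), dtype=np.uint8)
    out_lengths = np.zeros(n, dtype=np.int32)
    for c in range(n):
        L = lengths[c]
        mult = 1.0
        i = 0
        k = 0
        while i < L:
            p = profile[i] * mult
            if p > 1.0:
                p = 1.0
            if p > 0.0 and np.random.random() < p:
                # deletion event starting at i
                run = 1
                if np.random.random() < run_p:
                    run = 2
                    while np.random.random() < continuation_p:
                        run += 1
                i += run
                mult = burst_feedback
            else:
                out[c, k] = seqs[c, i]
                k += 1
                i += 1
        out_lengths[c] = k
    return out, out_lengths


@njit(cache=True)
def insertion_scan(
    seqs: np.ndarray,
    lengths: np.ndarray,
    rate: float,
    seed: int,
):
    """Uniform random single-base insertions at every inter-base gap.

    A copy of length L has L+1 insertion sites (both ends included); each site
    independently receives one uniformly random base with probability ``rate``.
    """
    np.random.seed(seed)
    n, width = seqs.shape
    max_out = 2 * width + 1
    out = np.zeros((n, max_out), dtype=np.uint8)
    out_lengths = np.zeros(n, dtype=np.int32)
    for c in range(n):
        L = lengths[c]
        k = 0
        for i in range(L + 1):
            if rate > 0.0 and np.random.random() < rate:
                out[c, k] = np.uint8(np.random.randint(0, 4))
                k += 1
            if i < L:
                out[c, k] = seqs[c, i]
                k += 1
        out_lengths[c] = k
    return out, out_lengths


@njit(cache=True)
def substitution_scan(
    seqs: np.ndarray,
    lengths: np.ndarray,
    profile: np.ndarray,
    base_mult: np.ndarray,
    row_cumulative: np.ndarray,
    seed: int,
):
    """Positional substitutions with base-biased rates and replacement rows.

    The probability of substituting position ``i`` of a copy carrying base
    ``b`` is ``profile[i] * base_mult[b]`` (clipped to 1).  The replacement
    base is drawn from ``row_cumulative[b]``, the cumulative conditional
    distribution over observed bases given a substitution of ``b``.
    Mutation is done in place; the number of substitutions is returned.
    """
    np.random.seed(seed)
    n, width = seqs.shape
    n_subs = 0
    for c in range(n):
        L = lengths[c]
        for i in range(L):
            b = seqs[c, i]
            p = profile[i] * base_mult[b]
            if p > 1.0:
                p = 1.0
            if p > 0.0 and np.random.random() < p:
                r = np.random.random()
                newb = 3
                for j in range(4):
                    if r < row_cumulative[b, j]:
                        newb = j
                        break
                seqs[c, i] = np.uint8(newb)
                n_subs += 1
    return n_subs
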