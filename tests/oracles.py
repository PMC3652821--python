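"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's log-space tail machinery: overlap
probabilities come from exhaustive enumeration over subsets (bitmask
representation) or from vectorized Monte-Carlo draws.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def enum_twoway_tail(N: int, a: int, b: int, t: int) -> float:
    """P(|A ∩ B| >= t) by enumerating every size-b subset against a fixed A.

    Fixing A = {0..a-1} is without loss of generality: the overlap law only
    depends on (N, a, b).
    """
    a_mask = (1 << a) - 1
    hits = 0
    total = 0
    for B in combinations(range(N), b):
        b_mask = 0
        for i in B:
            b_mask |= 1 << i
        total += 1
        if bin(a_mask & b_mask).count("1") >= t:
            hits += 1
    return hits / total


def enum_threeway_tail(N: int, a: int, b: int, c: int, t: int) -> float:
    """P(|A ∩ B ∩ C| >= t) by enumerating all (B, C) pairs against fixed A."""
    a_mask = (1 << a) - 1
    b_masks = []
    for B in combinations(range(N), b):
        m = 0
        for i in B:
            m |= 1 << i
        b_masks.append(m)
    c_masks = []
    for C in combinations(range(N), c):
        m = 0
        for i in C:
            m |= 1 << i
        c_masks.append(m)
    hits = 0
    for bm in b_masks:
        ab = a_mask & bm
        for cm in c_masks:
            if bin(ab & cm).count("1") >= t:
                hits += 1
    return hits / (len(b_masks) * len(c_masks))


def mc_threeway_overlap_counts(
    N: int, a: int, b: int, c: int, n_draws: int, seed: int
) -> np.ndarray:
    """Monte-Carlo draws of |A ∩ B ∩ C| with A fixed to the first a elements."""
    rng = np.random.default_rng(seed)
    rb = rng.random((n_draws, N)).argpartition(b - 1, axis=1)[:, :b]
    rc = rng.random((n_draws, N)).argpartition(c - 1, axis=1)[:, :c]
    b_mask = np.zeros((n_draws, N), dtype=bool)
    np.put_along_axis(b_mask, rb, True, axis=1)
    c_mask = np.zeros((n_draws, N), dtype=bool)
    np.put_along_axis(c_mask, rc, True, axis=1)
    return (b_mask & c_mask)[:, :a].sum(axis=1)
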