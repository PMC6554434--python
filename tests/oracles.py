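"""Independent brute-force oracles used by the test suite.

These enumerate the search spaces directly and deliberately share no code
with the package's dynamic-programming implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def lcs_by_enumeration(s1: str, s2: str) -> int:
    """Longest common subsequence length by enumerating subsequences of s1."""
    best = 0
    for r in range(len(s1), 0, -1):
        if r <= best:
            break
        for idxs in itertools.combinations(range(len(s1)), r):
            sub = "".join(s1[i] for i in idxs)
            it = iter(s2)
            if all(c in it for c in sub):
                best = r
                break
    return best


def chain_oracle(c1: np.ndarray, c2: np.ndarray, alpha: float) -> float:
    """Best monotone partial alignment of two windows, by exhaustive search.

    A chain is a set of matched bin pairs strictly increasing in both
    coordinates.  It scores the sum of the matched bins' inner products
    minus, for every maximal run of g skipped bins strictly between two
    consecutive matches (on either side), a charge exp(alpha * g).  Leading
    and trailing gaps are free and the empty chain scores 0.
    """
    L1, L2 = c1.shape[1], c2.shape[1]
    dots = c1.T @ c2
    best = 0.0
    for m in range(1, min(L1, L2) + 1):
        for rows in itertools.combinations(range(L1), m):
            for cols in itertools.combinations(range(L2), m):
                score = sum(dots[a, b] for a, b in zip(rows, cols))
                for t in range(1, m):
                    gv = rows[t] - rows[t - 1] - 1
                    gh = cols[t] - cols[t - 1] - 1
                    if gv > 0:
                        score -= math.exp(alpha * gv)
                    if gh > 0:
                        score -= math.exp(alpha * gh)
                if score > best:
                    best = score
    return best
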