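"""Edit-similarity core.

Two aligners live here:

* :func:`nw_score_strings` — the classic Needleman–Wunsch recursion on plain
  strings (match +1, gaps free), with β-table traceback returning the maximal
  common subsequence.  Used for validation and exposition.
* :func:`edit_similarity` — the extension to population spike windows.  A
  window is a string whose characters are the per-bin spike-count vectors;
  character coincidence is scored by the inner product of the two count
  vectors, a run of ``g`` consecutive gaps is charged ``exp(alpha * g)``, and
  scores are floored at zero so alignments may start anywhere inside the
  windows (local restart).  The similarity is the maximum cell of the dynamic
  programming table, i.e. the score of the best local chain of bin matches.

Gap runs are tracked greedily: each cell keeps the length of the best vertical
(resp. horizontal) gap run ending there, updated by comparing a fresh
single-gap start against extending the previous run, before the score cell is
evaluated.  Counters reset when the zero floor is taken (a restart begins a
fresh local alignment).  Tie-breaking prefers diagonal over vertical over
horizontal over restart, giving a deterministic traceback.

A numba kernel (:func:`batch_edit_similarity`) evaluates many window pairs at
once; it is score-only and must agree exactly with the traceback version.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "AlignmentResult",
    "SimilarityStore",
    "nw_score_strings",
    "edit_similarity",
    "batch_edit_similarity",
    "distance_from_similarity",
]


# ---------------------------------------------------------------------------
# Classic N-W on strings


def nw_score_strings(
    s1: str, s2: str, match_score: float = 1.0, gap_score: float = 0.0
) -> tuple[float, str]:
    """Needleman–Wunsch similarity between two strings.

    Returns ``(score, common_subsequence)``: the score is the top-right cell
    of the DP table; the subsequence collects the characters taken by
    diagonal moves during traceback.  With the default scoring this is the
    longest common subsequence.
    """
    n1, n2 = len(s1), len(s2)
    eps = np.zeros((n1 + 1, n2 + 1))
    for a in range(1, n1 + 1):
        for b in range(1, n2 + 1):
            diag = eps[a - 1, b - 1] + (match_score if s1[a - 1] == s2[b - 1] else 0.0)
            eps[a, b] = max(diag, eps[a - 1, b] + gap_score, eps[a, b - 1] + gap_score)
    # beta-table traceback, preferring diagonal moves
    out: list[str] = []
    a, b = n1, n2
    while a > 0 and b > 0:
        diag = eps[a - 1, b - 1] + (match_score if s1[a - 1] == s2[b - 1] else 0.0)
        if eps[a, b] == diag and s1[a - 1] == s2[b - 1]:
            out.append(s1[a - 1])
            a, b = a - 1, b - 1
        elif eps[a, b] == eps[a - 1, b] + gap_score:
            a -= 1
        elif eps[a, b] == eps[a, b - 1] + gap_score:
            b -= 1
        else:  # diagonal without coincidence
            a, b = a - 1, b - 1
    return float(eps[n1, n2]), "".join(reversed(out))


# ---------------------------------------------------------------------------
# Extended N-W on spike-count windows


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of one extended-N-W comparison."""

    similarity: float
    pairs: list[tuple[int, int]] | None = None  # matched (bin of W1, bin of W2)


def _check_shapes(c1: np.ndarray, c2: np.ndarray) -> None:
    if c1.ndim != 2 or c2.ndim != 2 or c1.shape[0] != c2.shape[0]:
        raise ValueError(
            f"windows must share the neuron dimension; got {c1.shape} vs {c2.shape}"
        )


def edit_similarity(
    w1, w2, alpha: float, with_traceback: bool = False
) -> AlignmentResult:
    """Edit similarity between two windows (count matrices or WindowMatrix).

    ``alpha >= 0`` sets the exponential gap penalty ``exp(alpha * g)`` per run
    of ``g`` gaps; larger values tolerate smaller timing lags between matched
    bins.  With ``with_traceback`` the strictly monotone list of matched bin
    pairs of the best chain is returned as well.
    """
    c1 = np.asarray(getattr(w1, "counts", w1), dtype=np.float64)
    c2 = np.asarray(getattr(w2, "counts", w2), dtype=np.float64)
    _check_shapes(c1, c2)
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    L1, L2 = c1.shape[1], c2.shape[1]
    dot = c1.T @ c2  # (L1, L2) bin-pair inner products
    gp = np.exp(alpha * np.arange(max(L1, L2) + 2))

    eps = np.zeros((L1 + 1, L2 + 1))
    vrun = np.zeros((L1 + 1, L2 + 1), dtype=np.int64)
    hrun = np.zeros((L1 + 1, L2 + 1), dtype=np.int64)
    move = np.zeros((L1 + 1, L2 + 1), dtype=np.int8)  # 0 stop, 1 diag, 2 vert, 3 horiz
    vjump = np.zeros((L1 + 1, L2 + 1), dtype=np.int64)
    hjump = np.zeros((L1 + 1, L2 + 1), dtype=np.int64)
    for a in range(1, L1 + 1):
        for b in range(1, L2 + 1):
            # gap-run counters, evaluated before the score cell: a fresh
            # single gap against extending the previous run to length pu+1,
            # both costed at this cell
            pu = vrun[a - 1, b]
            u = 1 if eps[a - 1, b] - gp[1] >= eps[a - 1 - pu, b] - gp[pu + 1] else pu + 1
            pr = hrun[a, b - 1]
            r = 1 if eps[a, b - 1] - gp[1] >= eps[a, b - 1 - pr] - gp[pr + 1] else pr + 1
            vrun[a, b], hrun[a, b] = u, r
            diag = eps[a - 1, b - 1] + dot[a - 1, b - 1]
            vert = eps[a - u, b] - gp[u]
            horiz = eps[a, b - r] - gp[r]
            best = max(0.0, diag, vert, horiz)
            eps[a, b] = best
            if diag == best and best > 0.0:
                move[a, b] = 1
            elif vert == best and best > 0.0:
                move[a, b] = 2
                vjump[a, b] = u
            elif horiz == best and best > 0.0:
                move[a, b] = 3
                hjump[a, b] = r
            else:  # zero floor: restart, reset the gap counters
                move[a, b] = 0
                vrun[a, b] = 0
                hrun[a, b] = 0

    score = float(eps.max())
    if not with_traceback:
        return AlignmentResult(score)
    pairs: list[tuple[int, int]] = []
    a, b = np.unravel_index(int(np.argmax(eps)), eps.shape)
    while a > 0 and b > 0 and move[a, b] != 0:
        m = move[a, b]
        if m == 1:
            pairs.append((a - 1, b - 1))
            a, b = a - 1, b - 1
        elif m == 2:
            a -= vjump[a, b]
        else:
            b -= hjump[a, b]
    pairs.reverse()
    return AlignmentResult(score, pairs)


@njit(cache=True)
def _dp_score(dot: np.ndarray, gp: np.ndarray) -> float:  # pragma: no cover - numba
    L1 = dot.shape[0]
    L2 = dot.shape[1]
    eps = np.zeros((L1 + 1, L2 + 1))
    vrun = np.zeros((L1 + 1, L2 + 1), dtype=np.int64)
    hrun = np.zeros((L1 + 1, L2 + 1), dtype=np.int64)
    best_all = 0.0
    for a in range(1, L1 + 1):
        for b in range(1, L2 + 1):
            pu = vrun[a - 1, b]
            if eps[a - 1, b] - gp[1] >= eps[a - 1 - pu, b] - gp[pu + 1]:
                u = 1
            else:
                u = pu + 1
            pr = hrun[a, b - 1]
            if eps[a, b - 1] - gp[1] >= eps[a, b - 1 - pr] - gp[pr + 1]:
                r = 1
            else:
                r = pr + 1
            vrun[a, b] = u
            hrun[a, b] = r
            best = 0.0
            diag = eps[a - 1, b - 1] + dot[a - 1, b - 1]
            if diag > best:
                best = diag
            vert = eps[a - u, b] - gp[u]
            if vert > best:
                best = vert
            horiz = eps[a, b - r] - gp[r]
            if horiz > best:
                best = horiz
            eps[a, b] = best
            if best <= 0.0:
                vrun[a, b] = 0
                hrun[a, b] = 0
            if best > best_all:
                best_all = best
    return best_all


@njit(cache=True)
def _batch_scores(
    wt: np.ndarray, w: np.ndarray, pairs: np.ndarray, gp: np.ndarray
) -> np.ndarray:  # pragma: no cover - numba
    out = np.empty(pairs.shape[0])
    for p in range(pairs.shape[0]):
        k1 = pairs[p, 0]
        k2 = pairs[p, 1]
        dot = np.dot(wt[k1], w[k2])
        out[p] = _dp_score(dot, gp)
    return out


def batch_edit_similarity(
    windows: np.ndarray, pairs: np.ndarray, alpha: float
) -> np.ndarray:
    """Edit similarity for many window pairs of one recording.

    Parameters
    ----------
    windows : (M, N, L) array
        Stacked spike-count matrices (see :func:`spikeseq.io.window_tensor`).
    pairs : (P, 2) int array
        Window-index pairs to score.
    alpha : float
        Gap-penalty weight.
    """
    w = np.ascontiguousarray(windows, dtype=np.float64)
    wt = np.ascontiguousarray(w.transpose(0, 2, 1))
    pairs = np.ascontiguousarray(pairs, dtype=np.int64)
    if pairs.size == 0:
        return np.zeros(0)
    L = w.shape[2]
    gp = np.exp(alpha * np.arange(L + 2, dtype=np.float64))
    return _batch_scores(wt, w, pairs, gp)


# ---------------------------------------------------------------------------
# Similarity store and the distance transform


@dataclass
class SimilarityStore:
    """Sparse symmetric map ``(k, k') -> edit similarity`` over M windows.

    Pairs pruned by the MinHash stage are never computed; the distance
    transform assigns them the maximal distance.
    """

    n_items: int
    values: dict[tuple[int, int], float] = field(default_factory=dict)

    @staticmethod
    def _key(i: int, j: int) -> tuple[int, int]:
        return (i, j) if i < j else (j, i)

    def set(self, i: int, j: int, value: float) -> None:
        if i == j:
            return
        self.values[self._key(i, j)] = float(value)

    def get(self, i: int, j: int, default: float = 0.0) -> float:
        if i == j:
            return 0.0
        return self.values.get(self._key(i, j), default)

    @classmethod
    def from_pairs(
        cls, n_items: int, pairs: np.ndarray, scores: np.ndarray
    ) -> "SimilarityStore":
        store = cls(n_items)
        for (i, j), s in zip(np.asarray(pairs), np.asarray(scores)):
            store.set(int(i), int(j), float(s))
        return store

    @property
    def max_value(self) -> float:
        if not self.values:
            raise ValueError("empty similarity store")
        return max(self.values.values())

    def dense(self, fill: float = 0.0, diagonal: float = 0.0) -> np.ndarray:
        """Dense symmetric matrix of the stored values."""
        m = np.full((self.n_items, self.n_items), fill)
        np.fill_diagonal(m, diagonal)
        for (i, j), v in self.values.items():
            m[i, j] = v
            m[j, i] = v
        return m


def distance_from_similarity(store: SimilarityStore) -> SimilarityStore:
    """Distance transform ``D(k,k') = E_max - E(k,k')``.

    ``E_max`` is the maximum over computed pairs; pairs never computed are at
    maximal distance ``E_max`` (the transform's zero-similarity image), which
    :meth:`SimilarityStore.dense` realises via its ``fill`` default here.
    """
    e_max = store.max_value
    dist = SimilarityStore(store.n_items)
    for (i, j), v in store.values.items():
        dist.set(i, j, e_max - v)
    return dist


def dense_distance_matrix(store: SimilarityStore) -> np.ndarray:
    """Full ``M x M`` distance matrix with uncomputed pairs at ``E_max``."""
    e_max = store.max_value
    m = np.full((store.n_items, store.n_items), e_max)
    np.fill_diagonal(m, 0.0)
    for (i, j), v in store.values.items():
        m[i, j] = e_max - v
        m[j, i] = e_max - v
    return m
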