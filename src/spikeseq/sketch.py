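"""Candidate-pair pruning with Jaccard similarity, MinHash and banding.

Computing the edit similarity for all ``M*(M-1)/2`` window pairs is
quadratic in the number of windows and dominates the cost of the whole
pipeline.  Window pairs that share few active neurons cannot score highly,
so we prune them: each window is reduced to the Boolean mask of neurons that
fire at least once in it, mask overlap is measured by Jaccard similarity,
and a banded MinHash signature selects candidate pairs without any pairwise
comparison.  Two windows become a candidate iff their signatures agree on
all ``l`` rows of at least one of ``b`` bands, which happens with
probability ``p(s) = 1 - (1 - s**l)**b`` for masks of Jaccard similarity
``s`` — an S-shaped curve acting as a soft threshold.

The band geometry ``(b, l)`` is chosen from the data itself: assuming
independent Poisson neurons at the observed mean rates, ``jaccard_1`` is the
mask similarity expected between unrelated windows and ``jaccard_2`` the
similarity expected when ``n_extra`` additional neurons coincide (a putative
assembly).  A brute-force search picks the cheapest ``(b, l)`` whose curve
discards the former (``p <= p_low``) and keeps the latter (``p >= p_high``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SpikeData, WindowConfig

__all__ = [
    "BandParams",
    "activity_masks",
    "jaccard",
    "candidate_probability",
    "estimate_jaccard_thresholds",
    "select_band_params",
    "build_signatures",
    "candidate_pairs",
]

_EMPTY_SENTINEL = np.uint64(0xFFFFFFFFFFFFFFFF)


@dataclass(frozen=True)
class BandParams:
    """Banded-MinHash geometry: ``n_bands * rows_per_band`` hash functions."""

    n_bands: int
    rows_per_band: int

    def __post_init__(self) -> None:
        if self.n_bands < 1 or self.rows_per_band < 1:
            raise ValueError("band parameters must be >= 1")

    @property
    def n_hashes(self) -> int:
        return self.n_bands * self.rows_per_band


def activity_masks(windows: np.ndarray) -> np.ndarray:
    """Boolean ``(M, N)`` matrix: neuron i fired at least once in window k.

    ``windows`` is the ``(M, N, L)`` count tensor (or a single ``(N, L)``
    matrix, giving a single mask).
    """
    w = np.asarray(windows)
    if w.ndim == 2:
        return w.sum(axis=1) >= 1
    return w.sum(axis=2) >= 1


def jaccard(m1: np.ndarray, m2: np.ndarray) -> float:
    """Jaccard similarity |m1 ∩ m2| / |m1 ∪ m2| of two Boolean masks.

    Two all-zero masks have similarity 0 by convention.
    """
    m1 = np.asarray(m1, dtype=bool)
    m2 = np.asarray(m2, dtype=bool)
    if m1.shape != m2.shape:
        raise ValueError("masks must have equal length")
    union = np.count_nonzero(m1 | m2)
    if union == 0:
        return 0.0
    return np.count_nonzero(m1 & m2) / union


def candidate_probability(s: float, n_bands: int, rows_per_band: int) -> float:
    """Probability ``1 - (1 - s**l)**b`` that banding keeps a pair.

    ``s`` is the Jaccard similarity of the two masks; the value is the chance
    that the two signature columns agree on every row of at least one band.
    """
    s = float(s)
    if not 0.0 <= s <= 1.0:
        raise ValueError("similarity must lie in [0, 1]")
    if n_bands < 1 or rows_per_band < 1:
        raise ValueError("band parameters must be >= 1")
    return 1.0 - (1.0 - s**rows_per_band) ** n_bands


def estimate_jaccard_thresholds(
    data: SpikeData, cfg: WindowConfig, n_extra: int
) -> tuple[float, float]:
    """Noise and signal Jaccard levels under independent Poisson firing.

    Per neuron, ``p_i = 1 - (1 - (#_i/T) * b)**L`` approximates the chance of
    at least one spike in a window (L bins of size b).  With
    ``N1 = sum p_i`` expected active neurons per window and ``N2 = sum p_i^2``
    expected coincidences between two windows, the expected Jaccard of two
    unrelated windows is ``N2 / (2*N1 - N2)``; if ``n_extra`` additional
    neurons coincide (the assumed assembly size), it rises to
    ``(N2 + n_extra) / (2*N1 - N2 - n_extra)``.
    """
    if n_extra < 0:
        raise ValueError("n_extra must be non-negative")
    rate_per_bin = data.rates() * cfg.bin_size
    p = 1.0 - (1.0 - np.clip(rate_per_bin, 0.0, 1.0)) ** cfg.n_bins
    n1 = float(p.sum())
    n2 = float((p**2).sum())
    if n1 == 0.0:
        return 0.0, 0.0 if n_extra == 0 else 1.0
    j1 = n2 / (2.0 * n1 - n2)
    denom = 2.0 * n1 - n2 - n_extra
    if denom <= 0 or (n2 + n_extra) / denom > 1.0:
        raise ValueError(
            f"n_extra={n_extra} too large for this population (jaccard_2 > 1)"
        )
    j2 = (n2 + n_extra) / denom
    return j1, j2


def select_band_params(
    jaccard1: float,
    jaccard2: float,
    p_low: float = 0.1,
    p_high: float = 0.8,
    search_max: int = 50,
) -> BandParams:
    """Brute-force search for the cheapest feasible band geometry.

    Feasible means ``p(jaccard1) <= p_low`` (unrelated pairs discarded) and
    ``p(jaccard2) >= p_high`` (assembly pairs kept), for ``b`` and ``l`` in
    ``[1, search_max]``.  Among feasible pairs the one with the fewest hash
    functions ``b*l`` wins; ties go to the smaller ``l``.
    """
    if not jaccard1 < jaccard2:
        raise ValueError("jaccard1 must be smaller than jaccard2")
    best: BandParams | None = None
    for l in range(1, search_max + 1):
        for b in range(1, search_max + 1):
            if best is not None and b * l >= best.n_hashes:
                break
            if (
                candidate_probability(jaccard1, b, l) <= p_low
                and candidate_probability(jaccard2, b, l) >= p_high
            ):
                cand = BandParams(b, l)
                if (
                    best is None
                    or cand.n_hashes < best.n_hashes
                    or (cand.n_hashes == best.n_hashes and l < best.rows_per_band)
                ):
                    best = cand
    if best is None:
        raise ValueError(
            f"no (bands, rows) in [1, {search_max}] separates jaccard "
            f"{jaccard1:.3f} from {jaccard2:.3f}; consider a larger n_extra"
        )
    return best


def _mix64(x: np.ndarray) -> np.ndarray:
    """splitmix64 finalizer: a bijective (hence collision-free) 64-bit mix."""
    z = x.astype(np.uint64, copy=True)
    with np.errstate(over="ignore"):
        z ^= z >> np.uint64(30)
        z *= np.uint64(0xBF58476D1CE4E5B9)
        z ^= z >> np.uint64(27)
        z *= np.uint64(0x94D049BB133111EB)
        z ^= z >> np.uint64(31)
    return z


def hash_family(n_hashes: int, n_neurons: int, seed: int) -> np.ndarray:
    """``(n_hashes, N)`` table of seeded 64-bit hash values per neuron id.

    Each row is an injective map of the id domain (a keyed bijective mixing
    function), so distinct neurons never collide within one hash function.
    """
    rng = np.random.default_rng(seed)
    keys = rng.integers(0, 2**63, size=n_hashes, dtype=np.uint64)
    ids = np.arange(n_neurons, dtype=np.uint64)
    # mixing (key << 32) is bijective in id for a fixed key only if we mix the
    # sum of a bijection of the key and the id; xor of mixed key with id is
    # injective in id, then a final mix keeps it injective.
    return _mix64(_mix64(keys[:, None]) ^ ids[None, :])


def build_signatures(
    masks: np.ndarray, params: BandParams, seed: int = 0
) -> np.ndarray:
    """MinHash signature matrix ``(n_hashes, M)`` of the activity masks.

    Entry ``(q, k)`` is the minimum of hash function q over the active
    neurons of window k.  Windows with an empty mask receive a sentinel value
    and never form candidate pairs.
    """
    masks = np.asarray(masks, dtype=bool)
    n_windows, n_neurons = masks.shape
    table = hash_family(params.n_hashes, n_neurons, seed)
    sig = np.empty((params.n_hashes, n_windows), dtype=np.uint64)
    masked = np.where(masks, np.uint64(0), _EMPTY_SENTINEL)  # (M, N) additive guard
    for q in range(params.n_hashes):
        sig[q] = np.minimum(table[q][None, :] | masked, _EMPTY_SENTINEL).min(axis=1)
    return sig


def candidate_pairs(signatures: np.ndarray, params: BandParams) -> np.ndarray:
    """Window pairs whose signatures agree on all rows of >= 1 band.

    Returns a ``(P, 2)`` int array with ``k < k'`` per row, sorted.  Band
    slices are grouped exactly (by the tuple of their ``l`` values), so there
    are no banding collisions beyond those of the hash family itself.
    """
    n_hashes, n_windows = signatures.shape
    if n_hashes != params.n_hashes:
        raise ValueError("signature matrix does not match band parameters")
    nonempty = ~(signatures == _EMPTY_SENTINEL).all(axis=0)
    pairs: set[tuple[int, int]] = set()
    for band in range(params.n_bands):
        rows = signatures[
            band * params.rows_per_band : (band + 1) * params.rows_per_band
        ]
        groups: dict[bytes, list[int]] = {}
        for k in range(n_windows):
            if not nonempty[k]:
                continue
            groups.setdefault(rows[:, k].tobytes(), []).append(k)
        for members in groups.values():
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    pairs.add((members[a], members[b]))
    if not pairs:
        return np.zeros((0, 2), dtype=np.int64)
    out = np.array(sorted(pairs), dtype=np.int64)
    return out
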