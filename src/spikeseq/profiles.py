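"""Consensus spatiotemporal profiles of window clusters.

Windows grouped into one cluster still vary in onset, timing and rate.  The
profile is the cluster's core pattern: an ``(N, L)`` matrix of z-scored
activity built by simplified iterative multiple alignment.  Two member
windows seed the profile; each iteration aligns one more member to the
current profile with the edit-similarity traceback, merges the aligned bins
by running average, and smooths along time with a Gaussian filter whose
width shrinks from the window length down to one bin as iterations proceed
(early iterations see coarse structure, late ones sharpen it, and the
shrinking filter keeps the profile from accreting more than one copy of the
pattern).  Iteration stops when successive profiles stop changing.

Activity is z-scored per neuron over the whole recording (mean subtracted,
difference divided by the variance), suppressing the dominance of highly
active cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .alignment import edit_similarity
from .io import SpikeData

__all__ = ["Profile", "zscore_windows", "build_profile", "match_profile"]


@dataclass
class Profile:
    """Cluster consensus pattern with its construction trace."""

    matrix: np.ndarray  # (N, L) z-scored consensus
    members: list[int]
    trace: list[float]  # similarity between successive profiles per update
    final_sigma: float

    @property
    def n_neurons(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    def peak_order(self) -> np.ndarray:
        """Neuron ids sorted by the time bin of their peak activity."""
        peaks = self.matrix.argmax(axis=1)
        active = np.flatnonzero(self.matrix.max(axis=1) > 0)
        return active[np.argsort(peaks[active], kind="stable")]


def zscore_windows(windows: np.ndarray) -> np.ndarray:
    """Z-score the ``(M, N, L)`` count tensor per neuron over all bins.

    Each count c of neuron i becomes ``(c - mean_i) / var_i`` where the
    moments are taken over every bin of every window.  Neurons with zero
    variance (silent or perfectly regular) carry no timing information and
    are zeroed out with a warning.
    """
    w = np.asarray(windows, dtype=np.float64)
    if w.ndim == 2:
        w = w[None]
    flat = w.transpose(1, 0, 2).reshape(w.shape[1], -1)
    mean = flat.mean(axis=1)
    var = flat.var(axis=1)
    dead = var == 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-variance neurons excluded from z-scoring")
    safe = np.where(dead, 1.0, var)
    z = (w - mean[None, :, None]) / safe[None, :, None]
    z[:, dead, :] = 0.0
    return z


def _merge(profile: np.ndarray, member: np.ndarray, pairs, weight: float) -> np.ndarray:
    """Average the member into the profile along the aligned bins.

    Aligned profile bins take the running mean with the member's matched bin;
    unaligned profile bins are averaged with zero, decaying towards 0 at the
    same ``1/weight`` rate.
    """
    aligned = np.zeros_like(profile)
    for a, b in pairs:
        aligned[:, a] = member[:, b]
    return ((weight - 1.0) * profile + aligned) / weight


def build_profile(
    members: np.ndarray,
    alpha: float,
    max_updates: int | None = None,
    seed: int = 0,
    tol: float = 1e-3,
    original_order: bool = False,
) -> Profile:
    """Iterative multiple alignment of a cluster's z-scored windows.

    Parameters
    ----------
    members : (m, N, L) array
        Z-scored member windows, m >= 2.
    alpha : float
        Gap penalty of the aligner.
    max_updates : int
        Update budget; defaults to ``10 * m`` (10x the member count, the low
        end of the range that saturates member-to-profile similarity).
    original_order : bool
        If True, follow the classic greedy strategy (always merge the member
        most similar to the current profile); default picks members in
        seeded random cycles, which performs equivalently and is cheaper.
    """
    members = np.asarray(members, dtype=np.float64)
    if members.ndim != 3 or members.shape[0] < 2:
        raise ValueError("need at least two member windows")
    m, n_neurons, L = members.shape
    if max_updates is None:
        max_updates = 10 * m
    rng = np.random.default_rng(seed)

    # the running aligned average stays unsmoothed; each iteration's
    # tentative profile is this accumulator seen through the current filter,
    # so the blur tracks the schedule instead of compounding across updates
    first, second = rng.choice(m, size=2, replace=False)
    res = edit_similarity(members[first], members[second], alpha, with_traceback=True)
    acc = _merge(members[first].copy(), members[second], res.pairs or [], 2.0)

    # geometric sigma schedule: window length (L bins) down to one bin
    sigmas = np.geomspace(L, 1.0, num=max(max_updates, 2))
    profile = gaussian_filter1d(acc, sigmas[0], axis=1, mode="constant")

    trace: list[float] = []
    order: list[int] = []
    sigma = sigmas[0]
    for it in range(max_updates):
        sigma = sigmas[min(it, len(sigmas) - 1)]
        if original_order:
            sims = [
                edit_similarity(profile, members[i], alpha).similarity
                for i in range(m)
            ]
            nxt = int(np.argmax(sims))
        else:
            if not order:
                order = list(rng.permutation(m))
            nxt = int(order.pop())
        res = edit_similarity(profile, members[nxt], alpha, with_traceback=True)
        acc = _merge(acc, members[nxt], res.pairs or [], float(it + 3))
        merged = gaussian_filter1d(acc, sigma, axis=1, mode="constant")
        change_sim = edit_similarity(profile, merged, alpha).similarity
        self_sim = edit_similarity(merged, merged, alpha).similarity
        trace.append(change_sim)
        converged = (
            it >= m  # every member seen at least roughly once
            and self_sim > 0
            and abs(self_sim - change_sim) / self_sim < tol
        )
        profile = merged
        if converged:
            break
    return Profile(profile, list(range(m)), trace, float(sigma))


def match_profile(profile: Profile | np.ndarray, window: np.ndarray, alpha: float) -> float:
    """Edit similarity between a profile and one z-scored window."""
    mat = profile.matrix if isinstance(profile, Profile) else profile
    return edit_similarity(mat, window, alpha).similarity
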