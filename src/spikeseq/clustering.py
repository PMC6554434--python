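"""Two-stage clustering of windows: OPTICS noise removal, then COPRA.

Windows containing repeated assembly patterns sit close together under the
edit-similarity metric while pattern-free windows are scattered outliers.
Density-based clustering (OPTICS) removes those outliers reliably but tends
to fuse adjacent dense groups; overlapping label propagation (COPRA)
separates groups well but happily absorbs nearby noise.  Applied in
sequence — OPTICS to keep only dense regions, COPRA on the similarity graph
of the survivors — the two stages compensate for each other's weakness.

COPRA (community detection by label propagation with at most ``v``
memberships per node) is implemented here directly; OPTICS delegates to
scikit-learn on the precomputed distance matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.cluster import OPTICS

from .alignment import SimilarityStore, dense_distance_matrix

__all__ = [
    "ClusterSet",
    "optics_filter",
    "build_similarity_graph",
    "copra",
    "cluster_pipeline",
]


@dataclass
class ClusterSet:
    """Possibly overlapping assignment of window indices to cluster labels.

    ``memberships[k]`` is the (possibly empty) set of labels of window k;
    an empty set means noise.  ``weights`` optionally carries the belonging
    coefficient of each (window, label) membership.
    """

    n_items: int
    memberships: dict[int, set[int]] = field(default_factory=dict)
    weights: dict[tuple[int, int], float] = field(default_factory=dict)
    converged: bool = True

    def labels_of(self, k: int) -> set[int]:
        return self.memberships.get(k, set())

    @property
    def cluster_ids(self) -> list[int]:
        out: set[int] = set()
        for labels in self.memberships.values():
            out |= labels
        return sorted(out)

    def members(self, label: int) -> list[int]:
        return sorted(k for k, ls in self.memberships.items() if label in ls)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    def primary_labels(self, noise: int = -1) -> np.ndarray:
        """One label per window: the highest-weight membership, else noise."""
        out = np.full(self.n_items, noise, dtype=np.int64)
        for k, labels in self.memberships.items():
            if labels:
                out[k] = max(labels, key=lambda c: (self.weights.get((k, c), 1.0), -c))
        return out

    def relabel(self) -> "ClusterSet":
        """Map cluster ids to consecutive integers 0..n_clusters-1."""
        remap = {c: i for i, c in enumerate(self.cluster_ids)}
        new = ClusterSet(self.n_items, converged=self.converged)
        for k, labels in self.memberships.items():
            if labels:
                new.memberships[k] = {remap[c] for c in labels}
        for (k, c), w in self.weights.items():
            if c in remap:
                new.weights[(k, remap[c])] = w
        return new


def optics_filter(
    distances: SimilarityStore | np.ndarray,
    min_pts: int,
    xi: float = 0.05,
) -> list[list[int]]:
    """Density-based tentative grouping; returns the dense groups found.

    ``distances`` is either a precomputed dense matrix or a distance store
    (uncomputed pairs at maximal distance).  Windows in no group of at least
    ``min_pts`` members are noise and are dropped by the pipeline.
    """
    if min_pts < 2:
        raise ValueError("min_pts must be >= 2")
    D = (
        dense_distance_matrix(distances)
        if isinstance(distances, SimilarityStore)
        else np.asarray(distances, dtype=np.float64)
    )
    n = D.shape[0]
    if n < min_pts:
        warnings.warn(f"fewer than min_pts={min_pts} windows; nothing retained")
        return []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = OPTICS(
            min_samples=min_pts, metric="precomputed", cluster_method="xi", xi=xi
        )
        labels = model.fit_predict(D)
    groups = [sorted(np.flatnonzero(labels == c)) for c in np.unique(labels) if c >= 0]
    # the xi extraction reports the root interval as one cluster when the
    # reachability profile is flat; a "cluster" spanning essentially the
    # whole sample without any density contrast is no cluster at all
    kept = []
    for g in groups:
        if len(g) > 0.9 * n:
            rr = model.reachability_[g]
            rr = rr[np.isfinite(rr)]
            spread = np.percentile(rr, 90) - np.percentile(rr, 10)
            if rr.size == 0 or spread <= xi * max(np.median(rr), 1e-12):
                continue
        kept.append(g)
    return kept


def build_similarity_graph(
    similarities: SimilarityStore,
    retained: list[int] | np.ndarray,
    edge_rule: str = "positive",
    top_k: int = 10,
    threshold: float = 0.0,
) -> nx.Graph:
    """Weighted graph over retained windows, edges from computed similarities.

    ``edge_rule``:

    * ``"positive"`` (default) — connect computed pairs with similarity > 0
      (the MinHash stage already restricts computation to plausible pairs);
    * ``"threshold"`` — connect computed pairs with similarity > threshold;
    * ``"top_k"`` — keep an edge iff both endpoints rank it among their K
      strongest positive edges (mutual K-nearest rule; degree <= K).
    """
    retained = [int(k) for k in retained]
    if not retained:
        raise ValueError("no retained windows to build a graph from")
    keep = set(retained)
    g = nx.Graph()
    g.add_nodes_from(retained)
    edges = [
        (i, j, v)
        for (i, j), v in similarities.values.items()
        if i in keep and j in keep
    ]
    if edge_rule == "positive":
        chosen = [(i, j, v) for i, j, v in edges if v > 0]
    elif edge_rule == "threshold":
        chosen = [(i, j, v) for i, j, v in edges if v > threshold]
    elif edge_rule == "top_k":
        per_node: dict[int, list[tuple[float, int, int]]] = {k: [] for k in retained}
        for i, j, v in edges:
            if v > 0:
                per_node[i].append((v, i, j))
                per_node[j].append((v, i, j))
        nominated: dict[int, set[tuple[int, int]]] = {}
        for k, lst in per_node.items():
            lst.sort(reverse=True)
            nominated[k] = {(i, j) for _, i, j in lst[:top_k]}
        chosen = [
            (i, j, v)
            for i, j, v in edges
            if (i, j) in nominated.get(i, set()) and (i, j) in nominated.get(j, set())
        ]
    else:
        raise ValueError(f"unknown edge_rule {edge_rule!r}")
    g.add_weighted_edges_from(chosen)
    return g


def copra(
    graph: nx.Graph,
    v: int = 1,
    max_iter: int = 100,
    seed: int = 0,
    min_size: int = 2,
) -> ClusterSet:
    """Overlapping community detection by label propagation.

    Each node holds at most ``v`` (label, belonging-coefficient) pairs.  Per
    sweep (asynchronous, in seeded shuffled order) a node averages its
    neighbours' label coefficients weighted by edge weight, prunes labels
    below ``1/v`` (keeping a seeded-random argmax if all fall below), and
    renormalises.  Iteration stops when the per-label node-count histogram is
    stable between sweeps, or at ``max_iter`` (flagged as non-converged).
    Communities smaller than ``min_size`` are dropped.
    """
    if v < 1:
        raise ValueError("v must be >= 1")
    nodes = list(graph.nodes)
    n_items = (max(nodes) + 1) if nodes else 0
    rng = np.random.default_rng(seed)
    labels: dict[int, dict[int, float]] = {x: {x: 1.0} for x in nodes}
    converged = False
    prev_hist: dict[int, int] | None = None
    for _ in range(max_iter):
        order = list(nodes)
        rng.shuffle(order)
        for x in order:
            acc: dict[int, float] = {}
            total = 0.0
            for y in graph.neighbors(x):
                w = graph[x][y].get("weight", 1.0)
                for c, coef in labels[y].items():
                    acc[c] = acc.get(c, 0.0) + w * coef
                total += w
            if not acc or total == 0.0:
                continue
            for c in acc:
                acc[c] /= total
            kept = {c: val for c, val in acc.items() if val >= 1.0 / v}
            if not kept:
                top = max(acc.values())
                best = sorted(c for c, val in acc.items() if val == top)
                c = best[int(rng.integers(len(best)))]
                kept = {c: acc[c]}
            norm = sum(kept.values())
            labels[x] = {c: val / norm for c, val in kept.items()}
        hist: dict[int, int] = {}
        for x in nodes:
            for c in labels[x]:
                hist[c] = hist.get(c, 0) + 1
        if hist == prev_hist:
            converged = True
            break
        prev_hist = hist
    else:
        converged = max_iter == 0
    if not converged:
        warnings.warn("COPRA did not converge within max_iter sweeps")
    cs = ClusterSet(n_items, converged=converged)
    counts: dict[int, int] = {}
    for x in nodes:
        for c in labels[x]:
            counts[c] = counts.get(c, 0) + 1
    for x in nodes:
        kept = {c for c in labels[x] if counts[c] >= min_size}
        if kept:
            cs.memberships[x] = kept
            for c in kept:
                cs.weights[(x, c)] = labels[x][c]
    return cs.relabel()


def cluster_pipeline(
    similarities: SimilarityStore,
    min_pts: int,
    v: int,
    seed: int = 0,
    xi: float = 0.05,
    max_iter: int = 100,
    edge_rule: str = "positive",
) -> ClusterSet:
    """OPTICS noise removal -> similarity graph -> COPRA communities.

    Returns a ClusterSet over all windows; windows discarded by OPTICS or
    left without a community are noise (empty membership).
    """
    dist = dense_distance_matrix(similarities)
    groups = optics_filter(dist, min_pts=min_pts, xi=xi)
    retained = sorted({k for g in groups for k in g})
    if not retained:
        return ClusterSet(similarities.n_items)
    graph = build_similarity_graph(similarities, retained, edge_rule=edge_rule)
    cs = copra(graph, v=v, max_iter=max_iter, seed=seed)
    cs.n_items = similarities.n_items
    return cs
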