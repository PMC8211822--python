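"""Independent oracles used by the tests, kept free of the code paths they check.

- Exhaustive unrooted-topology enumeration with least-squares branch fitting,
  as a brute-force alternative to neighbor joining on small additive matrices.
- Random additive distance matrices from random trees (path-length sums
  computed directly on the generating tree's edge structure).
- A matrix-exponential evaluation of the 20-state equal-rates substitution
  model, independent of the closed form used in the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_topologies(labels):
    """All unrooted binary topologies over the labels (3 for n=4, 15, 105...).

    Each topology is an adjacency dict node -> set(nodes); leaves are the
    label strings, internal nodes are negative ints.
    """
    labels = list(labels)
    assert len(labels) >= 3
    base = {labels[0]: {-1}, labels[1]: {-1}, labels[2]: {-1},
            -1: {labels[0], labels[1], labels[2]}}
    topologies = [base]
    next_internal = -2
    for leaf in labels[3:]:
        new_topologies = []
        for adj in topologies:
            edges = set()
            for u, nbrs in adj.items():
                for v in nbrs:
                    edges.add(frozenset((u, v)))
            for edge in edges:
                u, v = tuple(edge)
                new = {k: set(s) for k, s in adj.items()}
                w = next_internal
                new[u].discard(v)
                new[v].discard(u)
                new[u].add(w)
                new[v].add(w)
                new[w] = {u, v, leaf}
                new[leaf] = {w}
                new_topologies.append(new)
        next_internal -= 1
        topologies = new_topologies
    return topologies


def _edges(adj):
    out = set()
    for u, nbrs in adj.items():
        for v in nbrs:
            out.add(frozenset((u, v)))
    return sorted(out, key=lambda e: sorted(map(str, e)))


def _path_edges(adj, a, b):
    """Edges on the unique path between nodes a and b (DFS)."""
    stack = [(a, None, [])]
    while stack:
        node, parent, path = stack.pop()
        if node == b:
            return path
        for nb in adj[node]:
            if nb != parent:
                stack.append((nb, node, path + [frozenset((node, nb))]))
    raise ValueError("no path")


def splits_of(adj, labels):
    """Non-trivial bipartitions, each as the side holding min(labels)."""
    labels = set(labels)
    ref = min(labels)
    splits = set()
    for edge in _edges(adj):
        u, v = tuple(edge)
        # leaves reachable from u without crossing edge
        side = set()
        stack = [(u, v)]
        while stack:
            node, parent = stack.pop()
            if isinstance(node, str):
                side.add(node)
            for nb in adj[node]:
                if nb != parent and not (node == u and nb == v):
                    stack.append((nb, node))
        if 2 <= len(side) <= len(labels) - 2:
            splits.add(frozenset(side) if ref in side else frozenset(labels - side))
    return splits


def fit_branch_lengths(adj, labels, D):
    """Least-squares branch lengths for a fixed topology; returns (rss, lengths)."""
    edges = _edges(adj)
    edge_index = {e: i for i, e in enumerate(edges)}
    pairs = list(itertools.combinations(range(len(labels)), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for r, (i, j) in enumerate(pairs):
        for e in _path_edges(adj, labels[i], labels[j]):
            A[r, edge_index[e]] = 1.0
        y[r] = D[i, j]
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    rss = float(np.sum((A @ x - y) ** 2))
    return rss, dict(zip(edges, x))


def best_tree_by_enumeration(labels, D):
    """Exhaustive search: the topology minimising least-squares residual."""
    best = None
    for adj in enumerate_topologies(labels):
        rss, lengths = fit_branch_lengths(adj, labels, D)
        if best is None or rss < best[0]:
            best = (rss, adj, lengths)
    rss, adj, lengths = best
    return adj, rss, lengths


def random_additive_matrix(labels, rng, length_range=(0.1, 1.0)):
    """Random binary tree over labels; returns (D, its splits, adjacency)."""
    labels = list(labels)
    adj = {labels[0]: {-1}, labels[1]: {-1}, labels[2]: {-1},
           -1: {labels[0], labels[1], labels[2]}}
    next_internal = -2
    for leaf in labels[3:]:
        edges = _edges(adj)
        u, v = tuple(edges[int(rng.integers(0, len(edges)))])
        w = next_internal
        next_internal -= 1
        adj[u].discard(v)
        adj[v].discard(u)
        adj[u].add(w)
        adj[v].add(w)
        adj[w] = {u, v, leaf}
        adj[leaf] = {w}
    lengths = {e: float(rng.uniform(*length_range)) for e in _edges(adj)}
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = sum(lengths[e] for e in _path_edges(adj, labels[i], labels[j]))
            D[i, j] = D[j, i] = d
    return D, splits_of(adj, labels), adj, lengths


def equal_rates_difference_probability(d: float, n_states: int = 20) -> float:
    """P(two chain endpoints differ) after divergence d, via expm of the
    explicit rate matrix — independent of any closed form."""
    from scipy.linalg import expm

    k = n_states
    Q = np.full((k, k), 1.0 / (k - 1))
    np.fill_diagonal(Q, -1.0)
    P = expm(Q * d)
    return float(1.0 - P[0, 0])
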