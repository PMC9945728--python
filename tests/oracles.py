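"""Independent brute-force reference implementations used only by the tests.

Every routine here is written from the definition of the quantity, with no
shared code with the package, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np


def brute_nodf(binary: np.ndarray) -> float:
    """NODF from the definition: loop over ordered row and column pairs."""
    b = (np.asarray(binary) > 0).astype(int)

    def pair_term(u: np.ndarray, v: np.ndarray) -> float:
        fu, fv = u.sum(), v.sum()
        if fu <= fv or fv == 0:
            return 0.0
        shared = int(np.logical_and(u, v).sum())
        return 100.0 * shared / fv

    total = 0.0
    r, c = b.shape
    for i, j in itertools.combinations(range(r), 2):
        total += pair_term(b[i], b[j]) + pair_term(b[j], b[i])
    for i, j in itertools.combinations(range(c), 2):
        total += pair_term(b[:, i], b[:, j]) + pair_term(b[:, j], b[:, i])
    return total / (r * (r - 1) / 2 + c * (c - 1) / 2)


def brute_betweenness(nodes: list, edges: list[tuple]) -> dict:
    """Unnormalized betweenness by explicit enumeration of all shortest paths."""
    adj: dict = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    def all_shortest_paths(s, t):
        # BFS layer structure, then backtrack every geodesic
        dist = {s: 0}
        parents: dict = {s: []}
        q = deque([s])
        while q:
            x = q.popleft()
            for y in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + 1
                    parents[y] = [x]
                    q.append(y)
                elif dist[y] == dist[x] + 1:
                    parents[y].append(x)
        if t not in dist:
            return []
        paths = []

        def back(node, acc):
            if node == s:
                paths.append(list(reversed(acc + [s])))
                return
            for p in parents[node]:
                back(p, acc + [node])

        back(t, [])
        return paths

    bt = {n: 0.0 for n in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_shortest_paths(s, t)
        if not paths:
            continue
        for path in paths:
            for inner in path[1:-1]:
                bt[inner] += 1.0 / len(paths)
    return bt


def brute_compartments(nodes: list, edges: list[tuple]) -> int:
    """Connected components by union-find."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    return len({find(n) for n in nodes})


def brute_partner_diversity(weights: np.ndarray) -> float:
    """Weighted mean Shannon entropy of the rows, from the definition."""
    w = np.asarray(weights, dtype=float)
    num = 0.0
    den = 0.0
    for row in w:
        a = row.sum()
        h = 0.0
        for cell in row:
            if cell > 0:
                p = cell / a
                h -= p * math.log(p)
        num += a * h
        den += a
    return num / den


def brute_fc(weights: np.ndarray) -> float:
    """Total dendrogram branch length via a naive O(n^3) UPGMA.

    Leaves sit at height 0; each merge at the average pairwise distance
    between the two clusters contributes (height - child height) per child.
    """
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    clusters = {i: [i] for i in range(n)}
    heights = {i: 0.0 for i in range(n)}
    point_dist = {
        (i, j): float(np.linalg.norm(w[i] - w[j]))
        for i in range(n)
        for j in range(n)
    }
    total = 0.0
    next_id = n
    while len(clusters) > 1:
        pair_ds = [
            (np.mean([point_dist[(x, y)] for x in clusters[a] for y in clusters[b]]), a, b)
            for a, b in itertools.combinations(sorted(clusters), 2)
        ]
        dmin = min(d for d, _, _ in pair_ds)
        # same documented tie rule as the package: first pair within 1e-9
        d, a, b = next(t for t in pair_ds if t[0] <= dmin + 1e-9)
        total += (d - heights[a]) + (d - heights[b])
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        heights[next_id] = d
        next_id += 1
    return total


def brute_faith_pd(tree, tips: set[str]) -> float:
    """PD with root: an edge counts iff at least one selected tip lies below it."""
    total = 0.0
    for edge in tree._tree.preorder_edge_iter():
        if edge.head_node is tree._tree.seed_node:
            continue
        below = {
            (lf.taxon.label if lf.taxon else lf.label)
            for lf in edge.head_node.leaf_iter()
        }
        if below & tips:
            total += edge.length or 0.0
    return total


def brute_hypergeom_tails(n_total: int, n_a: int, n_b: int, j: int) -> tuple[float, float]:
    """Exact tail probabilities by full enumeration with binomial coefficients."""

    def pmf(k: int) -> float:
        if k < max(0, n_a + n_b - n_total) or k > min(n_a, n_b):
            return 0.0
        return (
            math.comb(n_a, k)
            * math.comb(n_total - n_a, n_b - k)
            / math.comb(n_total, n_b)
        )

    p_lt = sum(pmf(k) for k in range(0, j + 1))
    p_gt = sum(pmf(k) for k in range(j, min(n_a, n_b) + 1))
    return p_lt, p_gt
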