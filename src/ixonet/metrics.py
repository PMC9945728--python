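"""Structure indices of weighted bipartite parasite-host networks.

The suite covers the standard descriptors used to characterise host-parasite
webs: node/link counts, links per parasite species, Louvain modularity and
cluster count, NODF nestedness, Fisher's log-series alpha of the interaction
"abundances", family richness, functional complementarity (total branch
length of a UPGMA dendrogram over the parasites' interaction profiles),
weighted mean Shannon partner diversity, the exponent of the hyperbolic
secondary-extinction curve under random host removal, and the number of
compartments (connected components).  Node-level weighted degree and
(unweighted shortest-path) betweenness are also provided.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import networkx as nx
import numpy as np
from scipy.optimize import brentq, curve_fit
from scipy.spatial.distance import pdist, squareform

from .build import to_matrix
from .network import BipartiteNetwork, InteractionMatrix

__all__ = [
    "NetworkIndexReport",
    "NodeCentrality",
    "ExtinctionFitError",
    "basic_counts",
    "weighted_degree",
    "betweenness",
    "louvain_modularity",
    "compartments",
    "nodf",
    "fisher_alpha",
    "fisher_alpha_sn",
    "partner_diversity",
    "functional_complementarity",
    "extinction_slope",
    "network_report",
    "node_centralities",
]


@dataclass(frozen=True)
class NetworkIndexReport:
    """One row of the per-network index table."""

    order: int
    size: int
    links_per_species: float
    n_clusters: int
    nodf: float
    fisher_alpha: float
    n_host_families: int
    functional_complementarity: float
    partner_diversity: float
    extinction_slope: float
    n_compartments: int
    modularity: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class NodeCentrality:
    node: str
    weighted_degree: float
    betweenness: float


class ExtinctionFitError(RuntimeError):
    """The hyperbolic extinction fit failed; carries the pooled curve."""

    def __init__(self, message: str, curve: np.ndarray):
        super().__init__(message)
        self.curve = curve


# ---------------------------------------------------------------------------
# counts and centralities


def basic_counts(net: BipartiteNetwork) -> tuple[int, int, float, int]:
    """(order, size, links per tick species, number of family-rank hosts).

    Links per species always divides by the number of distinct tick *species*,
    even when the tick nodes are species x stage composites.
    """
    n_species = len(net.species())
    if n_species == 0:
        raise ValueError("network has no tick species")
    n_families = sum(
        1 for h in net.host_nodes if net.host_rank.get(h, "family") == "family"
    )
    return net.order, net.size, net.size / n_species, n_families


def weighted_degree(net: BipartiteNetwork, node: str) -> float:
    """Node strength: sum of incident edge weights."""
    if node not in net.tick_nodes and node not in net.host_nodes:
        raise KeyError(f"unknown node {node!r}")
    return float(sum(w for (t, h), w in net.edges.items() if node in (t, h)))


def betweenness(net: BipartiteNetwork) -> dict[str, float]:
    """Unnormalized Brandes betweenness on hop-count shortest paths.

    Citation weights measure sampling effort, not distance, so paths are
    unweighted; equal-length shortest paths split their contribution
    fractionally.
    """
    g = net.to_networkx()
    return dict(nx.betweenness_centrality(g, normalized=False, weight=None))


def compartments(net: BipartiteNetwork) -> int:
    """Number of connected components."""
    return nx.number_connected_components(net.to_networkx())


# ---------------------------------------------------------------------------
# modularity


def louvain_modularity(
    net: BipartiteNetwork,
    resolution: float = 1.0,
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[dict[str, int], float, int]:
    """Louvain partition of the weighted graph; best Q over seeded restarts.

    Returns ``(partition, Q, n_clusters)`` where Q is the Newman-Girvan
    weighted modularity of the returned partition.  Louvain's greedy sweeps
    depend on node visit order, so the best of ``n_restarts`` seeded runs is
    reported; the result never falls below the single-module partition (Q=0).
    """
    g = net.to_networkx()
    best_comms: list[set] = [set(g.nodes)]
    best_q = nx.community.modularity(g, best_comms, weight="weight", resolution=resolution)
    for i in range(n_restarts):
        comms = nx.community.louvain_communities(
            g, weight="weight", resolution=resolution, seed=seed + i
        )
        q = nx.community.modularity(g, comms, weight="weight", resolution=resolution)
        if q > best_q:
            best_q, best_comms = q, [set(c) for c in comms]
    partition = {
        node: idx for idx, comm in enumerate(best_comms) for node in comm
    }
    return partition, float(best_q), len(best_comms)


# ---------------------------------------------------------------------------
# matrix-based indices


def nodf(m: InteractionMatrix) -> float:
    """Nestedness by Overlap and Decreasing Fill, on the binary view, in [0, 100].

    For every pair of rows with strictly decreasing fill, the paired
    nestedness is 100 x (shared presences) / (fill of the sparser row); pairs
    of equal fill contribute 0.  Same over columns; the index averages over
    all row pairs and column pairs.
    """
    b = m.binary
    r, c = b.shape
    if r < 2 and c < 2:
        raise ValueError("NODF is undefined for a matrix with <2 rows and <2 cols")

    def paired_sum(mat: np.ndarray) -> float:
        fill = mat.sum(axis=1)
        overlap = mat @ mat.T
        total = 0.0
        n = mat.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                hi, lo = (i, j) if fill[i] > fill[j] else (j, i)
                if fill[hi] > fill[lo] and fill[lo] > 0:
                    total += 100.0 * overlap[hi, lo] / fill[lo]
        return total

    n_pairs = r * (r - 1) / 2 + c * (c - 1) / 2
    return float((paired_sum(b) + paired_sum(b.T)) / n_pairs)


def fisher_alpha_sn(s: int, n: float) -> float:
    """Fisher's log-series alpha for S realized interactions of total weight N.

    Solves ``S = alpha * ln(1 + N/alpha)`` for the unique positive root; the
    residual of the returned value is below 1e-10.  Requires N > S (with
    N <= S every interaction is a singleton and alpha diverges).
    """
    if s < 1:
        raise ValueError("need at least one realized interaction")
    if n <= s:
        raise ValueError(
            f"Fisher's alpha diverges for N <= S (N={n}, S={s}): "
            "all interactions are singletons"
        )

    def f(a: float) -> float:
        return a * np.log1p(n / a) - s

    lo, hi = 1e-9, 1e9
    alpha = float(brentq(f, lo, hi, xtol=1e-14, rtol=1e-15, maxiter=300))
    # one Newton polish; d/da [a ln(1+N/a)] = ln(1+N/a) - N/(a+N)
    deriv = np.log1p(n / alpha) - n / (alpha + n)
    if deriv != 0:
        alpha -= f(alpha) / deriv
    return float(alpha)


def fisher_alpha(m: InteractionMatrix) -> float:
    """Fisher's alpha of the interaction web: S = nonzero cells, N = total weight."""
    s = int((m.values > 0).sum())
    n = float(m.values.sum())
    return fisher_alpha_sn(s, n)


def partner_diversity(m: InteractionMatrix) -> float:
    """Weighted mean Shannon diversity (natural log) of each tick's host use.

    Each row's Shannon entropy is weighted by the row total, so heavily
    documented species dominate the mean exactly as they dominate the web.
    """
    w = m.values
    totals = w.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("every tick row must have positive total weight")
    h = np.zeros(len(totals))
    for i, row in enumerate(w):
        p = row[row > 0] / totals[i]
        h[i] = -(p * np.log(p)).sum()
    return float((totals * h).sum() / totals.sum())


def functional_complementarity(m: InteractionMatrix) -> float:
    """Total branch length of the UPGMA dendrogram over tick interaction profiles.

    Distances are Euclidean between the ticks' weighted host-use vectors;
    clustering is average linkage.  With leaves at height 0, the total branch
    length is the sum over all merges of (merge height minus each child's
    height) — the convention of ``vegan::treeheight``, which the R bipartite
    package uses for this index.  Identical profiles give 0.
    """
    n = m.shape[0]
    if n < 2:
        raise ValueError("functional complementarity needs at least 2 tick rows")
    d = pdist(m.values, metric="euclidean")
    if not d.any():
        return 0.0

    # UPGMA with a deterministic tie rule: among pairs within 1e-9 of the
    # current minimum distance, merge the lexicographically smallest pair of
    # cluster ids (leaves are numbered in lexical row order, merged clusters
    # in creation order).  Generic linkage codes break such ties by internal
    # traversal order, which is not reproducible across implementations.
    tie_tol = 1e-9
    n_total = 2 * n - 1
    dm = np.full((n_total, n_total), np.inf)
    dm[:n, :n] = squareform(d)
    np.fill_diagonal(dm, np.inf)
    size = {i: 1 for i in range(n)}
    height = dict.fromkeys(range(n), 0.0)
    total = 0.0
    for next_id in range(n, n_total):
        ids = sorted(size)
        sub = dm[np.ix_(ids, ids)]
        iu = np.triu_indices(len(ids), 1)
        vals = sub[iu]
        k = int(np.argmax(vals <= vals.min() + tie_tol))
        a, b = ids[iu[0][k]], ids[iu[1][k]]
        h = float(dm[a, b])
        total += (h - height[a]) + (h - height[b])
        # Lance-Williams average-linkage update
        sa, sb = size[a], size[b]
        for c in ids:
            if c not in (a, b):
                dm[next_id, c] = dm[c, next_id] = (sa * dm[a, c] + sb * dm[b, c]) / (sa + sb)
        size[next_id] = sa + sb
        height[next_id] = h
        del size[a], size[b]
    return float(total)


def extinction_slope(
    m: InteractionMatrix, n_replicates: int = 100, seed: int = 0
) -> float:
    """Exponent of the hyperbolic secondary-extinction curve under host removal.

    In each replicate, host columns are removed one at a time in uniformly
    random order; a tick goes "extinct" once every host it uses is gone.  The
    pooled points (proportion of hosts removed x, proportion of surviving
    ticks y) are fitted with ``y = 1 - x**a`` by nonlinear least squares; the
    returned exponent grows with host redundancy, so it doubles as a
    robustness measure.
    """
    b = m.binary
    n_ticks, n_hosts = b.shape
    if n_hosts < 2:
        raise ValueError("extinction slope needs at least 2 host columns")
    rng = np.random.default_rng(seed)
    xs = np.tile(np.arange(n_hosts + 1) / n_hosts, n_replicates)
    ys = np.empty_like(xs)
    pos = 0
    for _ in range(n_replicates):
        remaining = b.sum(axis=1).astype(int)
        ys[pos] = 1.0
        pos += 1
        for k, col in enumerate(rng.permutation(n_hosts), start=1):
            remaining -= b[:, col]
            ys[pos] = (remaining > 0).sum() / n_ticks
            pos += 1
    curve = np.column_stack([xs, ys])
    try:
        popt, _ = curve_fit(
            lambda x, a: 1.0 - np.power(x, a),
            xs,
            ys,
            p0=[1.0],
            bounds=(1e-6, 1e6),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - degenerate inputs
        raise ExtinctionFitError(f"extinction curve fit failed: {exc}", curve) from exc
    return float(popt[0])


# ---------------------------------------------------------------------------
# report driver


def network_report(
    net: BipartiteNetwork,
    seed: int = 0,
    n_replicates: int = 100,
    louvain_restarts: int = 10,
    resolution: float = 1.0,
) -> NetworkIndexReport:
    """Compute the full index row for one network.

    Count and graph indices (order, size, clusters, compartments) use the
    network as built; matrix indices (NODF, alpha, partner diversity,
    functional complementarity, extinction slope) use the family-rank
    interaction matrix so order-rank host nodes never double-count records.
    """
    order, size, lps, n_fam = basic_counts(net)
    _, q, n_clusters = louvain_modularity(
        net, resolution=resolution, seed=seed, n_restarts=louvain_restarts
    )
    matrix = to_matrix(net, host_rank_restriction="family")
    return NetworkIndexReport(
        order=order,
        size=size,
        links_per_species=lps,
        n_clusters=n_clusters,
        nodf=nodf(matrix),
        fisher_alpha=fisher_alpha(matrix),
        n_host_families=n_fam,
        functional_complementarity=functional_complementarity(matrix),
        partner_diversity=partner_diversity(matrix),
        extinction_slope=extinction_slope(matrix, n_replicates=n_replicates, seed=seed),
        n_compartments=compartments(net),
        modularity=q,
    )


def node_centralities(net: BipartiteNetwork) -> list[NodeCentrality]:
    """Weighted degree and betweenness for every node, sorted by label."""
    bt = betweenness(net)
    strength: dict[str, float] = {}
    for (t, h), w in net.edges.items():
        strength[t] = strength.get(t, 0.0) + w
        strength[h] = strength.get(h, 0.0) + w
    return [
        NodeCentrality(node=n, weighted_degree=strength.get(n, 0.0), betweenness=bt[n])
        for n in sorted(bt)
    ]
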