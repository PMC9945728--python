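"""Weighted bipartite parasite-host networks and their matrix form.

A :class:`BipartiteNetwork` has one node set for ticks and one for host taxa;
edges only join the two sets (a tick cannot parasitize another tick) and carry
positive citation-count weights.  :class:`InteractionMatrix` is the dense
tick x host weight matrix that the structure indices operate on.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "BipartiteNetwork",
    "InteractionMatrix",
    "BipartitenessError",
    "GraphMLDialect",
    "read_graphml",
    "write_graphml",
]


class BipartitenessError(ValueError):
    """An edge joins two nodes of the same partition."""


@dataclass
class BipartiteNetwork:
    """Weighted bipartite tick-host network.

    Parameters
    ----------
    tick_nodes, host_nodes
        Disjoint node identifier sets.  Tick nodes are species names or
        ``species::stage`` composites depending on the build granularity.
    edges
        Map ``(tick, host) -> weight`` with strictly positive weights.
    tick_species
        Optional map from tick node to underlying species name (used by
        per-species denominators when nodes are species x stage).
    host_rank
        Optional map from host node to taxonomic rank (``family``/``order``).
    """

    tick_nodes: set[str]
    host_nodes: set[str]
    edges: dict[tuple[str, str], float]
    tick_species: dict[str, str] = field(default_factory=dict)
    host_rank: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = self.tick_nodes & self.host_nodes
        if overlap:
            raise BipartitenessError(
                f"node(s) in both partitions: {sorted(overlap)[:5]}"
            )
        for (t, h), w in self.edges.items():
            if t not in self.tick_nodes or h not in self.host_nodes:
                raise BipartitenessError(
                    f"edge ({t!r}, {h!r}) does not join a tick to a host"
                )
            if w <= 0:
                raise ValueError(f"edge ({t!r}, {h!r}) has non-positive weight {w}")
        if not self.tick_species:
            self.tick_species = {t: t for t in self.tick_nodes}

    @property
    def order(self) -> int:
        """Number of nodes (ticks + hosts)."""
        return len(self.tick_nodes) + len(self.host_nodes)

    @property
    def size(self) -> int:
        """Number of links."""
        return len(self.edges)

    @property
    def total_weight(self) -> float:
        return float(sum(self.edges.values()))

    def species(self) -> set[str]:
        """Distinct tick species behind the tick nodes."""
        return {self.tick_species.get(t, t) for t in self.tick_nodes}

    def to_networkx(self) -> nx.Graph:
        """Undirected weighted graph with a 0/1 ``bipartite`` node attribute."""
        g = nx.Graph()
        for t in sorted(self.tick_nodes):
            g.add_node(t, bipartite=0, species=self.tick_species.get(t, t))
        for h in sorted(self.host_nodes):
            g.add_node(h, bipartite=1, rank=self.host_rank.get(h, "family"))
        for (t, h), w in sorted(self.edges.items()):
            g.add_edge(t, h, weight=float(w))
        return g

    def restrict_hosts(self, rank: str) -> "BipartiteNetwork":
        """Sub-network keeping only host nodes of the given rank; drops isolated ticks."""
        hosts = {h for h in self.host_nodes if self.host_rank.get(h, "family") == rank}
        edges = {(t, h): w for (t, h), w in self.edges.items() if h in hosts}
        ticks = {t for t, _ in edges}
        return BipartiteNetwork(
            tick_nodes=ticks,
            host_nodes={h for _, h in edges},
            edges=edges,
            tick_species={t: self.tick_species.get(t, t) for t in ticks},
            host_rank={h: rank for _, h in edges},
        )


@dataclass
class InteractionMatrix:
    """Dense weighted tick x host matrix with deterministic (lexical) ordering."""

    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray  # shape (len(row_labels), len(col_labels)), weights >= 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("matrix shape does not match label lengths")
        if len(set(self.row_labels)) != len(self.row_labels):
            raise ValueError("duplicate row labels")
        if len(set(self.col_labels)) != len(self.col_labels):
            raise ValueError("duplicate column labels")
        if (self.values < 0).any():
            raise ValueError("negative cell weights")
        row_fill = (self.values > 0).sum(axis=1)
        col_fill = (self.values > 0).sum(axis=0)
        if len(self.row_labels) and ((row_fill == 0).any() or (col_fill == 0).any()):
            raise ValueError("all-zero row or column after construction")

    @property
    def binary(self) -> np.ndarray:
        """Presence/absence view (cell > 0)."""
        return (self.values > 0).astype(int)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_network(
        self, tick_species: Mapping[str, str] | None = None
    ) -> BipartiteNetwork:
        """Inverse of matrix construction: nonzero cells back to weighted edges."""
        edges = {
            (self.row_labels[i], self.col_labels[j]): float(self.values[i, j])
            for i, j in zip(*np.nonzero(self.values))
        }
        ticks = {t for t, _ in edges}
        return BipartiteNetwork(
            tick_nodes=ticks,
            host_nodes={h for _, h in edges},
            edges=edges,
            tick_species={t: (tick_species or {}).get(t, t) for t in ticks},
        )


@dataclass(frozen=True)
class GraphMLDialect:
    """Attribute keys used by a GraphML file.

    ``partition_attr`` is the node attribute separating ticks from hosts;
    nodes whose attribute equals ``tick_value`` are ticks.  Files written by
    this package use ``bipartite`` with 0 = ticks, 1 = hosts.
    """

    partition_attr: str = "bipartite"
    tick_value: object = 0
    weight_attr: str = "weight"


def write_graphml(net: BipartiteNetwork, path: str | Path) -> None:
    """Serialize a network as undirected GraphML (edge weights under ``weight``)."""
    nx.write_graphml(net.to_networkx(), str(path))


def _heuristic_partition(g: nx.Graph, dialect: GraphMLDialect) -> tuple[set, set]:
    """Two-color nodes lacking the partition attribute from graph structure."""
    try:
        left, right = nx.algorithms.bipartite.sets(g)
    except (nx.NetworkXError, nx.AmbiguousSolution) as exc:
        raise BipartitenessError(f"graph is not two-colorable: {exc}") from exc
    logger.warning(
        "GraphML lacks node attribute %r on some nodes; partition inferred "
        "structurally (%d/%d nodes per side)",
        dialect.partition_attr,
        len(left),
        len(right),
    )
    return set(left), set(right)


def read_graphml(
    path: str | Path, dialect: GraphMLDialect = GraphMLDialect()
) -> BipartiteNetwork:
    """Read a bipartite network from GraphML.

    Partition membership comes from ``dialect.partition_attr``; if the
    attribute is absent the partition is inferred from the graph structure
    (two-coloring) and a warning is logged.  Missing edge weights default to 1
    with a warning.  An edge inside one partition raises
    :class:`BipartitenessError` naming the offending pair.
    """
    g = nx.read_graphml(str(path))
    g = nx.Graph(g)  # collapse directedness/multiedges if present

    attr = dialect.partition_attr
    has_attr = [n for n, d in g.nodes(data=True) if attr in d]
    if len(has_attr) == g.number_of_nodes() and g.number_of_nodes() > 0:
        ticks = {
            n
            for n, d in g.nodes(data=True)
            if str(d[attr]) == str(dialect.tick_value)
        }
        hosts = set(g.nodes) - ticks
    else:
        ticks, hosts = _heuristic_partition(g, dialect)
        # orient: if any attributed node exists, use it to name the tick side
        anchored = {
            n for n, d in g.nodes(data=True) if str(d.get(attr)) == str(dialect.tick_value)
        }
        if anchored and not (anchored <= ticks):
            ticks, hosts = hosts, ticks

    for u, v in g.edges:
        if (u in ticks) == (v in ticks):
            raise BipartitenessError(
                f"edge ({u!r}, {v!r}) joins two nodes of the same partition"
            )

    edges: dict[tuple[str, str], float] = {}
    n_default = 0
    for u, v, d in g.edges(data=True):
        t, h = (u, v) if u in ticks else (v, u)
        w = d.get(dialect.weight_attr)
        if w is None:
            w, n_default = 1.0, n_default + 1
        edges[(t, h)] = float(w)
    if n_default:
        warnings.warn(
            f"{n_default} edge(s) missing weight attribute "
            f"{dialect.weight_attr!r}; defaulted to 1",
            stacklevel=2,
        )

    species = {n: g.nodes[n].get("species", n) for n in ticks}
    rank = {n: g.nodes[n].get("rank", "family") for n in hosts}
    return BipartiteNetwork(
        tick_nodes=set(ticks),
        host_nodes=set(hosts),
        edges=edges,
        tick_species=species,
        host_rank=rank,
    )
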