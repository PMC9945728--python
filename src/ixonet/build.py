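"""Aggregate association records into bipartite networks and interaction matrices.

Networks can be built globally or per biogeographic realm; cosmopolitan
("worldwide") species enter only the complete network.  Host nodes can be
vertebrate families, orders, or both (a record then contributes one edge to
each rank); tick nodes can be species or species x stage composites.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .network import BipartiteNetwork, InteractionMatrix
from .records import AssociationRecord, Realm

__all__ = [
    "HostRank",
    "TickGranularity",
    "BuildOptions",
    "EmptyNetworkError",
    "build_network",
    "to_matrix",
    "STAGE_SEPARATOR",
]

#: Separator for species x stage composite tick node identifiers.
STAGE_SEPARATOR = "::"


class HostRank(str, enum.Enum):
    FAMILY = "family"
    ORDER = "order"
    BOTH = "both"


class TickGranularity(str, enum.Enum):
    SPECIES = "species"
    SPECIES_STAGE = "species_stage"


class EmptyNetworkError(ValueError):
    """No records survive the realm filter: refuse to emit a silent empty object."""


@dataclass(frozen=True)
class BuildOptions:
    """How records map onto network nodes.

    ``realm_filter=None`` builds the complete network (worldwide species
    included); a concrete realm keeps only records tagged with it.
    """

    host_rank: HostRank = HostRank.FAMILY
    realm_filter: Realm | None = None
    tick_granularity: TickGranularity = TickGranularity.SPECIES


def _tick_node(rec: AssociationRecord, granularity: TickGranularity) -> str:
    if granularity is TickGranularity.SPECIES_STAGE:
        return f"{rec.tick_species}{STAGE_SEPARATOR}{rec.stage.value}"
    return rec.tick_species


def build_network(
    records: Iterable[AssociationRecord], opts: BuildOptions = BuildOptions()
) -> BipartiteNetwork:
    """Sum record weights into a weighted bipartite network.

    Edge weight is the total citation count mapped to the (tick, host) pair;
    with ``host_rank=BOTH`` every record contributes both a family-rank and an
    order-rank edge.  Raises :class:`EmptyNetworkError` if the realm filter
    leaves nothing.
    """
    selected = [
        r
        for r in records
        if opts.realm_filter is None or r.realm == opts.realm_filter
    ]
    if not selected:
        raise EmptyNetworkError(
            f"no records match realm filter {opts.realm_filter!r}"
        )

    edges: dict[tuple[str, str], float] = {}
    tick_species: dict[str, str] = {}
    host_rank: dict[str, str] = {}

    def add(t: str, h: str, rank: str, w: int) -> None:
        edges[(t, h)] = edges.get((t, h), 0.0) + w
        host_rank[h] = rank

    for rec in selected:
        t = _tick_node(rec, opts.tick_granularity)
        tick_species[t] = rec.tick_species
        if opts.host_rank in (HostRank.FAMILY, HostRank.BOTH):
            add(t, rec.host_family, "family", rec.weight)
        if opts.host_rank in (HostRank.ORDER, HostRank.BOTH):
            add(t, rec.host_order, "order", rec.weight)

    return BipartiteNetwork(
        tick_nodes={t for t, _ in edges},
        host_nodes={h for _, h in edges},
        edges=edges,
        tick_species=tick_species,
        host_rank=host_rank,
    )


def to_matrix(
    net: BipartiteNetwork, host_rank_restriction: HostRank | str | None = None
) -> InteractionMatrix:
    """Dense weight matrix of a network, rows/columns sorted lexically.

    ``host_rank_restriction`` keeps only host columns of the given rank
    (the structure indices default to family-rank columns so mixed-rank
    networks do not double-count interactions).
    """
    if host_rank_restriction is not None:
        rank = (
            host_rank_restriction.value
            if isinstance(host_rank_restriction, HostRank)
            else str(host_rank_restriction)
        )
        net = net.restrict_hosts(rank)
    if not net.edges:
        raise EmptyNetworkError("network has no edges after rank restriction")
    rows = sorted(net.tick_nodes)
    cols = sorted(net.host_nodes)
    values = np.zeros((len(rows), len(cols)))
    ri = {t: i for i, t in enumerate(rows)}
    ci = {h: j for j, h in enumerate(cols)}
    for (t, h), w in net.edges.items():
        values[ri[t], ci[h]] = w
    return InteractionMatrix(row_labels=rows, col_labels=cols, values=values)


def species_of(matrix_rows: Sequence[str]) -> list[str]:
    """Species names behind (possibly species x stage) matrix row labels."""
    return [r.split(STAGE_SEPARATOR, 1)[0] for r in matrix_rows]
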