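"""Faith's phylogenetic diversity of the host set of each tick species and stage.

Faith's PD of a set of tips is the total branch length of the minimal subtree
spanning them.  With ``include_root=True`` (the default here, as in most
community-ecology implementations) the path from the set's most recent common
ancestor up to the root is part of that subtree, so a singleton host set gets
its root-to-tip distance rather than zero.  Profiles are computed separately
per realm and per known life stage, complemented by family richness, because a
tick can reach a high PD either through many host families or through a few
distantly related ones.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .records import FEEDING_STAGES, AssociationRecord, Realm, Stage
from .trees import Phylogeny

logger = logging.getLogger(__name__)

__all__ = ["PDProfile", "UnknownTipError", "faith_pd", "pd_profiles", "profiles_to_frame"]


class UnknownTipError(KeyError):
    """A requested tip label is absent from the tree."""


@dataclass(frozen=True)
class PDProfile:
    """PD and family richness of one (species, stage, realm) host set.

    ``n_unplaced`` counts host families present in the records but absent
    from the tree; they are excluded from both ``pd`` and ``n_families``.
    """

    tick_species: str
    stage: Stage
    realm: Realm
    pd: float
    n_families: int
    n_unplaced: int = 0


def faith_pd(tree: Phylogeny, tips: Iterable[str], include_root: bool = True) -> float:
    """Total branch length of the minimal subtree spanning ``tips``.

    ``include_root=False`` stops the subtree at the tip set's MRCA, so a
    singleton set has PD 0.  Unknown labels raise :class:`UnknownTipError`
    listing every missing label; an empty set returns 0 with a warning.
    """
    tip_list = sorted(set(tips))
    if not tip_list:
        warnings.warn("faith_pd called with an empty tip set; returning 0", stacklevel=2)
        return 0.0
    missing = [t for t in tip_list if t not in tree.tip_labels]
    if missing:
        raise UnknownTipError(f"tip label(s) not in tree: {missing}")

    # union of root-to-tip paths; each edge identified by its head node
    spanning: dict[int, float] = {}
    ancestor_sets = []
    for label in tip_list:
        node = tree.leaf(label)
        ancestors = set()
        while node.parent_node is not None:
            spanning.setdefault(id(node), node.edge.length or 0.0)
            node = node.parent_node
            ancestors.add(id(node))
        ancestor_sets.append(ancestors)
    total = sum(spanning.values())
    if include_root:
        return float(total)
    if len(tip_list) == 1:
        return 0.0  # the MRCA of a singleton is the tip itself

    # subtract the MRCA-to-root path: shared ancestors of all tips
    shared = set.intersection(*ancestor_sets)
    node = tree.leaf(tip_list[0])
    while node.parent_node is not None:
        parent = node.parent_node
        if id(parent) in shared:
            # edges strictly above the MRCA
            walker = parent
            while walker.parent_node is not None:
                total -= walker.edge.length or 0.0
                walker = walker.parent_node
            break
        node = parent
    return float(max(total, 0.0))


def pd_profiles(
    records: Sequence[AssociationRecord],
    tree: Phylogeny,
    realm: Realm | None = None,
    include_root: bool = True,
    stages: Sequence[Stage] = FEEDING_STAGES,
) -> list[PDProfile]:
    """One PD profile per (species, stage, realm) with at least one usable family.

    Stage-unresolved records are excluded (``stages`` defaults to the three
    feeding stages).  Families absent from the tree are dropped with a logged
    warning and tallied in ``n_unplaced``.  The result is sorted by species
    then stage order, and can be re-sorted by adult PD for panel layouts.
    """
    wanted = set(stages)
    groups: dict[tuple[str, Stage, Realm], set[str]] = {}
    for rec in records:
        if rec.stage not in wanted:
            continue
        if realm is not None and rec.realm != realm:
            continue
        groups.setdefault((rec.tick_species, rec.stage, rec.realm), set()).add(
            rec.host_family
        )

    all_unplaced: set[str] = set()
    profiles = []
    for (species, stage, rlm), families in sorted(
        groups.items(), key=lambda kv: (kv[0][0], kv[0][1].value, kv[0][2].value)
    ):
        placed = families & tree.tip_labels
        unplaced = families - tree.tip_labels
        all_unplaced |= unplaced
        if not placed:
            continue
        profiles.append(
            PDProfile(
                tick_species=species,
                stage=stage,
                realm=rlm,
                pd=faith_pd(tree, placed, include_root=include_root),
                n_families=len(placed),
                n_unplaced=len(unplaced),
            )
        )
    if all_unplaced:
        logger.warning(
            "%d host famil(ies) absent from the tree were excluded from PD: %s",
            len(all_unplaced),
            ", ".join(sorted(all_unplaced)[:10]),
        )
    return profiles


def profiles_to_frame(
    profiles: Sequence[PDProfile], sort_by_adult_pd: bool = False
) -> pd.DataFrame:
    """Profiles as a DataFrame; optionally sorted by each species' adult PD, descending."""
    frame = pd.DataFrame(
        {
            "tick_species": [p.tick_species for p in profiles],
            "stage": [p.stage.value for p in profiles],
            "realm": [p.realm.value for p in profiles],
            "pd": [p.pd for p in profiles],
            "n_families": [p.n_families for p in profiles],
            "n_unplaced": [p.n_unplaced for p in profiles],
        }
    )
    if sort_by_adult_pd and not frame.empty:
        adult = (
            frame[frame["stage"] == Stage.ADULT.value]
            .set_index(["tick_species", "realm"])["pd"]
            .to_dict()
        )
        frame["_adult_pd"] = [
            adult.get((s, r), float("-inf"))
            for s, r in zip(frame["tick_species"], frame["realm"])
        ]
        frame = (
            frame.sort_values(
                ["_adult_pd", "tick_species", "stage"], ascending=[False, True, True]
            )
            .drop(columns="_adult_pd")
            .reset_index(drop=True)
        )
    return frame
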