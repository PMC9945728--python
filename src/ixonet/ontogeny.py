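"""Ontogenetic host switching between consecutive tick life stages.

Ticks feed once per stage (larva, nymph, adult) and can change host spectrum
at each molt.  The switch statistic is the relative change of Faith's PD of
the host set between consecutive stages: 0 means no change, 1 means the PD
doubled, negative values mean the host spectrum contracted phylogenetically.
Stage-flow tables summarise, at the host-order level, how the mass of
literature records redistributes from one stage to the next; because
literature records never pair an individual larva with the nymph it became,
the flow uses the independence (outer-product) coupling of the two stages'
record distributions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .pd import PDProfile
from .records import FEEDING_STAGES, AssociationRecord, Realm, Stage

__all__ = [
    "Transition",
    "SwitchRate",
    "StageFlowTable",
    "switch_rate",
    "switch_table",
    "stage_flow",
    "switch_rates_to_frame",
    "flow_to_frame",
]


class Transition(str, enum.Enum):
    LARVA_NYMPH = "L->N"
    NYMPH_ADULT = "N->A"


_TRANSITION_STAGES: dict[Transition, tuple[Stage, Stage]] = {
    Transition.LARVA_NYMPH: (Stage.LARVA, Stage.NYMPH),
    Transition.NYMPH_ADULT: (Stage.NYMPH, Stage.ADULT),
}


@dataclass(frozen=True)
class SwitchRate:
    """Relative PD change of one species across one molt; ``rate >= -1``."""

    tick_species: str
    realm: Realm
    transition: Transition
    rate: float
    pd_prev: float
    pd_next: float

    @property
    def pd_difference(self) -> float:
        """Absolute PD change, exposed alongside the relative rate."""
        return self.pd_next - self.pd_prev


@dataclass
class StageFlowTable:
    """Host-order x host-order record flow for one molt; entries sum to 1."""

    transition: Transition
    from_orders: list[str]
    to_orders: list[str]
    proportions: np.ndarray  # shape (len(from_orders), len(to_orders))


def switch_rate(pd_prev: float, pd_next: float) -> float:
    """Relative change ``(pd_next - pd_prev) / pd_prev``.

    Undefined for ``pd_prev == 0``: returns NaN (a missing-value marker,
    never a silent 0, because "no change" and "no data" must stay distinct).
    """
    if pd_prev < 0 or pd_next < 0:
        raise ValueError("PD values must be non-negative")
    if pd_prev == 0:
        return float("nan")
    return (pd_next - pd_prev) / pd_prev


def switch_table(
    profiles: Sequence[PDProfile], realm: Realm | None = None
) -> tuple[list[SwitchRate], int]:
    """Per-species switch rates for every molt with PD known on both sides.

    Returns ``(rates, n_skipped)`` where ``n_skipped`` counts species in the
    selection lacking two consecutive known stages (those species produce no
    row but are never silently dropped from the tally).
    """
    by_species: dict[tuple[str, Realm], dict[Stage, float]] = {}
    for p in profiles:
        if realm is not None and p.realm != realm:
            continue
        by_species.setdefault((p.tick_species, p.realm), {})[p.stage] = p.pd

    rates: list[SwitchRate] = []
    n_skipped = 0
    for (species, rlm), stage_pd in sorted(by_species.items()):
        contributed = False
        for transition, (prev, nxt) in _TRANSITION_STAGES.items():
            if prev in stage_pd and nxt in stage_pd:
                # rate is NaN (a visible missing-value marker) when pd_prev == 0
                r = switch_rate(stage_pd[prev], stage_pd[nxt])
                rates.append(
                    SwitchRate(
                        tick_species=species,
                        realm=rlm,
                        transition=transition,
                        rate=r,
                        pd_prev=stage_pd[prev],
                        pd_next=stage_pd[nxt],
                    )
                )
                contributed = True
        if not contributed:
            n_skipped += 1
    return rates, n_skipped


def stage_flow(
    records: Sequence[AssociationRecord], realm: Realm | None = None
) -> list[StageFlowTable]:
    """Record-flow tables over host orders for each consecutive-stage molt.

    For each species with records at both stages of a transition, the
    earlier-stage record proportions over host orders are coupled to the
    later-stage proportions by their outer product; species contributions
    are weighted by their record counts at the two stages, and each table is
    normalized to sum to 1.
    """
    # (species, stage) -> {host_order: weight}
    weights: dict[tuple[str, Stage], dict[str, float]] = {}
    for rec in records:
        if realm is not None and rec.realm != realm:
            continue
        if rec.stage not in FEEDING_STAGES:
            continue
        d = weights.setdefault((rec.tick_species, rec.stage), {})
        d[rec.host_order] = d.get(rec.host_order, 0.0) + rec.weight

    species = sorted({sp for sp, _ in weights})
    tables: list[StageFlowTable] = []
    for transition, (prev, nxt) in _TRANSITION_STAGES.items():
        flow: dict[tuple[str, str], float] = {}
        for sp in species:
            w_prev = weights.get((sp, prev))
            w_next = weights.get((sp, nxt))
            if not w_prev or not w_next:
                continue
            tot_prev = sum(w_prev.values())
            tot_next = sum(w_next.values())
            sp_weight = tot_prev + tot_next  # species weighted by record mass
            for o1, a in w_prev.items():
                for o2, b in w_next.items():
                    flow[(o1, o2)] = (
                        flow.get((o1, o2), 0.0)
                        + sp_weight * (a / tot_prev) * (b / tot_next)
                    )
        if not flow:
            continue
        total = sum(flow.values())
        from_orders = sorted({o for o, _ in flow})
        to_orders = sorted({o for _, o in flow})
        mat = np.zeros((len(from_orders), len(to_orders)))
        for (o1, o2), v in flow.items():
            mat[from_orders.index(o1), to_orders.index(o2)] = v / total
        tables.append(
            StageFlowTable(
                transition=transition,
                from_orders=from_orders,
                to_orders=to_orders,
                proportions=mat,
            )
        )
    return tables


def switch_rates_to_frame(
    rates: Sequence[SwitchRate], sort_by: str = "nymph_adult", signed: bool = True
) -> pd.DataFrame:
    """Switch rates as a DataFrame, sorted for bar-chart layouts.

    ``sort_by='nymph_adult'`` orders species by their N->A rate in decreasing
    order (``signed=False`` sorts on magnitudes instead; both conventions
    occur in published charts).
    """
    frame = pd.DataFrame(
        {
            "tick_species": [r.tick_species for r in rates],
            "realm": [r.realm.value for r in rates],
            "transition": [r.transition.value for r in rates],
            "rate": [r.rate for r in rates],
            "pd_prev": [r.pd_prev for r in rates],
            "pd_next": [r.pd_next for r in rates],
            "pd_difference": [r.pd_difference for r in rates],
        }
    )
    if frame.empty or sort_by is None:
        return frame
    na = frame[frame["transition"] == Transition.NYMPH_ADULT.value]
    key = na.set_index(["tick_species", "realm"])["rate"]
    if not signed:
        key = key.abs()
    keys = key.to_dict()
    frame["_key"] = [
        keys.get((s, r), float("-inf"))
        for s, r in zip(frame["tick_species"], frame["realm"])
    ]
    return (
        frame.sort_values(["_key", "tick_species", "transition"], ascending=[False, True, True])
        .drop(columns="_key")
        .reset_index(drop=True)
    )


def flow_to_frame(tables: Sequence[StageFlowTable]) -> pd.DataFrame:
    """Flow tables in long format: transition, from_order, to_order, proportion."""
    rows = []
    for t in tables:
        for i, o1 in enumerate(t.from_orders):
            for j, o2 in enumerate(t.to_orders):
                if t.proportions[i, j] > 0:
                    rows.append(
                        {
                            "transition": t.transition.value,
                            "from_order": o1,
                            "to_order": o2,
                            "proportion": t.proportions[i, j],
                        }
                    )
    return pd.DataFrame(rows, columns=["transition", "from_order", "to_order", "proportion"])
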