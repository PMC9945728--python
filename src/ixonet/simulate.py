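"""Synthetic record tables and host trees with planted, recoverable structure.

The generator emulates a literature compilation of tick-host associations:
tick species are planted into modules, host families are partitioned across
the same modules (and mapped onto orders within them), each species and stage
draws its hosts from a module-concentrated preference, the host pool is
inherited or re-drawn across molts with a tunable switch intensity, and
citation effort is overdispersed (negative-binomial) to mimic the uneven
survey pressure of real literature data.  A companion routine grows random
non-ultrametric bifurcating trees standing in for a reference family-level
phylogeny.  Everything is deterministic under the seed, and the ground truth
(module labels, stage pools, realized switch events) is returned alongside
the records so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from .records import AssociationRecord, Realm, Stage
from .trees import Phylogeny

__all__ = ["SimulationConfig", "GroundTruth", "generate_tree", "generate_records"]

_FEEDING = (Stage.LARVA, Stage.NYMPH, Stage.ADULT)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic community.

    Defaults sketch a community of the same shape as a worldwide single-genus
    compilation, scaled to run in seconds: a few hundred parasite species over
    ~150 host families in ~30 orders, six planted modules, moderately
    concentrated host use and an intermediate switch intensity.

    ``module_affinity`` is the probability that a host draw stays inside the
    species' planted module; ``switch_sigma`` is the per-molt probability
    that a stage re-draws its host pool independently of the previous stage;
    ``records_per_species_stage`` is the mean of a negative-binomial citation
    count with shape ``dispersion``; ``effort_bias`` multiplies the citation
    effort of module 0 so tests can probe robustness to survey skew.
    """

    n_tick_species: int = 250
    n_host_families: int = 150
    n_host_orders: int = 30
    n_modules: int = 6
    module_affinity: float = 0.9
    switch_sigma: float = 0.5
    records_per_species_stage: float = 8.0
    dispersion: float = 1.0
    hosts_per_pool: int = 6
    nestedness_mode: bool = False
    effort_bias: float = 1.0
    realms: tuple[Realm, ...] = (Realm.PALEARCTIC,)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_tick_species, self.n_host_families, self.n_host_orders) < 1:
            raise ValueError("counts must be positive")
        if self.n_modules < 1 or self.n_modules > self.n_host_families:
            raise ValueError("need 1 <= n_modules <= n_host_families")
        if self.n_modules > self.n_host_orders:
            raise ValueError("need n_modules <= n_host_orders")
        if not 0.5 <= self.module_affinity <= 1.0:
            raise ValueError("module_affinity must lie in [0.5, 1]")
        if not 0.0 <= self.switch_sigma <= 1.0:
            raise ValueError("switch_sigma must lie in [0, 1]")
        if self.records_per_species_stage <= 0 or self.dispersion <= 0:
            raise ValueError("count-law parameters must be positive")


@dataclass
class GroundTruth:
    """Planted structure behind a generated record table."""

    module_of_species: dict[str, int]
    module_of_family: dict[str, int]
    order_of_family: dict[str, str]
    #: (species, realm) -> [nymph redrew?, adult redrew?]
    switch_events: dict[tuple[str, Realm], list[bool]]
    #: (species, stage, realm) -> planted host pool
    pools: dict[tuple[str, Stage, Realm], tuple[str, ...]] = field(default_factory=dict)
    total_weight: int = 0


def _species_name(i: int) -> str:
    return f"Ixodes_sp{i + 1:03d}"


def _family_name(i: int) -> str:
    return f"Family{i + 1:03d}"


def _order_name(i: int) -> str:
    return f"Order{i + 1:02d}"


def generate_tree(n_families: int, seed: int = 0) -> Phylogeny:
    """Random bifurcating tree over ``Family001..`` tips.

    Topology grows by sequential random tip attachment (each new tip splits a
    uniformly chosen existing branch); branch lengths are i.i.d.
    Exponential(mean 1), so the tree is non-ultrametric.  Deterministic under
    the seed.
    """
    if n_families < 2:
        raise ValueError("need at least 2 families")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    leaves: list[dendropy.Node] = []
    for i in range(2):
        child = tree.seed_node.new_child()
        child.taxon = taxa.new_taxon(_family_name(i))
        leaves.append(child)
    attachable = list(leaves)  # nodes whose parent edge can be split
    for i in range(2, n_families):
        target = attachable[rng.integers(len(attachable))]
        parent = target.parent_node
        joint = dendropy.Node()
        parent.remove_child(target)
        parent.add_child(joint)
        joint.add_child(target)
        leaf = joint.new_child()
        leaf.taxon = taxa.new_taxon(_family_name(i))
        attachable.extend([joint, leaf])
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = float(rng.exponential(1.0))
    return Phylogeny(tree)


def _partition_round_robin(items: Sequence[str], n_groups: int) -> dict[str, int]:
    return {item: i % n_groups for i, item in enumerate(items)}


def _nested_records(cfg: SimulationConfig) -> tuple[list[AssociationRecord], GroundTruth]:
    """Perfectly nested triangular incidence: tick i uses the first n-i families."""
    n = min(cfg.n_tick_species, cfg.n_host_families)
    families = [_family_name(i) for i in range(n)]
    orders = [_order_name(i % cfg.n_host_orders) for i in range(n)]
    records = []
    realm = cfg.realms[0]
    for i in range(n):
        for j in range(n - i):
            records.append(
                AssociationRecord(
                    tick_species=_species_name(i),
                    stage=Stage.ADULT,
                    host_family=families[j],
                    host_order=orders[j],
                    realm=realm,
                    weight=1,
                )
            )
    truth = GroundTruth(
        module_of_species={_species_name(i): 0 for i in range(n)},
        module_of_family={f: 0 for f in families},
        order_of_family=dict(zip(families, orders)),
        switch_events={},
        total_weight=len(records),
    )
    return records, truth


def generate_records(
    cfg: SimulationConfig,
) -> tuple[list[AssociationRecord], GroundTruth]:
    """Generate a record table with planted modules and switch behaviour.

    Realms are independent replicate communities sharing the species,
    modules and families.  Per species, stage and realm: the host pool is
    ``hosts_per_pool`` families sampled by the module-concentrated
    preference; a molt keeps the previous pool with probability
    ``1 - switch_sigma``; the stage's citation count is negative-binomial
    and spread multinomially over the pool.
    """
    if cfg.nestedness_mode:
        return _nested_records(cfg)

    rng = np.random.default_rng(cfg.seed)
    species = [_species_name(i) for i in range(cfg.n_tick_species)]
    families = [_family_name(i) for i in range(cfg.n_host_families)]
    orders = [_order_name(i) for i in range(cfg.n_host_orders)]

    module_of_species = _partition_round_robin(species, cfg.n_modules)
    module_of_family = _partition_round_robin(families, cfg.n_modules)
    module_of_order = _partition_round_robin(orders, cfg.n_modules)

    # families map to orders of their own module, spread round-robin
    orders_by_module: dict[int, list[str]] = {}
    for o, m in module_of_order.items():
        orders_by_module.setdefault(m, []).append(o)
    order_of_family: dict[str, str] = {}
    counters = {m: 0 for m in range(cfg.n_modules)}
    for fam in families:
        m = module_of_family[fam]
        pool = orders_by_module[m]
        order_of_family[fam] = pool[counters[m] % len(pool)]
        counters[m] += 1

    fam_array = np.array(families)
    fam_modules = np.array([module_of_family[f] for f in families])

    truth = GroundTruth(
        module_of_species=module_of_species,
        module_of_family=module_of_family,
        order_of_family=order_of_family,
        switch_events={},
    )

    # negative binomial with mean mu and shape k: n=k, p=k/(k+mu)
    k = cfg.dispersion

    records: list[AssociationRecord] = []
    total_weight = 0
    for realm in cfg.realms:
        for sp in species:
            m = module_of_species[sp]
            in_module = fam_modules == m
            n_in = int(in_module.sum())
            n_out = len(families) - n_in
            prefs = np.where(
                in_module,
                cfg.module_affinity / max(n_in, 1),
                (1.0 - cfg.module_affinity) / max(n_out, 1),
            )
            prefs = prefs / prefs.sum()

            def draw_pool() -> tuple[str, ...]:
                size = min(cfg.hosts_per_pool, len(families))
                picked = rng.choice(len(families), size=size, replace=False, p=prefs)
                return tuple(fam_array[np.sort(picked)])

            pools: dict[Stage, tuple[str, ...]] = {}
            events: list[bool] = []
            prev: tuple[str, ...] | None = None
            for stage in _FEEDING:
                if prev is None:
                    pool = draw_pool()
                else:
                    redraw = bool(rng.random() < cfg.switch_sigma)
                    events.append(redraw)
                    pool = draw_pool() if redraw else prev
                pools[stage] = pool
                prev = pool
                truth.pools[(sp, stage, realm)] = pool

                mu = cfg.records_per_species_stage
                if cfg.effort_bias != 1.0 and m == 0:
                    mu *= cfg.effort_bias
                n_rec = int(rng.negative_binomial(k, k / (k + mu)))
                if n_rec == 0:
                    continue
                counts = rng.multinomial(n_rec, np.full(len(pool), 1.0 / len(pool)))
                for fam, cnt in zip(pool, counts):
                    if cnt > 0:
                        records.append(
                            AssociationRecord(
                                tick_species=sp,
                                stage=stage,
                                host_family=fam,
                                host_order=order_of_family[fam],
                                realm=realm,
                                weight=int(cnt),
                            )
                        )
                        total_weight += int(cnt)
            truth.switch_events[(sp, realm)] = events

    truth.total_weight = total_weight
    return records, truth
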