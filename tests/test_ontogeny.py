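"""Ontogenetic switch rates and stage-flow tables."""

import math

import numpy as np
import pytest

from ixonet.ontogeny import (
    Transition,
    flow_to_frame,
    stage_flow,
    switch_rate,
    switch_rates_to_frame,
    switch_table,
)
from ixonet.pd import PDProfile, pd_profiles
from ixonet.records import AssociationRecord, Realm, Stage
from ixonet.simulate import SimulationConfig, generate_records, generate_tree

R = AssociationRecord


@pytest.mark.parametrize(
    "prev,nxt,expected",
    [(2.0, 4.0, 1.0), (3.3, 3.3, 0.0), (4.0, 2.0, -0.5), (1.0, 0.0, -1.0)],
)
def test_switch_rate_formula(prev, nxt, expected):
    assert switch_rate(prev, nxt) == pytest.approx(expected)


def test_switch_rate_zero_baseline_is_missing_not_zero():
    assert math.isnan(switch_rate(0.0, 2.0))


def test_switch_rate_is_scale_invariant():
    rng = np.random.default_rng(0)
    for _ in range(20):
        prev, nxt = rng.uniform(0.1, 10, size=2)
        c = rng.uniform(0.01, 100)
        assert switch_rate(c * prev, c * nxt) == pytest.approx(switch_rate(prev, nxt))


def prof(species, stage, pd, realm=Realm.NEARCTIC):
    return PDProfile(species, stage, realm, pd, n_families=1)


def test_switch_table_rows_and_skips():
    profiles = [
        prof("full", Stage.LARVA, 2.0),
        prof("full", Stage.NYMPH, 4.0),
        prof("full", Stage.ADULT, 2.0),
        prof("adults_only", Stage.ADULT, 3.0),
    ]
    rates, n_skipped = switch_table(profiles)
    assert n_skipped == 1
    by_transition = {(r.tick_species, r.transition): r.rate for r in rates}
    assert by_transition[("full", Transition.LARVA_NYMPH)] == pytest.approx(1.0)
    assert by_transition[("full", Transition.NYMPH_ADULT)] == pytest.approx(-0.5)
    assert len(rates) == 2


def test_switch_table_realm_filter():
    profiles = [
        prof("sp", Stage.LARVA, 1.0, Realm.NEARCTIC),
        prof("sp", Stage.NYMPH, 2.0, Realm.NEARCTIC),
        prof("sp", Stage.LARVA, 1.0, Realm.PALEARCTIC),
    ]
    rates, _ = switch_table(profiles, realm=Realm.NEARCTIC)
    assert len(rates) == 1 and rates[0].realm is Realm.NEARCTIC


def test_flow_single_species_single_path():
    records = [
        R("sp", Stage.LARVA, "Muridae", "Rodentia", Realm.NEARCTIC, 4),
        R("sp", Stage.NYMPH, "Turdidae", "Passeriformes", Realm.NEARCTIC, 2),
    ]
    (table,) = stage_flow(records)
    assert table.transition is Transition.LARVA_NYMPH
    assert table.from_orders == ["Rodentia"]
    assert table.to_orders == ["Passeriformes"]
    assert table.proportions[0, 0] == pytest.approx(1.0)


def test_flow_outer_product_coupling():
    records = [
        R("sp", Stage.LARVA, "Muridae", "Rodentia", Realm.NEARCTIC, 5),
        R("sp", Stage.LARVA, "Turdidae", "Passeriformes", Realm.NEARCTIC, 5),
        R("sp", Stage.NYMPH, "Cricetidae", "Rodentia", Realm.NEARCTIC, 9),
    ]
    (table,) = stage_flow(records)
    flows = {
        (f, t): table.proportions[i, j]
        for i, f in enumerate(table.from_orders)
        for j, t in enumerate(table.to_orders)
    }
    assert flows[("Rodentia", "Rodentia")] == pytest.approx(0.5)
    assert flows[("Passeriformes", "Rodentia")] == pytest.approx(0.5)


def test_flow_tables_normalized_and_reproducible():
    cfg = SimulationConfig(n_tick_species=30, n_host_families=24, n_host_orders=8,
                           n_modules=4, seed=6)
    records, _ = generate_records(cfg)
    tables = stage_flow(records)
    assert tables, "expected at least one transition table"
    for t in tables:
        assert t.proportions.sum() == pytest.approx(1.0)
        assert (t.proportions >= 0).all()
    again = stage_flow(records)
    for a, b in zip(tables, again):
        np.testing.assert_array_equal(a.proportions, b.proportions)


def test_flow_equals_brute_force_recomputation():
    cfg = SimulationConfig(n_tick_species=12, n_host_families=12, n_host_orders=4,
                           n_modules=3, seed=13)
    records, _ = generate_records(cfg)
    tables = {t.transition: t for t in stage_flow(records)}
    # brute force: accumulate outer products directly from the raw records
    for transition, (s_prev, s_next) in {
        Transition.LARVA_NYMPH: (Stage.LARVA, Stage.NYMPH),
        Transition.NYMPH_ADULT: (Stage.NYMPH, Stage.ADULT),
    }.items():
        raw = {}
        species = {r.tick_species for r in records}
        for sp in species:
            prev = [r for r in records if r.tick_species == sp and r.stage == s_prev]
            nxt = [r for r in records if r.tick_species == sp and r.stage == s_next]
            if not prev or not nxt:
                continue
            tp = sum(r.weight for r in prev)
            tn = sum(r.weight for r in nxt)
            for rp in prev:
                for rn in nxt:
                    key = (rp.host_order, rn.host_order)
                    raw[key] = raw.get(key, 0.0) + (tp + tn) * (rp.weight / tp) * (rn.weight / tn)
        if not raw:
            assert transition not in tables
            continue
        total = sum(raw.values())
        table = tables[transition]
        for (f, t), v in raw.items():
            i, j = table.from_orders.index(f), table.to_orders.index(t)
            assert table.proportions[i, j] == pytest.approx(v / total, abs=1e-12)


def test_planted_switch_intensity_orders_cohorts():
    """sigma=0 cohorts (stages reuse their pool) switch less than sigma=1 cohorts."""
    tree = generate_tree(60, seed=21)
    means = {}
    for sigma in (0.0, 1.0):
        cfg = SimulationConfig(
            n_tick_species=200, n_host_families=60, n_host_orders=12, n_modules=4,
            switch_sigma=sigma, records_per_species_stage=30, dispersion=5,
            seed=22,
        )
        records, _ = generate_records(cfg)
        rates, _ = switch_table(pd_profiles(records, tree))
        means[sigma] = np.nanmean([abs(r.rate) for r in rates])
    assert means[0.0] < means[1.0]


def test_switch_frame_sorting_by_nymph_adult_rate():
    profiles = [
        prof("a", Stage.LARVA, 1.0), prof("a", Stage.NYMPH, 1.0), prof("a", Stage.ADULT, 4.0),
        prof("b", Stage.NYMPH, 2.0), prof("b", Stage.ADULT, 1.0),
    ]
    rates, _ = switch_table(profiles)
    frame = switch_rates_to_frame(rates, sort_by="nymph_adult", signed=True)
    assert frame.iloc[0]["tick_species"] == "a"  # N->A rate 3.0 sorts first
    frame_abs = switch_rates_to_frame(rates, signed=False)
    assert set(frame_abs["tick_species"]) == {"a", "b"}
    long = flow_to_frame([])
    assert list(long.columns) == ["transition", "from_order", "to_order", "proportion"]
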