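"""Structure indices against brute-force oracles and analytic limits."""

import numpy as np
import pytest

from conftest import random_matrix
from oracles import (
    brute_betweenness,
    brute_compartments,
    brute_fc,
    brute_nodf,
    brute_partner_diversity,
)

from ixonet.build import to_matrix
from ixonet.metrics import (
    basic_counts,
    betweenness,
    compartments,
    extinction_slope,
    fisher_alpha,
    fisher_alpha_sn,
    functional_complementarity,
    louvain_modularity,
    network_report,
    nodf,
    partner_diversity,
    weighted_degree,
)
from ixonet.network import BipartiteNetwork, InteractionMatrix


def net_from_edges(edges):
    ticks = {t for t, _ in edges}
    hosts = {h for _, h in edges}
    return BipartiteNetwork(ticks, hosts, dict(edges))


def random_bipartite_net(rng, n_ticks=4, n_hosts=4, p=0.6):
    edges = {}
    for i in range(n_ticks):
        for j in range(n_hosts):
            if rng.random() < p:
                edges[(f"t{i}", f"h{j}")] = float(rng.integers(1, 6))
    if not edges:
        edges[("t0", "h0")] = 1.0
    return net_from_edges(edges)


# ---------------------------------------------------------------- counts


def test_basic_counts():
    edges = {
        ("t1", "h1"): 1.0, ("t1", "h2"): 1.0, ("t2", "h2"): 1.0,
        ("t2", "h3"): 1.0, ("t3", "h3"): 1.0, ("t3", "h4"): 1.0,
    }
    order, size, lps, n_fam = basic_counts(net_from_edges(edges))
    assert order == 7 and size == 6
    assert lps == pytest.approx(2.0)
    assert n_fam == 4

    single = net_from_edges({("t", "h"): 1.0})
    assert basic_counts(single)[2] == pytest.approx(1.0)


def test_links_per_species_uses_species_not_stage_nodes():
    net = BipartiteNetwork(
        {"a::larva", "a::adult"},
        {"F1", "F2"},
        {("a::larva", "F1"): 1.0, ("a::adult", "F2"): 1.0},
        tick_species={"a::larva": "a", "a::adult": "a"},
    )
    _, size, lps, _ = basic_counts(net)
    assert size == 2 and lps == pytest.approx(2.0)


def test_weighted_degree_is_incident_weight_sum():
    net = net_from_edges({("t1", "h1"): 2.0, ("t1", "h2"): 3.0, ("t2", "h1"): 5.0})
    assert weighted_degree(net, "t1") == 5.0
    assert weighted_degree(net, "h1") == 7.0
    with pytest.raises(KeyError):
        weighted_degree(net, "nope")


# ----------------------------------------------------------- betweenness


def test_betweenness_star_and_path():
    star = net_from_edges({("c", f"h{i}"): 1.0 for i in range(4)})
    bt = betweenness(star)
    assert bt["c"] == pytest.approx(6.0)  # (n-1)(n-2)/2
    assert all(bt[f"h{i}"] == 0.0 for i in range(4))

    path = net_from_edges({("t1", "h"): 1.0, ("t2", "h"): 1.0})
    assert betweenness(path)["h"] == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(5))
def test_betweenness_matches_path_enumeration(seed):
    net = random_bipartite_net(np.random.default_rng(seed), 4, 4, p=0.5)
    got = betweenness(net)
    nodes = sorted(net.tick_nodes | net.host_nodes)
    expected = brute_betweenness(nodes, list(net.edges))
    for n in nodes:
        assert got[n] == pytest.approx(expected[n], abs=1e-9)


# ------------------------------------------------------------ modularity


def two_block_net():
    edges = {}
    for t, h in [("t1", "h1"), ("t1", "h2"), ("t2", "h1"), ("t2", "h2")]:
        edges[(t, h)] = 1.0
    for t, h in [("t3", "h3"), ("t3", "h4"), ("t4", "h3"), ("t4", "h4")]:
        edges[(t, h)] = 1.0
    return net_from_edges(edges)


def test_louvain_attains_planted_two_block_partition():
    part, q, n = louvain_modularity(two_block_net(), seed=0)
    assert q == pytest.approx(0.5)
    assert n == 2
    block1 = {part["t1"], part["t2"], part["h1"], part["h2"]}
    block2 = {part["t3"], part["t4"], part["h3"], part["h4"]}
    assert len(block1) == 1 and len(block2) == 1 and block1 != block2


def test_single_edge_modularity_is_zero():
    _, q, n = louvain_modularity(net_from_edges({("t", "h"): 1.0}), seed=0)
    assert q == pytest.approx(0.0)
    assert n == 1


@pytest.mark.parametrize("seed", range(3))
def test_louvain_never_below_single_module_and_q_below_one(seed):
    net = random_bipartite_net(np.random.default_rng(seed + 10), 5, 5, p=0.4)
    _, q, _ = louvain_modularity(net, seed=seed)
    assert 0.0 <= q <= 1.0


def test_louvain_is_deterministic_given_seed():
    net = random_bipartite_net(np.random.default_rng(99), 6, 6, p=0.4)
    assert louvain_modularity(net, seed=5) == louvain_modularity(net, seed=5)


# ----------------------------------------------------------- components


def test_compartments_counts_connected_components():
    assert compartments(two_block_net()) == 2
    assert compartments(net_from_edges({("t", "h"): 1.0})) == 1


@pytest.mark.parametrize("seed", range(5))
def test_compartments_matches_union_find(seed):
    net = random_bipartite_net(np.random.default_rng(seed + 20), 5, 5, p=0.25)
    nodes = sorted(net.tick_nodes | net.host_nodes)
    assert compartments(net) == brute_compartments(nodes, list(net.edges))


# ----------------------------------------------------------------- NODF


def test_nodf_perfectly_nested_is_100():
    m = InteractionMatrix(
        ["r1", "r2", "r3", "r4"],
        ["c1", "c2", "c3", "c4"],
        np.array([[1, 1, 1, 1], [1, 1, 1, 0], [1, 1, 0, 0], [1, 0, 0, 0]]),
    )
    assert nodf(m) == pytest.approx(100.0)


def test_nodf_identical_rows_is_0():
    m = InteractionMatrix(["r1", "r2"], ["c1", "c2"], np.array([[2, 7], [1, 1]]))
    assert nodf(m) == pytest.approx(0.0)


def test_nodf_undefined_below_2x2():
    with pytest.raises(ValueError):
        nodf(InteractionMatrix(["r"], ["c"], np.array([[1]])))


def test_nodf_invariant_under_permutations_and_binary():
    rng = np.random.default_rng(7)
    m = random_matrix(rng)
    base = nodf(m)
    assert 0.0 <= base <= 100.0
    rp = rng.permutation(m.shape[0])
    cp = rng.permutation(m.shape[1])
    perm = InteractionMatrix(
        [m.row_labels[i] for i in rp],
        [m.col_labels[j] for j in cp],
        m.values[np.ix_(rp, cp)],
    )
    assert nodf(perm) == pytest.approx(base, abs=1e-12)
    binary = InteractionMatrix(m.row_labels, m.col_labels, m.binary)
    assert nodf(binary) == pytest.approx(base, abs=1e-12)


# --------------------------------------------------------- Fisher alpha


def test_fisher_alpha_satisfies_defining_equation():
    rng = np.random.default_rng(1)
    for _ in range(50):
        s = int(rng.integers(2, 400))
        n = float(s + rng.integers(1, 5000))
        a = fisher_alpha_sn(s, n)
        assert abs(a * np.log1p(n / a) - s) < 1e-10


def test_fisher_alpha_increases_with_richness_at_fixed_weight():
    alphas = [fisher_alpha_sn(s, 10_000) for s in (10, 50, 100, 500, 1000)]
    assert all(a < b for a, b in zip(alphas, alphas[1:]))


def test_fisher_alpha_diverges_when_all_singletons():
    m = InteractionMatrix(["a", "b"], ["x", "y"], np.array([[1, 0], [0, 1]]))
    with pytest.raises(ValueError, match="diverges"):
        fisher_alpha(m)


# ---------------------------------------------------- partner diversity


def test_partner_diversity_limits():
    one_host = InteractionMatrix(["a", "b"], ["x", "y"], np.array([[3, 0], [0, 9]]))
    assert partner_diversity(one_host) == pytest.approx(0.0)
    uniform = InteractionMatrix(["a"], ["x", "y", "z"], np.array([[2, 2, 2]]))
    assert partner_diversity(uniform) == pytest.approx(np.log(3))


def test_partner_diversity_bounded_by_log_host_count():
    rng = np.random.default_rng(11)
    for seed in range(5):
        m = random_matrix(np.random.default_rng(seed))
        assert partner_diversity(m) <= np.log(m.shape[1]) + 1e-12


# ------------------------------------------- functional complementarity


def test_fc_identical_rows_is_zero():
    m = InteractionMatrix(["a", "b"], ["x", "y"], np.array([[1, 2], [1, 2]]))
    assert functional_complementarity(m) == 0.0


def test_fc_two_orthogonal_ticks_hand_computed():
    m = InteractionMatrix(["a", "b"], ["x", "y"], np.array([[1, 0], [0, 1]]))
    # single merge at height sqrt(2); two branches from leaves at height 0
    assert functional_complementarity(m) == pytest.approx(2 * np.sqrt(2))


@pytest.mark.parametrize("seed", range(5))
def test_fc_matches_naive_upgma(seed):
    m = random_matrix(np.random.default_rng(seed + 40), shape=(5, 4))
    assert functional_complementarity(m) == pytest.approx(brute_fc(m.values), abs=1e-9)


# ------------------------------------------------------ extinction slope


def test_extinction_exponent_linear_limit():
    m = InteractionMatrix(
        [f"t{i}" for i in range(10)], [f"h{i}" for i in range(10)], np.eye(10)
    )
    assert extinction_slope(m, seed=0) == pytest.approx(1.0, abs=0.05)


def test_extinction_exponent_redundancy_extremum():
    m = InteractionMatrix(
        [f"t{i}" for i in range(5)], [f"h{i}" for i in range(10)], np.ones((5, 10))
    )
    assert extinction_slope(m, seed=0) > 5.0


def test_extinction_deterministic_given_seed_and_redundancy_helps():
    rng = np.random.default_rng(3)
    m = random_matrix(rng, shape=(8, 6))
    a1 = extinction_slope(m, n_replicates=200, seed=4)
    assert a1 == extinction_slope(m, n_replicates=200, seed=4)
    # duplicating a host column adds redundancy: exponent should not decrease
    dup = InteractionMatrix(
        m.row_labels, m.col_labels + ["h_dup"], np.hstack([m.values, m.values[:, :1]])
    )
    a2 = extinction_slope(dup, n_replicates=200, seed=4)
    assert a2 >= a1 - 0.05


# -------------------------------------------------------- oracle sweep


def test_all_matrix_indices_match_brute_force_on_random_matrices():
    for seed in range(20):
        m = random_matrix(np.random.default_rng(seed))
        assert nodf(m) == pytest.approx(brute_nodf(m.values), abs=1e-9)
        assert partner_diversity(m) == pytest.approx(
            brute_partner_diversity(m.values), abs=1e-9
        )
        assert functional_complementarity(m) == pytest.approx(
            brute_fc(m.values), abs=1e-9
        )


def test_network_report_is_coherent():
    rng = np.random.default_rng(5)
    net = random_bipartite_net(rng, 6, 6, p=0.6)
    rep = network_report(net, seed=1, n_replicates=20)
    assert rep.order == len(net.tick_nodes) + len(net.host_nodes)
    assert rep.size == len(net.edges)
    assert rep.n_compartments >= 1
    assert 0 <= rep.nodf <= 100
    assert rep.n_host_families == len(net.host_nodes)
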