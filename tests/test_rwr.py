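import numpy as np
import pytest

import fruitwalk as fw
from fruitwalk.rwr import NonConvergenceError


def _random_network(rng, n=50, p=0.12):
    triples = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                triples.append((f"n{i:03d}", f"n{j:03d}", int(rng.integers(150, 1000))))
    return fw.WeightedNetwork.from_edge_list(
        triples, extra_nodes=[f"n{i:03d}" for i in range(n)]
    )


# ---------------------------------------------------------------------------
# Transition matrix
# ---------------------------------------------------------------------------

def test_transition_matrix_two_nodes(two_node_network):
    m = fw.build_transition_matrix(two_node_network)
    dense = m.matrix.toarray()
    assert np.allclose(dense, [[0.0, 1.0], [1.0, 0.0]])


def test_transition_matrix_star_split(star_network):
    m = fw.build_transition_matrix(star_network)
    idx = m.node_index
    col_a = m.matrix.toarray()[:, idx["A"]]
    assert col_a[idx["B"]] == pytest.approx(0.25)  # 150 / (150 + 450)
    assert col_a[idx["C"]] == pytest.approx(0.75)


def test_transition_matrix_isolated_node_self_loop():
    net = fw.WeightedNetwork({("a", "b"): 500}, extra_nodes=["d"])
    m = fw.build_transition_matrix(net)
    idx = m.node_index
    dense = m.matrix.toarray()
    assert dense[idx["d"], idx["d"]] == 1.0
    assert np.allclose(dense.sum(axis=0), 1.0)


def test_transition_matrix_columns_stochastic_random():
    net = _random_network(np.random.default_rng(3))
    m = fw.build_transition_matrix(net)
    assert np.allclose(np.asarray(m.matrix.sum(axis=0)).ravel(), 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# Initial vector
# ---------------------------------------------------------------------------

def test_initial_vector_uniform_over_seeds():
    nodes = ("a", "b", "c", "d", "e")
    p0 = fw.initial_vector(fw.SeedSet(("a", "b", "c", "d")), nodes)
    assert p0["a"] == pytest.approx(0.25)
    assert p0["e"] == 0.0
    assert p0.total() == pytest.approx(1.0)


def test_initial_vector_single_seed():
    p0 = fw.initial_vector(fw.SeedSet(("b",)), ("a", "b"))
    assert p0["b"] == 1.0


def test_initial_vector_splits_isoform_mass():
    seeds = fw.SeedSet(("g",), node_groups={"g": ("x", "y")})
    p0 = fw.initial_vector(seeds, ("x", "y", "z"))
    assert p0["x"] == pytest.approx(0.5)
    assert p0["y"] == pytest.approx(0.5)


def test_initial_vector_unknown_seed_errors():
    with pytest.raises(ValueError, match="not in network"):
        fw.initial_vector(fw.SeedSet(("q",)), ("a", "b"))


# ---------------------------------------------------------------------------
# Propagation
# ---------------------------------------------------------------------------

def test_two_node_closed_form(two_node_network):
    # p = c (I - (1-c) M)^-1 p0 solved by hand: (5/6, 1/6) at c = 0.8
    m = fw.build_transition_matrix(two_node_network)
    p0 = fw.initial_vector(fw.SeedSet(("a",)), m.nodes)
    p = fw.run_rwr(m, p0, fw.RWRConfig(tolerance=1e-12))
    assert p["a"] == pytest.approx(5 / 6, abs=1e-9)
    assert p["b"] == pytest.approx(1 / 6, abs=1e-9)
    assert p.converged


def test_restart_probability_one_returns_p0(two_node_network):
    m = fw.build_transition_matrix(two_node_network)
    p0 = fw.initial_vector(fw.SeedSet(("a",)), m.nodes)
    p = fw.run_rwr(m, p0, fw.RWRConfig(restart_probability=1.0))
    assert np.allclose(p.values, p0.values)
    direct = fw.solve_rwr_direct(m, p0, restart_probability=1.0)
    assert np.allclose(direct.values, p0.values)


def test_complete_graph_all_seeded_is_uniform():
    n = 6
    net = fw.WeightedNetwork.from_edge_list(
        [(f"v{i}", f"v{j}", 500) for i in range(n) for j in range(i + 1, n)]
    )
    m = fw.build_transition_matrix(net)
    p0 = fw.initial_vector(fw.SeedSet(m.nodes), m.nodes)
    p = fw.run_rwr(m, p0, fw.RWRConfig(tolerance=1e-12))
    assert np.allclose(p.values, 1.0 / n, atol=1e-9)


def test_iterative_matches_direct_solve_on_random_graphs():
    for seed in range(20):
        rng = np.random.default_rng(seed)
        net = _random_network(rng)
        m = fw.build_transition_matrix(net)
        seeds = fw.SeedSet(tuple(sorted(rng.choice(m.nodes, 5, replace=False))))
        p0 = fw.initial_vector(seeds, m.nodes)
        iterative = fw.run_rwr(m, p0, fw.RWRConfig(tolerance=1e-11))
        direct = fw.solve_rwr_direct(m, p0)
        gap = np.abs(iterative.values - direct.values).sum()
        assert gap < 1e-8


def test_mass_conservation_standard_rule():
    for seed in (0, 1):
        net = _random_network(np.random.default_rng(seed))
        m = fw.build_transition_matrix(net)
        p0 = fw.initial_vector(fw.SeedSet(m.nodes[:4]), m.nodes)
        p = fw.run_rwr(m, p0, fw.RWRConfig(tolerance=1e-12))
        assert abs(p.total() - 1.0) < 1e-9


def test_seed_mass_monotone_in_restart_probability():
    net = _random_network(np.random.default_rng(11))
    m = fw.build_transition_matrix(net)
    seeds = fw.SeedSet(m.nodes[:5])
    p0 = fw.initial_vector(seeds, m.nodes)
    idx = [m.node_index[s] for s in seeds.node_ids]
    masses = []
    for c in (0.1, 0.5, 0.8, 0.95):
        p = fw.run_rwr(
            m, p0, fw.RWRConfig(restart_probability=c, tolerance=1e-11)
        )
        masses.append(float(p.values[idx].sum()))
    assert all(a <= b + 1e-12 for a, b in zip(masses, masses[1:]))


def test_literal_update_rule_diverges_on_regular_graph():
    # undamped update: on a cycle the propagation term keeps norm 1 while
    # the restart keeps injecting c, so the L1 norm grows without bound
    n = 12
    net = fw.WeightedNetwork.from_edge_list(
        [(f"v{i:02d}", f"v{(i + 1) % n:02d}", 500) for i in range(n)]
    )
    m = fw.build_transition_matrix(net)
    p0 = fw.initial_vector(fw.SeedSet((m.nodes[0],)), m.nodes)
    config = fw.RWRConfig(update_rule="literal", max_iterations=200)
    with pytest.raises(NonConvergenceError) as err:
        fw.run_rwr(m, p0, config)
    assert err.value.last_gap > 1.0  # still growing, not merely slow


def test_permutation_invariance_under_relabeling():
    rng = np.random.default_rng(5)
    net = _random_network(rng, n=30)
    mapping = {n: f"z{i:03d}" for i, n in enumerate(reversed(net.nodes))}
    relabeled = fw.WeightedNetwork.from_edge_list(
        [(mapping[a], mapping[b], s) for a, b, s in net.edges()],
        extra_nodes=[mapping[n] for n in net.nodes],
    )
    seeds = fw.SeedSet(net.nodes[:3])
    seeds_r = fw.SeedSet(tuple(sorted(mapping[s] for s in seeds.genes)))
    m1 = fw.build_transition_matrix(net)
    m2 = fw.build_transition_matrix(relabeled)
    p1 = fw.run_rwr(m1, fw.initial_vector(seeds, m1.nodes), fw.RWRConfig(tolerance=1e-11))
    p2 = fw.run_rwr(m2, fw.initial_vector(seeds_r, m2.nodes), fw.RWRConfig(tolerance=1e-11))
    d1 = p1.to_dict()
    d2 = p2.to_dict()
    for node, value in d1.items():
        assert d2[mapping[node]] == pytest.approx(value, abs=1e-12)


def test_direct_solve_guard():
    nodes = tuple(f"n{i}" for i in range(2001))
    net = fw.WeightedNetwork({("n0", "n1"): 500}, extra_nodes=nodes)
    m = fw.build_transition_matrix(net)
    p0 = fw.initial_vector(fw.SeedSet(("n0",)), m.nodes)
    with pytest.raises(ValueError, match="direct solve"):
        fw.solve_rwr_direct(m, p0)


# ---------------------------------------------------------------------------
# RWR gene selection
# ---------------------------------------------------------------------------

def test_select_rwr_genes_strict_threshold_and_seed_exclusion():
    nodes = ("g1", "g2", "g3", "s")
    p = fw.ProbabilityVector(
        nodes=nodes, values=np.array([2e-5, 1e-5, 1e-6, 0.9])
    )
    picked = fw.select_rwr_genes(p, fw.SeedSet(("s",)), fw.RWRConfig())
    assert picked == [("g1", 2e-5)]  # g2 at the boundary is excluded


def test_select_rwr_genes_zero_threshold_keeps_all_positive():
    nodes = ("a", "b", "c")
    p = fw.ProbabilityVector(nodes=nodes, values=np.array([0.5, 0.0, 0.2]))
    picked = fw.select_rwr_genes(
        p, fw.SeedSet(("a",)), fw.RWRConfig(probability_threshold=0.0)
    )
    assert picked == [("c", 0.2)]


def test_select_rwr_genes_tie_break_lexicographic():
    nodes = ("b", "a", "s")
    p = fw.ProbabilityVector(nodes=nodes, values=np.array([0.2, 0.2, 0.6]))
    picked = fw.select_rwr_genes(p, fw.SeedSet(("s",)), fw.RWRConfig())
    assert [g for g, _ in picked] == ["a", "b"]


def test_rwr_config_validation():
    with pytest.raises(ValueError):
        fw.RWRConfig(restart_probability=0.0)
    with pytest.raises(ValueError):
        fw.RWRConfig(update_rule="pagerank")
    with pytest.raises(ValueError):
        fw.RWRConfig(tolerance=0.0)
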