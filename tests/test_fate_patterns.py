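import numpy as np
import pytest

from icmfate.cell_graph import CellGraph, build_cell_graph
from icmfate.fate_patterns import (
    compose_populations,
    same_state_neighbor_fraction,
    simulate_local_clustering,
    simulate_nearest_neighbor,
    simulate_period_two,
    simulate_random,
)
from oracles import all_maximal_independent_sets, chain_states_reference


def _clique(n):
    pos = np.column_stack([np.arange(n) * 5.0, np.zeros(n), np.zeros(n)])
    return CellGraph(vertex_ids=list(range(n)), positions=pos,
                     edges={(i, j) for i in range(n) for j in range(i + 1, n)},
                     cutoff=30.0)


# --- random ------------------------------------------------------------


def test_random_conserves_positive_count():
    levels = np.array([1.0, 5.0, 9.0])
    for seed in range(20):
        pat = simulate_random(levels, threshold=4.0, seed=seed)
        assert pat.n_positive == 2


def test_random_threshold_below_min_all_positive():
    pat = simulate_random(np.array([3.0, 4.0, 5.0]), threshold=1.0, seed=0)
    assert pat.states.all()


def test_random_is_permutation_null():
    """Positive cells see ~the global positive fraction among neighbours."""
    rng = np.random.default_rng(10)
    pts = rng.uniform(0, 100, size=(1000, 3))
    g = build_cell_graph(pts)
    levels = np.concatenate([np.ones(300) * 9, np.ones(700)])
    fracs = [
        same_state_neighbor_fraction(g, simulate_random(levels, 5.0, seed))
        for seed in range(200)
    ]
    se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
    # mean positive-neighbour fraction of positives ~ 30% (permutation null)
    assert abs(np.mean(fracs) - 0.3) < 3 * se + 0.005


# --- period two --------------------------------------------------------


def test_period_two_single_vertex_positive():
    g = CellGraph(vertex_ids=[0], positions=np.zeros((1, 3)), edges=set())
    assert simulate_period_two(g, seed=0).states.all()


def test_period_two_triangle_exactly_one_positive():
    g = _clique(3)
    for seed in range(10):
        assert simulate_period_two(g, seed).n_positive == 1


def test_period_two_no_positive_positive_edges_and_maximal():
    rng = np.random.default_rng(4)
    pts = rng.uniform(0, 60, size=(30, 3))
    g = build_cell_graph(pts)
    for seed in range(10):
        pat = simulate_period_two(g, seed)
        for i, j in g.edges:
            assert not (pat.states[i] and pat.states[j])
        for i in range(30):  # maximality: every negative has a positive neighbour
            if not pat.states[i]:
                assert any(pat.states[j] for j in g.neighbor_indices(i))


def test_period_two_output_is_a_maximal_independent_set_of_the_graph():
    rng = np.random.default_rng(9)
    pts = rng.uniform(0, 40, size=(10, 3))
    g = build_cell_graph(pts)
    oracle = all_maximal_independent_sets(10, g.edges)
    for seed in range(10):
        pat = simulate_period_two(g, seed)
        assert frozenset(np.flatnonzero(pat.states).tolist()) in oracle


# --- chains ------------------------------------------------------------


def test_nearest_neighbor_two_cells():
    pat = simulate_nearest_neighbor(np.array([[0.0, 0, 0], [5.0, 0, 0]]), seed=0)
    assert pat.n_positive == 1  # one negative start, one positive neighbour


def test_nearest_neighbor_collinear_alternation():
    pts = np.array([[float(i), 0, 0] for i in range(5)])
    for seed in range(30):
        pat = simulate_nearest_neighbor(pts, seed)
        counts = sorted([pat.n_positive, 5 - pat.n_positive])
        assert counts == [2, 3]
        # a chain started at an end strictly alternates along the line
        rng = np.random.default_rng(seed)
        if int(rng.integers(5)) in (0, 4):
            assert all(pat.states[i] != pat.states[i + 1] for i in range(4))


def test_chain_matches_reference_implementation():
    rng = np.random.default_rng(12)
    pts = rng.uniform(0, 50, size=(40, 3))
    for seed in (0, 1, 7, 123):
        mine = simulate_nearest_neighbor(pts, seed).states
        ref = chain_states_reference(pts, seed, "nearest_neighbor")
        np.testing.assert_array_equal(mine, ref)
        for p in (0.2, 0.9):
            mine = simulate_local_clustering(pts, p, seed).states
            ref = chain_states_reference(pts, seed, "local_clustering", p)
            np.testing.assert_array_equal(mine, ref)


def test_local_clustering_p1_uniform_p0_alternating():
    rng = np.random.default_rng(2)
    pts = rng.uniform(0, 50, size=(25, 3))
    pat1 = simulate_local_clustering(pts, 1.0, seed=3)
    assert pat1.states.all() or not pat1.states.any()
    # p=0 equals the alternating chain up to the start-state coin flip
    pat0 = simulate_local_clustering(pts, 0.0, seed=3)
    nn = simulate_nearest_neighbor(pts, seed=3)
    agree = pat0.states == nn.states
    assert agree.all() or (~agree).all()


def _chain_order(pts, seed):
    """Visit order of the chain, which depends only on positions and seed."""
    n = len(pts)
    start = int(np.random.default_rng(seed).integers(n))
    order = [start]
    assigned = np.zeros(n, bool)
    assigned[start] = True
    current = start
    for _ in range(n - 1):
        d = np.linalg.norm(pts - pts[current], axis=1)
        d[assigned] = np.inf
        current = int(np.argmin(d))
        assigned[current] = True
        order.append(current)
    return order


def test_local_clustering_copy_rate_matches_p():
    """Consecutive same-state pairs along the chain occur at rate p."""
    rng = np.random.default_rng(1)
    pts = rng.uniform(0, 120, size=(500, 3))
    rates = []
    for seed in range(100):
        states = simulate_local_clustering(pts, 0.5, seed).states
        order = _chain_order(pts, seed)
        same = [states[a] == states[b] for a, b in zip(order, order[1:])]
        rates.append(np.mean(same))
    se = np.std(rates, ddof=1) / np.sqrt(len(rates))
    assert abs(np.mean(rates) - 0.5) < 3 * se


def test_clustering_monotone_in_p():
    """Same-state neighbour enrichment grows with the copy probability."""
    rng = np.random.default_rng(6)
    pts = rng.uniform(0, 90, size=(500, 3))
    g = build_cell_graph(pts)
    means = []
    for p in (0.1, 0.5, 0.9):
        vals = [
            same_state_neighbor_fraction(g, simulate_local_clustering(pts, p, s))
            for s in range(50)
        ]
        means.append(np.nanmean(vals))
    assert means[0] < means[1] < means[2]


def test_duplicate_positions_error():
    pts = np.array([[0.0, 0, 0], [0.0, 0, 0], [1.0, 0, 0]])
    with pytest.raises(ValueError, match="duplicate"):
        simulate_nearest_neighbor(pts, 0)
    with pytest.raises(ValueError, match="duplicate"):
        simulate_local_clustering(pts, 0.5, 0)


def test_simulators_are_bit_reproducible():
    rng = np.random.default_rng(5)
    pts = rng.uniform(0, 60, size=(60, 3))
    g = build_cell_graph(pts)
    for fn in (
        lambda s: simulate_random(np.arange(60.0), 30.0, s),
        lambda s: simulate_period_two(g, s),
        lambda s: simulate_nearest_neighbor(pts, s),
        lambda s: simulate_local_clustering(pts, 0.7, s),
    ):
        np.testing.assert_array_equal(fn(99).states, fn(99).states)


# --- composition -------------------------------------------------------


def test_compose_all_positive_is_dp():
    from icmfate.fate_patterns import BinaryPattern

    n = BinaryPattern(np.ones(5, bool), "random", 0)
    g = BinaryPattern(np.ones(5, bool), "random", 0)
    assert compose_populations(n, g) == ["DP"] * 5


def test_compose_complementary_is_epi_or_pre():
    from icmfate.fate_patterns import BinaryPattern

    states = np.array([True, False, True, False])
    n = BinaryPattern(states, "random", 0)
    g = BinaryPattern(~states, "random", 0)
    assert set(compose_populations(n, g)) == {"EPI", "PRE"}


def test_compose_counts_match_contingency():
    rng = np.random.default_rng(13)
    pts = rng.uniform(0, 70, size=(100, 3))
    g = build_cell_graph(pts)
    pn = simulate_random(rng.uniform(0, 1, 100), 0.6, seed=1)
    pg = simulate_period_two(g, seed=2)
    labels = compose_populations(pn, pg)
    from collections import Counter

    counts = Counter(labels)
    table = Counter(zip(pn.states, pg.states))
    assert counts["DP"] == table[(True, True)]
    assert counts["EPI"] == table[(True, False)]
    assert counts["PRE"] == table[(False, True)]
    assert counts["DN"] == table[(False, False)]


def test_compose_mismatched_sets_error():
    from icmfate.fate_patterns import BinaryPattern

    with pytest.raises(ValueError):
        compose_populations(
            BinaryPattern(np.ones(3, bool), "random", 0),
            BinaryPattern(np.ones(4, bool), "random", 0),
        )
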