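import numpy as np
import pandas as pd
import pytest

from icmfate.cell_graph import build_cell_graph
from icmfate.fate_patterns import simulate_local_clustering
from icmfate.neighborhood_stats import cohort_composition, specimen_composition
from icmfate.pattern_comparison import (
    BINARY_CLASSES,
    bonferroni_ci,
    rank_patterns,
    relative_deviation,
    scan_clustering_probability,
    wmw_bonferroni,
)
from icmfate.synthetic_data import generate_positions
from oracles import wmw_exact_two_sided_p


def test_wmw_small_sample_exact_third():
    assert wmw_bonferroni([1, 2], [3, 4], n_tests=1) == pytest.approx(1 / 3)
    assert wmw_bonferroni([1, 2], [3, 4], n_tests=2) == pytest.approx(2 / 3)


def test_wmw_identical_samples_capped_at_one():
    assert wmw_bonferroni([1, 2, 3], [1, 2, 3], n_tests=5) == 1.0


def test_wmw_empty_sample_errors():
    with pytest.raises(ValueError):
        wmw_bonferroni([], [1.0])


def test_wmw_exact_branch_matches_enumeration_up_to_6_6():
    """Exact rank-sum p equals full enumeration for every size pair ≤ (6,6)."""
    rng = np.random.default_rng(99)
    for n in range(1, 7):
        for m in range(1, 7):
            vals = rng.permutation(np.arange(1.0, n + m + 1))
            a, b = vals[:n], vals[n:]
            assert wmw_bonferroni(a, b, 1) == pytest.approx(
                wmw_exact_two_sided_p(a, b), abs=1e-12
            )


def test_ci_identical_samples_contains_zero():
    ci = bonferroni_ci([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert ci.contains_zero
    assert ci.low == pytest.approx(-ci.high)


def test_ci_separated_samples_excludes_zero():
    a = np.array([100.0, 100.1, 99.9, 100.05])
    ci = bonferroni_ci(a, a - 100.0)
    assert not ci.contains_zero and ci.low > 0


def test_ci_singleton_errors():
    with pytest.raises(ValueError):
        bonferroni_ci([1.0], [1.0, 2.0])


def test_ci_coverage_under_the_null():
    """0 falls inside the corrected CI at >= the nominal rate."""
    rng = np.random.default_rng(7)
    alpha, n_tests, n_sim = 0.05, 3, 2000
    hits = 0
    for _ in range(n_sim):
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        if bonferroni_ci(a, b, alpha=alpha, n_tests=n_tests).contains_zero:
            hits += 1
    nominal = 1 - alpha / n_tests
    mc_err = 3 * np.sqrt(nominal * (1 - nominal) / n_sim)
    assert hits / n_sim >= nominal - mc_err


@pytest.mark.parametrize("s,d,expected", [(1.0, 1.0, 0.0), (1.1, 1.0, 0.1), (0.5, 1.0, -0.5)])
def test_relative_deviation(s, d, expected):
    assert relative_deviation(s, d) == pytest.approx(expected)


def test_relative_deviation_zero_experimental_mean_errors():
    with pytest.raises(ValueError):
        relative_deviation(1.0, 0.0)


def _comp_frame(rows):
    return pd.DataFrame(rows, columns=["negative", "positive"])


def test_rank_patterns_identical_copy_wins():
    exp = _comp_frame([[60.0, 40.0], [62.0, 38.0], [58.0, 42.0]])
    shifted = exp + 15.0
    res = rank_patterns(exp, {"copy": exp.copy(), "shifted": shifted})
    by_name = {r.pattern: r for r in res}
    assert by_name["copy"].best and not by_name["shifted"].best
    assert by_name["copy"].mean_abs_deviation == 0.0
    assert all(v == 0.0 for v in by_name["copy"].effect_sizes.values())


def test_rank_patterns_tie_flagged_and_broken_by_name():
    exp = _comp_frame([[60.0, 40.0], [62.0, 38.0]])
    res = rank_patterns(exp, {"b_copy": exp.copy(), "a_copy": exp.copy()})
    assert [r.pattern for r in res] == ["a_copy", "b_copy"]
    assert res[0].best and res[0].tied and res[1].tied and not res[1].best


def test_rank_patterns_category_mismatch_errors():
    exp = _comp_frame([[60.0, 40.0], [62.0, 38.0]])
    bad = pd.DataFrame([[1.0]], columns=["positive"])
    with pytest.raises(ValueError):
        rank_patterns(exp, {"bad": bad})


def test_rank_patterns_recovers_generating_rule():
    """A cohort generated by local clustering picks local clustering as best."""
    from icmfate.fate_patterns import simulate_nearest_neighbor, simulate_period_two

    rng = np.random.default_rng(21)
    positions = [generate_positions(200, 40.0, 8.0, s) for s in range(8)]
    graphs = [build_cell_graph(p) for p in positions]

    def comp(g, pat):
        return specimen_composition(g, pat.labels(), classes=BINARY_CLASSES)

    exp_rows, sims = [], {"local_clustering": [], "nearest_neighbor": [], "period_two": []}
    for k, g in enumerate(graphs):
        exp_rows.append(comp(g, simulate_local_clustering(g.positions, 0.9, 100 + k)))
        sims["local_clustering"].append(comp(g, simulate_local_clustering(g.positions, 0.9, 200 + k)))
        sims["nearest_neighbor"].append(comp(g, simulate_nearest_neighbor(g.positions, 300 + k)))
        sims["period_two"].append(comp(g, simulate_period_two(g, 400 + k)))

    focal = "positive"
    exp = pd.DataFrame([c.loc[focal] for c in exp_rows]).reset_index(drop=True)
    sim_frames = {
        name: pd.DataFrame([c.loc[focal] for c in comps]).reset_index(drop=True)
        for name, comps in sims.items()
    }
    res = rank_patterns(exp, sim_frames, cell_class="positive")
    best = [r for r in res if r.best]
    assert len(best) == 1 and best[0].pattern == "local_clustering"


def test_pscan_single_entry_grid():
    positions = [generate_positions(60, 30.0, 8.0, 1)]
    g = build_cell_graph(positions[0])
    pat = simulate_local_clustering(positions[0], 0.5, 2)
    exp = cohort_composition(
        [specimen_composition(g, pat.labels(), classes=BINARY_CLASSES),
         specimen_composition(g, pat.labels(), classes=BINARY_CLASSES)],
        classes=BINARY_CLASSES,
    )
    scan = scan_clustering_probability(positions, exp, grid=[0.5], seed=0)
    assert scan.best_p == 0.5 and len(scan.deviations) == 1


def test_pscan_empty_grid_errors():
    with pytest.raises(ValueError):
        scan_clustering_probability([np.zeros((1, 3))], pd.DataFrame(), grid=[], seed=0)


def test_pscan_recovers_generating_p():
    """Parameter recovery at desk scale: p = 0.2 and 0.8 on small cohorts."""
    positions = [generate_positions(250, 45.0, 8.0, 50 + s) for s in range(10)]
    graphs = [build_cell_graph(p) for p in positions]
    for ptrue in (0.2, 0.8):
        comps = [
            specimen_composition(
                g, simulate_local_clustering(g.positions, ptrue, 700 + i).labels(),
                classes=BINARY_CLASSES,
            )
            for i, g in enumerate(graphs)
        ]
        exp = cohort_composition(comps, classes=BINARY_CLASSES)
        scan = scan_clustering_probability(
            positions, exp, grid=[0.2, 0.5, 0.8], seed=3, graphs=graphs
        )
        assert scan.best_p == ptrue
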