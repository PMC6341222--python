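"""Measure who neighbours whom: per-population neighbourhood composition.

For each focal population, the percentages of its graph neighbours'
populations are pooled within a specimen (neighbour slots) and averaged
across specimens (mean ± SEM, specimen = independent unit). Same-fate
percentages above the population's own share indicate local clustering.
"""

from icmfate import (
    build_cell_graph,
    cohort_composition,
    generate_cohort,
    organoid_preset,
    specimen_composition,
)

cohort = generate_cohort(organoid_preset("24h"), n_specimens=6, seed=3)
comps = [
    specimen_composition(
        build_cell_graph(t.positions, ids=t.nucleus_ids),
        dict(zip(t.nucleus_ids, t.ground_truth)),
    )
    for t in cohort
]
table = cohort_composition(comps)
print(table.to_string(index=False, float_format=lambda x: f"{x:.2f}"))
print("Rows sum to 100% per focal population. With fates drawn i.i.d. from")
print("the preset mix (DP 30, EPI 20, PRE 35, DN 15%), every focal row simply")
print("mirrors that mix — no spatial structure, the salt-and-pepper baseline.")
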