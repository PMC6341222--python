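"""Build the 30 µm Delaunay cell graph for one synthetic organoid.

Vertices are nucleus centroids; edges are Delaunay edges strictly
shorter than 30 µm, approximating physical cell–cell contacts.
"""

import numpy as np

from icmfate import build_cell_graph, generate_specimen, organoid_preset

specimen = generate_specimen(organoid_preset("24h"), specimen_id="org-1")
graph = build_cell_graph(specimen.positions, cutoff=30.0, ids=specimen.nucleus_ids)

degrees = [graph.degree(v) for v in graph.vertex_ids]
lengths = graph.edge_lengths()
print(f"cells: {len(graph)}   contacts: {graph.n_edges}")
print(f"neighbours per cell: mean {np.mean(degrees):.1f} (range {min(degrees)}-{max(degrees)})")
print(f"contact length (µm): median {np.median(lengths):.1f}, max {lengths.max():.1f}")
print("A confluent aggregate gives ~10-14 neighbours per interior cell; every")
print("edge is below the 30 µm cutoff by construction.")
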