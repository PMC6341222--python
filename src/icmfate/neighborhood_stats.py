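"""Neighbourhood lineage composition statistics.

For each focal population the quantity of interest is the percentage
breakdown of the populations found among its graph neighbours. Within a
specimen, neighbour slots are pooled: the composition for focal class F is
(number of F→c neighbour slots) / (total F neighbour slots) × 100 for each
neighbour class c. Across specimens the mean and SEM are taken with the
specimen (organoid or embryo) as the independent unit.

Both label spaces are supported: the four populations and the binary
NANOG±/GATA6± states — the caller simply passes whichever labels it wants.
"""

from __future__ import annotations

from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

from icmfate.cell_graph import CellGraph


def _label_array(graph: CellGraph, labels: Mapping[Hashable, str] | Sequence[str]) -> list[str]:
    if isinstance(labels, Mapping):
        missing = [v for v in graph.vertex_ids if v not in labels]
        if missing:
            raise ValueError(f"unlabeled vertices: {missing[:5]}")
        return [labels[v] for v in graph.vertex_ids]
    labels = list(labels)
    if len(labels) != len(graph):
        raise ValueError("labels length does not match graph vertex count")
    return labels


def cell_neighbor_fractions(
    graph: CellGraph, labels: Mapping[Hashable, str] | Sequence[str]
) -> tuple[pd.DataFrame, list[Hashable]]:
    """Per-cell neighbour-class fractions.

    Returns a DataFrame indexed by nucleus id with one column per class,
    rows summing to 1, covering every cell with at least one neighbour,
    plus the list of isolated cells (flagged, excluded from aggregation).
    """
    lab = _label_array(graph, labels)
    classes = sorted(set(lab))
    cindex = {c: k for k, c in enumerate(classes)}
    rows, index, isolated = [], [], []
    for i, vid in enumerate(graph.vertex_ids):
        nbrs = graph.neighbor_indices(i)
        if not nbrs:
            isolated.append(vid)
            continue
        counts = np.zeros(len(classes))
        for j in nbrs:
            counts[cindex[lab[j]]] += 1
        rows.append(counts / counts.sum())
        index.append(vid)
    return pd.DataFrame(rows, index=index, columns=classes), isolated


def specimen_composition(
    graph: CellGraph,
    labels: Mapping[Hashable, str] | Sequence[str],
    classes: Sequence[str] | None = None,
    per_cell: bool = False,
) -> pd.DataFrame:
    """Neighbour-class percentages per focal class for one specimen.

    Default pooling counts neighbour slots: each (focal cell, neighbour)
    pair contributes one slot to the focal cell's class. ``per_cell=True``
    instead averages per-cell fraction vectors — a sensitivity variant.
    Focal classes with no member (or members without neighbours) are
    absent from the output. Rows sum to 100.
    """
    lab = _label_array(graph, labels)
    if classes is None:
        classes = sorted(set(lab))
    else:
        classes = list(classes)
        unknown = set(lab) - set(classes)
        if unknown:
            raise ValueError(f"labels outside the class space: {sorted(unknown)}")
    cindex = {c: k for k, c in enumerate(classes)}
    codes = np.array([cindex[l] for l in lab])
    K = len(classes)

    if per_cell:
        frac_sum = np.zeros((K, K))
        n_cells = np.zeros(K)
        for i in range(len(graph)):
            nbrs = list(graph.neighbor_indices(i))
            if not nbrs:
                continue
            v = np.bincount(codes[nbrs], minlength=K) / len(nbrs)
            frac_sum[codes[i]] += v
            n_cells[codes[i]] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            mat = 100.0 * frac_sum / n_cells[:, None]
        keep = n_cells > 0
    else:
        counts = np.zeros((K, K))
        ia, ib = graph.edge_arrays()
        if len(ia):
            np.add.at(counts, (codes[ia], codes[ib]), 1.0)
            np.add.at(counts, (codes[ib], codes[ia]), 1.0)
        totals = counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mat = 100.0 * counts / totals[:, None]
        keep = totals > 0

    df = pd.DataFrame(mat, index=classes, columns=classes)
    df.index.name = "focal"
    return df.loc[keep]


def cohort_composition(
    specimens: Sequence[pd.DataFrame], classes: Sequence[str] | None = None
) -> pd.DataFrame:
    """Mean ± SEM composition across specimens.

    ``specimens`` are per-specimen frames from :func:`specimen_composition`.
    A specimen lacking a focal class is omitted from that row's n; neighbour
    classes missing in a specimen (but in the shared class space) count as
    0%. Output is tidy: one row per (focal, neighbor) with mean_pct,
    sem_pct and n_specimens; SEM is NaN when n = 1.
    """
    if not specimens:
        raise ValueError("no specimens")
    if classes is None:
        classes = sorted(set().union(*[set(df.columns) for df in specimens]))
    classes = list(classes)
    rows = []
    for focal in classes:
        vals = [
            df.loc[focal].reindex(classes, fill_value=0.0)
            for df in specimens
            if focal in df.index
        ]
        if not vals:
            continue
        arr = np.array([v.to_numpy(dtype=float) for v in vals])
        n = len(arr)
        mean = arr.mean(axis=0)
        sem = arr.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.full(len(classes), np.nan)
        for k, nb in enumerate(classes):
            rows.append(
                {
                    "focal": focal,
                    "neighbor": nb,
                    "mean_pct": mean[k],
                    "sem_pct": sem[k],
                    "n_specimens": n,
                }
            )
    return pd.DataFrame(rows, columns=["focal", "neighbor", "mean_pct", "sem_pct", "n_specimens"])


def composition_matrix(cohort: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy cohort composition to a focal × neighbor mean_pct matrix."""
    return cohort.pivot(index="focal", columns="neighbor", values="mean_pct")
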