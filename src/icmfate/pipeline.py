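"""End-to-end analysis pipeline.

Wires the stages together: read per-nucleus tables → drop TE → obtain
population labels (k-means classification, or trust provided lineage
labels) → build cell graphs → neighbourhood compositions (four-population
and binary) → simulate the four null patterns on the same positions →
statistical comparison and local-clustering p-scan → write TSV result
tables plus a run manifest. Reruns with the same config and inputs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from icmfate.cell_graph import CellGraph, build_cell_graph
from icmfate.fate_patterns import (
    BinaryPattern,
    simulate_local_clustering,
    simulate_nearest_neighbor,
    simulate_period_two,
    simulate_random,
)
from icmfate.io_tables import (
    SpecimenTable,
    filter_icm,
    read_nucleus_table,
    write_results,
)
from icmfate.neighborhood_stats import (
    cohort_composition,
    specimen_composition,
)
from icmfate.pattern_comparison import (
    BINARY_CLASSES,
    DEFAULT_P_GRID,
    rank_patterns,
    scan_clustering_probability,
)
from icmfate.population_classify import (
    POPULATIONS,
    binarize_fates,
    classify_populations,
    stage_specimen,
    stage_summary,
)

log = logging.getLogger("icmfate")


@dataclass
class PipelineConfig:
    input_path: str
    out_dir: str
    column_map: Mapping[str, str] | None = None
    specimen_kind: str = "embryo"
    cutoff: float = 30.0
    seed: int = 0
    label_space: str = "population"  # or "binary"
    p_grid: Sequence[float] = field(default_factory=lambda: list(DEFAULT_P_GRID))
    alpha: float = 0.05
    force_reclassify: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def content_hash(self) -> str:
        d = asdict(self)
        d["column_map"] = dict(d["column_map"]) if d["column_map"] else None
        d["p_grid"] = [float(p) for p in d["p_grid"]]
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _binary_states(labels: Sequence[str], channel: str) -> np.ndarray:
    fates = binarize_fates(labels)
    if channel == "nanog":
        return np.array([f.nanog_positive for f in fates])
    return np.array([f.gata6_positive for f in fates])


def _simulate_patterns(
    graph: CellGraph,
    levels: np.ndarray | None,
    threshold: float | None,
    states: np.ndarray,
    seeds: Mapping[str, int],
) -> dict[str, BinaryPattern]:
    """All four null patterns on one specimen's positions.

    The random pattern permutes observed intensity levels when available;
    with label-only input it permutes the binary states themselves, which
    is the same null.
    """
    if levels is not None and threshold is not None:
        rand = simulate_random(levels, threshold, seeds["random"])
    else:
        rand = simulate_random(states.astype(float), 0.5, seeds["random"])
    return {
        "random": rand,
        "period_two": simulate_period_two(graph, seeds["period_two"]),
        "nearest_neighbor": simulate_nearest_neighbor(graph.positions, seeds["nearest_neighbor"]),
        "local_clustering": simulate_local_clustering(
            graph.positions, 0.9, seeds["local_clustering"]
        ),
    }


def _focal_frame(comps: list[pd.DataFrame], focal: str) -> pd.DataFrame:
    """Rows = specimens having the focal class, columns = neighbour classes."""
    rows = [df.loc[focal] for df in comps if focal in df.index]
    return pd.DataFrame(rows).reset_index(drop=True)


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run the full analysis; returns the result tables it also writes."""
    specimens = read_nucleus_table(
        config.input_path, config.column_map, specimen_kind=config.specimen_kind
    )
    log.info("read %d specimens from %s", len(specimens), config.input_path)

    have_lineage = all(t.has_lineage for t in specimens)
    if have_lineage:
        specimens = [filter_icm(t) for t in specimens]

    # --- population labels ---------------------------------------------
    thresholds: dict[str, float] = {}
    if have_lineage and not config.force_reclassify:
        labels_per_spec = {t.specimen_id: list(t.lineages) for t in specimens}
        log.info("using provided lineage labels; classification skipped")
    else:
        if not all(t.has_intensities for t in specimens):
            raise ValueError("classification requires NANOG/GATA6 intensities")
        # cohort fit: pool all cells, then split back per specimen
        nanog = np.concatenate([t.nanog for t in specimens])
        gata6 = np.concatenate([t.gata6 for t in specimens])
        result = classify_populations(nanog, gata6, seed=config.seed)
        thresholds = {
            "nanog_threshold": result.nanog_threshold,
            "gata6_threshold": result.gata6_threshold,
        }
        labels_per_spec = {}
        offset = 0
        for t in specimens:
            labels_per_spec[t.specimen_id] = result.labels[offset : offset + len(t)]
            offset += len(t)
        log.info(
            "classified %d cells (thresholds NANOG %.4g, GATA6 %.4g)",
            len(result.labels),
            result.nanog_threshold,
            result.gata6_threshold,
        )

    label_rows = []
    for t in specimens:
        labs = labels_per_spec[t.specimen_id]
        fates = binarize_fates(labs)
        for r, lab, f in zip(t.records, labs, fates):
            label_rows.append(
                {
                    "specimen_id": t.specimen_id,
                    "nucleus_id": r.nucleus_id,
                    "population": lab,
                    "nanog_state": "positive" if f.nanog_positive else "negative",
                    "gata6_state": "positive" if f.gata6_positive else "negative",
                }
            )
    labels_table = pd.DataFrame(label_rows)

    # --- staging --------------------------------------------------------
    staging = stage_summary(labels_per_spec)

    # --- graphs and compositions ----------------------------------------
    graphs = {
        t.specimen_id: build_cell_graph(
            t.positions, cutoff=config.cutoff, ids=t.nucleus_ids
        )
        for t in specimens
    }
    pop_comps = [
        specimen_composition(graphs[t.specimen_id], labels_per_spec[t.specimen_id],
                             classes=POPULATIONS)
        for t in specimens
    ]
    comp_population = cohort_composition(pop_comps, classes=POPULATIONS)

    binary_comps = {}
    for channel in ("nanog", "gata6"):
        comps = [
            specimen_composition(
                graphs[t.specimen_id],
                ["positive" if s else "negative"
                 for s in _binary_states(labels_per_spec[t.specimen_id], channel)],
                classes=BINARY_CLASSES,
            )
            for t in specimens
        ]
        binary_comps[channel] = comps

    comp_binary = pd.concat(
        [
            cohort_composition(binary_comps[ch], classes=BINARY_CLASSES).assign(channel=ch)
            for ch in ("nanog", "gata6")
        ],
        ignore_index=True,
    )

    # --- null-pattern simulation and comparison -------------------------
    ss = np.random.SeedSequence(config.seed)
    comparison_rows = []
    pscan_rows = []
    for channel in ("nanog", "gata6"):
        sim_comps: dict[str, list[pd.DataFrame]] = {}
        for t in specimens:
            g = graphs[t.specimen_id]
            states = _binary_states(labels_per_spec[t.specimen_id], channel)
            seeds = dict(
                zip(
                    ("random", "period_two", "nearest_neighbor", "local_clustering"),
                    (int(s % 2**31) for s in ss.spawn(1)[0].generate_state(4)),
                )
            )
            levels = t.nanog if (t.has_intensities and channel == "nanog") else (
                t.gata6 if t.has_intensities else None
            )
            thr = thresholds.get(f"{channel}_threshold") if thresholds else None
            patterns = _simulate_patterns(g, levels, thr, states, seeds)
            for name, pat in patterns.items():
                sim_comps.setdefault(name, []).append(
                    specimen_composition(g, pat.labels(), classes=BINARY_CLASSES)
                )

        for focal in BINARY_CLASSES:
            exp_df = _focal_frame(binary_comps[channel], focal)
            sim_dfs = {name: _focal_frame(comps, focal) for name, comps in sim_comps.items()}
            sim_dfs = {k: v for k, v in sim_dfs.items() if len(v) >= 2}
            if len(exp_df) < 2 or not sim_dfs:
                continue
            for res in rank_patterns(exp_df, sim_dfs, cell_class=f"{channel}:{focal}"):
                for cat in exp_df.columns:
                    comparison_rows.append(
                        {
                            "channel": channel,
                            "focal": focal,
                            "pattern": res.pattern,
                            "neighbor": cat,
                            "p_adjusted": res.p_adjusted[cat],
                            "effect_size": res.effect_sizes[cat],
                            "mean_abs_deviation": res.mean_abs_deviation,
                            "best": res.best,
                            "tied": res.tied,
                        }
                    )

        exp_cohort = cohort_composition(binary_comps[channel], classes=BINARY_CLASSES)
        scan = scan_clustering_probability(
            [graphs[t.specimen_id].positions for t in specimens],
            exp_cohort,
            grid=config.p_grid,
            seed=int(ss.spawn(1)[0].generate_state(1)[0] % 2**31),
            cutoff=config.cutoff,
            graphs=[graphs[t.specimen_id] for t in specimens],
        )
        for p, d in zip(scan.grid, scan.deviations):
            pscan_rows.append(
                {"channel": channel, "p": p, "mean_abs_deviation": d,
                 "best": p == scan.best_p}
            )
        log.info("p-scan (%s): best p = %.1f", channel, scan.best_p)

    comparison = pd.DataFrame(comparison_rows)
    pscan = pd.DataFrame(pscan_rows)

    tables = {
        "labels": labels_table,
        "staging": staging,
        "composition_population": comp_population,
        "composition_binary": comp_binary,
        "comparison": comparison,
        "pscan": pscan,
    }
    out_dir = Path(config.out_dir)
    write_results(tables, out_dir)
    manifest = {
        "config": {**asdict(config), "p_grid": [float(p) for p in config.p_grid]},
        "config_hash": config.content_hash(),
        "n_specimens": len(specimens),
        "thresholds": thresholds,
        "tables": sorted(tables),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return tables
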