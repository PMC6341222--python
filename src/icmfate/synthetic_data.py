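"""Synthetic organoid/embryo specimens with known ground truth.

Generates the inputs the analysis assumes without any microscopy:
nucleus centroids packed in a ball under a hard-core minimum-separation
constraint (dart throwing), fates placed either by fixed population
proportions or by one of the rule-based patterns, and two-channel
intensities drawn from population-conditional log-normal distributions.
Embryo mode adds a trophectoderm shell of TE-labelled cells just outside
the ICM ball so that TE filtering and staging can be exercised.

The default intensity model separates negative and positive log-intensity
components by 12 component SDs (ln 50 vs ln 400 with σ = 0.25), so that
fate classification on default specimens is essentially noise-free; a
"hard" model with 2-SD separation (σ = 1.5) exists for robustness tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from icmfate.cell_graph import build_cell_graph
from icmfate.fate_patterns import (
    compose_populations,
    simulate_local_clustering,
    simulate_nearest_neighbor,
    simulate_period_two,
    simulate_random,
)
from icmfate.io_tables import NucleusRecord, SpecimenTable
from icmfate.population_classify import POPULATIONS

#: (log-location, log-scale) per channel, per population, natural log.
#: Keys: population → ("nanog" | "gata6") → (mu, sigma).
DEFAULT_INTENSITY_MODEL: dict[str, dict[str, tuple[float, float]]] = {
    "DN": {"nanog": (np.log(50.0), 0.25), "gata6": (np.log(50.0), 0.25)},
    "DP": {"nanog": (np.log(400.0), 0.25), "gata6": (np.log(400.0), 0.25)},
    "EPI": {"nanog": (np.log(400.0), 0.25), "gata6": (np.log(50.0), 0.25)},
    "PRE": {"nanog": (np.log(50.0), 0.25), "gata6": (np.log(400.0), 0.25)},
}

#: 2-SD separation variant for robustness tests.
HARD_INTENSITY_MODEL: dict[str, dict[str, tuple[float, float]]] = {
    pop: {ch: (mu, 1.04) for ch, (mu, _) in chans.items()}
    for pop, chans in DEFAULT_INTENSITY_MODEL.items()
}

# TE intensities resemble DN (both fate markers low).
_TE_INTENSITY = {"nanog": (np.log(50.0), 0.25), "gata6": (np.log(50.0), 0.25)}


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic specimen family.

    ``fate_rule`` is either a dict of population proportions summing to 1,
    or a tuple (rule_name, params) applied per channel as in
    :func:`generate_specimen`. ``te_shell`` (embryo mode) is the number of
    TE cells placed on a shell outside the ICM ball.
    """

    n_cells: int = 450
    ball_radius: float = 50.0  # µm
    min_separation: float = 8.0  # µm
    fate_rule: Mapping[str, float] | tuple | None = None
    intensity_model: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: DEFAULT_INTENSITY_MODEL
    )
    te_shell: int = 0
    cutoff: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_separation <= 0:
            raise ValueError("min_separation must be positive")
        if isinstance(self.fate_rule, Mapping):
            total = sum(self.fate_rule.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"fate proportions sum to {total}, not 1")
            unknown = set(self.fate_rule) - set(POPULATIONS)
            if unknown:
                raise ValueError(f"unknown populations {sorted(unknown)}")


def organoid_preset(age: str = "24h") -> SyntheticSpec:
    """Aggregate-like preset: ~450 cells (24h) or ~1050 (48h) in a ball.

    Radii are chosen so the hard-core packing stays feasible and the
    median Delaunay edge is well below the 30 µm cutoff, mimicking a
    confluent aggregate. Default fate mix reflects a mid-differentiation
    stage: DP 30%, EPI 20%, PRE 35%, DN 15%.
    """
    props = {"DP": 0.30, "EPI": 0.20, "PRE": 0.35, "DN": 0.15}
    if age == "24h":
        return SyntheticSpec(n_cells=450, ball_radius=50.0, fate_rule=props)
    if age == "48h":
        return SyntheticSpec(n_cells=1050, ball_radius=66.0, fate_rule=props)
    raise ValueError(f"unknown organoid age {age!r}")


def classification_preset() -> SyntheticSpec:
    """Mixture preset for classification recovery checks.

    Co-expressing (DP) cells are a minority (DP 10%, DN 25%, EPI 30%,
    PRE 35%), as in mid-to-late specimens. This is the regime in which
    the three-cluster k-means scheme is well-posed: when DP dominates it
    forms its own extremal cluster and classification refuses (by design)
    rather than mislabelling.
    """
    return SyntheticSpec(
        fate_rule={"DP": 0.10, "DN": 0.25, "EPI": 0.30, "PRE": 0.35}
    )


def embryo_preset(stage: str = "mid", n_icm: int = 30, n_te: int = 20) -> SyntheticSpec:
    """Blastocyst-like preset: 20–45 ICM cells plus a TE shell.

    Stage presets fix the DP proportion relative to the >55%/0 staging
    rule: early 70% DP, mid 25% DP, late 0% DP.
    """
    props = {
        "early": {"DP": 0.70, "EPI": 0.10, "PRE": 0.10, "DN": 0.10},
        "mid": {"DP": 0.25, "EPI": 0.30, "PRE": 0.35, "DN": 0.10},
        "late": {"DP": 0.0, "EPI": 0.40, "PRE": 0.50, "DN": 0.10},
    }[stage]
    return SyntheticSpec(
        n_cells=n_icm,
        ball_radius=18.0,
        min_separation=7.0,
        fate_rule=props,
        te_shell=n_te,
    )


def generate_positions(
    n: int,
    ball_radius: float,
    min_separation: float,
    seed: int | np.random.Generator = 0,
    max_tries: int = 20000,
) -> np.ndarray:
    """Hard-core dart throwing: n points uniform in a ball, pairwise ≥ min_separation.

    Feasibility is pre-checked with a loose packing bound (spheres of
    diameter min_separation must occupy ≤ 40% of the ball volume).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    packing = n * (min_separation / 2) ** 3 / ball_radius**3
    if packing > 0.4:
        raise ValueError(
            f"infeasible packing (fraction {packing:.2f} > 0.4): "
            "increase ball_radius or decrease min_separation"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pts = np.empty((n, 3))
    k = 0
    tries = 0
    while k < n:
        if tries >= max_tries:
            raise RuntimeError(
                f"dart throwing exceeded {max_tries} tries at point {k}/{n}; "
                "increase ball_radius"
            )
        # uniform in ball: gaussian direction x cube-root radius
        v = rng.standard_normal(3)
        v /= np.linalg.norm(v)
        r = ball_radius * rng.random() ** (1 / 3)
        cand = r * v
        if k == 0 or np.min(np.linalg.norm(pts[:k] - cand, axis=1)) >= min_separation:
            pts[k] = cand
            k += 1
            tries = 0
        else:
            tries += 1
    return pts


def _shell_positions(
    n: int, radius: float, min_separation: float, rng: np.random.Generator,
    existing: np.ndarray, max_tries: int = 20000,
) -> np.ndarray:
    """Points on a sphere of the given radius, hard-core vs themselves and existing."""
    pts = np.empty((n, 3))
    k = 0
    tries = 0
    while k < n:
        if tries >= max_tries:
            raise RuntimeError("TE shell placement exceeded retry cap; enlarge the shell")
        v = rng.standard_normal(3)
        v /= np.linalg.norm(v)
        cand = radius * v
        others = np.vstack([existing, pts[:k]]) if k else existing
        if len(others) == 0 or np.min(np.linalg.norm(others - cand, axis=1)) >= min_separation:
            pts[k] = cand
            k += 1
            tries = 0
        else:
            tries += 1
    return pts


def _draw_intensities(
    labels: Sequence[str],
    model: Mapping[str, Mapping[str, tuple[float, float]]],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    n = len(labels)
    nanog = np.empty(n)
    gata6 = np.empty(n)
    for i, lab in enumerate(labels):
        chans = model[lab] if lab != "TE" else _TE_INTENSITY
        mu_n, sd_n = chans["nanog"]
        mu_g, sd_g = chans["gata6"]
        nanog[i] = rng.lognormal(mu_n, sd_n)
        gata6[i] = rng.lognormal(mu_g, sd_g)
    return nanog, gata6


def _assign_fates(
    spec: SyntheticSpec, positions: np.ndarray, rng: np.random.Generator
) -> list[str]:
    """Population labels per ICM cell, by proportions or by pattern rules."""
    n = len(positions)
    if spec.fate_rule is None or isinstance(spec.fate_rule, Mapping):
        props = spec.fate_rule or {"DP": 0.25, "EPI": 0.25, "PRE": 0.25, "DN": 0.25}
        pops = [p for p in POPULATIONS if props.get(p, 0) > 0]
        weights = np.array([props[p] for p in pops])
        return [pops[i] for i in rng.choice(len(pops), size=n, p=weights / weights.sum())]

    rule, params = spec.fate_rule
    seed_n, seed_g = (int(s) for s in rng.integers(0, 2**31, size=2))
    if rule == "local_clustering":
        pat_n = simulate_local_clustering(positions, params["p"], seed_n)
        pat_g = simulate_local_clustering(positions, params["p"], seed_g)
    elif rule == "nearest_neighbor":
        pat_n = simulate_nearest_neighbor(positions, seed_n)
        pat_g = simulate_nearest_neighbor(positions, seed_g)
    elif rule == "period_two":
        graph = build_cell_graph(positions, cutoff=spec.cutoff)
        pat_n = simulate_period_two(graph, seed_n)
        pat_g = simulate_period_two(graph, seed_g)
    elif rule == "random":
        levels = params["levels"]
        thr = params["threshold"]
        pat_n = simulate_random(levels, thr, seed_n)
        pat_g = simulate_random(levels, thr, seed_g)
    else:
        raise ValueError(f"unknown fate rule {rule!r}")
    return compose_populations(pat_n, pat_g)


def generate_specimen(spec: SyntheticSpec, specimen_id: str = "synthetic-0") -> SpecimenTable:
    """One synthetic specimen with ground-truth labels.

    ICM ground-truth population labels are stored in ``ground_truth`` (and,
    for embryo mode, also as lineage labels so TE filtering and staging
    work on them); intensities are drawn conditionally on the true label.
    """
    rng = np.random.default_rng(spec.seed)
    positions = generate_positions(
        spec.n_cells, spec.ball_radius, spec.min_separation, rng
    )
    labels = _assign_fates(spec, positions, rng)

    if spec.te_shell:
        shell = _shell_positions(
            spec.te_shell,
            spec.ball_radius + spec.min_separation,
            spec.min_separation,
            rng,
            positions,
        )
        positions = np.vstack([positions, shell])
        labels = labels + ["TE"] * spec.te_shell

    nanog, gata6 = _draw_intensities(labels, spec.intensity_model, rng)
    embryo_mode = spec.te_shell > 0
    records = [
        NucleusRecord(
            specimen_id=specimen_id,
            nucleus_id=f"{specimen_id}-c{i:04d}",
            x=float(positions[i, 0]),
            y=float(positions[i, 1]),
            z=float(positions[i, 2]),
            nanog=float(nanog[i]),
            gata6=float(gata6[i]),
            lineage=labels[i] if embryo_mode else None,
        )
        for i in range(len(positions))
    ]
    return SpecimenTable(
        specimen_id=specimen_id,
        records=records,
        specimen_kind="embryo" if embryo_mode else "organoid",
        ground_truth=list(labels),
    )


def generate_cohort(
    spec: SyntheticSpec, n_specimens: int, seed: int = 0, prefix: str = "synthetic"
) -> list[SpecimenTable]:
    """Independent specimens via seed-sequence spawning; deterministic overall."""
    if n_specimens < 1:
        raise ValueError("n_specimens must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.generate_state(n_specimens)
    return [
        generate_specimen(
            replace(spec, seed=int(children[k] % (2**31))), specimen_id=f"{prefix}-{k:03d}"
        )
        for k in range(n_specimens)
    ]
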