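"""Four-population fate classification from NANOG/GATA6 intensities.

Cells are classified into DN (double negative), DP (double positive),
EPI (N+/G−) and PRE (N−/G+) by k-means with k = 3 on log-transformed
intensities: the three clusters are the DN, EPI and PRE populations, and
DP cells — which sit high in both channels and do not form a separable
cluster at the co-expression stage — are carved out afterwards. A
provisional per-channel cut is placed at the midpoint between the DN
centre and the respective positive cluster centre; cells at or above both
cuts are DP. The reported positivity thresholds are then the channel-wise
minimum intensities over the DP cells (falling back to the provisional
cuts when no DP cell exists).

Specimens are staged by DP content: >55% DP → early, 0 DP → late,
otherwise mid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

#: ICM populations, fixed order used in all result tables.
POPULATIONS = ("DN", "DP", "EPI", "PRE")
STAGES = ("early", "mid", "late")

DP_STAGE_FRACTION = 0.55  # strict ">" for early


def log_transform(intensity: np.ndarray) -> np.ndarray:
    """Natural log of (intensity + 1); the +1 guards zero intensities."""
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity < 0) or not np.all(np.isfinite(intensity)):
        raise ValueError("intensities must be finite and >= 0")
    return np.log1p(intensity)


@dataclass
class ClassificationResult:
    labels: list[str]  # one of POPULATIONS per cell
    centers: np.ndarray  # (3, 2) in (log NANOG, log GATA6), rows DN/EPI/PRE
    nanog_threshold: float  # original intensity scale
    gata6_threshold: float
    seed: int

    def __post_init__(self) -> None:
        if len(np.unique(self.centers, axis=0)) != 3:
            raise ValueError("cluster centers are not distinct")


@dataclass(frozen=True)
class BinaryFate:
    """Per-channel positive/negative state of one cell."""

    nanog_positive: bool
    gata6_positive: bool


_LABEL_TO_BINARY = {
    "DP": BinaryFate(True, True),
    "EPI": BinaryFate(True, False),
    "PRE": BinaryFate(False, True),
    "DN": BinaryFate(False, False),
}


def classify_populations(
    nanog: np.ndarray, gata6: np.ndarray, seed: int = 0
) -> ClassificationResult:
    """Classify cells into DN/DP/EPI/PRE from raw intensities.

    k-means (k=3, 10 restarts, seeded) runs on (ln(NANOG+1), ln(GATA6+1)).
    Clusters are named semantically: DN has the smallest coordinate sum,
    EPI the largest log-NANOG centre, PRE the largest log-GATA6 centre —
    so the result does not depend on k-means' arbitrary cluster order. A
    cluster maximal in both channels means the populations are not
    separable and raises.
    """
    nanog = np.asarray(nanog, dtype=float)
    gata6 = np.asarray(gata6, dtype=float)
    if nanog.shape != gata6.shape or nanog.ndim != 1:
        raise ValueError("nanog and gata6 must be equal-length 1D vectors")
    if len(nanog) < 4:
        raise ValueError("need at least 4 cells to classify")
    X = np.column_stack([log_transform(nanog), log_transform(gata6)])
    if len(np.unique(X, axis=0)) < 3:
        raise ValueError("fewer than 3 distinct (log NANOG, log GATA6) points")

    km = KMeans(n_clusters=3, n_init=10, random_state=int(seed))
    assign = km.fit_predict(X)
    centers = km.cluster_centers_

    dn = int(np.argmin(centers.sum(axis=1)))
    epi = int(np.argmax(centers[:, 0]))
    pre = int(np.argmax(centers[:, 1]))
    if len({dn, epi, pre}) != 3:
        raise ValueError(
            "populations not separable: one cluster is extremal in both channels"
        )

    # provisional per-channel cuts: midpoint between DN and positive centre
    nanog_cut = 0.5 * (centers[dn, 0] + centers[epi, 0])
    gata6_cut = 0.5 * (centers[dn, 1] + centers[pre, 1])

    name = {dn: "DN", epi: "EPI", pre: "PRE"}
    is_dp = (X[:, 0] >= nanog_cut) & (X[:, 1] >= gata6_cut)
    labels = ["DP" if dp else name[a] for a, dp in zip(assign, is_dp)]

    if np.any(is_dp):
        nanog_threshold = float(nanog[is_dp].min())
        gata6_threshold = float(gata6[is_dp].min())
    else:
        # no DP cell: report the provisional cuts, mapped back from log scale
        nanog_threshold = float(np.expm1(nanog_cut))
        gata6_threshold = float(np.expm1(gata6_cut))

    ordered_centers = centers[[dn, epi, pre]]
    return ClassificationResult(
        labels=labels,
        centers=ordered_centers,
        nanog_threshold=nanog_threshold,
        gata6_threshold=gata6_threshold,
        seed=int(seed),
    )


def binarize_fates(labels: Sequence[str]) -> list[BinaryFate]:
    """Collapse four populations to per-channel binary states.

    NANOG-positive = DP or EPI; GATA6-positive = DP or PRE.
    """
    try:
        return [_LABEL_TO_BINARY[l] for l in labels]
    except KeyError as e:
        raise ValueError(f"unknown population label {e.args[0]!r}") from None


def stage_specimen(labels: Sequence[str]) -> str:
    """Stage one specimen from its ICM population labels.

    late if no DP cell at all; early if the DP fraction strictly exceeds
    55%; otherwise mid (a specimen at exactly 55% is mid). TE labels must
    already be removed.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("empty label set")
    bad = [l for l in labels if l not in POPULATIONS]
    if bad:
        raise ValueError(f"non-ICM labels present: {sorted(set(bad))}")
    n_dp = sum(l == "DP" for l in labels)
    if n_dp == 0:
        return "late"
    if n_dp / len(labels) > DP_STAGE_FRACTION:
        return "early"
    return "mid"


def stage_summary(staged: Mapping[str, Sequence[str]] | Iterable[tuple[str, Sequence[str]]]) -> pd.DataFrame:
    """Per-stage specimen counts and mean ± SEM ICM cell number.

    ``staged`` maps specimen id → its ICM population labels. SEM is the
    sample SD over √n; stages with a single specimen report SEM as NaN,
    empty stages report count 0 and NaN means.
    """
    items = list(staged.items()) if isinstance(staged, Mapping) else list(staged)
    if not items:
        raise ValueError("no specimens")
    rows = []
    by_stage: dict[str, list[int]] = {s: [] for s in STAGES}
    for sid, labels in items:
        by_stage[stage_specimen(labels)].append(len(list(labels)))
    for stage in STAGES:
        sizes = np.array(by_stage[stage], dtype=float)
        n = len(sizes)
        mean = sizes.mean() if n else np.nan
        sem = sizes.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        rows.append({"stage": stage, "n_specimens": n, "mean_cells": mean, "sem_cells": sem})
    return pd.DataFrame(rows, columns=["stage", "n_specimens", "mean_cells", "sem_cells"])
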