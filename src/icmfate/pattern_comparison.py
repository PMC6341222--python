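"""Statistical comparison of experimental vs simulated neighbourhood data.

Per-category differences are tested with the Wilcoxon–Mann–Whitney
rank-sum test, Bonferroni-corrected over the test family; Welch-type
confidence intervals for mean differences use the same correction. The
fit of each simulated pattern to the experimental data is summarised by
the signed relative deviation (s̄ − d̄)/d̄ of the simulated mean s̄ from
the experimental mean d̄, and patterns are ranked by the mean absolute
relative deviation across neighbour categories. For the local-clustering
rule, the copy probability p is chosen by scanning a grid (0.1…0.9 by
default) and minimising that same deviation score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from icmfate.cell_graph import build_cell_graph
from icmfate.fate_patterns import simulate_local_clustering
from icmfate.neighborhood_stats import cohort_composition, specimen_composition

DEFAULT_P_GRID = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))

BINARY_CLASSES = ("negative", "positive")


@dataclass
class ComparisonResult:
    """Fit of one simulated pattern to the experimental data, one cell class."""

    cell_class: str
    pattern: str
    p_adjusted: dict[str, float]  # per neighbour category
    effect_sizes: dict[str, float]  # signed (s̄−d̄)/d̄ per category
    mean_abs_deviation: float
    best: bool = False
    tied: bool = False


@dataclass
class PScanResult:
    grid: tuple[float, ...]
    deviations: tuple[float, ...]  # mean |relative deviation| per p
    best_p: float

    def __post_init__(self) -> None:
        if self.best_p not in self.grid:
            raise ValueError("best_p must be a grid point")


def wmw_bonferroni(
    sample_a: Sequence[float], sample_b: Sequence[float], n_tests: int = 1
) -> float:
    """Two-sided Wilcoxon–Mann–Whitney p, Bonferroni-multiplied and capped at 1.

    The exact null distribution is used whenever the smaller sample has
    ≤ 8 observations and the pooled sample is tie-free; otherwise the
    normal approximation with tie and continuity corrections.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (min(a.size, b.size) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(1.0, res.pvalue * n_tests))


@dataclass(frozen=True)
class ConfidenceInterval:
    low: float
    high: float
    level: float

    @property
    def contains_zero(self) -> bool:
        return self.low <= 0.0 <= self.high


def bonferroni_ci(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    alpha: float = 0.05,
    n_tests: int = 1,
) -> ConfidenceInterval:
    """Welch-type CI for mean(a) − mean(b) at level 1 − alpha/n_tests."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    adj = alpha / n_tests
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se = np.sqrt(va / na + vb / nb)
    diff = a.mean() - b.mean()
    if se == 0.0:
        return ConfidenceInterval(float(diff), float(diff), 1 - adj)
    # Welch–Satterthwaite degrees of freedom
    dof = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    tcrit = stats.t.ppf(1 - adj / 2, dof)
    return ConfidenceInterval(float(diff - tcrit * se), float(diff + tcrit * se), 1 - adj)


def relative_deviation(sim_mean: float, exp_mean: float) -> float:
    """Signed effect size (s̄ − d̄)/d̄; undefined at d̄ = 0."""
    if exp_mean == 0:
        raise ValueError("relative deviation undefined for zero experimental mean")
    return (sim_mean - exp_mean) / exp_mean


def rank_patterns(
    experimental: pd.DataFrame,
    simulated: Mapping[str, pd.DataFrame],
    cell_class: str = "",
    n_tests: int | None = None,
) -> list[ComparisonResult]:
    """Compare simulated patterns with the experimental cohort, one cell class.

    ``experimental``: rows = specimens, columns = neighbour categories
    (per-specimen percentages). ``simulated``: pattern name → rows =
    replicates, same columns. The Bonferroni family defaults to
    (categories × patterns). The pattern with the smallest mean absolute
    relative deviation wins; exact ties go to the alphabetically first
    rule name and are flagged.
    """
    if experimental.shape[0] < 2:
        raise ValueError("need >= 2 experimental specimens")
    categories = list(experimental.columns)
    for name, df in simulated.items():
        if list(df.columns) != categories:
            raise ValueError(
                f"pattern {name!r}: neighbour categories {list(df.columns)} "
                f"do not match experimental {categories}"
            )
        if df.shape[0] < 2:
            raise ValueError(f"pattern {name!r}: need >= 2 replicates")
    if n_tests is None:
        n_tests = len(categories) * len(simulated)

    results = []
    for name in sorted(simulated):
        sim = simulated[name]
        pvals, effects = {}, {}
        for cat in categories:
            pvals[cat] = wmw_bonferroni(experimental[cat], sim[cat], n_tests=n_tests)
            effects[cat] = relative_deviation(sim[cat].mean(), experimental[cat].mean())
        results.append(
            ComparisonResult(
                cell_class=cell_class,
                pattern=name,
                p_adjusted=pvals,
                effect_sizes=effects,
                mean_abs_deviation=float(np.mean([abs(v) for v in effects.values()])),
            )
        )
    best_dev = min(r.mean_abs_deviation for r in results)
    winners = [r for r in results if r.mean_abs_deviation == best_dev]
    winners[0].best = True  # sorted by rule name already
    if len(winners) > 1:
        for r in winners:
            r.tied = True
    return results


def _composition_deviation(
    sim: pd.DataFrame, exp: pd.DataFrame, signed: bool = False
) -> float:
    """Mean (absolute) relative deviation between two tidy cohort tables."""
    merged = sim.merge(exp, on=["focal", "neighbor"], suffixes=("_sim", "_exp"))
    merged = merged[merged["mean_pct_exp"] != 0]
    if merged.empty:
        raise ValueError("no comparable (focal, neighbor) categories")
    dev = (merged["mean_pct_sim"] - merged["mean_pct_exp"]) / merged["mean_pct_exp"]
    return float(dev.mean() if signed else dev.abs().mean())


def scan_clustering_probability(
    positions_sets: Sequence[np.ndarray],
    experimental: pd.DataFrame,
    grid: Sequence[float] = DEFAULT_P_GRID,
    seed: int = 0,
    cutoff: float = 30.0,
    signed: bool = False,
    graphs: Sequence | None = None,
) -> PScanResult:
    """Scan the local-clustering copy probability against experimental data.

    For each p in the grid, a local-clustering pattern is simulated on
    every position set, the binary-class cohort composition is computed on
    the corresponding cell graphs, and the mean absolute relative
    deviation from the tidy ``experimental`` composition (columns focal,
    neighbor, mean_pct) is scored; best_p minimises it. Pass precomputed
    ``graphs`` to skip re-triangulating the same positions.
    """
    grid = [float(p) for p in grid]
    if not grid:
        raise ValueError("empty probability grid")
    if any(not 0.0 < p < 1.0 for p in grid):
        raise ValueError("grid probabilities must lie strictly inside (0, 1)")
    if not positions_sets:
        raise ValueError("need at least one position set")
    if graphs is None:
        graphs = [build_cell_graph(pos, cutoff=cutoff) for pos in positions_sets]

    # common random numbers: every p reuses the same per-specimen seeds, so
    # grid points share their chain starts and coin draws and the deviation
    # differences across p reflect the copy probability, not sampling noise
    child_seeds = np.random.SeedSequence(seed).generate_state(len(graphs))
    deviations = []
    for p in grid:
        comps = []
        for g, s in zip(graphs, child_seeds):
            pat = simulate_local_clustering(g.positions, p, int(s % (2**31)))
            comps.append(
                specimen_composition(g, pat.labels(), classes=BINARY_CLASSES)
            )
        cohort = cohort_composition(comps, classes=BINARY_CLASSES)
        deviations.append(_composition_deviation(cohort, experimental, signed=signed))
    best = int(np.argmin(deviations))
    return PScanResult(
        grid=tuple(grid), deviations=tuple(deviations), best_p=grid[best]
    )
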