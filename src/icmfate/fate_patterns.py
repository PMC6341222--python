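"""Rule-based null patterns for binary cell fates on fixed positions.

Four generative rules formalise candidate spatial arrangements of a
positive/negative fate on measured nucleus positions:

random
    Observed expression levels are randomly permuted over the cells and
    thresholded — the classic "salt-and-pepper" null. The positive-cell
    count is conserved exactly.
period_two
    Positive cells have only negative neighbours on the cell graph
    (lateral-inhibition-like). Exact two-colourings do not exist on
    general Delaunay graphs, so the pattern is realised as a seeded
    maximal independent set built by random sequential adsorption.
nearest_neighbor
    A chain: a random start cell is negative; the nearest unassigned cell
    to the most recently assigned cell gets the opposite state; repeat.
local_clustering
    The same chain, but the start state is a fair coin flip and each next
    cell copies the previous state with probability p (flips with 1−p).
    p → 1 yields large same-fate patches, p → 0 recovers alternation.

Determinism: every simulator draws from ``numpy.random.default_rng(seed)``
in a documented order — chain rules draw the start index first, then (for
local clustering) one uniform for the start coin and one uniform per chain
step; period-two draws a single permutation. Distance ties are broken by
the lowest cell index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from icmfate.cell_graph import CellGraph

RULES = ("random", "period_two", "nearest_neighbor", "local_clustering")


@dataclass
class BinaryPattern:
    """Positive/negative state per cell produced by one rule."""

    states: np.ndarray  # bool, True = positive
    rule: str
    seed: int
    p: float | None = None  # local_clustering only

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=bool)
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def n_positive(self) -> int:
        return int(self.states.sum())

    def labels(self) -> list[str]:
        return ["positive" if s else "negative" for s in self.states]


def simulate_random(levels: np.ndarray, threshold: float, seed: int) -> BinaryPattern:
    """Permute observed expression levels over cells, then threshold.

    A level >= threshold is positive, so the number of positives equals
    the count in the input levels for every permutation.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise ValueError("empty level vector")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    rng = np.random.default_rng(seed)
    permuted = rng.permutation(levels)
    return BinaryPattern(states=permuted >= threshold, rule="random", seed=int(seed))


def simulate_period_two(graph: CellGraph, seed: int) -> BinaryPattern:
    """Maximal independent set by seeded random sequential adsorption.

    Cells are visited in a random order; a cell turns positive unless a
    neighbour already is. The result has zero positive–positive edges and
    is maximal: every negative cell has a positive neighbour.
    """
    rng = np.random.default_rng(seed)
    n = len(graph)
    states = np.zeros(n, dtype=bool)
    blocked = np.zeros(n, dtype=bool)
    for i in rng.permutation(n):
        if not blocked[i]:
            states[i] = True
            blocked[i] = True
            for j in graph.neighbor_indices(int(i)):
                blocked[j] = True
    return BinaryPattern(states=states, rule="period_two", seed=int(seed))


def _chain(
    positions: np.ndarray, seed: int, rule: str, p: float | None
) -> np.ndarray:
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2:
        raise ValueError("positions must be 2D")
    n = len(positions)
    if n < 1:
        raise ValueError("need at least one position")
    if len(np.unique(positions, axis=0)) != n:
        raise ValueError("duplicate positions")
    rng = np.random.default_rng(seed)
    start = int(rng.integers(n))
    states = np.zeros(n, dtype=bool)
    assigned = np.zeros(n, dtype=bool)

    if rule == "nearest_neighbor":
        states[start] = False
    else:
        states[start] = rng.random() < 0.5
    assigned[start] = True

    current = start
    for _ in range(n - 1):
        d = np.linalg.norm(positions - positions[current], axis=1)
        d[assigned] = np.inf
        nxt = int(np.argmin(d))  # argmin takes the lowest index on ties
        if rule == "nearest_neighbor":
            states[nxt] = not states[current]
        else:
            states[nxt] = states[current] if rng.random() < p else not states[current]
        assigned[nxt] = True
        current = nxt
    return states


def simulate_nearest_neighbor(positions: np.ndarray, seed: int) -> BinaryPattern:
    """Alternating chain: each next-nearest unassigned cell flips state.

    The start cell (uniform random) is negative. "Nearest neighbour" means
    the nearest not-yet-assigned cell to the most recently assigned one,
    so the chain never gets stuck.
    """
    states = _chain(positions, seed, "nearest_neighbor", None)
    return BinaryPattern(states=states, rule="nearest_neighbor", seed=int(seed))


def simulate_local_clustering(positions: np.ndarray, p: float, seed: int) -> BinaryPattern:
    """Copying chain: each next cell keeps the previous state w.p. ``p``.

    The start cell's state is a fair coin flip. p = 0 is the alternating
    chain (up to the start coin); p = 1 paints every cell the start state.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    states = _chain(positions, seed, "local_clustering", float(p))
    return BinaryPattern(states=states, rule="local_clustering", seed=int(seed), p=float(p))


def compose_populations(nanog: BinaryPattern, gata6: BinaryPattern) -> list[str]:
    """Combine per-channel binary patterns into four-population labels.

    (N+,G+)→DP, (N+,G−)→EPI, (N−,G+)→PRE, (N−,G−)→DN.
    """
    if len(nanog) != len(gata6):
        raise ValueError("patterns cover different cell sets")
    out = []
    for npos, gpos in zip(nanog.states, gata6.states):
        if npos and gpos:
            out.append("DP")
        elif npos:
            out.append("EPI")
        elif gpos:
            out.append("PRE")
        else:
            out.append("DN")
    return out


def same_state_neighbor_fraction(graph: CellGraph, pattern: BinaryPattern) -> float:
    """Mean fraction of same-state neighbours among positive cells.

    The clustering summary used to compare patterns: for each positive
    cell with at least one neighbour, the fraction of its neighbours that
    are also positive, averaged over those cells. NaN if no positive cell
    has neighbours.
    """
    states = pattern.states
    fracs = []
    for i in range(len(graph)):
        if not states[i]:
            continue
        nbrs = list(graph.neighbor_indices(i))
        if not nbrs:
            continue
        fracs.append(np.mean(states[nbrs]))
    return float(np.mean(fracs)) if fracs else float("nan")
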