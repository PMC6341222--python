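"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected result from first principles (full
enumeration, the defining geometric predicate, or a literal transcription
of a rule), deliberately sharing no code path with the implementation it
checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def brute_force_delaunay_edges(points: np.ndarray, rel_tol: float = 1e-9) -> set[tuple[int, int]]:
    """Delaunay edges by the empty-circumsphere test over all point 4-tuples.

    A tetrahedron belongs to the Delaunay triangulation iff its
    circumsphere contains no other point (general position assumed); its
    six edges are Delaunay edges. Vectorised in chunks over the
    C(n, 4) candidate tetrahedra.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    quads = np.array(list(combinations(range(n), 4)))
    sq = (points**2).sum(axis=1)
    edges: set[tuple[int, int]] = set()
    chunk = 20000
    for lo in range(0, len(quads), chunk):
        q = quads[lo : lo + chunk]
        a = points[q]  # (m, 4, 3)
        A = 2.0 * (a[:, 1:] - a[:, :1])  # (m, 3, 3)
        b = sq[q[:, 1:]] - sq[q[:, :1]]  # (m, 3)
        det = np.linalg.det(A)
        ok = np.abs(det) > 1e-12
        centers = np.full((len(q), 3), np.nan)
        centers[ok] = np.linalg.solve(A[ok], b[ok][:, :, None])[:, :, 0]
        radii = np.linalg.norm(a[:, 0] - centers, axis=1)
        # distance of every point to every circumcenter
        d = np.linalg.norm(points[None, :, :] - centers[:, None, :], axis=2)  # (m, n)
        inside = d < radii[:, None] * (1.0 - rel_tol)
        # the four defining points do not count
        rows = np.arange(len(q))[:, None]
        inside[rows, q] = False
        empty = ok & ~inside.any(axis=1)
        for quad in q[empty]:
            for i, j in combinations(quad.tolist(), 2):
                edges.add((min(i, j), max(i, j)))
    return edges


def wmw_exact_two_sided_p(sample_a, sample_b) -> float:
    """Two-sided rank-sum p by full enumeration of all rank arrangements.

    Assumes no ties. Counts arrangements whose U statistic deviates from
    its null mean mn/2 at least as much as the observed one.
    """
    a = list(sample_a)
    b = list(sample_b)
    n, m = len(a), len(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == n + m, "oracle requires tie-free samples"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in a) - n * (n + 1) / 2
    center = n * m / 2
    dev = abs(u_obs - center)
    total = 0
    hits = 0
    for combo in combinations(range(1, n + m + 1), n):
        u = sum(combo) - n * (n + 1) / 2
        total += 1
        if abs(u - center) >= dev - 1e-12:
            hits += 1
    return hits / total


def _partitions_into_3(items):
    """All partitions of ``items`` into exactly 3 non-empty blocks."""
    items = list(items)

    def rec(rest, blocks):
        if not rest:
            if len(blocks) == 3:
                yield [list(b) for b in blocks]
            return
        x = rest[0]
        for b in blocks:
            b.append(x)
            yield from rec(rest[1:], blocks)
            b.pop()
        if len(blocks) < 3:
            blocks.append([x])
            yield from rec(rest[1:], blocks)
            blocks.pop()

    yield from rec(items, [])


def best_3_partition(points: np.ndarray) -> tuple[frozenset, float]:
    """Exhaustive minimiser of the within-cluster sum of squares over 3-partitions.

    Returns the optimal partition as a frozenset of frozensets of indices
    and its WCSS.
    """
    points = np.asarray(points, dtype=float)
    best = None
    best_cost = math.inf
    for blocks in _partitions_into_3(range(len(points))):
        cost = 0.0
        for b in blocks:
            p = points[b]
            cost += ((p - p.mean(axis=0)) ** 2).sum()
        if cost < best_cost - 1e-12:
            best_cost = cost
            best = frozenset(frozenset(b) for b in blocks)
    return best, best_cost


def chain_states_reference(positions, seed, rule, p=None):
    """Literal re-implementation of the chain rules (pure python loops).

    Replays the documented RNG protocol: draw the start index, then (for
    local clustering) one uniform for the start coin and one uniform per
    step. Nearest unassigned cell by Euclidean distance, ties to the
    lowest index.
    """
    positions = [tuple(map(float, q)) for q in positions]
    n = len(positions)
    rng = np.random.default_rng(seed)
    start = int(rng.integers(n))
    if rule == "nearest_neighbor":
        state = False
    else:
        state = bool(rng.random() < 0.5)
    states = {start: state}
    current = start
    while len(states) < n:
        best_j, best_d = None, math.inf
        cx, cy, cz = positions[current]
        for j in range(n):
            if j in states:
                continue
            x, y, z = positions[j]
            d = math.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2)
            if d < best_d:
                best_d, best_j = d, j
        prev = states[current]
        if rule == "nearest_neighbor":
            states[best_j] = not prev
        else:
            states[best_j] = prev if rng.random() < p else not prev
        current = best_j
    return np.array([states[i] for i in range(n)])


def all_maximal_independent_sets(n_vertices: int, edges) -> set[frozenset]:
    """Every maximal independent set of a small graph, by subset enumeration."""
    adj = {i: set() for i in range(n_vertices)}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    out = set()
    for mask in range(1 << n_vertices):
        sel = [i for i in range(n_vertices) if mask >> i & 1]
        s = set(sel)
        if any(adj[i] & s for i in sel):
            continue  # not independent
        if any(not (adj[v] & s) for v in range(n_vertices) if v not in s):
            continue  # not maximal: some outside vertex is unblocked
        out.add(frozenset(sel))
    return out
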