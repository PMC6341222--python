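# Methods

## Cell graph

Cell contacts are approximated by the Delaunay triangulation of nucleus
centroids, keeping an edge only when its Euclidean length is *strictly*
less than a cutoff (default 30 µm — roughly two nuclear radii plus
cytoplasm in mouse ICM tissue). An edge of length exactly 30 µm is
excluded; with floating-point centroid data ties are measure-zero, but
the convention is fixed so results are reproducible. Degenerate inputs
are handled explicitly because a 3D triangulation is undefined there:
fewer than three non-collinear points connect all pairs within the
cutoff, collinear sets connect consecutive points along the line, and
coplanar sets (numerical rank 2 of the centred coordinates, tolerance
1e−9 relative to the largest singular value) are triangulated in their
best-fit plane. Duplicate centroids are an error rather than being
merged: they indicate an upstream segmentation fault and would create
zero-length edges. Robustness of the triangulation itself is delegated
to Qhull via `scipy.spatial.Delaunay`; the test suite checks the result
against a brute-force empty-circumsphere enumeration over all point
4-tuples with a 1e−9 relative tolerance on the in-sphere test.

## Fate classification

Intensities are transformed as ln(x + 1); the +1 guards zero
backgrounds and is negligible at typical staining intensities (tens to
hundreds of arbitrary units). k-means with k = 3 (10 restarts, seeded)
is fitted to the pooled cohort of a condition — pooling stabilises the
cluster geometry for small specimens; per-specimen fitting is possible
by calling the classifier per table. Clusters are named semantically so
the result cannot depend on k-means' arbitrary ordering: DN is the
centre with the smallest coordinate sum, EPI the largest log-NANOG
centre, PRE the largest log-GATA6 centre. If one cluster is maximal in
both channels the populations are not separable under this scheme and
the classifier raises instead of guessing; in practice this happens
when co-expressing (DP) cells dominate and form their own extremal
cluster, so classification is intended for cohorts where DP is not the
largest population.

DP cells do not get their own cluster. A provisional cut per channel is
placed at the midpoint between the DN centre and the respective positive
cluster centre (log scale); cells at or above both cuts are DP, all
other cells keep their cluster's label. The *reported* positivity
thresholds are then the channel-wise minimum intensities over the DP
cells (falling back to the provisional cuts mapped to the original
scale when no DP cell exists), which makes the threshold an observable
property of the classified data rather than an internal parameter.

Staging uses only the DP share of the ICM: more than 55 % DP → early
blastocyst; no DP cell at all → late; otherwise mid. The 0-DP check is
applied first, and exactly 55 % falls to mid because the early rule is
strict.

## Neighbourhood composition

Within a specimen, the composition of a focal class pools neighbour
slots: each (focal cell, neighbour) pair contributes one slot, and the
percentage of slots per neighbour class is reported. This weights cells
by their number of contacts, i.e. it is a percentage of the total of
neighbouring cells; an alternative per-cell averaging (each cell's
neighbour-fraction vector counted once) is available via
`per_cell=True` for sensitivity checks. Isolated cells are flagged and
excluded. Across specimens, the mean and SEM are taken with the
specimen as the independent unit; specimens lacking a focal class are
omitted from that row's n, while neighbour classes absent from a
specimen count as 0 %.

## Null patterns

All four simulators are bit-reproducible given (positions, parameters,
seed) and draw from `numpy.random.default_rng(seed)` in a documented
order (start index, optional start coin, one uniform per chain step) so
that an independent re-implementation can replay them.

- **random**: the observed expression levels are permuted uniformly over
  the cells and thresholded (≥ threshold → positive), conserving the
  positive count exactly — the permutation null behind the
  salt-and-pepper hypothesis.
- **period two**: "positive cells have only negative neighbours" cannot
  in general be realised as a proper 2-colouring, because Delaunay
  contact graphs contain triangles; the weakest pattern satisfying the
  defining property together with maximality (no cell could still be
  turned positive) is a maximal independent set, generated by random
  sequential adsorption in a seeded random vertex order.
- **nearest neighbour**: a chain starting at a random cell (negative);
  the nearest *unassigned* cell to the most recently assigned cell takes
  the opposite state, iterated until all cells are assigned. Taking the
  nearest unassigned cell (rather than the overall nearest, which may
  already be assigned) means the chain never traps. Distance ties break
  to the lowest cell index.
- **local clustering**: the same chain, with a fair-coin start state and
  each next cell copying the previous state with probability p. p = 0
  recovers the alternating chain; p = 1 paints the whole specimen one
  state.

Two binary patterns (one per channel) compose into four-population
labels by the obvious mapping ((N+,G+) → DP, etc.).

## Statistical comparison

Per neighbour category, experimental per-specimen percentages are
compared to simulated per-replicate percentages with the two-sided
Wilcoxon–Mann–Whitney test; the exact null distribution is used when
the smaller sample has ≤ 8 observations and the pooled sample is
tie-free, otherwise the normal approximation with continuity and tie
corrections. p-values are Bonferroni-multiplied over the family
(categories × patterns by default) and capped at 1. Welch-type
confidence intervals for mean differences use the same correction
(level 1 − α/m). The effect size is the signed relative deviation
(s̄ − d̄)/d̄ of the simulated from the experimental mean, undefined at
d̄ = 0; patterns are ranked by the mean *absolute* relative deviation
across categories (a signed-mean variant exists for sensitivity), with
exact ties broken alphabetically by rule name and flagged.

The copy probability p is selected by scanning a grid (0.1–0.9 in steps
of 0.1 by default): for each p, one local-clustering pattern per
position set is simulated, the binary cohort composition computed, and
the mean absolute relative deviation from the experimental composition
scored; the best p minimises it. The scan uses common random numbers —
every grid point reuses the same per-specimen chain seeds — so that
differences between grid points reflect the copy probability rather
than sampling noise; this sharpens the argmin considerably at interior
p, where adjacent grid points differ by only a few percent of
composition.

## Synthetic data

The generator produces what the analysis consumes, with known ground
truth. Positions are drawn by hard-core dart throwing: uniform in a
ball, rejecting candidates closer than a minimum separation (default
8 µm, about one nuclear diameter), with a feasibility pre-check that the
implied packing fraction stays ≤ 0.4 (random sequential packing jams
near 0.38, so presets stay well below). Preset geometries — organoid
24 h: 450 cells in a 50 µm ball; 48 h: 1050 cells in 66 µm; embryo:
20–45 ICM cells in an 18 µm ball plus a TE shell one separation outside
— are chosen so the aggregate is confluent: the 30 µm cutoff retains
over 95 % of Delaunay edges and interior cells have ~10–14 neighbours.

Fates are placed either i.i.d. from fixed proportions (the spatially
random baseline) or by one of the null-pattern rules per channel.
Intensities are drawn from population-conditional log-normals; the
default model separates negative (ln 50) and positive (ln 400)
components by 12 component SDs (σ = 0.25) so that classification tests
measure the algorithm, not the noise; a "hard" variant with 2-SD
separation (σ = 1.04) exists for robustness work. The
`classification_preset` mixture keeps DP at 10 % — below DN — because
the three-cluster scheme is only well-posed when co-expressing cells do
not dominate (see above). Ground-truth labels ride along on a separate
attribute and never enter the analysis path.

What the generator does *not* emulate: real nuclei are ellipsoidal and
vary in size, intensity distributions have heavier tails and spatial
intensity gradients (depth attenuation), segmentation errors produce
missing and merged nuclei, and embryo ICMs are not spherical. Passing
tests therefore demonstrate correctness of the computations under the
stated geometric and distributional assumptions, not robustness to
microscopy artefacts.

## Problem sizes and seeds

Test and acceptance runs use cohorts of 30 specimens × 500 cells for
parameter-recovery checks (the scale at which the scan separates
adjacent grid points cleanly), 20 random 60-point sets for the
brute-force Delaunay comparison, and 100 patterns over five 450-cell
aggregates for the period-two invariant. All randomness flows through
explicit integer seeds or `numpy.random.SeedSequence` spawning;
pipeline reruns with identical config and inputs are byte-identical.

## Known limitations

- The DP carve-out (midpoint cuts between DN and the positive centres)
  is one defensible reading of "determining DP cells from the three
  clusters"; thresholds-first alternatives would shift DP counts near
  the cuts. The reported thresholds (minima over DP) are exact given
  the rule.
- The period-two construction is an independent-set surrogate; graphs
  admitting a true 2-colouring would also accept stricter patterns.
- With label-only input (no intensities), the random pattern permutes
  binary states directly — the same null, but intensity thresholds are
  then unavailable.
- Specimens are treated as exchangeable independent units; no
  batch/litter structure is modelled.
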