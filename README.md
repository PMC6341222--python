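# icmfate

Quantitative 3D spatial analysis of NANOG/GATA6 cell-fate patterning in
inner-cell-mass (ICM) organoids and mouse blastocysts.

During preimplantation development, ICM cells commit to either the
epiblast (Epi, NANOG+) or the primitive endoderm (PrE, GATA6+) fate. The
resulting mosaic is traditionally described as a "salt-and-pepper"
pattern — implying random intermingling of the two fates — while
lateral-inhibition signalling models predict the opposite extreme, an
alternating ("period-two") arrangement. Deciding between these
hypotheses requires quantitative analysis of the full 3D neighbourhood
structure, which this package provides for anyone working with segmented
nucleus tables from organoids or embryos:

- **Cell graphs** — Delaunay triangulation of nucleus centroids with
  edges kept only when strictly shorter than 30 µm, approximating
  physical cell contacts.
- **Fate classification** — k-means with k = 3 on
  (ln NANOG, ln GATA6) finds the DN (double-negative), N+/G− (Epi
  precursor) and N−/G+ (PrE precursor) clusters; double-positive (DP)
  cells are carved out above per-channel cuts, and positivity thresholds
  are reported as the channel-wise minima over DP cells. Specimens are
  staged by DP share (>55 % → early, 0 → late, else mid blastocyst).
- **Neighbourhood composition** — for each focal population, the
  percentage breakdown of its neighbours' populations, pooled over
  neighbour slots within a specimen and averaged (± SEM) across
  specimens.
- **Rule-based null patterns** on the measured positions: *random*
  (permuted expression levels), *period two* (positive cells have only
  negative neighbours; realised as a seeded maximal independent set),
  *nearest neighbour* (alternating chain through nearest unassigned
  cells) and *local clustering* (the same chain copying the previous
  state with probability p). Two binary patterns compose into
  four-population labels.
- **Model comparison** — Wilcoxon–Mann–Whitney tests and Welch
  confidence intervals with Bonferroni correction; the effect size is the
  relative deviation (s̄ − d̄)/d̄ of the simulated from the experimental
  mean; patterns are ranked by mean absolute relative deviation, and the
  clustering probability p is chosen by a grid scan (0.1–0.9, step 0.1).
- **Synthetic data** — hard-core packed nucleus positions in a ball
  (plus an optional trophectoderm shell), pattern- or proportion-driven
  fates, and population-conditional log-normal intensities, so every
  stage is testable without microscopy data.

## Worked example

`examples/05_null_patterns_and_pscan.py` generates 15 synthetic
specimens of 400 cells whose binary fates follow the local-clustering
chain at p = 0.9, then asks which null pattern explains them:

```
  local_clustering: mean |relative deviation| = 0.036  <-- best fit
  nearest_neighbor: mean |relative deviation| = 0.289
        period_two: mean |relative deviation| = 1.244
p-scan best copy probability: 0.9
```

The generating rule wins by an order of magnitude, and the scan recovers
the copy probability that produced the data. The remaining examples
(`examples/01`–`04`) walk through cohort generation, graph construction
(450-cell organoid: 3040 contacts, mean 13.5 neighbours per cell),
classification (100 % agreement with generator ground truth;
thresholds NANOG 191.8, GATA6 234.9 a.u.) and neighbourhood composition
(i.i.d. fates reproduce the global mix in every focal row — the
salt-and-pepper baseline).

The full pipeline runs from a shell:

```sh
icmfate synth --preset embryo --n-specimens 6 --seed 7 --out cohort.csv
icmfate run --config config.yaml       # labels, staging, compositions,
                                       # pattern comparison, p-scan
```

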