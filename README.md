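# crispr3d

Chromatin 3D density features from Hi-C contact maps, and their association
with CRISPR cleavage efficiency.

CRISPR efficiency models lean almost entirely on local sequence and
thermodynamic properties of the 20-nt target site. This package implements
an orthogonal, cell-state-dependent axis: the *spatial density* of the
chromatin around the cut site, estimated from Hi-C contact maps. It is
aimed at people building or auditing sgRNA efficiency models who want to
test whether 3D genome structure carries signal their feature set lacks.

## The method

Each chromosome is binned at 10 kb and its normalized Hi-C interaction
frequencies IF(i, j) define a weighted graph with edge weights

&nbsp;&nbsp;&nbsp;&nbsp;*d*(i, j) = 1 / IF(i, j),

so frequently touching bins are modelled as spatially close. The distance
between two bins is the mean length of the *p* = 5 shortest simple paths
with at most 2 edges between them — averaging a handful of short, feasible
routes smooths single-contact noise, and at most *p* × 2 = 10 interaction
frequencies ever enter one estimate. From the pairwise distances two
per-bin density feature families are derived:

* **Distance (n)** — mean of the *n* smallest distances from the bin
  (*n* ∈ {1000, 2500, 5000, 10000}); *inversely* proportional to density.
* **Radius (m)** — number of bins within the radius given by the *m*-th
  percentile of the chromosome-wide sorted distance vector
  (*m* ∈ {10, 15, 20, 25, 30}); proportional to density.

These nine 3D features are joined (one at a time) to the 425 classic
predictors — 80 positional nucleotide indicators, 320 positional
dinucleotide indicators, 4 + 16 composition frequencies, four
nearest-neighbor melting temperatures (protospacer regions 1–20, 1–4,
5–12, 16–20) and the sgRNA minimum free energy — and evaluated by:

* Pearson/Spearman correlation and **partial correlation** (residual
  projection on controls) with measured efficiency;
* a top-vs-bottom 20% efficiency **quintile contrast** (Wilcoxon
  rank-sum) giving the direction of the density–efficiency link;
* **paired repeated cross-validation** (5-fold × 200 repeats): a lasso or
  gradient-boosted-tree model is trained twice per fold on identical
  splits, with and without the single 3D column, and the paired test
  correlations are compared by Wilcoxon's signed-rank test, alongside
  RMSE, lasso selection counts and permutation/gain importance ranks.

Because matched deep Hi-C and in-vivo CRISPR datasets are large and
external, the package ships a first-class synthetic generator: power-law
contact decay with TAD-like enriched blocks, coverage noise and dropout,
plus target sites whose efficiency carries a planted logistic dependence
on local 3D density (and GC content). Every statistic above can be
validated against the known ground truth it plants.

## Worked example

```python
import crispr3d as c3

hic = c3.SyntheticHiCParams(n_bins=120, tad_boundaries=(40, 80),
                            tad_enrichment=2.0, coverage_noise_sd=0.2, seed=7)
crispr = c3.SyntheticCrisprParams(n_sites=250, density_effect=-1.0, seed=8)
contacts, dists, table, sites = c3.simulate_dataset(hic, crispr)

fm = c3.assemble(sites, table, include_3d=table.feature_names[0])
model = c3.DensityEfficiencyModel(fm, table.feature_names[0])
res = model.fit(c3.CVConfig(k=5, repeats=20, seed=9, feature_screen=30))
print(res.summary())
```

```
               Density-efficiency association
============================================================
Sites                                                    250
Density feature                                Distance (10)
Pearson r (p)                             0.8560 (5.08e-73)
Spearman rho (p)                          0.8506 (3.42e-71)
Partial r | GC                                        0.9488
Top vs bottom 20% efficiency: feature higher in top (rank-sum p = 6.86e-18)
------------------------------------------------------------
CV protocol                       20x5-fold,      lasso
Paired evaluations                                       100
Mean test r with / without 3D           0.9511 /    0.2525
Mean RMSE with / without 3D             0.0707 /    0.2282
Relative r2 change                                  1023.0%
Signed-rank p (r with vs without)                   3.90e-18
============================================================
```

Reading the table: the planted Distance-type feature (an inverse-density
measure) correlates *positively* with efficiency — synthetic sites in
sparse neighborhoods edit better, which is the planted direction — and the
correlation survives controlling for GC. The quintile contrast confirms
high-efficiency sites sit at larger 3D distances. Adding the single 3D
column to a lasso trained on the top-30 classic features raises the mean
held-out correlation from 0.25 to 0.95 (the synthetic density effect is
deliberately strong); the signed-rank p-value certifies the paired
improvement. On real data the effect sizes are far smaller; the synthetic
run validates machinery and sign conventions, not magnitudes.

The same pipeline runs from the shell:

```sh
crispr3d run-all --out-dir run --seed 7          # simulate ... evaluate
crispr3d simulate --n-bins 200 --tads 60,120 --seed 1 --out-dir run2
crispr3d validate run/contacts.tsv --format contacts
```

Each stage exchanges plain TSV artifacts (`contacts.tsv`,
`distances.tsv`, `bin_features.tsv`, `features.tsv`, `cv_report.tsv`) and
the run writes a `manifest.json` with checksums and seeds; re-running the
same config reproduces identical checksums.

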