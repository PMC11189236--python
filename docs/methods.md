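# Methods

This note documents the models and procedures implemented in `crispr3d`,
the defaults they ship with, and the choices made where more than one
reasonable design existed.

## From contact maps to distances

A chromosome's Hi-C matrix at resolution *R* (default 10 kb) is held as an
upper-triangular triplet list of normalized interaction frequencies
IF(i, j) between 1-based bins; file coordinates are 0-based bin starts.
Diagonal entries are dropped on construction: self-contacts carry no
between-bin geometry and the distance graph must have no self-loops.
Duplicate records (e.g. a dump containing both triangles) are summed, not
rejected.

The graph model sets edge weight *d* = 1/IF for every observed contact.
A pair with IF = 0 gets **no edge** rather than an infinite one: an
unobserved contact is missing evidence, not evidence of infinite
separation. The distance between bins i and j is the mean length of the
*p* shortest simple paths with at most `max_edges` edges (defaults *p* = 5,
`max_edges` = 2, i.e. the direct edge plus two-hop routes through a shared
neighbor). When fewer than *p* admissible paths exist the available ones
are averaged — this keeps the estimator defined on sparse maps — and a pair
with no admissible path is *missing*, excluded from every downstream
statistic rather than imputed. The direct edge counts as a (1-edge) path.
Ties among equal-length paths do not affect the mean.

The all-pairs sweep is a per-bin vectorized neighbor intersection
(`W[a,:][:,None] + W` per anchor bin, partial sort per column), not a
generic all-pairs shortest-path, so a ~2,000-bin chromosome completes in
minutes on one CPU. For non-default `max_edges` it falls back to bounded
depth-first enumeration per pair.

Properties that follow from the construction, and that the test suite
verifies against an independent path-enumeration oracle: symmetry; the
estimate is bracketed by the shortest and the *p*-th shortest admissible
path; strengthening any contact (raising IF) never increases any pair's
distance; and at most *p* × `max_edges` = 10 interaction frequencies
contribute to a single estimate.

## Balancing and rebinning

Inputs are typically already balanced (KR/VC) upstream, so balancing is
optional. `vc` divides each entry by the product of its two bin marginal
sums and rescales to the original total mass; `ice` runs iterative
proportional fitting until the non-zero bin sums change by < 1e-5
relatively (cap 200 rounds). Both preserve the zero pattern. The full
Knight–Ruiz algorithm is not implemented; ICE reaches the same balanced
target for these inputs.

Rebinning to a coarser resolution assigns each fine bin to the coarse bin
containing its start coordinate — deterministic and well-defined also for
non-multiple targets (25 kb from 10 kb) — then sums constituent pairs and
drops mass that lands on the coarse diagonal.

## Density features

For bin B: **Distance (n)** is the mean of the n smallest computed
distances from B; if B has only k < n computed distances the k available
are averaged; an isolated bin gets the sentinel 0 plus a `missing` flag,
and flagged bins are dropped from correlations and from site joins —
a 0 there is a placeholder, never a measurement. **Radius (m)** counts
bins within distance r of B, where r is the element at 1-based position
ceil(N·m/100) (clamped to [1, N]) of the ascending vector of all N
computed unordered-pair distances; the comparison is inclusive (ties at
exactly r count). N counts unordered pairs with a finite distance only:
missing pairs have no rank. Ceil was chosen to make the percentile index
deterministic for non-integer N·m/100.

Sites are mapped to the single bin containing the 0-based cut coordinate
(`floor(pos/R) + 1`); no interpolation across bin boundaries.

## Classic target-site features

Sequences are strand-resolved 20-nt protospacers (positions numbered 1,
PAM-distal, to 20, PAM-proximal) plus at least one PAM-side context base.
The 420 sequence features are: 80 positional nucleotide indicators, 320
positional dinucleotide indicators — position 20's dinucleotide spans the
last protospacer base and the first context base, the minimal consistent
reading of a 20-position dinucleotide scheme — 4 nucleotide and 16
overlapping-dinucleotide frequencies over positions 1–20. Note the
dinucleotide frequencies are *not* invariant under shuffling a sequence
(overlapping pairs depend on order); only the 4 mononucleotide
frequencies are.

Thermodynamics: nearest-neighbor melting temperatures of regions 1–20,
1–4, 5–12 and 16–20 using the unified SantaLucia parameter set at
Biopython's default salt and strand concentrations (50 mM Na⁺, 25 nM each
strand), and the minimum free energy of the guide RNA (RNA copy of
positions 1–20). The default MFE backend is a bundled simplified
Zuker-style dynamic program — Watson–Crick/GU pairs, approximate
Turner-style stacking energies, tabulated hairpin initiation with minimum
loop 3, linear bulge/interior penalties, no multibranch scoring (on
20-mers multiloops are essentially unreachable). It is deterministic and
dependency-free; its absolute energies are coarser than a full Turner
model, which is acceptable because the downstream feature consumes
ordering (structured vs unstructured guides), not calorimetry. An
RNAfold backend is available for full-model folding; tests pin the
bundled backend and cross-check it qualitatively against RNAfold.

Epigenetic features average a bedGraph signal over ±`window` bp around
the cut site (default 500 bp), coverage-weighted with uncovered stretches
contributing zero; the window is a configuration knob because no single
canonical window exists.

## Statistical battery

Partial correlation residualizes both variables on [1, controls] by least
squares and correlates the residuals; the Spearman variant
rank-transforms every vector first. Rank-deficient control matrices and
zero residual variance (a variable exactly explained by its controls) are
reported as degenerate inputs, not silently propagated.

The quintile contrast compares a feature between the top-20% and
bottom-20% efficiency sites by two-sided Wilcoxon rank-sum, reporting the
direction as the sign of the top-minus-bottom mean.

Repeated cross-validation pairs two fits per fold on identical splits:
one without and one with the single 3D column. Lasso features are
z-scored with training-fold statistics (the response is left raw) and the
penalty is chosen by inner 5-fold CV over a 30-point path; the
gradient-boosted-tree model uses fixed hyperparameters (100 trees, depth
4, learning rate 0.1, subsample 0.9) with a per-iteration seed. An
optional screen keeps the top-N classic features by |Pearson r| with
efficiency; by default the screen is recomputed inside each training fold
(no leakage), and `screen_scope="global"` reproduces a single pre-CV
screen. A degenerate (constant) test-fold prediction scores r = 0: it
carries no linear signal. Test RMSE is computed on the raw efficiency
scale. The paired correlations are compared by two-sided Wilcoxon
signed-rank, and the headline effect is reported as
(mean r²_with − mean r²_without) / mean r²_without. Feature importance is
recorded as lasso selection indicators, permutation importance (drop in
held-out r² after shuffling one column once, seeded per iteration), and
tree gain; per-iteration ranks are averaged over the iterations in which
a feature was in play. The whole report is deterministic given the
config: identical configs produce byte-identical frames.

## Synthetic data: what it emulates, what it does not

The contact generator draws IF(i, j) = base · |i−j|^(−α), multiplied by a
TAD enrichment factor when i and j share a block, by per-bin log-normal
coverage factors, and thinned by Bernoulli dropout. Defaults: α = 1
(canonical contact-decay slope at the 10 kb–1 Mb scale), base 10,
enrichment 1 (off unless blocks are configured), coverage sd 0.2 and 200
bins / 300 sites in the pipeline demo — sizes chosen so a full run
completes on one CPU while every statistic retains power. It does not
model restriction fragments, read-level noise, trans contacts, or A/B
compartment structure; conclusions from passing tests are therefore about
the machinery's correctness and sign conventions, not about real-data
effect sizes, which are an order of magnitude smaller.

Site efficiencies follow logistic(β·z(density) + γ·z(GC) + ε) clipped to
[0, 1], with β = −1, γ = 0.5, ε ~ N(0, 0.3) by default. Both the density
feature and GC are standardized so the two coefficients are on one scale.
β multiplies *density*: when the planted feature is a Distance(n) —
an inverse-density measure — its standardized values are negated before β
applies, so β < 0 plants the relation "denser regions edit less
efficiently" regardless of which feature family carries it. The planted
feature defaults to a small-n Distance computed on the generated matrix
through the real contacts → graph → distances → features pipeline, so
recovery tests close the loop through every stage. Sequences are random
20-mers plus an NGG PAM context (23 nt total).

## Known limitations

* Per-chromosome only; no inter-chromosomal distances or 3D coordinate
  reconstruction.
* The bundled MFE model is intentionally simplified (see above).
* TAD calling, compartment eigenvectors and external model scores are out
  of scope; the partial-correlation machinery accepts arbitrary score
  vectors, so external predictions can be controlled for when available.
* Collinear features shield each other under permutation importance (the
  drop splits across copies); this is documented behavior, and selection
  counts plus gain importance are reported alongside to triangulate.
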