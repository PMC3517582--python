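# Methods

`paleoniche` implements a phyloclimatic analysis: climate-envelope
niche models for extant species, ancestral envelope reconstruction on a
dated phylogeny, projection of ancestral envelopes into paleoclimate
grids, and niche-overlap statistics. This note describes the models,
the numerical choices, and what the synthetic tests do and do not show.

## Envelope (Bioclim-style) niche model

A taxon's climate envelope is, per climate variable *v*, the closed
interval [min_v, max_v] of values observed at the cells containing its
occurrence localities. Projected into a scenario with *L* variables,
the suitability of a cell is

    s(cell) = #{v : min_v <= x_v(cell) <= max_v} / L,

so surfaces take values in {0, 1/L, ..., 1}. Classified maps follow
the convention red = all *L* variables suitable, yellow = exactly
*L* − 1, below otherwise. Bounds are closed intervals deliberately: a
narrow endemic known from a single climate cell has a degenerate
min = max envelope that must still match its own training cell.
Species with fewer than 10 occurrence points are modeled anyway (a
warning is logged); for genuinely narrow endemics extra points would
resample the same cells and leave the envelope unchanged, so the
minimal model is preferred over dropping the species.

The simplicity of the envelope model is load-bearing: because each
variable is treated independently, each bound of each variable is a
univariate continuous character that can be reconstructed on a tree.
Algorithms that model interactions among predictors do not decompose
this way.

## Evaluation and variable selection

Models are scored by the ROC AUC: the probability that a random
presence cell scores above a random background cell, ties counted half
(Mann–Whitney convention — necessary because surfaces take at most
L + 1 distinct values). Presences are the distinct valid occurrence
cells; duplicates within a cell collapse. Background cells are drawn
uniformly at random, without replacement, from non-nodata non-presence
cells, with default size min(10·n_presence, 10000) and an explicit
seed. Uniform random background is a documented stand-in: no source
specifies the absence-generation scheme for this design, so printed
AUC values from other implementations are not exactly reproducible.

Variable selection: per variable, a single-variable envelope is fitted
per species and its AUC recorded; the per-variable mean is taken over
species contributing at least `min_unique = 10` *environmentally
unique* points (distinct joint climate-value vectors at cell
resolution — the strictest reproducible reading; a per-variable
reading would count distinct scalars instead, and is intentionally not
used). Then, greedily, the remaining pair with the largest |r| above
the threshold (default 0.8, Pearson, absolute value — a correlation of
−0.95 is as redundant as +0.95) loses its lower-mean-AUC member, until
no pair exceeds the threshold. Equal AUCs keep the first-listed
variable (configurable to a hard error). Greedy highest-|r|-first with
recomputation is deterministic and removes the most redundant variable
first.

Applied to the bundled sixteen-variable reference table, this rule
retains **five** variables: the four flagged as selected in the source
(coolest-month temperature, temperature standard deviation,
warmest-month precipitation, coolest-month precipitation) **plus**
warmest-quarter mean temperature, whose only above-threshold partner
(warmest-month temperature, r = 0.99) has the lower printed AUC (0.90
vs 0.91). The source reports four; unrounded AUC values or an
undocumented extra step could explain the difference. The package
reports what the stated rule yields and flags the discrepancy in the
exclusion log rather than forcing the four-variable set.

## Ancestral reconstruction

Each envelope bound of each variable (8 characters for 4 variables) is
reconstructed independently under Brownian motion by joint maximum
likelihood. The ML states solve the sparse linear system in which each
internal state is the branch-length-inverse-weighted mean of its
neighbors' states; these coincide with the GLS estimates built from
the phylogenetic covariance matrix C (C_ij = shared root-to-tip path
length), and they obey the maximum principle — every reconstructed
state lies within the tip value range. Agreement with an explicit
dense C⁻¹ oracle is tested to 1e-8 relative error.

Rate and likelihood: with Q = (x − â1)ᵀC⁻¹(x − â1) at the GLS root â
(equal to the minimized sum over edges of Δ²/branch), we report
σ̂² = Q/n (marginal ML, n tips) and Q/(n−1) (REML) side by side. Note
that R's `ape::ace` ML routine reports the joint-ML rate Q/(2n−2) over
branch increments; states are identical, only the divisor differs, and
the cross-check test converts explicitly. The log-likelihood uses
log|C| from a dense slogdet (trees here are small; no pruning needed).

Zero-length branches are collapsed by merging nodes (shared state, with
a warning); merged tips with unequal values are an error. Non-ultrametric
trees are accepted with a warning; node ages are then tree height minus
node depth.

Because min and max are reconstructed independently with the *same*
tree and hence the same positive averaging weights, a node's
reconstructed width is the same positive affine combination of tip
widths, so max < min cannot actually occur on a shared tree; a repair
rule (collapse to midpoint + log) exists defensively and is asserted
idle in the tests.

Node ids are assigned tips-first then internals, both in postorder, so
the root has the largest id. Reference ancestral tables use their own
figure-specific numbering; reproducing such labels requires a
user-supplied mapping.

### Known defect in the bundled ancestral reference table

In the bundled ancestral-bounds table the coolest-month precipitation
*minimum* column is row-for-row identical to the warmest-month
precipitation minimum column (38/38 rows), and its values (0.0–0.2 mm/day)
lie below every tip's value for that character (tip range 0.5–6.4).
No branch-weighted averaging of tip values can produce that, so the
column is a printing/transcription defect of the source table. The data
are kept faithful to the printed source; the test asserting the maximum
principle on that table fails on exactly that column and is expected to.

## Projection of ancestral models

Internal nodes with posterior probability above 0.95 (the root is
included when it carries no label) are projected twice: into the
scenario whose age is closest to the node's age (ties resolved toward
the younger scenario), and into present-day climate — the latter holds
the scenario constant so differences between node maps reflect
differences between inferred models only. No resampling is done
between scenarios; projection uses each scenario's native grid, and
paleo grids are treated on modern coordinates.

## Niche overlap and age–range correlation

Surfaces are compared on the common non-nodata mask, normalized to sum
to one after masking, then

    D = 1 − ½ Σ|p_x − p_y|        (Schoener's D)
    I = 1 − ½ Σ(√p_x − √p_y)²     (Hellinger-based I),

both in [0, 1], 1 iff identical, 0 iff disjoint. The age–range
correlation regresses pairwise overlap on MRCA age (OLS; adjusted
r² = 1 − (1−r²)(n−1)/(n−2)). Because pairs sharing a taxon are not
independent, the p-value comes from a permutation null that jointly
relabels the rows and columns of the overlap matrix, with +1 smoothing:
p = (1 + #{|slope*| ≥ |slope|}) / (1 + B). The parametric OLS p is
reported alongside, since either could be meant by a bare "p" in
published analyses.

## Raster and point conventions

ESRI ASCII grids, cell-registered; row 0 is the northernmost row.
Point-in-cell uses half-open intervals, [x, x + cell) in longitude and
(y − cell, y] in latitude going south from the north edge, so edge
points land in exactly one cell. Coordinates are geographic lon/lat
(WGS84 semantics, no reprojection). Cleaning is deterministic: exact
coordinate duplicates are dropped, then points off-grid or on a nodata
cell of any layer (e.g. coastal records in the ocean); the report
counts removals by reason, and cleaning is idempotent.

## Synthetic ground-truth generator

The generator emulates the pipeline's three inputs from one seed
(split via `numpy` SeedSequence):

* **Tree** — pure-birth (Yule) process started from the root split,
  grown to `n_tips`, with every tip extended by the waiting time to
  the next unrealized event (keeps tip ages exchangeable). Internal
  nodes get synthetic support labels in [0.5, 1] emulating posterior
  probabilities; the root gets 1.
* **Envelopes** — per variable, the interval midpoint and log-width
  evolve as independent Brownian motions (variance = rate × branch
  length); min/max are derived as center ∓ width/2, so simulated truth
  is always valid. The inference stage still reconstructs min and max
  independently; this deliberate parameterization mismatch is itself a
  test of the independence assumption.
* **Climate** — layers are unit-variance Gaussian noise smoothed with
  a Gaussian kernel (sd `smoothing_scale` cells) plus a north–south
  gradient, rescaled per variable to span the union of simulated
  envelopes with a 50% margin. The grid is then partitioned into one
  contiguous territory tile per tip and tile cells are redrawn
  uniformly inside that tip's envelope, guaranteeing each species a
  coherent region of fully suitable climate (as real species have).
  Paleo scenarios add an age-scaled smooth anomaly (15% of the
  variable span at the oldest age) to the present field.
* **Occurrences** — drawn uniformly with replacement from cells where
  the tip's true envelope scores 1.0, jittered uniformly within the
  cell.

Default study conditions (chosen once as a realistic mid-sized clade
analysis): 32 tips, birth rate 0.25/Ma (root ages around 12 Ma), four
variables with the temperate-montane root envelope in
`default_root_envelope` (°C and mm/day), center rate 0.05 units²/Ma,
log-width rate 0.005/Ma, 60×60 grids at 0.25°, smoothing 3 cells, 100
occurrences per tip, paleo slices at 3, 8 and 10 Ma.

What the generator does **not** emulate: GCM-like spatial structure,
covariance among climate variables, sampling bias, georeferencing
error, dispersal limitation or biotic interactions. Passing tests
therefore show correctness of the algorithms under the stated
statistical model, not robustness to real-data pathologies.

### End-to-end recovery, honestly measured

With the default conditions, the full pipeline recovers the true root
envelope with per-variable interval-Jaccard ≥ 0.5 in roughly 78–88% of
seeded replicates (seed-set dependent; the acceptance test's fixed set
measures 44/50). The misses are concentrated in the narrowest variable
(warmest-month precipitation, root width 1.4 mm/day): per-lineage
center drift of sd ≈ √(0.05 × 12) ≈ 0.8 over a 12 Ma root age means
clade-wide drift occasionally carries the ML root estimate outside the
Jaccard-0.5 band. This is root-state estimator variance inherent to
Brownian reconstruction at these rates, not an implementation error —
the estimates match the dense GLS oracle to 1e-8 and fitted tip bounds
are nested in the true ones by construction.

## Numerical choices

* AUC via ranks (`scipy.stats.rankdata`), exact for ties; verified
  against exhaustive pair enumeration.
* Pearson correlations via `numpy.corrcoef` on pooled valid occurrence
  values; constant columns get r = 0 with a warning (undefined
  otherwise); fewer than 3 points is an error.
* Grid round-trips are bit-exact: ASCII grids are written with full
  `repr` precision and envelope tables with `%.17g` + round-trip float
  parsing.
* Ultrametricity tolerance: 1e-6 × tree height on root-to-tip spread.
* Surface normalization tolerance 1e-12; all-zero surfaces are an
  error.
* Background sampling, permutation tests and all simulations take
  explicit integer seeds; pipeline artifacts are pure functions of
  (inputs, config, seed) and CSV outputs are byte-reproducible.
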