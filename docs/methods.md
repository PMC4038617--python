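# Methods

This note documents the models, estimators and design choices behind
`ricenest`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Synthetic landscape model

The generator produces, from a seed, every input the analysis chain needs.

**DEM.** Gaussian-filtered white noise (filter SD `smoothness`, default 4
cells), normalised to [0, 1], raised to a hypsometric exponent (default 2)
and rescaled onto `relief_range` (default 370–2400 m). The exponent skews
the elevation distribution towards low values, emulating a floodplain that
rises into mountains; because it is strictly monotone it does not affect
rank-based terrain classification. An infinite smoothness degenerates to a
constant field at the relief midpoint.

**Terrain position.** Each cell's elevation percentile (mid-rank over ties)
within a circular neighbourhood of `radius_cells` (default 8), cut at
0.10/0.35/0.65/0.90 into gully, lower mid-slope, mid-slope, upper mid-slope,
ridge. This is a terrain-position-index style classifier: a rank statistic,
invariant under monotone transforms of the DEM, with gully/ridge rare and
mid-slope common by construction. The defaults give roughly a
5/22/46/22/5 % split on the default DEM. Elevation evidence is binned
left-closed/right-open at 700 and 1400 m (valley, mid-mountain, high); a
cell exactly at a break belongs to the class above.

**Land cover.** Seven classes (winter-flooded rice, winter-dry rice,
rain-fed, open water, forest, shrub/grass, other) drawn independently per
cell from a hand-authored categorical distribution per
(elevation band × terrain position) stratum. The tables are decisive —
flooded rice takes 55 % of low-elevation gullies, forest ~77 % of the high
mid-slopes — because real agricultural mountain landscapes are strongly
terrain-constrained, and this dependence is precisely the signal the
expert-system evidence exploits. Default composition: ~9 % flooded rice,
~11 % dry rice, ~11 % rain-fed, ~2 % open water, ~43 % forest, ~20 %
shrub/grass, ~4 % other.

**Spectra.** Four bands; each cell's value is its class mean plus i.i.d.
Gaussian noise (SD 0.08 in reflectance units). The two rice classes differ
by ≈0.05 across all bands combined, as do forest and shrub/grass — about one
noise SD, so the base classifier confuses exactly the pairs that terrain and
elevation evidence can disambiguate. Winter scenes separating flooded from
dry paddies poorly is the realistic regime the defaults emulate.

**Field plots.** 768 plot centres by stratified random sampling,
proportional to stratum area (largest remainder) with a floor of four plots
per present stratum when the budget allows (two otherwise), labelled with
the truth class at the plot-centre cell (plots are 50 × 50 m on a coarser
grid, so a centre rule is the only unambiguous choice). The train/test split
is stratified: half of each stratum per side, odd leftovers balanced across
strata so the halves are exactly equal (384/384).

**Nests.** A habitat-anchored Thomas cluster process: `n_parents` (8)
cluster centres placed, with probability `association`, uniformly inside a
uniformly chosen habitat cell (else uniformly in the window); each parent
gets Poisson(`offspring_mean` = 13) nests displaced by an isotropic Gaussian
(SD `sigma_m` = 500 m). Offspring falling outside the window are redrawn,
not clipped, keeping intensity homogeneous near edges. Defaults yield ~100
nests. `association` interpolates continuously between habitat-independent
clustering (0) and fully habitat-anchored clustering (1); the process is the
minimal one that is both clumped and habitat-associated.

## Classification and refinement

The base classifier maps band vectors at training-plot centres to calibrated
class probabilities. Default is Gaussian maximum-likelihood classification
with per-class diagonal covariances (Gaussian naive Bayes): the classic
remote-sensing supervised family, exactly matched to the generator's
isotropic Gaussian noise, well calibrated, deterministic, and stable for
classes with very few plots. An RBF-SVM with cross-validated sigmoid
calibration is available (`method="svm"`); in our experiments its
probability calibration on ~50 plots per class is too coarse for evidence
fusion to help reliably, which is why it is not the default. Rule stacks are
renormalised cellwise before use, and nodata in any band propagates to all
seven probability layers.

Evidence evaluation applies Bayes' rule once per evidence layer in declared
order, the posterior of step k becoming the prior of step k+1. This is exact
when evidence items are conditionally independent given the class;
sequential updating over m layers equals a single update with the
elementwise product of the m likelihood vectors (a tested identity, 1e-12),
so the order cannot matter. Cells whose evidence value is nodata are left
un-updated by that layer. Cells whose evidence is impossible under every
class (zero normaliser) keep their prior and are counted in a diagnostics
field rather than aborting the run. Ties in the final argmax relabelling
break to the lowest class index in scheme order.

The conditional probability tables P(A = a | B_j) default to empirical
frequencies over the training plots (evidence value at the plot cell versus
plot label), Laplace-smoothed with α = 1 so that every declared evidence
value has support; a class never seen falls back to the uniform likelihood.
Estimating from the full truth map is also supported for oracle studies.

What the improvement test shows: over 20 seeded landscapes whose land cover
truly depends on terrain and elevation, median overall accuracy and κ of the
refined map are at least those of the base map, and the refinement corrects
more base errors than it introduces in the median run. It does **not** show
that refinement helps on any single seed (it can lose a few tenths of a
point), nor that it would help where land cover is independent of the
evidence, nor with a poorly calibrated prior — with an uninformative table
the refined map equals the base map exactly, which is also tested.

## Point-pattern statistics

Estimator: the unweighted ordered-pair form K̂(r) = |W|/(n(n−1)) Σ 1(d ≤ r)
(cross version |W|/(n1 n2) over all pairs, symmetric in the patterns), with
distances exactly equal to r counted as within. No edge correction by
default: appropriate when all points lie well inside the study window, and
the convention under which all defaults were calibrated. A translation edge
correction (weights |W| / ((W−|dx|)(H−|dy|)) for rectangular windows) is
available behind a flag for real-world use where points approach the
boundary; it is not used by the pipeline.

Two estimator facts matter when reading L near zero. K̂ is unbiased for
|W|·P(d ≤ r), which in a unit square is πr² − 8r³/3 + r⁴/2 — the r³ term is
the uncorrected edge deficit, so E[L(0.1)] ≈ −0.004, not exactly 0; and the
square root adds a further small negative (Jensen) bias at small counts.
The calibration checks therefore test K̂ against its exact closed-form CSR
expectation and require mean L to be zero only at reporting precision.

Envelopes are pointwise rank envelopes: with nsim simulations and level α,
the band is the k-th smallest/largest simulated value, k = ⌊α/2·(nsim+1)⌋,
so under the null the observed statistic falls outside with probability
exactly 2k/(nsim+1) — 0.05 at nsim = 199 or 999 (nsim ≥ 39 required at
α = 0.05). They are pointwise, not simultaneous: reading across many radii
inflates the family-wise rate, which matches the per-distance reading used
throughout.

Null models: CSR (fresh uniform patterns, conditioned on the observed n)
for univariate tests; population independence for bivariate tests, simulated
by rigid toroidal shifts of the second pattern over the rectangular window —
each pattern keeps its internal structure, only the relative displacement is
randomised. A zero shift reproduces the observed L12 exactly. Rectangular
windows only.

Power and its limits: with fully habitat-anchored nests (association 1,
σ = 500 m) on a *patchy* habitat (a few isolated 1.2-km patches), the
independence test reads "above" at essentially all radii ≤ 1500 m. When the
habitat instead covers broad contiguous lowlands, rigid shifts barely change
the nest-habitat overlap and power drops sharply — an intrinsic property of
the null, not an implementation artifact. The power tests therefore use the
patchy alternative (`patchy_habitat`), and users should expect weak
bivariate verdicts when the focal class is widespread.

## Buffers, clustering and group tests

Buffer areas use cell-centre-in-circle counting (zonal-statistics
semantics): a cell contributes its full area iff its centre is within the
radius. This is deterministic and exactly checkable against a full-scan
oracle; against exact circle geometry it errs by at most the boundary-cell
ring (well under 1 % at 30–100 m cells versus a 3-km radius). The
geometric upper bound used for validation is the disc dilated by half a
cell diagonal.

Ward clustering is implemented from scratch: merge cost
Δ(A,B) = |A||B|/(|A|+|B|)·‖c_A − c_B‖² (the increase in within-cluster error
sum of squares), maintained with the Lance-Williams recurrence, cost ties
broken to the lexicographically smallest cluster-id pair. For this cost the
merge sequence is non-decreasing (no reversals), which is asserted in tests;
the merge sequence is verified against a from-scratch oracle that recomputes
ESS increases directly from member coordinates, and partitions against
scipy's Ward linkage. Final labels are renumbered 1..k by ascending cluster
centroid (first coordinate) so runs are reproducible. Nest clustering uses
raw planar coordinates (no standardisation); habitat-extent levels cluster
the 1-D buffer areas, so level 1 is always the smallest-area group.

Group differences: Kruskal-Wallis across nest clusters followed by all
pairwise two-sided Mann-Whitney U tests, reported raw with a Holm-adjusted
column alongside (the annotation convention flags pairs with p ≥ 0.05 as not
significant). Per-cluster nest-habitat association is compared by one-way
ANOVA on the observed bivariate L values pooled over the bivariate radius
grid per cluster, with Tukey HSD post-hoc; with no within-group variance
anywhere the F statistic is reported as undefined rather than fabricated.

## Accuracy assessment

Overall accuracy, Cohen's κ (marginal-product chance agreement), and
per-class producer's/user's accuracy from a reference-by-predicted confusion
matrix on the held-out plot half only; classes with a zero marginal report
the corresponding metric as missing. McNemar's test compares two classifiers
on the same plots through the discordant counts b and c:
χ² = (b − c)²/(b + c) on 1 df, without continuity correction by default
(the corrected variant is behind a flag); with b + c = 0 the statistic is
undefined and p = 1.

## Numerical and I/O conventions

Rasters are square-celled, north-up, with the origin at the lower-left
corner; the centre of cell (row, col) is
(x₀ + (col + ½)·s, y₀ + (nrows − row − ½)·s). Categorical rasters are uint8
with 255 as nodata; continuous rasters float32 with NaN nodata. Rasters are
stored as TIFF with the planar georeferencing (cell size, origin, nodata) in
a JSON ImageDescription tag; non-square cell sizes are rejected on read.
Points travel as CSV (`x,y`, plus optional cluster/area columns) or GeoJSON
Point features with the window in `bbox`. Every pipeline CSV starts with a
`#` provenance line carrying the stage, seed and config digest; all
randomness derives from the single config seed through spawned generators,
so repeated runs are byte-identical.

## Problem sizes

Default pipeline: 128×128 cells at 100 m (a 12.8-km square), 768 plots,
nsim = 199 envelopes — a desk-scale landscape that preserves the structure
of the full-size problem (a ~4000 km² scene at 30 m with nsim = 999 runs the
same code unchanged, only longer). The statistical test battery uses 64×64
landscapes for the 20-seed refinement study, 500 CSR replicates and 200
coverage trials for calibration, and 20 replicates for the power checks.

## Known limitations

Spectra are i.i.d. Gaussian around class means: no spatial autocorrelation
of noise, no mixed pixels, no phenology, no topographic illumination
effects — so classifier accuracies here say nothing quantitative about real
imagery. Land-cover cells are conditionally independent given their stratum;
real landscapes have patch structure beyond what terrain induces. The
expert system assumes conditional independence of evidence items given the
class; strongly redundant evidence layers would double-count. Envelopes are
pointwise; no inhomogeneous K; windows are rectangles; no CRS handling or
reprojection.
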