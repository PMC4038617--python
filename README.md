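# ricenest

Habitat-association analysis for a wetland-nesting bird on an agricultural
mountain landscape: map the focal habitat class (winter-flooded rice fields)
from multi-band imagery, refine the map with a Bayesian expert system driven
by terrain evidence, then quantify how nest sites relate to that habitat
with point-pattern statistics and hierarchical clustering.

The package is aimed at spatial ecologists and remote-sensing analysts who
want each stage of such a workflow as a tested, scriptable component — and at
anyone who needs the whole chain runnable end-to-end without field data: a
first-class synthetic-landscape generator produces a DEM, a seven-class
land-cover map whose composition genuinely depends on elevation and terrain
position, noisy per-pixel spectra, stratified ground plots, and clumped,
habitat-anchored nest patterns.

## What it computes

**Bayesian post-classification refinement.** A probabilistic classifier
(Gaussian maximum likelihood by default, an SVM optionally) turns the band
stack into per-class probability ("rule") images, the priors P(B_j). Each
categorical evidence layer A — terrain position (gully … ridge, from a
neighbourhood elevation percentile) and binned elevation — updates them cell
by cell through Bayes' rule

    P(B_j | A) = P(A | B_j) P(B_j) / Σ_i P(A | B_i) P(B_i),   j = 1 … 7,

applied forward over the evidence items; every cell is then relabelled by
its maximum-posterior class. Map quality is assessed on held-out plots with
a confusion matrix, overall accuracy, Cohen's κ, producer's/user's
accuracies, and the McNemar paired test between base and refined maps.

**Point-pattern association.** Ripley's K and Besag's L,

    K̂(r) = |W| / (n(n−1)) · Σ_{i≠j} 1(d_ij ≤ r),    L(r) = √(K(r)/π) − r,

with pointwise Monte-Carlo envelopes: complete spatial randomness (CSR) for
single patterns (L > upper envelope ⇒ clumped), and the population-
independence null for nest-vs-habitat association, simulated by rigid random
toroidal shifts of the habitat point pattern (L12 above the envelope ⇒
attraction, below ⇒ repulsion). Habitat extent around nests is measured as
the focal-class area inside 3-km buffers; nests are grouped by Ward's
hierarchical clustering (implemented from scratch via the Lance-Williams
recurrence) into geographical clusters (k = 5) and habitat-extent levels
(k = 3), with Kruskal-Wallis / Mann-Whitney and ANOVA / Tukey HSD test
batteries across groups.

## Worked example

Run the full synthetic pipeline (128×128 cells at 100 m, 768 plots,
199-simulation envelopes):

```sh
ricenest report --out run7 --seed 7
```

or equivalently from Python:

```python
from ricenest import RunConfig, run_pipeline
summary = run_pipeline(RunConfig(seed=7), "run7")
```

The run writes per-stage artifacts (GeoTIFF-style rasters, provenance-headed
CSVs, GeoJSON) plus `summary.json`. For seed 7 the summary contains:

```
n_nests            103
base_overall       0.706     base_kappa     0.572
refined_overall    0.708     refined_kappa  0.576
mcnemar            b=20, c=19 (chi2 = 0.026, p = 0.87)
kruskal            H = 79.70, p = 2.0e-16
anova              F = 8.73,  p = 1.5e-4
nests_univariate   12 of 12 radii above the CSR envelope
```

Reading: the nest pattern is significantly clumped at every radius tested
(univariate L above its CSR envelope); the expert system nudges overall
accuracy and κ upward on this seed (the improvement is a median property
across seeds, not a per-seed guarantee); and the rice-field area within 3-km
nest buffers differs strongly among the five geographical nest clusters
(Kruskal-Wallis), as does the per-cluster nest-habitat association (ANOVA on
the pooled bivariate L values). Per-radius envelope tables land in
`nests_univariate_L.csv`, `rice_univariate_L.csv`, `bivariate_L.csv` and
`cluster_L12.csv` with columns `r,L,lo,hi,verdict`.

Individual stages are also exposed as CLI verbs over files — `simulate`,
`terrain`, `classify`, `refine`, `assess`, `ppa`, `cluster` — e.g.

```sh
ricenest ppa --points run7/nests.csv --against run7/rice_points.csv \
         --raster run7/dem.tif --rmax 3000 --step 500 --nsim 999 \
         --seed 1 --out assoc.csv
```

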