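# Methods

This note records the models, conventions and numerical choices behind
`gliotopo`, in the spirit of a statistical methods appendix: what each
stage assumes, which knobs matter, what the synthetic generator does and
does not emulate, and where genuinely open design choices were fixed.

## Synthetic study design (`fixtures`)

The generator emulates the statistical structure of three data sources the
analysis was designed around — a co-registered lesion cohort, a
group-level functional connectome, and a spatially sampled post-mortem
expression atlas — without any claim to anatomical realism.

**Geometry.** The "brain" is an ellipsoid on a 64³ grid of 2 mm voxels
(semi-axes 0.46 of each extent), split by a sagittal midline (x axis even,
reflection `x → nx−1−x`).  The parcellation is a seeded Voronoi partition
of the left half-ellipsoid, mirrored to the right with an id offset, so
every parcel has an exact homotopic partner and is convex-by-construction
(hence contiguous; a cleanup pass reattaches rare voxelization strays).
Defaults match the study conditions: 167 parcels per hemisphere, 8 of them
subcortical (deep central seeds); the 159 cortical seeds sit on an outer
shell, and their unit direction from the hemisphere origin is stored as the
spherical centroid the spin test rotates.  Two subcortical parcels per
hemisphere are tagged `hippocampus` and `caudate` as NSC-niche stand-ins.
Seven spatially coherent "networks" come from k-means clustering of the
cortical seed directions; subcortical parcels inherit the nearest cortical
community.

**Ground-truth fields.** Parcel-level Gaussian-kernel smoothing
(bandwidth `smoothness_mm`, default 12 mm, on volumetric parcel centroids)
of white noise gives spatially autocorrelated left-hemisphere fields.
Planted effects are mixtures: `hub = ρ·base + √(1−ρ²)·independent smooth
noise`, likewise `opc` and `driver`, with `base` an affine transform of
the (non-negative) lesion-placement intensity.  Effect sizes default to
0.5 — the magnitude of the moderate map–map correlations this kind of
analysis reports.  Because smooth fields have few effective degrees of
freedom, the *realized* per-seed correlation scatters around the planted
value; calibration statements are therefore about means over seeds.

**Lesion cohort.** 335 patients, P(LGG) = 0.23.  Each patient contributes
one spherical blob whose centre parcel is drawn with probability
proportional to the truth field (mirrored bilaterally) and whose radius is
log-normal, median 20 mm (≈34 cm³, the scale of mixed-grade glioma
volumes; the shape of real lesions is irrelevant downstream, only the
placement law matters), σ = 0.4.  With these conditions the full-cohort
map reaches split-half reliability ≈ 0.7 and mean voxel frequency ≈ 4.5%,
the regime a real mixed-grade cohort exhibits.

**Connectome source.** Each parcel gets a 256-vector of "component
loadings": a fixed community latent (weight 0.5), a global hub axis whose
per-node weight increases with the hub-truth rank (mixed with noise at the
planted level), and i.i.d. noise.  Correlating rows therefore yields a
modular graph (within-community correlations ≈ 0.3) whose nodal strength
rank-correlates with hub truth at a controlled level (planted 0.8 →
realized Spearman ≈ 0.73–0.79).

**Expression atlas.** 600 samples at random in-parcel coordinates, left
hemisphere only, subcortical parcels oversampled 5× (mimicking the uneven
sampling of post-mortem atlases), 2000 genes.  Background genes are
half-smooth/half-white mixtures.  The marker panel (25 genes) shares a
common spatial profile correlated with the target field at the planted
`opc` effect; the driver panel (17 genes, of which 3 anti-correlated
decoys by default) loads on a profile at the `driver` effect; member genes
carry the shared profile at weight √0.5.

**What the generator does not emulate** — and hence what green tests do
not show about real data: registration/segmentation error, site effects,
lesion mass effects and infiltration geometry, probe/donor structure of
expression atlases, distance-dependent connectivity artefacts, and any
anatomically meaningful network layout.  Passing tests demonstrate the
*methods* are correct and calibrated under the assumed statistical
structure, not that the scientific conclusions transfer.

## Pipeline conventions

**Mapping** (`lesionmap`).  Frequency = 100 × overlap count / N.
Smoothing uses σ = FWHM/(2√(2 ln 2)) per axis, values clipped to [0,100].
Mirroring *averages* a voxel with its reflection on the target hemisphere
(preserving the percentage interpretation) and keeps the source hemisphere
unchanged; the unsmoothed, unmirrored map is always retained because the
transcriptomic alignment consumes it separately.  Parcel aggregation
dilates labels up to 4 mm into unlabelled voxels; competing parcels are
resolved by nearest boundary, exact ties by lower parcel id.  Pipeline
order is fixed: count → smooth → mirror → aggregate.  Empty parcels are
NaN, never silent zeros.  Split-half replicability stratifies by grade so
group 1 holds ≈1.5× the cohort LGG fraction and group 2 ≈0.5×, repeats 100
times, and reports the first repeat's Pearson r with a [2.5, 97.5]
percentile interval.

**Spin test** (`spatialnull`).  One uniform random rotation per spin is
applied jointly to all cortical unit-sphere centroids (the mirrored
rotation to the right hemisphere); each rotated centroid takes the value
of its nearest original centroid.  This nearest-neighbour reassignment can
duplicate donors (standard parcel-level behaviour); a bijective
optimal-assignment mode (`bijective=True`) exactly conserves the value
multiset and is the mode under which conservation is asserted.
Subcortical parcels have no spherical embedding and are uniformly permuted
among themselves (or excluded with `include_subcortex=False`).  The
default p-value is one-sided in the direction of the observed sign with
the +1 correction — appropriate for the directional hub/cell hypotheses —
and `sidedness="two"` doubles the smaller tail; two-sided is what a
symmetric α=0.05 calibration check must use, since the directional p
rejects ~10% of exchangeable nulls by construction.  Maps with missing
parcels are handled pairwise-complete.  Moran's I uses row-normalised
1/distance weights on the spherical centroids; its permutation null has
mean −1/(n−1).

**Hub metrics** (`hubgraph`).  Edge weights are Pearson correlations of
parcel-mean loadings with negatives and the diagonal zeroed — no further
thresholding.  Shortest-path metrics use edge lengths 1/weight;
betweenness is normalised by (n−1)(n−2) over ordered pairs (computed via
igraph, verified against exhaustive path enumeration).  Participation
`P_i = 1 − Σ_m (κ_im/k_i)²` and within-module degree z (population SD)
use the parcel table's fixed communities, not data-driven modularity.
Clustering is the Onnela geometric-mean form; "local efficiency" is nodal
efficiency (mean inverse shortest-path length to all other nodes); both
are screened out in practice.  Isolated nodes: strength, betweenness and
participation all 0 by convention.  Metrics are computed on the full
334-node graph, then homotopic pairs are averaged to 167 values.
Screening removes metrics with |Spearman| > 0.95 against strength
(strength itself is always kept) and reports stability across thresholds
0.65–0.99; the screened set is monotone in the threshold.

**Cell origin** (`cellorigin`).  The niche test compares the mean
frequency of the two tagged parcels to n random distinct parcel pairs
(pairs may include the niche parcels; the exhaustive mode enumerates all
pairs for an exact p).  Co-expression specificity compares the set's mean
pairwise Pearson correlation to random same-size sets; the null size
defaults to 1000 (a 10 000 option exists).  Filtering is a single pass
removing genes whose mean correlation with the rest is ≤ 0 — not iterated
to convergence, though it is idempotent on its own output in practice.
The OPC score is the per-sample median of z-scored member expression,
aggregated as the median over each cortical parcel's nearest-neighbour
samples.

**PLS** (`plstx`).  The response is √(map value) at each (mirrored)
sample coordinate; gene columns are z-scored (sample SD).  The algorithm
is NIPALS with a single response and X-deflation: `w ∝ X'y` (unit norm),
`t = Xw`, deflate, repeat — so component 1's weight vector *is* the
dominant singular direction of the gene–response cross-covariance, which
is the oracle test.  Variance explained is reported as deflated increments
(orthogonal scores make them additive); a scree of extra components
supports the two-component stopping choice.  Implementing the loop
directly (~20 lines) keeps 1000 permutations + 1000 bootstraps to seconds;
sklearn's PLSRegression serves as an independent cross-check in the test
suite, never as the implementation.  Bootstrap components are sign-aligned
to the original by weight-vector dot product; z = original weight /
bootstrap SD; ranks descend by z with ties broken by gene id.  Enrichment
is the median rank of the (pre-filtered) gene set against random same-size
sets, small ranks = enriched; an exhaustive mode enumerates all subsets
for toy instances.  Parcels with no samples take the mean loading of the
whole sample group.

**Integrative model** (`multifactor`).  All columns are z-scored on their
non-missing parcels first; missing cells (subcortical OPC scores, empty
PLS parcels) are then zero-filled — i.e. set to the column mean — and
flagged in metadata.  The interaction model adds the five two-way
cross-scale products; "no significant interactions" means no term with
p < 0.05 uncorrected, reported transparently.  Partial variance is the
squared partial correlation × 100 (equivalently t²/(t²+df));
the four partial R² values are *not* constrained to sum to the total R²,
and the pipeline asserts that non-identity rather than enforcing it.
Predictor significance spins the *response* map (the stated null of
spatially contiguous frequency models; spinning the predictor instead is
available behind a flag) and Bonferroni-corrects over the 4 predictors;
permutation p-values are floored at 1/(n_spins+1), never literal zero.

## Numerical and reproducibility choices

- All randomness flows from `SeedSequence([seed, stream])` with disjoint
  stream ids per generator and per analysis stage; identical configs give
  bit-identical outputs, which the manifest (config snapshot + SHA-256 of
  every written file) makes checkable.  Run manifests exclude wall-clock
  timings for exactly this reason.
- Spin counts default to 10 000, permutations/bootstraps to 1000, null
  pairs to 10 000 — the analysis defaults; tests use smaller sizes where
  only correctness (not resolution) is at stake.
- Degenerate inputs fail loudly: constant vectors in correlation tests,
  all-zero placement fields, rank-deficient designs (the offending columns
  are named), gene sets emptied by filtering.
- Tolerances: graph metrics match brute force to 1e-12; z-scoring is
  checked to 1e-8; dilation/assignment distance ties use a 1e-9 buffer.

## Problem sizes

The default configuration — 64³ grid, 334 parcels, 335 patients, 2000
genes × 600 samples, 10 000 spins, 1000 permutations and bootstraps — was
chosen so a full pipeline run completes in about a minute and the whole
test suite (including 500-simulation calibration and 100-seed power
sweeps) in a few minutes on one core, while keeping every inferential
routine at its full default resolution.  The expression atlas is a
~10×-reduced rendition of a real post-mortem atlas's 20 647 genes × 2748
samples; nothing in the implementation depends on the reduction.

## Known limitations

- The spin reassignment's duplicated donors bias spun-map Moran's I
  slightly upward (~5% on average here); the bijective mode avoids this at
  the cost of departing from common practice.
- Single-pass gene filtering can, in principle, leave a set whose
  re-filtering would remove further genes; observed rarely at these
  coherence levels.
- The PLS variance explained by leading components is inflated by
  construction (supervised maximization over many genes); the permutation
  test, not the raw percentage, carries the inference.
- Network communities are fixed from the parcel table; mis-specified
  communities would distort participation and within-module z.
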