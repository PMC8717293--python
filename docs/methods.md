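# Methods

This note documents the models, estimators and numerical choices behind
`nichesdm`, and what its synthetic validation does and does not establish.

## 1. Niche quantification in PCA-environment space

**Ordination.** Climate variables are centred and scaled to unit variance
over the *pooled background* of the two ranges being compared (not over a
global calibration), and the first two principal components span the niche
space. Calibrating per comparison means the axes always describe the
climates actually available to the two populations under study; a constant
variable is a calibration error (it cannot be standardized), reported by
name.

**Gridding.** Occurrence scores and background scores are smoothed onto an
R × R grid (default R = 100) whose bounds are the min/max of the pooled
background scores. Kernels are Gaussian, truncated at 4 bandwidths, with a
per-axis normal-reference bandwidth computed from the occurrence scores,

h = 1.06 · min(sd, IQR/1.34) · n^(−1/5), floored at one grid cell.

The same bandwidth smooths both the occurrence density *o* and the
availability density *e* of a given range: because the two densities then
roll off identically at the margin of the available environment, their
ratio stays bounded there instead of exploding where *e* → 0.

**Occupancy correction and its regularization.** The occupancy surface is
z ∝ o/e on cells with e > 0, normalized to sum 1. The raw ratio is a
noisy estimator wherever few background environments fall: one occurrence
over a near-empty availability pocket can otherwise capture a large share
of the total occupancy mass and corrupt both D and the COUE indices. The
denominator is therefore floored at a quantile of the positive
availability density (default: the median, `AVAILABILITY_FLOOR_QUANTILE`);
well-sampled environments are fully corrected, marginal ones revert
smoothly toward the uncorrected density. Setting the quantile to 0
recovers the plain ratio. An uncorrected mode falls out of the same switch.

**Presence floor.** Kernels have infinite support, so "where a niche is
absent" needs a convention: occupancy is absent where z = 0 after the
4-bandwidth kernel truncation. This makes expansion/stability/unfilling
deterministic functions of the data. Analogue climates are cells whose
availability density exceeds the `intersection_quantile` quantile in both
ranges (default 0 = available in both; the framework admits 0–0.25 and the
setting is config-exposed).

**Indices.** D = 1 − ½Σ|z₁ − z₂| on the full normalized surfaces.
Expansion is the invasive occupancy mass (within analogue cells) on cells
where the native niche is absent; unfilling mirrors it for the native
niche; stability = 1 − expansion exactly. By construction
expansion(A, B) = unfilling(B, A) on a common frame.

**Permutation tests.** Equivalency: pool the occurrence sets, reallocate
labels, recompute D; p = (1 + #{D_null ≤ D_obs})/(n_perm + 1) for the
"less equivalent than random" direction (a two-sided variant is available).
Similarity: recentre the second niche on a random available cell of its own
background and recompute D; the default direction asks whether the niches
are more similar than their available climates would suggest. Both use the
add-one estimator, so p ∈ (0, 1].

## 2. The virtual-species simulator and its oracle

**Climate.** Each layer is seeded white noise smoothed by a Gaussian
kernel of width `autocorrelation_length` (cells) and affinely rescaled to
bioclim-like ranges (defaults: bio4 100–1200, bio5 5–42 °C, bio6 −30–20 °C,
bio12 0–3000 mm, bio15 5–120). An optional rank transform
(`marginal="uniform"`) flattens a layer's value histogram while preserving
its spatial pattern; the default keeps the bell-shaped histogram of the
smoothed field, which is closer to real bioclim rasters.

**Species.** Suitability is a product of independent Gaussian responses,
one per layer — the simplest truth with closed-form structure and cheap
integration. Occurrences are n distinct cells drawn with probability
proportional to suitability and placed at cell centres, matching the
one-record-per-cell resolution of thinned real data.

**Support convention.** For the purpose of deciding *presence vs absence*
(the quantity the COUE indices binarize), the response is truncated at
`SUPPORT_SD` = 4 breadth-scaled (Mahalanobis) radii. The truncation is
radial rather than per-axis: a per-axis rule would call corner regions
"present" whose suitability is ~e⁻⁸ and which no realistic survey would
ever record, making the truth unattainable for any finite-sample
estimator. Four radial standard deviations mirror the estimator's own
4-bandwidth kernel truncation, so both routes answer the same question.
The smooth (untruncated) surface is used for sampling and for SDM
recovery.

**Oracle.** `niche_truth` computes D/expansion/stability/unfilling in raw
layer units, independently of the PCA/KDE estimator: the realized
environment (all valid cells) is binned on a lattice coarse enough that an
average occupied bin holds several cells — the occupied-bin set then
approximates the *region* of available environments (uniform measure over
support), which is the measure the estimator's uniform PCA grid uses —
with interior holes closed morphologically. Each niche's truncated
response is evaluated at bin centres and normalized; the indices follow
directly. Total-variation distance and set masses are invariant under the
(linear) PCA map, so oracle and estimator are comparable despite living in
different coordinates.

**Reference scenario suite.** `coue_oracle_suite` builds a climate with two
disjoint environmental regimes (cool and warm, with a wide gap of
unavailable intermediate conditions) and five native/invasive pairs whose
oracle expansion spans 0 → 1: a nested contraction (expansion 0), three
broad niches straddling the regimes with optima progressively deeper in the
warm regime (≈ 0.25/0.50/0.75), and a complete relocation (1). Expansion
into conditions *absent from the native range* is the cleanest real-world
mechanism of niche shift and, importantly, puts the decision boundary in
the availability gap where neither sampling noise nor kernel support
inflation can move mass across it — which is what makes agreement between
estimator and oracle to within ±0.05 at n = 2000, R = 100 an achievable
and meaningful bar. Translation-only scenarios whose support edge cuts
through the opposing niche's density bulk are intrinsically harder: there
the index is sensitive to the exact support edge, which no 2000-point
sample can pin down to better than a few tenths of a breadth. The suite
uses uniform-marginal layers so that availability weighting does not
confound the comparison of measures.

**What passing does not show.** The simulator has no sampling bias, no
spatial clustering of effort, no label noise, and its niches are unimodal
Gaussians; real occurrence data violate all four. Passing the oracle suite
shows the estimator chain (PCA → KDE → correction → indices) is
numerically faithful, not that D values from heterogeneous real data carry
the same accuracy.

## 3. Ensemble distribution modelling

**Pseudo-absences.** 10,000 distinct non-nodata cells drawn uniformly from
those at least `exclusion_radius` (default two grid cells, great-circle)
from every presence; presence cells are ineligible regardless of radius.
A shortfall of eligible cells is an error that reports the deficit rather
than silently sampling fewer.

**Class weighting.** Presences and pseudo-absences are weighted to equal
total weight (prevalence 0.5); the weights are passed as observation
weights to every algorithm that accepts them. The neural network (sklearn
`MLPClassifier`) accepts none, so its training set is balanced by integer
replication of the minority class — an approximation of the same
prevalence correction.

**Members.**

| algorithm | implementation | settings |
|---|---|---|
| ANN | sklearn MLP, 1 hidden layer, lbfgs | size ∈ {2,4,6,8} × decay ∈ {0.001,0.01,0.1} by 5-fold CV (ROC AUC), ≤ 200 iterations |
| GAM | statsmodels GLMGam, binomial/logit | cubic B-splines, df 6 per variable; predictions clip inputs to the training range of the spline basis |
| GBM | sklearn GradientBoosting | ≤ 2500 trees, learning rate 0.01, depth 7, ≥ 10 obs per leaf; tree count by internal validation (20% holdout, patience 25) |
| GLM | statsmodels GLM, binomial | bidirectional stepwise AIC over linear + quadratic terms, quadratic only alongside its linear term, greedy one move per sweep from the full model |
| FDA | hand-written | optimal-scoring discriminant on a forward-selected hinge (piecewise-linear) basis, knots at deciles, ≤ 21 basis functions; score mapped to [0,1] by logistic calibration |
| RF | sklearn RandomForest | 500 trees, min leaf 5 |

The MLP's initial weights follow the library's Glorot scheme rather than a
uniform [−0.1, 0.1] draw; with standardized inputs and CV-selected decay
this has no practical effect on the selected models. A member whose fit
raises is returned flagged (`converged=False`, diagnostics attached) and
is excluded from the consensus instead of aborting the run.

**Evaluation and consensus.** One stratified 80/20 split (config-exposed;
the number of replicates is configurable by re-running with derived
seeds). AUC is the rank-based Mann–Whitney statistic with ties counted
half. The equal-sensitivity/specificity threshold is chosen among midpoints
of consecutive distinct scores, minimizing |sens − spec| with ties broken
toward higher TSS then lower threshold. Members with AUC > 0.95 enter the
consensus with weights ∝ AUC; the consensus prediction is the weighted
mean, hence bounded by the member predictions.

**Recovery benchmark.** A noiseless Gaussian virtual species (500
presences, 10,000 pseudo-absences, 120 × 120 raster — the smallest grid
that leaves 10,000 eligible cells outside the exclusion disks) must yield
consensus evaluation AUC ≥ 0.9 and Spearman ≥ 0.9 between predicted and
true suitability over all cells. The niche is deliberately narrow relative
to the available climate: when suitable habitat is common, randomly placed
pseudo-absences frequently fall on genuinely suitable cells and the
*achievable* AUC of any method drops — a property of the design, not of
the estimators.

## 4. Projection, range change, risk

Binarization uses ≥ threshold (boundary suitable). Change maps classify
(current, future) binary pairs into never-suitable / new / stable /
disappearance; the categories are exhaustive and exclusive on non-nodata
cells and raising the threshold can only shrink the suitable set. Country
risk is the unweighted mean suitability over cells whose centre falls in
the country polygon (boundary inclusive), with a cos-latitude-weighted
option; bins are half-open — minimal [0, 0.15), low [0.15, 0.25), moderate
[0.25, 0.50), high [0.50, 1] — so every mean maps to exactly one category.
A country covering no cells is reported as `no-data` rather than dropped.

## 5. Reproducibility

One master seed fans out deterministically to named per-stage seeds
(synthesis, pseudo-absences, split, members, permutations); a synthetic
run is bit-for-bit reproducible from its config and seed, and each run
directory carries a manifest with the package version, config hash, stage
seeds and input checksums. GeoTIFF I/O writes baseline geo tags
(ModelPixelScale, ModelTiepoint, GDAL nodata) plus a JSON description with
layer names, and reads either form.

## 6. Problem sizes of the shipped validation

The test suite and the acceptance script size their simulations to run on
one CPU in a few minutes: oracle suite at n = 2000 per range and R = 100
(the sizes at which the ±0.05 agreement bar is stated); recovery at
500 presences + 10,000 pseudo-absences on 120 × 120; null-AUC checks at
n = 1000 rows per algorithm; permutation tests at 99–199 permutations.

## 7. Known limitations

* Only two ordination axes; niche structure orthogonal to PC1/PC2 is
  invisible to the comparison.
* Kernel-density D between two *independent* samples of the *same* niche
  has a negative noise bias that shrinks with n but is still ≈ 0.02–0.05
  at n = 2000, R = 100; D near 1 is therefore estimated conservatively.
* The availability floor trades a small mass-ratio bias (≲ 0.03 on the
  indices in the validation suite) for a large variance reduction; studies
  with very evenly sampled backgrounds may prefer quantile 0.
* Stepwise GLM explores main and quadratic effects only (no interactions),
  matching its role as the parametric baseline of the ensemble.
* Great-circle exclusion treats cell centres as point locations; at coarse
  resolutions the disk is approximate near the poles.
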