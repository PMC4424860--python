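# Methods

This note records the models implemented in `icsift`, the defaults and the
reasoning behind choices the underlying problem leaves open.

## Data model and scope

The package operates downstream of ICA: its inputs are per-component
statistic maps (one 3D t/z volume per component, melodic-style 4D stack),
the mixing matrix (T × NIC, columns are time courses) and binary tissue
masks on the same voxel grid. Grids must already be aligned; the affine is
carried through I/O but never used for resampling, and any grid mismatch is
a hard error rather than a silent interpolation. NaNs are rejected on read
because no downstream operation defines semantics for them. Preprocessing,
registration and the ICA decomposition itself are out of scope.

## Thresholding and cluster-extent filtering

Maps are thresholded voxelwise at p (default 0.001), one-sided positive by
default because the classification criteria concern peak *activations*;
two-sided is available. With integer degrees of freedom the Student-t
quantile is used, otherwise the normal quantile. Contiguity defaults to
face adjacency (6-connectivity, the most conservative neighbourhood;
18/26 available). Clusters smaller than `min_cluster` (default 20 voxels)
are discarded, and all features are computed on the mask restricted to the
retained clusters.

The Monte-Carlo calibration estimates P(max null cluster ≥ k): per
iteration, unit white Gaussian noise on the stated grid is smoothed with an
isotropic Gaussian of the stated FWHM, re-standardized to zero mean / unit
variance *within the analysis mask* (so the voxelwise cutoff keeps its
nominal rate after smoothing — smoothing would otherwise shrink the
variance), thresholded, and the maximum cluster size recorded. The tabled
probability is the exceedance fraction over iterations; it is non-increasing
in k by construction and reproducible given the seed. The simulation uses
z quantiles (Gaussian noise) even when maps are thresholded as t maps. No
particular simulation grid is canonical; the bundled demonstration uses
20³ voxels at 2 mm, where a 6 mm kernel is wide enough (σ ≈ 1.27 voxels)
for the smoothing effect on the extent-20 exceedance probability to be well
resolved with 2000 iterations. On coarse 3 mm grids the same effect exists
but is much rarer at extent 20.

## The five features

Full formal definitions of the feature battery this design descends from
are not in circulation; the definitions below are this package's normative
ones, chosen to mirror the manual criteria (gray-matter peak activation,
little overlap with known artifact territory, slow fluctuations, compact
geometry).

1. **gm_pos_overlap** — sum of positive statistic values over the retained
   suprathreshold mask intersected with gray matter, divided by the sum over
   the whole retained mask. Value-weighted rather than voxel-counted, so
   strong peaks dominate the judgment the way they do visually; both
   choices are defensible, value-weighting is ours.
2. **peak_in_gm** — indicator that the maximum suprathreshold statistic lies
   in gray matter. Ties are broken by the lowest linear (raster) voxel
   index, making the feature deterministic.
3. **freq_ratio** — periodogram power in the low band (default
   0.01–0.08 Hz: the conventional upper edge of spontaneous-fluctuation
   power plus a conventional 0.01 Hz floor) divided by total non-DC power
   up to Nyquist. Low/total rather than low/high keeps it bounded in
   [0, 1]. A plain untapered periodogram is the default for exact
   reproducibility; Welch is available behind a flag.
4. **lag1_autocorr** — Pearson correlation of the series with its one-sample
   lag; smooth slow signals score near 1, spike trains near 0.
5. **bbox_voxel_ratio** — size-weighted mean over retained clusters of
   bounding-box volume over cluster size; 1 for a solid box, large for
   sheets, lines and shells (the rim-artifact geometry).

Components with *no* retained cluster cannot be networks under the
filtering rule: they receive documented degenerate values
(overlap 0, peak 0, bbox ratio 27 — the worst case for an isolated voxel's
3×3×3 neighbourhood), are flagged, and the classifier force-labels them ART.

Conditioning is mean-centring and division by the training-set sample
standard deviation; the statistics travel with the trained model so
classification of new sets uses the training conditioning. A zero-variance
feature is an error naming the feature. The Andrews projection
f(x, t) = x₁sin t + x₂cos t + x₃sin 2t + x₄cos 2t + x₅sin 3t is provided
for feature-space visualization.

## Feature selection

The two-class F-score is the Fisher ratio
[(x̄⁺−x̄)² + (x̄⁻−x̄)²] / (s²₊+s²₋) with within-class *sample* variances.
The reduction loop sweeps an ascending threshold list; at each threshold the
surviving features are evaluated by mean validation accuracy over
`n_repeats` (default 50) stratified random splits (default holdout 0.3)
of the training data using the same SVM configuration as classification.
"Accuracy decreases significantly" is operationalized as: stop once the
mean drops more than `stop_tol` (default 0.02) below the best mean so far;
the kept set is the smallest whose mean accuracy is within `keep_tol`
(default 0.02) of the best observed. No numeric stopping criterion is
canonical; these tolerances are this package's defaults and are
configurable.

Explanatory power uses a binomial-variance, logit-link GLM with intercept;
per-coefficient Wald statistics and two-sided p-values are reported (Wald
rather than likelihood-ratio, matching a per-coefficient t/p presentation),
plus the model AIC. Perfect separation is flagged, not hidden. Relative
AIC is exp((AIC₁−AIC₂)/2).

## Classification model

The kernel is exp(−σ‖x−y‖²). (The unsigned form sometimes printed for this
kernel is unbounded; the negative exponent is the LIBSVM/kernlab convention
and the only one that yields a valid kernel.) σ defaults to a seeded
uniform draw between the 0.1 and 0.9 quantiles of the inverse squared
pairwise-distance statistic on a random subsample — any value in that
bracket performs comparably, so the draw is recorded via the seed; a
midpoint option exists for strict determinism without a seed. Cost defaults
to 100. The asymmetric objective ("do not discard true networks") is
implemented as per-class error weights with the heavier weight (default
10:1, configurable) on the RFN class; the weight ratio itself has no
canonical value. RFN is the positive class throughout the metrics.

Grid search evaluates every node of C ∈ [10, 1000] step 10 ×
σ ∈ [0.1, 1.0] step 0.1 (exactly 1000 nodes) by stratified k-fold
cross-validation (default 5 folds), keeping nodes whose mean sensitivity is
1 and maximizing mean accuracy among them, ties broken by smaller C then
smaller σ; if no node attains sensitivity 1 the search falls back to pure
accuracy with a warning. The QP itself is solved by scikit-learn's
LIBSVM-based SVC; the trained model is serialized to JSON (support vectors,
dual coefficients, bias, σ, C, class weights, conditioning, feature names)
and predictions after a round trip are recomputed from the stored state by
this package's own kernel code.

## Tracking across model orders

The tracker is an ε-SVR (default ε = 0.1, C = 100, RBF kernel with the same
σ heuristic) fitted on the conditioned features of the reference
decomposition with the reference component as 1 and all others 0. Raw
regression outputs on a target decomposition, clipped to [0, 1], are used
directly as class probabilities — no calibration step is applied — and the
descending ranking (ties by component id) names the match.

CISOTA = 1/(overlap × r), with overlap the fraction of the reference's
thresholded, extent-filtered pattern covered by the candidate's, and r the
Pearson correlation of the time courses. Binarization uses the same
threshold specification as classification by default. The index is 1 for
an unchanged component and undefined when overlap × r ≤ 0, in which case a
flagged infinite sentinel is returned instead of a signed value. ICA sign
ambiguity can be absorbed with an absolute-correlation flag (off by
default). Cross-sectional change between consecutive model orders matches
each component of the lower order to the candidate with the strongest
association (largest overlap × r, i.e. smallest CISOTA) and counts
components whose best match still exceeds a change threshold; a per-component
SVR for every consecutive pair would add cost without changing what the
count measures.

## Synthetic generator

The generator emulates what the framework consumes — statistic maps and
time courses — not the physics upstream: no BOLD simulation or actual ICA
is run. Templates are nested ellipsoids (brain; a gray-matter shell at
0.52–0.95 of the brain radius; a central ventricle at ≤ 0.25). Defaults:
32×32×16 grid at 3 mm, 200 timepoints at TR 2 s, blob amplitude 8 over
unit noise — sized so tests run in seconds while every planted pattern
clears p < 0.001 with clusters well beyond 20 voxels.

RFN components are compact Gaussian blobs (σ ≈ 2 voxels) centred mid-shell
with band-limited 0.012–0.05 Hz time courses. Artifact styles: *rim*
(suprathreshold shell on the brain contour, high-frequency time course),
*ventricle* (blob in the ventricle region), *spike* (deep blob, large
isolated time-course deviations), *highfreq* (deep blob, dominant power
well above 0.08 Hz). Model-order series are built from a fixed blueprint
pool so components persist across orders with small fresh perturbations;
the designated reference appears verbatim below the planned split order and
as two children above it, formed by half-space masking of the parent's
signal over the parent's own noise field, so the children's suprathreshold
regions partition the parent's exactly and their overlaps with it sum
to ≈ 1. Pool networks carry extra time-course noise (a spread of spectral
quality) so the clean reference remains identifiable — tracking a component
that is feature-identical to several others is ill-posed for any
feature-based tracker.

What passing tests on this corpus do **not** show: robustness to real
artifact taxonomies (the four styles are caricatures), to partial-volume and
registration error (absent by construction), to heterogeneous within-class
geometry, or to the borderline mixed components that dominate real
disagreement between raters. The generator's separation margins make the
classification task easier than real single-subject data; results on it
bound the pipeline's correctness, not its field performance.

## Numerical notes

* All randomness flows through `numpy.random.default_rng` seeds; identical
  (inputs, config, seed) give identical outputs, including byte-identical
  CLI TSVs.
* Peak and ranking ties are broken deterministically (lowest linear voxel
  index; smaller component id; smaller C then σ).
* Undefined classification ratios (zero denominators) are reported as NaN
  with the affected metric named, never silently as 0.
* The SVM decision recomputed from serialized state matches scikit-learn to
  machine precision; training-order permutations move the decision function
  only within the QP solver's convergence tolerance (~1e-3).
* Degenerate inputs (constant time courses, empty masks, single-class
  training sets, all-identical points in the σ heuristic) raise or warn
  explicitly as documented per function.

## Problem sizes used in the bundled checks

Training corpora of 50 components (17 networks / 33 artifacts) and held-out
corpora of 30 (10/20); model-order series at NIC 8–16; calibration runs of
2000 iterations on 16³–20³ grids; selection sweeps of 15–20 repeated splits
over 200-sample planted matrices. These sizes were chosen so the full suite
completes in a few minutes while keeping every statistical margin wide.
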