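# Methods

`dfncstates` implements a whole-brain dynamic functional network
connectivity (dFNC) analysis for multi-group resting-state fMRI cohorts:
post-processing of ICA component timecourses, static and sliding-window
regularized connectivity estimation, k-means identification of recurring
connectivity states, group statistics on state-specific connectivity and
state transitions, and signed-modularity summaries of state matrices. A
synthetic cohort generator with known ground truth supports validation of
every stage.

## Model and assumptions

The core modeling assumption is piecewise stationarity: a subject's C
component timecourses are treated as draws from a zero-mean multivariate
Gaussian whose covariance switches among k recurring "connectivity
states". Functional connectivity is the Pearson correlation between
component timecourses; static FNC uses the whole run, dynamic FNC a
tapered sliding window. Because a 22-sample window gives a noisy, often
ill-conditioned covariance, each windowed precision matrix is estimated by
graphical lasso (L1 penalty on off-diagonal precision entries), and the
covariance implied by that sparse precision is normalized to a correlation
matrix and Fisher-z transformed. Averaging and all group tests are done on
the z scale.

Connectivity states are centroids of a k-means clustering of all windowed
connectivity matrices (vectorized upper triangles). Clustering is seeded
in two stages: high-variability windows ("exemplars", local maxima of the
across-edge SD of the windowed matrix) are clustered first, and those
centroids initialize the clustering of every window. The final model is
never allowed to be worse, in total within-cluster distance, than random
k-means++ restarts on the same data.

## Pipeline stages and key parameters

| stage | parameter | default | rationale |
|---|---|---|---|
| window | width | 22 TRs (33 s at TR = 1.5 s) | standard dFNC window for this acquisition |
| window | step | 1 TR | maximal temporal resolution |
| window | Tukey shape alpha | 0.5 | the taper family is fixed, the shape is not; 0.5 tapers half the window |
| glasso | lambda grid | 10 log-spaced values in [0.01, 1] | spans near-unpenalized to fully diagonal |
| glasso | CV folds | 5 contiguous window blocks | contiguity respects the serial dependence of overlapping windows |
| glasso | solver tolerance / max iterations | 1e-4 / 200 | changes correlation estimates by < 1e-4 while keeping per-window cost at milliseconds |
| states | metric | L1 (correlation, cosine available) | L1 centroids are coordinate-wise medians; the alternatives are robustness checks |
| states | k search range | 2–10 | brackets the plausible number of states |
| post-processing | detrend order | 3 | removes scanner drift up to cubic |
| post-processing | despike threshold | 4 robust z | MAD scaled by 1.4826 to be SD-consistent |
| post-processing | low-pass cutoff | 0.15 Hz, 5th-order Butterworth, zero-phase | only the cutoff is prescribed; zero-phase filtering avoids phase distortion of the windowed correlations |
| QC | max translation / SFNR | 2 mm / 275 (strict inequalities) | exclusion thresholds for subject data |
| statistics | FDR level | q < 0.05, Benjamini–Hochberg per state-and-pair family | each state/pair significance mask is its own family |

## Numerical choices

- **Graphical lasso** is solved on the correlation scale (variances divided
  out, penalty therefore scale-free) and mapped back; short-window
  covariances are ill-conditioned on the raw scale and this is the standard
  remedy. At lambda = 0 the solution is the exact matrix inverse, computed
  directly. A diagonal ridge (1e-3, then 1e-2) is the fallback when the
  coordinate-descent solver reports a non-SPD system.
- **Lambda selection**: per subject, precision matrices are fitted on the
  pooled training-window covariance and scored on held-out windows by
  `log det(T) - tr(S T)`. Two selection rules are exposed. `max` (default)
  takes the best mean held-out score and is the right choice when the
  *values* of the connectivity estimates matter; it is likelihood-consistent
  and therefore tends toward small penalties. `1se` takes the largest lambda
  within one standard error of the best score; the held-out likelihood is
  typically flat near its maximum, and the parsimony rule is the right
  choice when the *sparsity pattern* itself is of interest.
- **Window count**: starts are `0, step, 2*step, ...` while
  `start + width <= T`, giving `floor((T-width)/step) + 1` windows — 185
  for a 206-frame run at width 22, step 1. Any trimming convention can be
  applied by the caller via the spec's width/step fields.
- **Elbow criterion**: the cluster-validity ratio is the mean distance of
  each window to its own centroid divided by the mean distance to the other
  centroids (both terms on the point level). k* is the sharpest bend of
  the ratio curve — the maximizer of its discrete second difference over
  interior k. A curve that is non-decreasing, non-finite, or whose best
  bend is below 10% of the curve's total range carries no evidence of
  cluster structure; the smallest k is returned with a warning.
- **k-means**: Lloyd iterations under the chosen metric with k-means++
  seeding per replicate; L1 centroids are coordinate-wise medians,
  correlation/cosine centroids are normalized means; empty clusters are
  re-seeded at the farthest point.
- **Infomax ICA**: natural-gradient Infomax (minibatch, annealed learning
  rate) on internally whitened data; the logistic nonlinearity (default)
  suits the super-Gaussian sparse spatial maps of fMRI, and an extended
  variant with a kurtosis-sign switch handles sub-Gaussian sources. The
  converged unmixing matrix is symmetrically decorrelated — on whitened
  data the true unmixing is orthogonal — which makes recovered sources
  exactly uncorrelated and gives duplicated ICASSO runs a stability index
  of exactly 1. Component sign convention: the maximum-magnitude element
  of each map is positive, applied to the unmixing rows so maps and mixing
  stay consistent.
- **Group PCA** is computed by exact SVD; an EM accelerator would be a
  memory optimization, not a different estimator, and at the problem sizes
  this package targets the exact decomposition is cheap.
- **Signed modularity**: Q weights the positive within-module excess by
  total positive strength and the negative excess by total strength (the
  standard asymmetric signed formulation). Bipartitions come from the
  leading eigenvector of the signed modularity matrix followed by
  Kernighan–Lin refinement with incremental gain evaluation; more modules
  by recursive splitting while Q improves. An all-positive or all-zero
  matrix yields a single module, flagged as degenerate.
- **Despiking**: outliers are `|x - median| > 4 * 1.4826 * MAD`; flagged
  samples are replaced by a cubic spline through the clean samples, with
  nearest-clean-value replacement at the boundaries where a spline would
  extrapolate. Columns with more than half their samples flagged are
  replaced by the column median and reported.

## The synthetic cohort generator

The generator emulates exactly the statistical structure the pipeline
assumes: per subject, a Markov chain over k latent states (default stay
probability 0.99, i.e. mean dwell 100 TRs against a 22-TR window) selects
which of k SPD correlation matrices generates each timepoint's Gaussian
draw; group-specific effects add Fisher-z offsets on chosen edges in
chosen states (re-projected to SPD by eigenvalue clipping); artifacts are
layered on top — polynomial drift up to cubic, motion-coupled nuisance
signal driven by random-walk realignment parameters, and sporadic
heavy-tailed spikes (scaled Student-t, df = 2) to exercise the despiking
operator. Default run length is 206 timepoints at TR = 1.5 s (a 210-frame
acquisition minus 4 dummy frames).

States are drawn with factor structure (low-rank loadings plus a small
diagonal) and correlation-scaled, which guarantees positive definiteness
and strong, sign-varying connectivity patterns. A `separation` parameter
in (0, 1] controls how similar states are: state loadings mix a shared
base with fresh draws in proportion `1 - separation`, and candidate states
are rejected until all pairwise pattern correlations (absolute Pearson
correlation of the off-diagonal entries) stay below `1 - separation`.
Validation cohorts use separation 0.95 and 20 subjects of 400 timepoints —
the "well-separated, long-dwell" regime in which windowed clustering is
expected to work; the elbow criterion then picks k = 5 in at least 8 of 10
cohorts and two-stage clustering recovers planted window labels with
adjusted Rand index above 0.9.

What the generator does *not* emulate: hemodynamic convolution and
autocorrelation within states, spatial smoothness of the mixing maps
beyond sparse random supports, scanner-specific noise spectra, and
within-state non-stationarity. Passing tests therefore show that the
estimation and inference machinery is correct under the model's own
assumptions — not that those assumptions hold in any particular real
dataset.

Statistical validation of the group contrasts simulates subject state
centroids directly on the Fisher-z scale (between-subject SD 0.25, a
realistic magnitude for centroids averaged over tens of windows): the
1000-repeat null calibration and the planted-offset power checks test the
Welch-t/Benjamini–Hochberg machinery at a cost that permits that many
repeats.

## Problem sizes used in the shipped checks

Demographic statistics are exact arithmetic on the printed cohort table
(n = 61/60/38). State-selection and recovery checks use 20 subjects x 400
timepoints x 10 components per cohort (10 cohorts for the elbow, 3–5 for
recovery). ICA recovery uses 4 subjects, 500 voxels, 8 components. The
end-to-end reproducibility check runs the full pipeline twice on a 6
subject x 140 timepoint cohort; the default configuration (two groups of
20, T = 206, C = 10, full lambda cross-validation and k search) completes
in a few minutes on one CPU.

## Known limitations

- ICN identification by spectral criteria (low-frequency power fraction,
  dynamic range) is an automated surrogate for what is in practice a
  partly anatomical, partly visual curation step; the user keep-list is
  the intended channel for that knowledge.
- The elbow criterion is a heuristic; on cohorts without clear state
  structure its answer is arbitrary and the no-bend warning should be
  heeded.
- Transition-count comparisons use Welch t-tests on counts, which is a
  pragmatic choice, not a claim that counts are Gaussian; with the window
  counts involved (hundreds) the approximation is mild.
- Subjects that never visit a state contribute no centroid there and are
  excluded from that state's contrasts; the per-contrast subject counts
  are reported alongside the statistics.
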