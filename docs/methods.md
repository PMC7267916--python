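# Methods

This document describes the generative model behind the synthetic
cohorts, the analysis pipeline, parameter defaults, and the numerical
decisions embedded in the implementation.

## 1. Synthetic grayordinate space (`resttask.space`)

The spatial domain mimics a grayordinate system: two cortical
hemispheres plus subcortical structures.

- Each hemisphere is a set of points drawn uniformly on the unit sphere;
  the right hemisphere is the exact mirror image (x → −x) of the left,
  so vertex `i` on the left has homologue `mirror[i]` on the right.
- Surface adjacency is a symmetrised k-nearest-neighbour graph
  (default `k_neighbors=6`, roughly the valence of a triangulated
  surface mesh); disconnected components are bridged by their closest
  point pairs so each hemisphere is one connected graph.
- Subcortical structures are labelled groups of nodes
  (`nodes_per_structure=5`) without surface geometry; they carry their
  own signals and each forms its own parcel.

Defaults: 1000 vertices per hemisphere and 32 subcortical structures.

## 2. Cohort generator (`resttask.cohort`)

The generator emulates the statistical structure the analysis assumes
about multi-run resting-state fMRI, not the physics of the scanner: no
hemodynamic response function, no spatial noise correlations, no motion
or physiological artefacts, and a sphere rather than a folded cortical
sheet. What it does emulate, with known ground truth:

**Group networks.** K smooth Gaussian random fields are drawn per
hemisphere (angular-distance kernel; `smoothness=5` in units of the
typical nearest-neighbour spacing). Each vertex joins the field with the
largest value there provided it exceeds that field's
`sparsity_quantile=0.9` quantile (winner-take-all), giving K binary,
contiguous, mutually disjoint patches, scaled to unit SD. Right
hemisphere maps are the exact mirrors. The binary, disjoint design is a
deliberate numerical choice: per-vertex variance normalisation of the
time series then rescales every network uniformly, so dual regression
inverts the noiseless generative model exactly — a property used by the
recovery tests. Graded inter-subject structure comes from the subject
perturbation, not the group maps.

**Subjects.** Subject maps = group maps + `subject_variability=0.5` ×
independent smooth fields per network and hemisphere. Each of
`n_runs=4` runs of `n_timepoints=200` is (subject loadings)ᵀ × latent
AR(1) time courses (ρ=0.3, unit marginal variance; one course per
network per hemisphere and per subcortical structure) + white noise of
SD `ts_noise_sd=0.5`. The subject's *true feature matrix* is the
z-scored column set of their loading matrix (2K network maps + binary
structure indicators), F_true = 2K + n_structures.

**Task maps.** Per parcel `p`, the activation over its vertices is
`g(X_true) @ w_p + noise`, with `w_p` sparse (3 active features,
standard-normal weights) and `g` either the identity (linear link) or
`tanh(2x)` (saturating nonlinear link); the map is then z-scored over
vertices, matching the use of task z-maps as targets. `task_noise_sd`
defaults to 0.3.

All randomness descends from one seed through spawned streams;
`save_cohort`/`load_cohort` round-trip through HDF5, and
`regenerate_cohort` replays a manifest bitwise-identically.

Free knobs chosen for the synthetic regime (not derivable from the
analysis itself): `subject_variability=0.5` makes subjects clearly
distinct yet recognisably similar; `ts_noise_sd=0.5` is strong but
leaves group structure recoverable; `n_active=3` keeps the
feature→activation links sparse so both linear and nonlinear models are
identifiable at small cohort sizes.

## 3. Parcellation (`resttask.parcellation`)

Each hemisphere is tessellated into `n_per_hemisphere=50` random
geodesic Voronoi parcels: seeds drawn uniformly over vertices, every
vertex joining the seed with minimal unweighted graph-hop distance (ties
to the lower seed index, resolved deterministically by ring-ordered
multi-source BFS, which also keeps every parcel connected). Subcortical
structures are appended as one parcel each. Parcels carry no functional
meaning; they only localise the per-parcel regressions.

## 4. Feature extraction (`resttask.features`)

1. Each run is z-scored per vertex; constant vertices are flagged and
   zeroed.
2. Group PCA: exact SVD of all subjects' concatenated normalised runs
   (time × vertices); the retained representation is `s·Vᵗ` (spatial
   modes scaled by singular values), `target_dim=100` by default.
3. Spatial ICA per hemisphere (scikit-learn FastICA, `fun="cube"`,
   suited to sparse localised sources). Non-convergence triggers seeded
   retries with escalating tolerance (1e-3 × 10^(attempt/2)): the
   sources are coarse spatial maps, so 1e-2 precision is ample when
   1e-3 cycles. Maps are sign-fixed to non-negative skewness, unit-SD
   scaled, and ordered by mixing-column norm.
4. Symmetry filtering: right-hemisphere maps are brought into left
   vertex order through the mirror map and matched greedily to left
   maps by absolute spatial correlation; pairs scoring ≥ 0.5 are
   retained. This mirrors the observation that reliable networks are
   left/right symmetric, and it is what reduces K ICA components to the
   retained set.
5. Dual regression: stage 1 regresses the concatenated data on the
   retained group maps (time courses); stage 2 regresses each vertex's
   series on those courses (subject maps). Minimum-norm least squares
   with a rank-deficiency warning.
6. Final features: the subject's component maps plus binary subcortical
   indicator maps form a spatial design; regressing the data on it
   gives one course per feature, and each course is Pearson-correlated
   with every vertex's series. Degenerate vertices get 0. Columns are
   normalised to zero mean, unit SD. Feature count = 2 × retained + 
   n_structures (the reference configuration yields 2×34+32 = 100).

## 5. Models (`resttask.models`)

All three families share one interface: training rows are the stacked
(vertex, subject) pairs of the training subjects, one predictor is fit
per parcel, and predictions are reassembled into full maps.

- **GLM** — closed-form per-parcel least squares. A per-parcel
  intercept is fitted by default (stored separately; the coefficient
  matrix keeps its features × parcels shape). The intercept is a
  deliberate deviation from the plain pseudoinverse form: z-scoring the
  target maps introduces a per-map constant offset that is not in the
  span of the per-parcel features, and without the intercept the
  noiseless linear regime would not be exactly recoverable.
- **Neural network** — hand-written full-batch feed-forward net
  (1–3 tanh hidden layers, linear output, Glorot-uniform init) trained
  with iRprop−: per-weight step sizes grow ×1.2 while the gradient sign
  persists and halve (with the gradient forgotten) when it flips,
  making training insensitive to gradient magnitude. Rows are split
  60/20/20 into train/validation/test; the epoch with minimum
  validation MSE is kept (patience 6, hard epoch cap 1000) and the test
  MSE is recorded. Resilient backpropagation is implemented directly
  because no dependency-light library version exists and its update
  rule is the method under test.
- **Random-forest bagging** — scikit-learn `RandomForestRegressor`
  (bootstrap aggregation of regression trees with feature subsampling
  per split). Defaults follow the tuned reference configuration: 100
  trees, ⌊F/3⌋ predictors per split, minimum leaf 5.

`train_ensemble` fits M members differing only in their random seeds;
ensemble prediction is the arithmetic mean of member maps. The GLM is
deterministic, so its averaging curve is exactly flat.

## 6. Hyperparameter search (`resttask.tuning`)

A generic coordinate sweep minimises an objective one parameter at a
time in fixed order, freezing each at its minimiser: hidden size →
layer count → learning rate for the network (grids 1–50, 1–3,
0.001–0.1 step 0.002), and tree count → predictors per split → minimum
leaf for the forest (1–200, 1–F−1, 1–30). The sweep equals a full grid
search only for separable objectives — which is the assumption the
procedure makes, and what the oracle test checks. Scoring is RMSE on a
held-out 20% of the pooled hyperopt-subject rows, with optional seeded
row subsampling (default cap 5000 rows) to bound cost.

## 7. Evaluation (`resttask.evaluation`)

- **Prediction matrix**: entry (i, j) is the Pearson correlation of
  subject i's predicted map with subject j's actual map. Accuracy is
  the mean diagonal. `normalize_matrix` z-scores rows then columns.
- **Diagonal dominance**: permutation test of mean(diag) −
  mean(off-diag) under row permutations; p = (1 + #{≥ observed}) /
  (1 + B).
- **Mixture thresholding**: each z-map is modelled as a central
  Gaussian plus a positive and a mirrored negative gamma, fit by EM.
  The gamma locations are anchored at a robust centre (the median)
  rather than left free: free location parameters break the monotone
  log-likelihood guarantee of EM, while the fixed-anchor EM is monotone
  by construction; the anchor is then refined once to the fitted
  Gaussian mean and the EM re-run. A component whose responsibility
  mass collapses below 1e-4 is dropped and flagged (pure-Gaussian maps
  degrade gracefully to a two- or one-component fit). The activation
  threshold is the median of the fitted positive gamma; thresholded
  masks are compared with the Dice coefficient (two empty masks → 0).
- **Model comparison**: one-way repeated-measures ANOVA (statsmodels
  `AnovaRM`) over per-subject accuracies plus one-sided paired t-tests
  for each ordered contrast, Bonferroni-corrected by the number of
  pairwise tests. Identical score columns (a degenerate but reachable
  case) return F = 0, p = 1 instead of 0/0.
- **Curves**: accuracy vs number of training subjects and vs number of
  averaged models, on fixed test subjects.

## 8. Pipeline and reproducibility (`resttask.pipeline`)

Every stage seed is derived from one master seed by
`derive_seed(master, stage)` — SHA-256 of `"master:stage"` reduced
mod 2³¹ — so stages are independently reproducible and adding a stage
never perturbs the others. Subject splits (train/test/hyperopt) are
disjoint by construction and serialisable to YAML, as is the full
`ExperimentConfig`, whose hash is recorded in every artifact.

## 9. Limitations

- The synthetic cortex is a sphere with white temporal noise and
  mirror-exact homotopy; effect sizes are not calibrated to real fMRI,
  so only qualitative relations (exactness in the noiseless regime,
  diagonal dominance, nonlinear ≥ linear under a saturating link,
  monotone learning curves) transfer.
- Group ICA quality degrades with inter-subject variability (the group
  concatenation mixes subject-shifted versions of each network); the
  recovery guarantees are stated for the noiseless regime, and the
  estimated-feature pipeline is validated only through its downstream
  behaviour.
- The sequential hyperparameter sweep is a heuristic; it is only
  optimal for separable objectives.
- Per-parcel models ignore spatial continuity across parcel borders;
  predicted maps can be discontinuous there.
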