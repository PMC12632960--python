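# Methods

This note documents the models implemented in `reactage`, the parameter
choices that matter, what the synthetic generators do and do not emulate, and
the numerical conventions the results depend on.

## Dual regression (REACT)

The molecular-enrichment step treats K receptor-density templates as a
spatial design for the BOLD signal. With `Y ∈ ℝ^{T×V}` (time × in-mask
voxels) and `X₁ ∈ ℝ^{V×K}`:

1. **Stage 1.** For every time frame, the voxel vector (demeaned over the
   stage-1 mask) is regressed jointly on all K templates, standardized to
   zero mean / unit variance within that mask. The result `β̂₁ ∈ ℝ^{T×K}` is
   a per-target weight time series in BOLD-weighted units.
2. **Stage 2.** Every voxel's time series (demeaned over time) is regressed
   jointly on the column-standardized `β̂₁`, giving enriched connectivity
   maps `β̂₂ ∈ ℝ^{V×K}` in units of BOLD change per 1 SD of the weight time
   series.

Conventions and their consequences:

* **Joint fitting.** All K targets enter one design at both stages, so
  shared variance between spatially overlapping templates is partitioned by
  least squares rather than double-counted. Templates are chosen (and, in
  the synthetic generator, constructed) with pairwise voxel-wise |Pearson|
  ≤ 0.5 to keep the design well conditioned.
* **Standardization.** Because design columns are standardized within the
  analysis mask, `β̂₁` and `β̂₂` are invariant to affine rescaling of the raw
  templates; the [0, 1] min-max rescaling is a convention, not a modeling
  assumption. Both estimates scale linearly with the BOLD amplitude.
* **Masks.** Stage 1 runs on the intersection, over all targets, of template
  support (template > 0) with the gray-matter mask — a joint design needs a
  single voxel set; per-target support is recorded separately. Stage 2 runs
  on the gray-matter mask. An empty intersection for any target is an error
  naming the target.
* **Sample-size preconditions.** Stage 1 regresses across voxels frame by
  frame, so it requires more stage-1 voxels than K+1; stage 2 regresses
  across time, so it requires more frames than K+1.
* **Solver.** Least squares via LAPACK (`numpy.linalg.lstsq`); a design
  condition number above 1e6 raises a warning, exact rank deficiency is an
  error listing collinear targets when identifiable. Voxels are ordered
  row-major over the mask, and maps round-trip through NIfTI-1 exactly
  (zero-filled outside the mask).

Upstream preprocessing (motion correction, nuisance regression, filtering,
smoothing) and the preparation of real PET/SPECT templates are out of scope:
the pipeline consumes already-denoised BOLD or synthetic equivalents.

## Parcellation and feature blocks

Enriched maps are reduced to the arithmetic mean over each atlas ROI,
restricted to in-mask voxels (the maps exist only on gray matter). Label
images and maps must share one grid and affine; mismatches are an error —
no implicit resampling. Parcellation is linear in the maps.

The default atlas composition mirrors a three-source parcellation: 200
cortical parcels split over seven canonical networks, 15 subcortical and 32
cerebellar regions, 247 ROIs in total. Feature blocks: DAT / NET / SERT
(247 regional features each), MEF (stacked transporters, 741), SMF
(structural morphometry, 649), MMF (MEF‖SMF, 1390). Block sizes are
conserved for any atlas: |MEF| = K·R, |MMF| = |MEF| + |SMF|.

The structural block reproduces the composition of a FreeSurfer stats
export: 85 global/subcortical volumes, 2 hemispheres × 31 cortical regions
× 8 surface metrics (gray-matter volume, surface area, mean thickness,
thickness SD, folding index, mean/Gaussian curvature, curvature index), and
68 regional white-matter volumes. Each column carries (source stats file,
measure nature) metadata; the declared granularity — aseg×volume, each
hemisphere's aparc × {volume, area, thickness, folding, curvature},
wmparc×volume, 12 subgroups — defines the structural harmonization
subgroups, since the exact grouping is otherwise a free design choice.

A *common-parcellation* mode generates the structural block on the same
atlas as the functional features (one volumetric feature per ROI), so both
modalities carry identical parcel identifiers in their metadata; this
isolates parcellation mismatch when comparing multimodal configurations.
Computing real morphometry from images (FreeSurfer) and real image-quality
metrics (MRIQC) is out of scope; fixtures stand in for both.

**Quality screening.** A value is an outlier when it falls outside
[Q1 − 1.5·IQR, Q3 + 1.5·IQR], with quartiles computed by linear
interpolation (type-7) — the estimator is a convention and is used
consistently by implementation and tests. IQR = 0 yields no flags (the
fence collapses onto the shared value). Flags are invariant under adding a
constant and equivariant under positive scaling.

## ComBat harmonization

Per feature g, subject j in batch (site) i:

    x_ijg = α_g + X_j β_g + γ_ig + δ_ig ε_ijg,   ε ~ N(0, σ_g²)

Age (years, linear) and sex (0/1) form the covariate design `X`; their
effects are estimated on all data and re-added after adjustment, so
harmonization removes site effects without erasing biological signal.
Estimator conventions follow the standard reference implementations so that
results are directly comparable: batch-size-weighted grand mean
(sum-to-zero identifiability), pooled residual variance σ̂² = RSS/N,
per-batch location γ̂ = batch mean of standardized residuals, per-batch
scale δ̂² = unbiased batch variance.

* **CBI** uses γ̂, δ̂² directly (no borrowing across features).
* **CBE** shrinks them by parametric empirical Bayes — normal prior on γ,
  inverse-gamma on δ² — with method-of-moments hyperparameters estimated
  within each feature subgroup separately (transporter × parcel set;
  stats file × nature), so strength is borrowed only among features of the
  same kind. The conditional estimates are obtained by the standard
  iteration, stopped when the maximum relative parameter change is ≤ 1e-4
  (cap 100 iterations, logged per subgroup × batch). Adjusted subgroup
  matrices are recombined in the original column order.

Consequences of these conventions worth knowing: a single batch level is an
identity transform (nothing to remove); re-fitting on adjusted data finds
zero location effects and equal scale effects across batches, but the
refitted δ̂ equals N/(N−k) rather than exactly 1 because δ̂ is unbiased
while σ̂² pools over N — an inherent property of the reference estimators,
not a defect. Preconditions: ≥ 2 batches with ≥ 3 subjects each, covariates
not confounded with batch, no feature with zero within-batch variance.
Non-parametric priors and reference-batch mode are not implemented.
Harmonization is fitted on the full table before cross-validation, matching
the study workflow; fitting inside folds is a deliberate non-default
alternative left to the caller (apply `fit_combat`/`apply_combat` per fold).

## Brain-age protocol

* **Outer loop:** 10-fold CV repeated 10 times (100 outer models per
  configuration). Folds are age-stratified: ages are cut into
  `n_strat_bins` = `n_folds` quantile bins, subjects are shuffled within
  bins (seeded per repeat) and dealt round-robin with the dealing position
  carried across bins, so fold sizes differ by at most one and fold mean
  ages are tight. Folds are regenerated per repeat.
* **Scaling:** median/IQR (25th–75th, type-7) fitted on training rows only;
  IQR 0 → scale 1. Applied inside inner folds as well — no statistic ever
  sees held-out rows.
* **Model:** RBF-kernel SVR. Grid: C ∈ {0.1, 1, 10, 100},
  γ ∈ {0.1, 1, 10}/d (d = feature count), ε ∈ {0.1, 1, 2} years — chosen as
  a compact span of three orders of magnitude around scikit-learn's scale
  heuristic; all overridable in `CVConfig`. Inner selection: 5-fold CV
  scored by MAE; ties break toward the smallest C, then γ, then ε, making
  selection deterministic.
* **Metrics per test fold:** MAE, RMSE, Pearson r(y, ŷ),
  R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)², and age-bias ρ = Spearman(ŷ−y, y). Summaries
  follow the convention mean over all folds and repeats ± SD of the
  per-repeat means. Undefined correlations (constant inputs, e.g. a perfect
  predictor's zero errors) are reported as NaN, never silently 0.
* **Brain-age gap:** Δ = ŷ − y per subject, averaged over repeats; no
  post-hoc bias correction is applied (ρ is reported instead).

## Synthetic data: what it emulates, what it does not

All generators are pure functions of (config, seed); the same seed gives
bit-identical output. Feature values are in arbitrary units — no public
distributional description of the real features exists, so scales were
chosen once for plausibility (volumes ~2000±400, thicknesses ~2.5±0.25,
etc.) and are documented as arbitrary.

* **Templates** are Gaussian blobs at random in-mask centers, blurred and
  min-max rescaled; candidates are rejected until all pairwise correlations
  are ≤ 0.5. This is the simplest construction meeting the collinearity
  bound; it does not emulate realistic receptor topography.
* **BOLD runs** are the planted low-rank signal `ts · Zᵀ` (Z = templates
  standardized exactly as stage 1 standardizes them, on the joint stage-1
  mask) plus i.i.d. Gaussian voxel noise. With zero noise the dual
  regression recovers the planted time series and maps to machine
  precision — an algebraic identity that anchors the oracle tests. No
  hemodynamics, motion, physiological noise or temporal autocorrelation.
* **Cohorts** follow exactly the ComBat generative model (uniform ages over
  the configured range, Bernoulli(1/2) sex, per-site location/scale effects
  on Gaussian residuals), so harmonization parameter recovery is
  well-posed. Real site effects need not be location/scale; passing tests
  show correctness of the estimator, not adequacy of the model for any
  particular scanner difference.
* **IQM tables** plant gross outliers displaced 6–8 SD on one metric of
  each chosen row. Base variation is uniform with the stated SD (bounded at
  ±√3 SD), which keeps every unplanted value strictly inside the Tukey
  fences with a deterministic margin — Gaussian tails would produce ~0.7%
  legitimate fence-crossers and make exact planted-outlier recovery
  impossible. Consequently the fixture tests the flagging rule, not the
  base-rate behavior of real IQM distributions.

Because of these simplifications, passing the suite demonstrates that every
stage implements its model correctly and that the pipeline is leakage-free
and deterministic; it does not certify accuracy figures on real cohorts,
which depend on preprocessing, template fidelity and site idiosyncrasies
outside this package's scope.

## Problem sizes

Default verification sizes were chosen so the whole suite runs on a laptop
CPU: a 12³ voxel grid (~840 in-mask voxels, enough to host 247 non-empty
parcels), T = 40–200 frames, cohorts of 200–400 subjects, and 24-feature
tables for the repeated nested-CV runs (18,100 SVR fits per configuration).
The protocol itself (10×10×5-fold, 36-point grid) is the full-size one.

## Known limitations

* Parametric EB only; no reference-batch ComBat; no harmonization of
  covariate-free tables with confounded designs.
* SVR with a fixed small grid; no ensembles or deep models, and no
  bias-corrected brain-age variants.
* No resampling between grids; inputs must share one affine.
* The EB iteration inherits the reference implementations' relative-change
  stopping rule, including its sensitivity to near-zero per-feature location
  estimates (division by γ̂-old); subgroups are required to hold ≥ 2
  features for the moment estimators to exist, and many more in practice
  for stable priors.
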