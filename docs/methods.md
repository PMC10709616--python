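# Methods

This note documents the models and procedures `thoughtspace` implements,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## The analysis in one paragraph

Participants perform a sustained-attention task in the scanner (frequent
non-targets, rare targets) while multidimensional experience sampling
(mDES) probes interrupt vigilance periods and collect 13 ratings of ongoing
thought on a 1-10 scale. Probe-level PCA with varimax rotation reduces the
ratings to a small set of thought patterns; per-probe component scores feed
a six-EV first-level GLM (vigilance, target detection, a 6-s pre-probe
window, and three parametric thought regressors) whose subject-level z-stat
contrast maps are located in a 5-d "neural state space": each map's
Spearman rank correlation with five macroscale connectivity gradients gives
five coordinates in [-1, 1]. Linear mixed models compare the coordinates of
task states per dimension, multiple regressions relate coordinates and
scores to response times, and a cluster bootstrap supplies robustness
checks.

## Experience-sampling PCA (`mdes`)

- **Correlation-matrix PCA.** Items are z-scored (mean/sd with ddof=1)
  before eigendecomposition, so a 1-10 item with large variance cannot
  dominate. Loadings are eigenvectors scaled by the square root of their
  eigenvalues (item-component correlations).
- **Varimax** uses Kaiser row-normalization, tolerance 1e-6, at most 100
  sweeps (the SVD formulation). The rotation is orthogonal, so per-item
  communalities and the total retained variance are invariant; both are
  asserted in tests. The implementation reproduces R's `stats::varimax`
  elementwise to ~1e-10 on a frozen fixture.
- **Retention is fixed at k=3** by configuration; an eigenvalue>1 helper
  (`kaiser_count`) exists but no automated rule is applied.
- **Sign and order conventions.** Components are ordered by descending
  rotated variance; each column is signed so its largest-|loading| item is
  positive. This makes loadings and downstream word-cloud-style outputs
  reproducible.
- **Scoring** is the literal dot product of standardized items with the
  rotated loadings (not regression-based factor scores). Projection of an
  external dataset uses the *training* item means/sds — never the external
  set's — which is what makes scores comparable across datasets.
- **ICC.** Run-wise consistency of a component is the two-way
  mixed-effects, consistency-type, single-measure ICC (ICC3 in the
  Shrout-Fleiss taxonomy) computed on per-run participant means, via
  pingouin. Participants missing a run are excluded (logged). ICC(3,1) was
  chosen because the runs are the only "raters" of interest and systematic
  run effects (fatigue, habituation) should not count against consistency.

## First-level GLM (`glm`)

- **HRF**: gamma density with mean lag 6 s and sd 3 s (shape 4, scale
  1.5 s), sampled at the TR over >= 32 s and normalized to unit sum.
- **Design**: EV1/EV2 are boxcars over non-target/target trials (fractional
  TR occupancy); EV3 is a unit boxcar over the pre-probe window, snapped to
  whole volumes (2 volumes at TR 3 s) ending at the volume containing the
  probe onset; EV4-EV6 are the same support scaled by each probe's
  component score, mean-centered within run. Snapping makes the parametric
  EVs exactly orthogonal to EV3 before convolution (asserted to 1e-10).
  The 13 rating screens themselves are unmodeled; they occupy scheduled
  time only. Confounds enter unconvolved and are excluded from contrasts.
- **Centering is applied to the per-probe scores before multiplication**
  with the window boxcar (volume-level centering after multiplication is
  the other defensible reading; per-probe centering keeps "equal scores →
  zero regressor" exact).
- **High-pass filter**: Gaussian-weighted running-line fit (weight sd =
  sigma, default 50 s) subtracted at each timepoint. It removes any global
  linear trend exactly and passes a 20-s oscillation with <10% attenuation.
- **Estimation** is plain OLS per parcel; t statistics convert to z by
  exact two-sided tail matching (no large-dof shortcut). No prewhitening by
  default — the simulator's noise is white — but an AR(1) Cochrane-Orcutt
  flag exists for colored noise. Run-level results combine within subject
  by inverse-variance (fixed-effects) averaging; the combined z treats the
  precision-weighted estimate as normal.

## State-space coordinates (`statespace`)

- Coordinates are Spearman correlations between a parcel map and each
  gradient, aligned by parcel id (never order), average ranks for ties,
  pairwise-complete over shared parcels (>= 3 required; missing count
  logged). Coordinates are invariant under strictly increasing transforms
  of the map and under parcel permutation — both property-tested.
- Computation is parcelwise. A voxel path exists through the NIfTI reader
  (voxels collapse to atlas parcels first).
- Network summaries average a map (or a gradient) within each of the 7
  canonical networks; the standardized variant z-scores the 7 means
  (population sd) for radar-style comparison across maps on different
  scales. Empty networks are reported missing, never as zero.

## Inference (`infer`)

All models share four conventions: REML estimation, sum-to-zero factor
coding (intercept = grand mean; a 2-level factor's coefficient is half the
level difference), type-3 F tests with Satterthwaite denominator df, and
marginal means at covariate means. The engine covers the random-intercept
case — the only random structure these analyses use.

- **REML** profiles the residual variance out of the criterion and
  optimizes the variance ratio on a bounded interval. A ratio on the zero
  boundary is flagged as a singular fit; results are still returned, and
  contrast df then fall back to the residual df.
- **Satterthwaite df** follow the lmerTest recipe: eigendecompose the
  contrast covariance, compute per-direction df by the delta method
  (finite-difference gradient of the contrast variance over the two
  variance parameters; parameter covariance from the numerical REML
  information), and combine. On an unbalanced fixture the engine matches R
  `lmerTest` F, denominator df, coefficients, and variance components to
  ~4 decimals, and on balanced 2-level data the type-3 F equals the paired
  t-test's t² to 1e-6.
- **Marginal means** set the factor of interest to each level, average the
  other factors out (their sum codes average to zero), and hold continuous
  covariates at their means. Gender enters as a sum-coded factor; age and
  mean movement are standardized before entry (this stabilizes the
  bootstrap and makes covariates-at-zero the covariate mean).
- **Bootstrap** resamples participants (clusters) whole, with replacement,
  keeping the cluster count; percentile 95% CIs; the two-sided P value is
  twice the smaller sign share, floored at 2/n_iter. Degenerate resamples
  (one distinct cluster, or a lost factor level) are redrawn and counted.
  Cluster resampling was chosen over row resampling because rows within a
  participant are exchangeable only conditionally on the random intercept.
- **RT regressions** are OLS with the same design machinery (exact residual
  df). The outlier rule runs first: rows with |z-scored RT| > 2.5 have the
  z set to zero (not dropped), and the count is reported.
- **The state-by-network model** fits per-subject network means with
  state, network, and state x network fixed effects plus a participant
  intercept; pairwise state contrasts within each network are
  Bonferroni-corrected for the 7 networks.
- **Multiple-model families** use alpha = 0.05 / number of models.

## Synthetic cohorts (`synth`)

The generator reproduces the *statistical structure* the analysis assumes,
with known ground truth:

- **Gradients**: smooth 1-d random fields over the parcel index, iterated
  Gram-Schmidt on rank vectors until all pairwise |Spearman| < 0.01. Each
  parcel gets one of 7 network labels from the gradient pole it is most
  extreme on (poles share networks the way real gradients' poles do), with
  the least extreme 15% labeled limbic — so every gradient's extremes are
  network-coherent, as with real gradients.
- **mDES ratings**: per probe, a latent 3-vector = participant trait mean
  (sd 0.8) + standard-normal probe deviation; ratings are
  5.5 + 1.5 x (loadings x latent + item noise), clipped to [1, 10]. The
  trait component gives run-wise ICCs in the 0.7-0.85 range at default
  noise (the clipped fraction is reported and stays <5%). Correlation-matrix
  PCA standardizes items, so recovery checks compare against the planted
  loadings rescaled to the standardized-item metric.
- **Task runs**: trials fixed at 3 s with 1.5-2.5 s jittered ISIs, 20%
  targets in expectation, 8 probe blocks (13 screens x 4.5 s) per run of
  267 volumes at TR 3 s. Probes land only after trial 2 so the 6-s window
  fits; trials overlapping a pre-probe window are forced non-target
  (probes occur in vigilance periods) and the target probability of the
  remaining trials is raised so the overall rate stays 20% in expectation.
  The trial count per run is configurable (default 48, chosen so the
  default schedule fits the run with slack). Timeseries are built through
  the same design code the GLM uses — the design-construction logic itself
  is validated against a literal per-volume oracle, so this shared path is
  a deliberate identifiability check, not a circular test.
- **Brain maps**: planted mixtures of standardized gradients plus Gaussian
  parcel noise, with optional per-subject jitter of the mixing weights
  (between-subject coordinate variability).
- **Not emulated**: voxel-level structure, spatial autocorrelation within
  parcels, motion beyond a scalar covariate, physiological noise spectra,
  rating-scale discreteness, and any true coupling between the mDES latents
  and the brain maps (conditions are planted independently). Passing tests
  therefore certify the *estimators* — recovery, calibration, invariances —
  not the neurobiology of real data.

## Problem sizes and numerical choices

Simulated checks run at the study's scale where that is cheap (1456-probe
PCA, 57-subject mixed models, 400 parcels, 267 volumes) and at reduced
replicate counts where full Monte Carlo would be wasteful: type-I error
uses 1000 replicates, bootstrap coverage 60 outer replicates at n_iter=200,
end-to-end recovery 20 seeds. Variance-ratio optimization tolerance is
1e-10; Hessian steps scale with eps^(1/4) of the parameter; rank-deficient
designs and degenerate inputs (constant maps, zero-variance items, empty
networks, null contrasts) raise explicit signals rather than propagating
NaN.

## Known limitations

- The mixed-model engine supports a single random intercept, not slopes or
  crossed factors.
- Type-3 tests are computed from sum-coded model matrices; with severe
  imbalance their usual caveats apply.
- The GLM path has no slice-timing, motion, or registration model; it
  consumes parcel timeseries as given.
- Satterthwaite df at a singular boundary fall back to residual df, which
  is mildly liberal when the true variance is small but nonzero.
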