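# Methods

## Model and procedure

The pipeline performs two-group voxel-wise classification on registered
scalar diffusion maps. Its statistical core is a soft-margin linear SVM on
Fisher-score-selected voxel features, wrapped in a *nested* leave-one-out
cross-validation (LOOCV): with n subjects, each fold holds out one subject
and recomputes every training-derived quantity — Fisher scores, the feature
ranking, the top-k selection, the per-feature standardiser and the SVM —
from the other n − 1 subjects. The held-out subject only ever passes
through transforms fitted without it, so the reported accuracy is free of
selection and scaling leakage. This contract is enforced by construction
(`loocv._run_fold` sees a training index set) and asserted by tests that
perturb only the held-out volume and require bit-identical fold models.

Assumptions worth stating explicitly:

- Volumes are already registered to a common grid; no spatial normalisation
  is performed here. Misregistration shows up as noise, not as an error.
- Features are raw voxel values inside one analysis mask; voxels are
  treated exchangeably (no spatial model beyond the input smoothing).
- The two groups are coded control = +1, patient = −1, so a positive
  decision value reads "control"; a decision value of exactly zero is
  assigned to the patient group.
- C is fixed at 1. The method deliberately has no hyperparameter search;
  the only swept quantity is the feature count k.

## Parameters

| parameter | units | default | rationale |
|---|---|---|---|
| `mask_threshold` | FA | 0.2 | voxels enter the analysis when the across-subject mean exceeds it; 0.2 is the conventional white-matter cut for FA analyses |
| `fwhm` | mm | 6 | isotropic Gaussian smoothing applied to registered maps; σ = fwhm/(2√(2 ln 2)) per axis in voxel units |
| `C` | — | 1 | soft-margin penalty, fixed by design |
| `step`, `k_max` | features | 100, 20 000 | feature-count grid {step, …, k_max}; 200 points at the study scale. When the mask holds fewer than `k_max` voxels the grid truncates at m |
| `fraction` | — | 0.10 | per-sign map threshold (fraction of the positive maximum for positive voxels, of the negative minimum for negative voxels) |
| `min_size` | voxels | 20 | cluster-size filter, inclusive |
| `connectivity` | — | 26 | 3-D cluster connectivity (6/18/26 selectable) |
| `n_perm` | — | 10 000 | label permutations for the accuracy null |

## Synthetic cohorts

`generate_cohort` emulates a two-group FA study: per subject, a constant
baseline (default 0.5 FA) plus i.i.d. Gaussian voxel noise (default sd
0.05) is smoothed at 6 mm FWHM — yielding the spatially correlated noise
characteristic of smoothed FA maps — after which each patient receives the
planted effects: spheres of constant signed delta, scaled by a per-patient
severity multiplier ~ U(0.8, 1.2), and values are clipped to [0, 1].
Default group sizes are 26 controls vs 22 patients on a 32³ grid of 2 mm
voxels. The patient clinical score is 70 − 30 × multiplier + N(0, 3²),
i.e. ≈ 40 ± 4.6 with higher scores for milder disease, emulating an
ALSFRS-R-like severity scale; because the same multiplier scales the FA
effect, the score is positively associated with the classifier's decision
value by construction. All randomness derives from one seed through
per-subject spawned streams, so cohorts are bit-reproducible and
generation order cannot drift.

The multiplier's narrow range is a considered choice: it makes severity
(and hence the score correlation) recoverable while keeping the planted
contrast within 20 % of delta, so cohorts generated with delta well above
the noise sd remain essentially separable. A wider severity spread would
make the mildest patients genuinely ambiguous at small n — a realistic
regime, but not the controlled one the recovery tests need.

What the generator does *not* emulate: diffusion physics, anatomy
(effects are spheres, not tracts), registration error, scanner/site
effects, age/sex confounds, or lesion heterogeneity beyond the scalar
multiplier. Passing recovery tests therefore demonstrates the *pipeline's*
correctness — ranking finds the planted voxels, the SVM separates the
groups, the map localises the plant — not that real ALS cohorts are
separable at these accuracies.

## Numerical choices

- **Feature ↔ voxel correspondence.** The mask's index map enumerates
  in-mask voxels in C scan order (ascending coordinates, last axis
  fastest); all rankings break ties by ascending feature index, so results
  are platform-independent.
- **Degenerate Fisher scores.** Zero within-group variance with equal
  group means scores 0; with unequal means it scores +∞ and ranks first (a
  within-group-constant, between-group-separated feature is maximally
  discriminative — the limit of the score's definition).
- **Standardisation.** "Centering and normalisation" is implemented as
  z-scoring with training-fold statistics; sample sds are floored at 1e−8
  so constant columns map to 0 rather than NaN. Unit range or unit norm
  would also be defensible readings; unit variance is the declared choice.
- **SVM solver.** The dual is solved by libsvm (via scikit-learn's
  binding), stopping tolerance 1e−8 with a deterministic fallback to 1e−6
  for the rare degenerate instances on which libsvm cycles at the tighter
  tolerance (iteration cap 100 000 per attempt). The returned multipliers
  satisfy the KKT conditions and match an independent quadratic-programming
  oracle to 1e−6 in tests. The bias is libsvm's, i.e. derived from the
  margin support vectors' KKT interval. Identical input gives an identical
  model.
- **Plateau-midpoint rule.** "Pick the middle of the best plateau" is
  formalised as: longest contiguous accuracy-maximal run of the k grid,
  earliest run on ties, midpoint in k-space snapped down to the grid. This
  makes the selection total and deterministic (e.g. a maximal run spanning
  1 400–3 400 on a step-100 grid yields 2 400; a run {100, 200} yields 100).
- **Weight map.** Fold weight vectors are averaged after scattering to the
  full in-mask feature space (voxels a fold did not select contribute 0),
  because fold feature sets differ slightly; the average is taken in the
  standardised feature space in which the weights were learned, so the map
  reads as standardised-FA discriminability. Un-scaling would mix
  fold-specific scalers without changing the sign interpretation.
- **Per-sign map threshold.** Thresholding at a fraction of the *global*
  absolute maximum would let one strong sign suppress all clusters of the
  other; each sign is therefore thresholded against its own extremum,
  which preserves weak-but-consistent clusters of both directions.
- **Permutation test.** Labels are shuffled over the whole cohort and the
  complete nested LOOCV is re-run at the fixed working k (re-running the
  entire 200-point sweep per permutation is statistically stricter but
  ~200× the cost; the fixed-k variant matches how the observed accuracy at
  the chosen k is actually assessed). Both the count/N p-value (which can
  be exactly 0) and the (count+1)/(N+1) estimator are reported. The
  permutation RNG is seeded independently of cohort generation.
- **Spearman correlation** uses mid-ranks for ties and the large-sample t
  approximation for p; it is computed over patients only, since controls
  carry no severity score.

## Problem sizes used in the test suite

Unit and property tests run on 8³–16³ grids with 8–24 subjects. The
end-to-end recovery test uses the full study geometry (24 + 24 subjects,
32³ grid, one 33-voxel planted sphere at 10× the noise sd). The
permutation-calibration experiment uses 200 effect-free cohorts of 16
subjects with 200 permutations each on an 8³ grid with k = 64 — small
enough to repeat hundreds of times, large enough that the LOOCV/permutation
machinery runs exactly as at full scale. These sizes are the package's own
validation design; nothing in the implementation depends on them.

## Known limitations

- LOOCV accuracy on small cohorts has high variance, and under the null
  its folds are negatively correlated; the permutation test — not the
  sweep's maximum — is the inferential guard.
- The permutation p-value at the *selected* k does not account for the
  selection of k itself; a full-sweep permutation would, at much higher
  cost.
- Fisher scores evaluate features marginally; jointly informative but
  marginally weak voxel pairs rank low by design.
- AUC confidence intervals (e.g. DeLong) and exact small-sample Spearman
  p-values are out of scope.
- Cluster reports carry voxel coordinates (plus world coordinates when an
  affine is present); anatomical labelling is out of scope.
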