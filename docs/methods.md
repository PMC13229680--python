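# Methods

`leafspec` estimates leaf chlorophyll content from hyperspectral
reflectance (400–1000 nm) under small-sample conditions. Its two core
ingredients are (i) physically constrained spectral augmentation of the
training set and (ii) a convex-weighted heterogeneous ensemble of three
base regressors. This note records the model, the parameters that matter,
the numerical choices, and what the synthetic test bed does and does not
demonstrate.

## Problem setting and data model

The supervised unit is a pair (reflectance spectrum, chlorophyll reference
value). Spectra live on a shared, strictly increasing wavelength axis in
nm; reflectance is unitless in roughly [0, 1]; the chlorophyll label is a
continuous, unit-agnostic real (wet-chemistry reference scales differ
between campaigns, so the package never assumes a unit). Matching between
a label table and a spectra table is exact string identity after
whitespace stripping — no fuzzy matching — and rows are ordered by sorted
identifier before the seeded 70/30 split so that membership depends only
on (identifiers, seed), never on file row order. The training size is
`floor(n * fraction + 0.5)`; at the reference scale n = 1113 and fraction
0.7 this gives 779/334.

Band trimming uses a closed interval: `trim_bands(ds, 400, 1000)` keeps
every wavelength λ with 400 ≤ λ ≤ 1000.

## Preprocessing

Smoothing is a centered moving average counted in bands (default window
63), chosen as a compromise between suppressing high-frequency noise and
preserving the chlorophyll absorption and red-edge structure near
670–750 nm. At the spectrum ends the window truncates to the available
bands (a shrinking window): this preserves length and fabricates no
reflectance outside the measured range. The operator is linear and never
leaves the input's range, both of which are asserted as property tests.

Diagnostics are descriptive: per-band Pearson correlation with the label
(zero-variance bands are flagged NaN, not silently zeroed), tertile
stratification into low/medium/high chlorophyll levels (ties broken by
identifier; group sizes differ by at most one), and a PCA split check
whose basis is fit on the training rows only, with validation projected
into it. The PCA view is a coverage check, not evidence that the partition
is unbiased.

## Augmentation operators

Two perturbations expand the training distribution while staying
physiologically plausible:

* **Additive Gaussian noise.** i.i.d. N(0, σ²) per band, σ in reflectance
  units, searched over 0.001–0.008. No clipping is applied afterwards:
  at σ ≤ 0.008 negative reflectance is vanishingly rare on leaf spectra,
  and values below −0.05 trigger a warning rather than silent repair.
* **Smooth wavelength warping.** A displacement field d(λ) built from 4
  interior anchors with displacements drawn Uniform(−m·span, +m·span),
  endpoints pinned to zero, interpolated by a natural cubic spline. The
  magnitude m (searched over 0.01–0.07) is interpreted as the maximum
  displacement as a fraction of the modeled span, so m = 0.07 allows at
  most 42 nm of drift on a 600 nm axis. If the spline overshoots the bound
  or the remap λ ↦ λ + d(λ) loses monotonicity, the whole field is
  rescaled by the largest admissible factor, computed in closed form from
  the per-interval remap differences. Spectra are resampled at the warped
  wavelengths by linear interpolation, clamped at the axis ends.

  Warping magnitude could plausibly be read as a band-index shift or an
  amplitude modulation instead; the fractional-wavelength reading is this
  package's choice because it is smooth, bounded, monotone and scales with
  the modeled range.

The composite operator applies warping first, then noise: shape drift
happens before the sensor, and adding noise last keeps its spectrum white.
Each sample receives its own fresh warp field — a shared field would make
the perturbations of all samples perfectly correlated, which is not what
instrument or sample-state variation looks like.

`build_augmented_training_set` doubles the training set exactly (one
variant per original), copies labels verbatim, and records
(mode, parent id) provenance. It refuses input that already contains
augmented rows, so perturbations can never compound, and it is only ever
applied to the training partition — the parent of every variant is
therefore a training sample by construction, which the test suite asserts
across 50 random split seeds.

## Base learners

Three regressors with complementary inductive biases sit behind one
fit/predict contract:

* **latent_linear** — partial least squares regression (scikit-learn
  NIPALS). Components maximize spectrum–target covariance; suited to
  hundreds of collinear bands. `scale=False`: bands share units, so X and
  y are centered but not variance-scaled.
* **ridge_linear** — L2-penalized linear regression (scikit-learn Ridge,
  with intercept), the stable linear baseline under multicollinearity.
  Its coefficients are verified against the closed form
  (XᶜᵀXᶜ + αI)⁻¹Xᶜᵀyᶜ.
* **boosted_trees** — gradient-boosted regression trees (XGBoost,
  squared-error objective, `tree_method="hist"`). Tree boosting is a
  commodity component here, not a contribution, so it is delegated. The
  estimator uses `max_bin=64`: reflectance is smooth and bounded, so 64
  histogram bins lose nothing measurable while cutting fit time roughly
  fourfold on 601-band spectra.

Interpretability: PLS VIP scores
(VIP_j = sqrt(p · Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a), with SSY_a from
the regression of y on the component scores; Σ_j VIP_j² = p identically),
ridge |coefficients|, and gain-based tree importances, all mapped back to
physical wavelengths with deterministic tie-breaking.

## Tuning and ensembling

Each learner's hyperparameters maximize the mean R² over 5-fold
cross-validation on the (augmented) training set. The fold partition is
derived from the experiment seed and shared across every candidate, so
objective values are paired. The search itself is a seeded random search
over bounded dimensions (log-scaled where spans are multiplicative,
integers by rounding the continuous proposal), 30 trials per learner. Any
bounded black-box optimizer satisfies this contract; random search was
chosen because it is transparent, trivially reproducible, and adequate for
the 1–5-dimensional spaces involved. Default spaces:

| learner | dimension | range | scale |
|---|---|---|---|
| latent_linear | n_components | 1 … min(30, p, ⌊2n/3⌋−1) | int |
| ridge_linear | alpha | 1e-4 … 1e3 | log |
| boosted_trees | n_estimators | 50 … 300 | int |
| | max_depth | 2 … 6 | int |
| | learning_rate | 0.02 … 0.3 | log |
| | subsample | 0.5 … 1.0 | linear |
| | colsample | 0.3 … 0.9 | linear |

The PLS cap subtracts the cross-validation shrinkage (only ~(k−1)/k of
rows are fitted inside a fold). The boosted-tree ranges reflect what
small-n, highly collinear spectra support: deeper or longer boosters
overfit long before they pay for their cost.

The ensemble prediction is ŷ = Σ_m w_m ŷ_m with w_m ≥ 0 and Σ w_m = 1.
Weights are calibrated by minimizing the 3-fold cross-validated MSE of the
combined out-of-fold predictions on the training set. Base learners are
refit inside each fold, so held-out targets never influence the
predictions being weighted. Out-of-fold prediction columns are computed
once; every weight candidate is then evaluated in microseconds. The search
runs in two free coordinates (a, b) ∈ [0,1]² mapped onto the simplex as
(a, b(1−a), (1−a)(1−b)); the three vertices and the uniform point are
always evaluated first, then 40 seeded random candidates, then a
Nelder–Mead polish of the incumbent. Vertex seeding guarantees the
calibrated ensemble's CV MSE never exceeds the best single learner's.

## Experiment harness

`run_baseline` and `run_augmentation_grid` produce tidy tables of
(setting, model) → train/validation R²/RMSE. Default grids: noise
0.001–0.008 in steps of 0.001 (8 settings), warp 0.01–0.07 in steps of
0.01 (7 settings), and the 16 composite combinations
{0.001–0.004} × {0.01, 0.015, 0.02, 0.025}. Hyperparameters are re-tuned
per setting by default (each setting is its own experiment);
`reuse_tuning` tunes once on the un-augmented originals and reuses those
specs, the cheaper protocol for large sweeps. The zero-perturbation
setting runs the identical no-augmentation code path as the baseline:
doubling a training set with bitwise duplicates would silently change fold
contents, so "identity augmentation" is defined as "no augmentation", and
the equality is asserted bitwise in the tests.

R² is 1 − SS_res/SS_tot with SS_tot taken about the mean of the split
being evaluated; RMSE is in label units. Residual analysis reports
residuals (observed − predicted), a Gaussian-kernel density with Silverman
bandwidth on a fixed padded grid (a constant residual vector degenerates
to a unit spike marker), and per-tertile mean residuals, which expose the
high-range compression typical of shrinkage-dominated linear fits.
`sample_size_curve` repeats the pipeline on nested training subsets across
seeds and reports mean ± sd validation RMSE per model.

## Synthetic generator

The generator is phenomenological, not radiative-transfer: a logistic red
edge whose inflection is λ_re = 690 + 0.5·chl (nm), a green reflectance
peak at 550 nm whose amplitude 0.15·exp(−chl/40) shrinks with increasing
chlorophyll, an NIR plateau at ~0.5 reflectance, a Gaussian water-
absorption dip at 975 nm of depth 0.06, multiplicative log-normal
brightness (sd 0.05), additive per-band Gaussian noise (sd 0.003), and
clipping to [0, 1]. Chlorophyll is uniform on (10, 70), unit-agnostic; the
label equals the true chlorophyll unless a label-noise term is enabled.
Defaults: n = 1000 samples, 400–1000 nm at 1 nm (601 bands).

This structure gives the tests exactly what they need — monotone,
localized, physiologically ordered features with known ground truth
(including each sample's true red-edge position) — and no more. Passing
on it shows the pipeline recovers a recoverable signal, honors its
leakage, determinism and simplex contracts, and tracks the red edge; it
does not show field-data accuracy, instrument transfer, or robustness to
canopy/soil effects, none of which the generator emulates.

## Red-edge estimator

First derivative by central differences on the nm axis (one-sided at the
ends; exact for affine spectra, and for quadratics at interior points),
then the argmax of the derivative within a 680–760 nm window, ties broken
toward the longer wavelength. Max-first-derivative is the standard
estimator choice and is recorded in the output metadata; fitted-inflection
variants (Gaussian, four-point interpolation) are deliberately out of
scope. A result on the window boundary (no red edge in view) is flagged
rather than silently returned. On a 1 nm grid the estimate is exact to
±1 nm; samples whose true positions differ by less than the grid step can
land on the same band, so rank-correlation checks use chlorophyll values
spaced 2 units apart (distinct true bands).

## Problem sizes and determinism

The test suite and the acceptance script run the full pipeline at
n = 1000 (the generator's default study condition, 30 tuning trials) and
grid sweeps at n = 300 with a shared tuning pass; unit and property tests
use 20–200-sample problems. All randomness flows from explicit integer
seeds through `numpy.random.default_rng`, XGBoost's `random_state` and
scikit-learn's `KFold`; identical seeds give bitwise-identical splits,
augmented sets, trial logs and metrics, which several tests assert.

## Known limitations

* Absolute performance on real leaf datasets is out of reach of the
  synthetic bed; results here validate mechanism, not field accuracy.
* On the synthetic bed, wavelength warping cannot be benefit-neutral: the
  generator's red-edge position is a deterministic function of the label,
  so warping a spectrum while copying its label perturbs the very feature
  that encodes the target — measured, composite augmentation roughly
  doubles validation RMSE there, while noise-only augmentation is
  neutral-to-beneficial. On real spectra the position–chlorophyll map is
  itself noisy and warping can compensate genuine acquisition drift; the
  suite therefore asserts the no-hurt trend for the noise operator only,
  and treats warp benefit as a property of real data that synthetic
  evidence can neither confirm nor refute.
* The warping parameterization is one defensible reading of "smooth
  wavelength warping"; others (band-index shifts, amplitude warps) exist.
* The weight calibration reuses one out-of-fold prediction matrix per
  seed rather than refitting per weight candidate; this is exact for the
  CV-MSE objective but, like any single-split protocol, is not an
  unbiased estimate of generalization error (no nested CV).
* Labels are treated as noise-free; reference-measurement error can be
  simulated via the generator's label-noise term but is off by default.
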