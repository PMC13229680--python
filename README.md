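# leafspec

Small-sample hyperspectral estimation of leaf chlorophyll content:
physically constrained spectral augmentation feeding a tuned,
convex-weighted heterogeneous ensemble.

## The problem

Chlorophyll content is the workhorse indicator of plant nitrogen status
and photosynthetic capacity, and leaf reflectance in the 400–1000 nm
range carries its signature: strong visible absorption, a red-edge
transition near 680–760 nm that shifts longward as chlorophyll rises, and
an NIR plateau. Regressing chlorophyll on hundreds of collinear
reflectance bands from a few hundred labelled leaves is, however,
fragile: measurement noise, calibration drift, and single-model variance
all bite hardest exactly when samples are scarce.

`leafspec` addresses this with two complementary levers, for
phenotyping and chemometrics practitioners who work from delimited
spectrum/label tables:

1. **Augmentation as input-space regularization.** The training set (and
   only the training set) is doubled with physically plausible variants:
   additive Gaussian noise R′ = R + ε, ε ~ N(0, σ²) per band
   (σ ∈ 0.001–0.008), and smooth wavelength warping R′(λ) = R(λ + d(λ))
   where d is a smooth, endpoint-pinned, monotone displacement field with
   |d| ≤ m · span (m ∈ 0.01–0.07). Labels are copied from parents, and
   lineage is recorded so no variant of a validation sample can ever
   reach training.

2. **A convex-weighted heterogeneous ensemble.** Three base learners with
   different inductive biases — partial least squares (latent covariance
   structure), ridge regression (stable linear shrinkage) and
   gradient-boosted trees (nonlinearity and interactions) — are each
   tuned by maximizing the mean 5-fold cross-validated R² on the training
   set (30 trials over bounded spaces), then combined as

   ŷ = Σₘ wₘ ŷₘ,  wₘ ≥ 0,  Σₘ wₘ = 1,

   with w calibrated against 3-fold cross-validated MSE over the simplex.
   The simplex vertices are always evaluated, so the ensemble never loses
   to its best member on the calibration objective.

A synthetic leaf-spectrum generator with known ground truth (logistic red
edge at λ_re = 690 + 0.5·chl nm, chlorophyll-dependent green peak, NIR
plateau, 975 nm water dip) makes every stage verifiable without
downloading data. See `docs/methods.md` for the full model description.

## Worked example

```python
import leafspec as ls

config = ls.SyntheticConfig(n_samples=300, seed=7)
dataset, truth = ls.generate_dataset(config)
smoothed = ls.smooth_dataset(dataset, window=63)
train, val = ls.split_dataset(smoothed, train_fraction=0.7, seed=42)

augment = ls.AugmentConfig(mode="composite", noise_sigma=0.002,
                           warp_magnitude=0.02, seed=42)
model = ls.EnsembleRegression(train, augment=augment, n_trials=10, seed=42)
results = model.fit()
results.evaluate(val, "val")
print(results.summary())
```

prints

```
Convex-weighted ensemble regression
============================================================
training rows: 420 (augmentation: composite, sigma=0.002, warp=0.02)
bands: 601 (400-1000 nm)

Ensemble weights (3-fold CV-MSE calibrated, cv_mse=2.9411):
  boosted_trees   w = 0.7850
  latent_linear   w = 0.2150
  ridge_linear    w = 0.0000

Tuned base learners:
  boosted_trees   n_estimators=251, max_depth=4, learning_rate=0.04366, subsample=0.8412, colsample=0.3839  (cv R^2 = 0.9909)
  latent_linear   n_components=5  (cv R^2 = 0.9700)
  ridge_linear    alpha=0.1181  (cv R^2 = 0.9698)

Metrics on 'val':
  model                R^2       RMSE
  boosted_trees     0.9916     1.5258
  latent_linear     0.9743     2.6728
  ridge_linear      0.9751     2.6307
  ensemble          0.9932     1.3779
```

Reading the output: the 210 training originals were doubled to 420 rows
by composite augmentation; tuning preferred a moderately deep, heavily
column-subsampled booster and a 5-component PLS; weight calibration put
most mass on the booster with a PLS correction and dropped ridge, and the
resulting ensemble explains 99.3% of the validation variance with an RMSE
of 1.38 chlorophyll units — below the best single model (1.53). On noisy
real data the absolute numbers will be far lower; the synthetic bed
verifies mechanism, not field accuracy.

`EnsembleResults` also exposes `predict`, `band_importances`, `vip`,
`plot_predictions` and `plot_residuals`. Experiment-scale sweeps live in
`leafspec.experiments` (`run_baseline`, `run_augmentation_grid`,
`sample_size_curve`, `residual_analysis`); diagnostics (red-edge
position, correlation profiles, stratified means) in
`leafspec.diagnostics` and `leafspec.preprocess`.

## Command line

The same pipeline is scriptable; commands compose through a dataset
directory schema (`spectra.csv`, `labels.csv`, `provenance.csv`,
`meta.yaml`):

```
leafspec simulate --n 1000 --seed 7 --out synth/
leafspec match --labels L.csv --spectra S.csv --lo 400 --hi 1000 --out ds/
leafspec preprocess --in ds/ --window 63 --out ds_smooth/
leafspec augment --in train/ --mode composite --noise 0.002 --warp 0.02 --seed 42 --out train_aug/
leafspec train --in train_aug/ --trials 30 --seed 42 --out model/
leafspec grid --in ds_smooth/ --mode composite --seed 42 --reuse-tuning --out results/
leafspec diagnose --in ds_smooth/ --out diag/
```

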