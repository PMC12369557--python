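# Methods

This note documents the models, the synthetic data generator, the
numerical choices and the limitations of `nirtransfer`.

## Regression model

The quantification core is PLS regression of a univariate response
(blend proportion of tobacco silk, % of total mass) on absorbance
spectra, computed with the SIMPLS algorithm.  SIMPLS was chosen over
NIPALS because it is a finite, deterministic deflation sequence with no
convergence tolerance; for a univariate response the two algorithms
produce identical predictions (asserted against scikit-learn's NIPALS
implementation in the test suite).  Spectra are mean-centered only — no
autoscaling, derivatives or scatter correction — so the fitted model is
the affine map `ŷ = ȳ + (x − x̄)·b`.  Predictions are never clipped to
[0, 100].

SIMPLS coefficient paths nest: the coefficients for `k` latent variables
are a prefix sum of per-component terms, so one decomposition per
cross-validation fold yields the CV curve for every component count.
The number of latent variables is selected by seeded k-fold CV (default
10 folds, shuffled partition) minimizing pooled CV-RMSE over
`1..max_lv` with `max_lv = min(20, n−1, d)`; 20 is a conventional
ceiling for NIR calibrations.  Near-ties (within `1e-8` relative /
`1e-10` absolute of the minimum) are resolved toward fewer components,
so noiseless low-rank problems select their true rank instead of chasing
round-off.

## Calibration/prediction split

The pooled experiment sorts all samples by target value (stable sort,
ties by original index), groups consecutive triples, and assigns
positions 1 and 3 to calibration and position 2 to prediction — an exact
2:1 split whenever `n` is divisible by 3.  A trailing remainder of one
or two samples goes to calibration.  792 merged samples therefore split
528/264.

## Transfer methods

A transfer task calibrates on one brand (source) and predicts another
(target).  Three methods are compared:

**Direct.**  PLSR on raw source spectra, applied unchanged to the
target.

**TCA (primal).**  With stacked, combined-mean-centered data `Z` and
between-domain matrix `L` (`1/n_s²`, `1/n_t²`, `−1/(n_s n_t)` blocks),
`ZᵀLZ` reduces to the rank-one matrix `g gᵀ` with `g = μ_s − μ_t`.  The
projection `W` consists of the top-`m` generalized eigenvectors of
`(g gᵀ + μI)⁻¹ ZᵀHZ`, computed exactly in the row space of the centered
data (economy SVD followed by an `r × r` symmetric-definite eigenproblem
solved with `scipy.linalg.eigh`): both quadratic forms annihilate the
orthogonal complement of the row space, so the reduction is lossless and
avoids a dense `d × d` solve at `d = 1501`.  Eigenvector signs are fixed
(largest-magnitude entry positive) and the **B-orthonormal scaling is
kept**: coordinates along the domain-mean-difference direction are
attenuated by roughly `sqrt(μ / (μ + |g|²))`, which is the mechanism by
which TCA suppresses the shift.  Defaults: `m = 30`, `μ = 0.1` (`μ` is a
documented choice; the subspace dimension is the study's setting).
PLSR is then fitted on the projected source and applied to the projected
target; calibration metrics are reported in the projected space where
the model was fitted.  The fitted transform records the training-pair
MMD before and after projection together with a same-dimension PCA
baseline for comparison.

**CORAL.**  The recoloring map `A = C_s^{−1/2} C_t^{1/2}` built from
symmetric eigendecomposition square roots, assembled from the economy
SVD of each centered domain (cost `O(n d²)` instead of `O(d³)`);
eigenvalues are floored at 0 before rooting.  Because `n < d` makes both
covariances singular, a relative diagonal shrinkage
`λ = 1e-6 · trace(C)/d` per domain is the default (`λ = 0` requires full
rank and otherwise raises, naming the smallest eigenvalue).  Two mean
modes exist: `"match"` (default) recenters recolored source rows on the
target mean, so the downstream PLSR sees target-centered data; `"none"`
applies the raw linear map, reproducing covariance-only CORAL.  The
target is never transformed — it is its own reference frame.

**Model updating.**  `update_domains` moves `round(f · n_target)`
labeled target samples into the source (default selection: evenly spaced
positions of the y-sorted target list, which covers the target's blend
range deterministically; a seeded uniform-random mode is available) and
removes them from the prediction set, guaranteeing disjointness and
sample conservation.  Fractions are defined relative to the target
size.  "Updating only" is the direct method with `f > 0`; "updating
plus adaptation" simply re-runs TCA/CORAL on the updated domains — the
two scenarios share one code path.  The latent-variable count is
re-selected inside every task on the current calibration pool.

## Synthetic data generator

No public spectra exist for this problem, so the generator emulates the
study's structure:

* **Grid** 10,000 → 4,000 cm⁻¹ at 4 cm⁻¹ spacing (1501 points,
  descending).  The instrument resolution (8 cm⁻¹) does not fix the
  export spacing; the grid is configurable.
* **Endmembers.**  Each raw material's spectrum is a baseline plus
  Gaussian bands at the characteristic peaks (6780, 5760, 5130, 4700,
  4280 cm⁻¹, plus two auxiliary bands shaping the grid ends), producing
  troughs near 6055, 5360, 4950, 4500, 4160 cm⁻¹.  All components share
  one band pattern and differ chiefly in overall absorptivity (silk
  1.00, cut stem 0.70, fermented cut stem 0.72, expanded silk 0.68) with
  25 % per-band shape jitter: blends of plant materials share their
  functional-group chemistry, and the blend proportion is read partly
  from overall intensity, partly from shape.  This also makes a flat
  baseline offset act on the intensity channel — the mechanism that
  degrades direct cross-brand prediction.
* **Mixing** is linear in mass fractions (Beer–Lambert idealization):
  `x = gain · Σ_c (f_c/100) e_c + offset + slope·(w − w̄) + nuisance +
  noise`.  Compositions are drawn by rejection sampling inside the
  per-brand range boxes (minors uniform, analyte takes the remainder to
  100 %), honouring the boxes exactly.
* **Nuisance structure.**  22 smooth random spectral modes (random
  centers, widths 150–500 cm⁻¹, unit norm), shared across brands, with
  per-sample coefficients of sd 0.2.  They emulate moisture, particle
  size and drift effects and give the data the effective rank (> 30) of
  real NIR spectra.  This matters for TCA: with low-rank data a
  30-dimensional subspace retains everything and CV-selected PLS undoes
  any attenuation (regression is invariant to invertible linear
  reparameterization), so only a subspace that genuinely *excludes* the
  shift direction — possible when transferable structure fills all 30
  dimensions — shows the adaptation benefit.
* **Brand designs** follow the study table: #1 n=210 (silk 59–100, cut
  stem 0–20, fermented 0–20, expanded 0–25), #2 n=199 (silk 75–100,
  fermented 0–25), #3 n=200 and #4 n=183 (silk 75–100, cut stem 0–25).
* **Domain shifts.**  #2/#3: offsets ±0.006 absorbance (near-identical
  domains); #1/#4: offsets ±0.10 with tilts ±1.5e-5 absorbance/cm⁻¹ in
  opposite directions plus strongly perturbed, independent silk variants
  (5 % band-amplitude scale; #2/#3 carry near-identical 2 % variants —
  silk differs per brand, stems are shared).  Measurement noise is
  1e-3 absorbance (duplicate-scan averaged FT-NIR).  Magnitudes were
  calibrated once so that the default study reproduces the qualitative
  transfer ordering — similar pair easiest, TCA helping on every task
  involving #1/#4, CORAL best on #2↔#3 — and they are configuration, not
  physics.
* Compositions are drawn from a seed derived from the design itself, so
  regenerating with a different noise seed changes spectra but not
  targets; the whole study is bit-reproducible for a fixed seed.

What the generator does **not** model: nonlinear detector response,
band shifts/broadening, correlated (pink) noise, scatter artifacts that
SNV/MSC would target, moisture as an explicit variable, and physically
calibrated absorptivities.  Passing tests therefore demonstrate the
correctness and the qualitative behavior of the pipeline, not
instrument-grade accuracy claims for real tobacco spectra.

## Study orchestration and determinism

`run_full_study` executes the pooled experiment, all 12 ordered brand
pairs × three methods, and the configured updating sweeps (default: the
strongly shifted pair #1→#4 with direct and TCA at 1–10 %).  One master
seed fans out deterministically (SeedSequence over a CRC of each task
label) to per-task seeds; a rerun reproduces the serialized report byte
for byte.  Reports serialize losslessly to JSON and export CSV tables in
the `R_c | RMSEC (%) | R_p | RMSEP (%) | MAE (%)` layout.

Problem sizes used in the shipped checks: the full 792-sample study on
the 1501-point grid; orderings are asserted on means over five seeded
realizations, which keeps the whole acceptance computation around a
minute of CPU.

## Known limitations

* Kernelized TCA, joint-distribution adaptation, subspace alignment and
  instrument-standardization methods (PDS/DS) are out of scope.
* The CORAL mean-handling mode of the original study is not documented
  there; both variants are provided and `"match"` is the default.
* Per-seed transfer errors fluctuate substantially (the drawn endmember
  shapes decide how strongly a given offset couples into a given
  model); orderings are therefore stated and tested as 5-seed averages.
* The YAML schema exposes grids, brand designs, silk variants, shifts,
  seeds and all model hyperparameters, but not the band table itself;
  custom band sets require the Python API.
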