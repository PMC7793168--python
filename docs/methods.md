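# Methods

## The problem

Distributed M/EEG source estimation maps a few hundred sensor channels onto
thousands of candidate cortical current dipoles. Any such estimator blurs
and displaces activity; quantifying *how much* — its spatial fidelity — is
classically done with the analytic resolution matrix **R** = **KG**, which
exists only for linear estimators and says nothing about noise robustness.
This package implements the empirical alternative: simulate the activation
of one cortical patch at a time, superpose realistic sensor noise at a
controlled signal-to-noise ratio, reconstruct with any estimator (linear or
not), and average the absolute source amplitudes per patch over time. The
result is the patch × patch *empirical resolution matrix*

R̂ᵢⱼ = Σₜ Σ_{k∈Pᵢ} |X̂ₖₜ| / (nₜ |Pᵢ|),

whose column j is the (noisy, possibly non-linear) point-spread of patch j.
At infinite SNR and for a linear estimator R̂ equals the patch-reduced
analytic matrix, which the test suite uses as a built-in verification of
the whole simulation chain.

## Synthetic study conditions

All inputs can be generated internally; the defaults emulate a typical
evoked-response protocol:

| quantity | default | why |
|---|---|---|
| source space | 600 dipoles on a radially perturbed sphere, r = 8 cm | quasi-uniform spherical Fibonacci lattice + seeded jitter; near-uniform patch areas |
| bumpiness | 0.1 | perturbs normals off-radial so no source is magnetically near-silent |
| patches | 60 disjoint, ≥ 4 dipoles each | nearest-seed tiling with rebalancing, emulating atlas parcellations whose patch sizes span 4–65 dipoles |
| sensors | 64 magnetometer-like channels, r = 12 cm | free-space current-dipole fields projected on slightly tilted axes |
| activation | 100 ms constant 10 nAm per dipole, one patch at a time | standard extended-source amplitude; constant waveform keeps linear-method results waveform-independent |
| noise | rank-8 spatially mixed AR(1) (a = 0.95) + 10% white floor, ~1e-13 T RMS | two-knob stand-in for background brain activity plus instrument noise |
| epochs | 135 × 0.5 s at 1000 Hz; 49 averaged for evoked noise, 86 held out for covariance | evoked averaging shrinks noise variance ≈ 1/49; covariance from held-out data avoids circularity |
| covariance loading | 0.05 × mean diagonal | guarantees a positive-definite matrix for whitening |
| SNR grid | {0, 0.01, 0.1, 1, 3, 10, ∞} | spans chance level to the analytic limit |
| virtual subjects | 3 independent geometry/noise seeds | across-"subject" medians ± standard errors |

The signal is scaled per SNR by a single dimensionless α so the *mean
amplitude* SNR across patch activations and sensor modalities hits the
target (RMS of the projected signal over a modality's sensors and time,
divided by the RMS of the evoked noise on those sensors, averaged over
patches, then over modalities). SNR = ∞ is implemented as exactly zero
noise with α = 1; SNR = 0 as α = 0 with noise retained. Each patch
activation receives an independent, seed-derived noise draw so columns of
R̂ are statistically independent.

## Estimators

Five estimators, all with fixed dipole orientations and no depth weighting:

- **MNE** — K = Gᵀ(GGᵀ + λ²C)⁻¹, computed by symmetric (Cholesky) solve.
- **dSPM** — MNE rows divided by the mapped noise energy,
  wᵢ = 1/√(KCKᵀ)ᵢᵢ.
- **sLORETA** — MNE rows divided by the resolution diagonal,
  wᵢ = 1/√(KG)ᵢᵢ.
- **eLORETA** — K = D⁻¹Gᵀ(GD⁻¹Gᵀ + λ²C)⁻¹ with depth weights found by
  fixed-point iteration dᵢ ← x₀⁻¹√(gᵢᵀM⁻¹gᵢ), x₀ = 1 A·m. The square root
  follows from the dimension [D] = 1/(A·m)²; it is validated by the exact
  zero-localization property below. Initialization d = 1, relative-change
  stop at 1e-6, cap 100 iterations; non-convergence is reported on the
  kernel, not raised.
- **MxNE** — the row-sparse minimizer of ½‖Ỹ − G̃X‖²_F + α Σᵢ‖Xᵢ,:‖₂ after
  whitening by C^(-1/2) (symmetric eigendecomposition square root). Solved
  by FISTA with step 1/L (L = largest squared singular value of G̃) and the
  block soft-threshold prox; stop when the relative objective decrease
  falls below tol (default 1e-6, cap 3000 iterations). α is expressed as a
  percentage of α_max = maxᵢ‖g̃ᵢᵀỸ‖₂, the smallest value that zeroes the
  solution; default 55. α ≥ α_max short-circuits to the exact zero matrix
  so full regularization is exactly, not approximately, zero. Optimality is
  certified in the tests by the standard ℓ2,1 duality gap and by KKT
  residuals on active/inactive rows.

### Regularization convention

λ² = SNR⁻² throughout (λ² = 0 at SNR = ∞; a fixed large λ² at SNR = 0,
where SNR⁻² diverges and the estimate is pure noise regardless). λ² is
*dimensionless*: the kernel-dispatch layer multiplies it by
trace(C⁻¹GGᵀ)/n_sensors — the mean eigenvalue of the whitened Gram matrix —
before forming the kernels, so λ² = 1 balances the data term against the
penalty. This is the convention standard source-estimation software uses
when tying the Tikhonov parameter to an SNR; without it, gain values
(fields per unit dipole moment, ~1e-6 T/A·m) and sensor noise covariances
(~1e-26 T²) differ by so many orders of magnitude that λ²C would be
numerically inert at every SNR of interest. The low-level kernel functions
take λ² literally, so the closed scalar forms hold exactly.

## Fidelity metrics

- **PE** (peak localization error): Euclidean distance from the activated
  patch's centre dipole — the member closest to the patch's centre of
  gravity on the reference sphere (the stand-in for an inflated surface) —
  to the dipole of maximum time-averaged absolute estimate. All-zero
  estimates (possible for MxNE) yield an undefined PE/SD, are excluded
  from medians, and their fraction is reported as a statistic of its own.
- **SD** (spatial dispersion): estimate-weighted ℓ1 mean of distances from
  the peak dipole; ℓ1 rather than squared weighting mitigates outliers.
- **E_cg** (centre-of-gravity error, optional): distance from the true
  source to the amplitude-weighted centroid. On surface source spaces the
  centroid is biased toward the centre of the head; provided for
  comparison with older literature only.
- **Classifier sweep**: each column of R̂ is normalized to its maximum; a
  patch is called active when its normalized amplitude strictly exceeds a
  threshold T (ties at T inactive, for determinism). The diagonal is
  ground truth. Sweeping 1001 evenly spaced thresholds over [0, 1] traces
  ROC and precision-recall curves; where no positives exist (T → 1) the
  undefined precision is replaced by its value at the highest threshold
  with positives (horizontal asymptote). The ROC curve is augmented with
  (0,0) and (1,1); areas are trapezoidal over the sorted abscissae. The
  grid density and integration rule are conventions of this package,
  chosen so the trapezoid error is < 1e-3 on smooth fixtures and
  oracle-tested on hand-enumerated cases.
- **Sigmoid summary**: AUROC(SNR) = a·tanh(b·log10 SNR + c) + d fitted by
  nonlinear least squares (three multistarts from a = 0.25, b = 1, c = 0,
  d = 0.75; best residual wins); r² = 1 − SS_res/SS_tot; constant data
  returns the flat fit with r² = 0. SNR = 0 and ∞ are excluded (log10
  undefined).

## Numerical and design choices

- Ties everywhere (argmax, nearest seed, patch centre) break to the lowest
  index; every random draw is seeded, and derived seeds stay below 2³¹.
- The whitener is the symmetric inverse square root of the loaded
  covariance.
- Empirical-resolution columns that fail in the estimator are flagged and
  zeroed; the run continues.
- The experiment driver persists one CSV/JSON bundle per
  subject × method × SNR cell, keyed by a configuration hash, so reruns
  skip finished cells; aggregation (median, std/√n across subjects) is
  reproducible from the persisted files alone.
- Desk-scale defaults (600 sources, 60 patches, 64 sensors, 3 virtual
  subjects) preserve every structural property of a full-scale study
  (tens of thousands of sources, ~1000 patches) as a configuration change,
  not a code change.

## What the synthetic conditions do and do not show

The generator reproduces the *structure* of the evaluation — extended
patch sources, structured temporally correlated noise, evoked averaging,
held-out covariance, SNR control — but not real cortical folding, real
sensor layouts, or volume-conduction physics (free-space dipole fields
replace boundary-element models; EEG-like channels use an unbounded
homogeneous medium). Consequently the *trends* transfer (monotone
improvement with SNR, the sigmoidal AUROC(SNR) relationship, sparse
estimators' low dispersion and low sensitivity, dSPM→sLORETA convergence
at strong regularization, exact zero point-source localization for
s/eLORETA) while absolute error magnitudes, per-region topographies, and
case fractions (e.g. how often a sparse estimator zeroes the active patch)
do not. Tests assert the former and deliberately not the latter.

## Known limitations

- Single-patch activations only; simultaneous multi-source configurations
  explode combinatorially (C(n, k) patch subsets) and would need
  Monte-Carlo sampling plus redefined metrics.
- Constant-amplitude waveforms; estimators with temporal priors would need
  a waveform hook.
- 3-D Euclidean distances, not geodesics, in PE/SD.
- Free-space forward physics, as above.
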