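# Methods

This note records the models, numerical choices and limitations behind
`radialtherm`, in the order the pipeline runs.

## Acquisition model and simulator

The simulator generates multi-channel 2D radial golden-angle gradient-echo
data: spoke `m` is acquired at `t_m = m·TR` at the accumulated angle
`m·180°/φ` (values stored un-reduced; reduced mod 360 when sampling).
Default protocol constants are the reference acquisition's: TR 24.14 ms,
TE 20 ms, 2× readout oversampling, 250 Hz/px readout bandwidth, 1.5 T,
and a PRF coefficient α = −0.01 ppm/°C with γ = 42.577 MHz/T (α is a
literature convention, configurable).

Scenes are strictly 2D (slice thickness is metadata only).  A scene holds:

* a smooth-edged disk object with gentle internal texture (magnitude ≥ 0);
* per-channel smooth complex sensitivities (default 4 imaging channels),
  normalized to unit RMS sum-of-squares;
* two micro-coil point sources with a Gaussian footprint of 1.5 px SD —
  implemented analytically in k-space (Gaussian apodization × linear
  phase), so their projected position is exact;
* rigid in-plane motion: a tanh-smoothed two-position square wave
  (phantom emulation: 26 mm at 0.33 Hz) or respiratory (0.25 Hz,
  4.5/2.12 mm peak-to-peak) plus cardiac (0.825 Hz, 1.92/1.52 mm)
  sinusoids; displacement is zero at t = 0 by construction;
* an optional through-plane sinusoid that only attenuates the micro-coil
  amplitude (`exp(−z²/2σ_z²)`, σ_z = 3 mm) — the qualitative Z-intensity
  surrogate, never a 2D displacement;
* a motion-state-coupled order-2 polynomial background phase, a linear
  B₀ drift (default 0.005 rad/s), and a parametric Gaussian hotspot
  (σ = 4 mm, linear ramp, optional exponential decay; no bioheat PDE);
* complex Gaussian noise whose per-sample SD is calibrated numerically so
  the fully sampled sum-of-squares image reaches a target in-object SNR.

**Rigid motion is applied exactly as a per-spoke k-space phase ramp**
(Fourier shift theorem), never by image interpolation.  Consequently
`simulate(shifted scene) = ramp × simulate(static scene)` holds to
floating-point precision and the simulator is an analytic oracle for the
motion-correction operator.  Imaging-channel transforms run in single
precision by default (~1e-6 relative); the ramp and micro-coil channels
stay in double precision, so shift relations remain exact.

### Default study conditions

The synthetic studies use a 96 mm FoV at native matrix 96, so "1 mm"
resolution is matrix 96 and a full study (learning + stability + 60 s
ramp) stays desk-sized; all pipeline constants (TR, TE, filter cutoffs,
bin counts, λ/β) are the full-protocol values.  The default image SNR of
10 was chosen to land the per-frame temperature noise in the few-tenths
to ~1 °C range that the reference protocol's uncertainty tables report;
the micro-coil amplitude is tied to the imaging-spoke RMS level
(`microcoil_gain`, default 1), giving a static localization scatter of
~0.15 px at that SNR.  What the generator does **not** emulate: through-
plane displacement of the object, non-rigid deformation, flow, fat,
arrhythmic beat-to-beat variability, and receive-chain drifts other than
a linear global phase.  Passing tests therefore demonstrate correctness
of the algorithms under rigid 2D motion with smooth coil maps, not
robustness to every in-vivo confound.

## Radial Fourier transform

No approximate gridding is used: forward and adjoint transforms are exact
direct summations, evaluated with a per-spoke phasor recurrence (one
complex exponential per pixel, then repeated multiplication along the
equally spaced readout).  At the matrix sizes used here (≤ 128) an
operator application costs a single BLAS product once materialized
(complex64 dense matrix, capped at ~1.2 GB).  The adjoint identity holds
to machine precision by construction.  Gridded reconstructions apply ramp
(|k_r|) density weights — the polar area element per sample, with the
centre sample carrying the shared centre-disk area — and the `1/N²`
Jacobian, which gives unit DC gain on a uniform disk to within ~2%.

Readout truncation keeps `|k_r| ≤ (FoV/target)/2` and sets the matrix to
`ceil(FoV/target)` (220 mm at 3 mm → 74, matching the reference
protocol's table); the radial acceleration factor is the unrounded
Nyquist count `π/2·FoV/res` over the spokes per frame.

## Tracking

Each micro-coil spoke is inverse-Fourier transformed into a projection
profile (2×FoV span at native pixel size).  The profile is smoothed with
a 2 px Gaussian and located by the intensity-weighted barycenter over the
contiguous region above half the smoothed maximum — deterministic and
robust to split peaks.  Pairs of consecutive projections (111.25° apart)
are solved algebraically for (x, y); near-parallel pairs (< 5°
separation mod 180°) are flagged invalid and linearly interpolated in
time.  A projection-angle-dependent bias is removed by fitting an
order-4 Fourier series in the spoke angle over the learning span
(constant term retained — it is the true mean position).  The filtered /
respiratory / cardiac variants use zero-phase Gaussian low-passes whose
*amplitude* response is −3 dB at 0.883 / 0.377 Hz
(`σ_f = f_c/√ln2`), with the cardiac component as their difference; all
in-plane variants are mean-centered.  Gating keeps the fraction of spoke
pairs with the smallest smoothed `|dZ/dt|` (earliest samples win exact
ties).

With the coil at the slice centre the noiseless localization is exact
(grid-symmetric profiles); off-centre, barycenter discretization leaves a
small deterministic angle-dependent residual (~0.01–0.1 px) that the
angle-bias fit largely removes.

## Preprocessing

Imaging-channel noise covariance is estimated from the outer 5% of
readout samples (object-free at these scene sizes); whitening uses the
inverse Cholesky factor applied as `x @ W^H` so that re-estimating on the
whitened data yields exactly the identity.  A negligible covariance
(noiseless input) falls back to the identity transform.  PCA compression
keeps the leading components reaching 90% cumulative variance
(threshold 1.0 keeps all channels; a single channel passes through).
Motion correction applies the conjugate shift ramp per spoke with the
pair's displacement assigned to both of its spokes (linear interpolation
available), displacements taken relative to the learning-span mean
position.  Micro-coil channels are never whitened, compressed or
corrected.

## Multibaseline library and polynomial basis

Learning-phase spokes are binned by motion state: equal-count quantile
bins of the drive displacement (default 10 — near-equal counts are what
makes per-bin reconstructions comparable), or jointly by respiratory
amplitude quantile (8) × cardiac phase tertile (3), with cardiac cycle
boundaries from peaks of the cardiac signal (dominant-frequency-guided
peak picking; fewer than two peaks raises an error suggesting 1D
binning).  Each bin is reconstructed per channel by the density-
compensated adjoint; bins under 20 spokes raise an error or are merged
into a neighbour when requested.  The ramp density weights assume
quasi-uniform angles within each bin, which golden-angle ordering
provides because motion phase and spoke angle decorrelate.

The background basis consists of 2D monomials up to total order 6 on
[−1, 1]² (28 columns), QR-orthonormalized over the object mask (mean
baseline magnitude above 10% of maximum by default; the temperature fits
use a 0.5% threshold internally so that essentially all signal voxels are
modeled).

## Direct k-space temperature fit

Per window the model
`y_ch = E[(Σ_b x_b,ch w_b)·e^{i(Ac+θ)}]` is fitted by minimizing
`½Σ_ch‖W^{1/2}(y_ch − model)‖² + λ‖θ‖₁ + β θᵀDᵀDθ` with `D` second-order
finite differences along both axes.  Numerical scheme (the method's
literature leaves the optimizer open; these are this package's choices):

* **Density-compensated preconditioning.** The fidelity is weighted by
  the ramp density weights, making `EᴴWE` approximately the identity;
  the operator is normalized to unit spectral norm (power iteration,
  shared across the golden-angle windows of a series) and the library
  stack to unit RMS magnitude over the mask, so λ and β are
  dimensionless and transfer across scenes and resolutions.
* **Majorize–minimize outer loop.** With `‖Ê‖ ≤ 1`, each iteration forms
  the Landweber surrogate image `q = u + Êᴴ(ŷ − Êu)` and solves an
  image-domain subproblem on `q`: w by (nonnegative) least squares, c by
  weighted polynomial regression, θ by diagonal proximal steps.
* **Incremental, damped phase.** The phase update uses
  `δ = angle(q·conj(u))` accumulated onto the current model phase —
  immune to ±π wrapping of heating + background + drift — damped by the
  channel coherence and by local SNR (`weight/(weight+0.02·max)`), with
  each increment capped at π/2, so noise-dominated voxels cannot random-
  walk.
* **Noise-referenced sparsity.** After an unregularized warm-up pass the
  per-voxel phase-noise scale `σθ_j = κ/|m_j|` is estimated from the
  robust residual spread, with κ referenced to Nyquist sampling
  (`×√(N_window/N_Nyquist)`).  The soft threshold is `λ·σθ_j`: the
  printed λ values act as mild, noise-relative sparsity — consistent
  with the reference protocol's own tuning rule (λ lowered until the
  temperature stops changing) and with its finite background
  uncertainties — and the threshold is fixed in radians per resolution,
  so stronger undersampling raises the background SD rather than the
  threshold.
* **Drift/heat separation.** The polynomial fit excludes the heated
  neighbourhood (|θ| support above 0.1 rad, dilated 3 px, plus a smooth
  per-voxel attenuation); if the exclusion would swallow the object the
  previous drift estimate is kept.
* **Support debias.** A final pass refits θ on its confidently heated
  support (>3σθ, dilated) with both penalties off, removing the l1
  shrinkage and the roughness flattening of the (often 1–2 px wide)
  hotspot peak; the sub-threshold background keeps its regularized
  values.
* θ starts at zero every frame (fresh support detection); warm starts
  carry only w and c and are off by default — per-frame independence
  proved more robust than chaining.  The heating sign constraint
  (θ ≤ 0 for α < 0) is applied at every proximal step.  Convergence is
  declared at `max|Δθ| < 1e-3` rad per phase, capped at 40 iterations
  per phase.

The image-domain reference fit (`image_domain_fit`) alternates the same
three blocks voxelwise on a fully sampled complex frame and serves as the
brute-force oracle: with λ = β = 0 and full radial sampling the k-space
fit agrees with it to better than 1e-2 rad over the object interior.

Temperature conversion is `ΔT = θ/(2π γ B₀ α 10⁻⁶ TE)`; series are
filtered per voxel with a zero-phase order-4 Butterworth low-pass at
0.14 Hz.  The uncertainty metric is the mean ± SD over an unheated ROI of
each voxel's temporal SD, strictly after the learning span and before
heating onset.  λ is interpreted in radians (not °C), and frames advance
by the window length by default, reproducing the printed frame rates
(0.48/0.72/0.97 s at TR 24.14 ms).

## Problem sizes of the shipped studies

The acceptance protocols use: a 48-matrix square-wave phantom (60 s of
data; 2 mm uncertainty comparisons at 40/30/20 spokes, corrected vs
uncorrected at 30 spokes) and a 96-matrix in-vivo-like ablation (105 s,
25 s learning, 60 s ramp to 30 °C; recovery measured as the median frame
peak of the last 4–5 plateau frames at 3 mm/40 spokes and 1 mm/20
spokes).  These sizes are the package's default desk-scale protocol; all
are configurable upward.

## Known limitations

* Strictly 2D; through-plane motion only modulates micro-coil intensity.
* Heating above ~78 °C phase-wraps beyond the solver's safety bound.
* The square-wave phantom's transition windows mix two motion states
  faster than the 0.883 Hz tracking filter can follow, producing
  occasional outlier frames — the same oscillation the reference
  experiments report for fast switching motion.
* Equal-count binning assumes the learning span samples every motion
  state; arrhythmic or drifting motion would need re-learning.
* External raw data is read from the package's documented HDF5 container
  only; converting vendor or ISMRMRD files requires third-party tooling.
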