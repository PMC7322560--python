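# Methods

## Scope and model

`lcmvbench` studies how linearly constrained minimum-variance (LCMV)
beamformer pipelines localize a single focal source as a function of input
signal-to-noise ratio, using fully synthetic MEG in a geometry where the
forward problem has a closed form.  Everything downstream of the physics —
covariance conventions, regularization, sensor-type combination, scanning,
metrics — mirrors the choices made by widely used analysis toolboxes, so
the package can reproduce the qualitative behavior of those pipelines
without touching real recordings.

### Forward model

The conductor is a homogeneous sphere.  The magnetic field of a primary
current dipole **Q** at **r₀** measured at **r** outside the sphere is the
closed-form solution

    a = r − r₀,  a = |a|,  R = |r|
    F = a (aR + R² − r₀·r)
    ∇F = (a²/R + a·r/a + 2a + 2R) r − (a + 2R + a·r/a) r₀
    B(r) = µ₀ / (4πF²) · ( F (Q×r₀) − (Q×r₀·r) ∇F )

Volume currents are fully accounted for; a radial dipole is silent, so the
local M×3 leadfield at any scan point has numerical rank 2.  The forward
model is validated in the tests against an independent Biot–Savart line
integral over the phantom triangle construction (an isosceles triangular
current loop whose long legs meet at the sphere origin reproduces a
tangential dipole in the sphere), agreeing to better than 0.5%.

### Sensor array

A triple-sensor helmet: sites on a Fibonacci lattice covering a spherical
cap (default radius 0.12 m, cap half-angle 120°), each site carrying one
magnetometer (field along the outward normal, unit T) and two orthogonal
planar gradiometers (two-point finite difference of that component across a
17-mm in-plane baseline, unit T/m).  102 sites reproduce the 306-channel
layout of the real system; the simulation sweeps default to 34 sites
(102 channels), which preserves all structure (two sensor types, mixed
units, radial orientations) at a third of the cost.  The gradiometer is a
two-point difference rather than a coil-surface integral; at these source
distances the difference is far below the noise level.

### Scanning space

An axis-aligned rectangular grid with 5-mm spacing, anchored at the sphere
origin, restricted to the upper half of the sphere and to radii at least
7.5 mm inside the conductor surface (phantom suite: 5-mm margin in a
75-mm sphere).  Points are ordered lexicographically by (z, y, x); the peak
of a map is the first point attaining the maximum, so tie-breaks are
deterministic and a tie triggers a warning.  One grid point represents
125 mm³.

## Synthetic data

### Sources and waveforms

Simulation-style datasets drive one tangentially oriented dipole with a
10-Hz, 200-ms (two-cycle) burst starting at t = 0; epochs nominally span
−200…+200 ms at 1 kHz, with noise/data covariance windows −200…−20 ms and
20…200 ms (half-open).  Default amplitudes follow the benchmark ladder
{10, 30, 80, 200, 300, 450, 600, 800} nAm and each dataset has 110 trials.
Phantom-style datasets place tangential dipoles at 34/44/54/64 mm radius on
one meridian (15° apart), driven by a 20-Hz sinusoid for 500 ms followed by
500 ms of silence, ~100 one-second epochs, windows −500…−50 and
50…500 ms.  Waveform samples are taken at half-sample offsets and
renormalized, so the burst has unit peak and no sample sits exactly on a
zero crossing.

### Noise surrogate

Real ongoing MEG is replaced by (i) white sensor noise with separate
per-sample SDs for magnetometers (3.5 pT) and gradiometers (0.2 nT/m), and
(ii) 100 random interior dipoles with independent band-limited (2–45 Hz,
flat in band) Gaussian time courses of 45 nAm RMS, giving the noise the
spatial correlation structure of distributed brain activity.  Background
time courses are drawn independently per trial: the jittered inter-trial
interval of a real experiment decorrelates ongoing activity across epochs,
and without this property trial-averaging fails to suppress it at the epoch
rate.  A flat in-band spectrum is used rather than a steep 1/f shape: with
dominant sub-5-Hz power the window-demeaned noise covariance no longer
represents the noise at samples far from the estimation window and the SNR
estimator develops a ~6 dB false floor; with the flat band the null floor
sits at ~1–2 dB.  These defaults place the 10–800 nAm ladder across roughly
1–26 dB of input SNR, with the 3-dB reliability threshold crossed around
80 nAm for mid-depth sources.

The phantom environment (`quiet_noise`) is white only, at about 1 pT
in-band for magnetometers.  This level is chosen so that the anti-causal
tail that any zero-phase filter smears from the strongest (1000 nAm) burst
into the baseline window (~1.5% of the burst RMS) stays below the noise
floor; if it does not, the noise covariance is signal-contaminated and the
NAI contrast collapses.  A corollary of a physically consistent noise
floor is that the 20-nAm phantom datasets fall below 3 dB input SNR and are
excluded by the SNR filter of the phantom benchmark.

### Filtering order

Zero-phase filtering of short epochs creates edge transients that real
pipelines avoid by filtering the continuous recording before epoching.  The
sweep therefore simulates epochs with 150 ms of temporal padding per side,
filters, and crops to the analysis window (`EpochedData.crop`).  The
band-pass itself (`design="butter"`) applies the squared magnitude response
of a 4th-order Butterworth 2–40 Hz filter in the frequency domain — the
steady state of a forward–backward `filtfilt` run, exact for circularly
extended data and free of per-epoch transients.  A time-domain linear-phase
FIR option is retained to expose the IIR/FIR axis along which toolboxes
differ.

### SSS surrogate

True signal-space separation is out of scope.  Its dominant effect on
beamforming — rank reduction of the data — is emulated by projecting every
sample onto the subspace spanned by the leading `r` left singular vectors
of a dense interior-grid leadfield matrix (10-mm grid, gradiometer rows
scaled by their baseline so both sensor types are commensurate), default
r = 80.  Dipolar signals from inside the sphere pass with < 2% relative
distortion at r = 80 (measured in the commensurate units; the raw
mixed-unit Frobenius norm, which adds T² to (T/m)², has no physical
meaning), while the output data rank drops to r.  The surrogate does not
remove external interference, does not include the temporal (tSSS)
projection, and does not model head movement.

## Preprocessing

* **Trial rejection**: the per-trial statistic is the maximum over channels
  of the per-channel variance; trials strictly above its 98th or strictly
  below its 2nd linear-interpolation percentile are dropped, so an
  all-equal distribution drops nothing.
* **Covariance**: per-trial scatter over the (half-open) window after
  per-trial, per-channel mean removal, pooled and divided by the total
  sample count Ns.  Demeaning is the default convention and can be turned
  off.  The eigen-spectrum is recorded; eigenvalues below 1e-8 of the
  largest count as near-zero, and the effective rank Meff is the channel
  count minus that number.  Regularized copies carry the pre-regularization
  Meff forward, since loading makes every eigenvalue nominally positive.
* **Regularization**: C + λI with λ = ratio · Trace(C)/M and ratio 0.05 by
  default, applied identically to data and noise covariances.  Optionally λ
  is computed and added per sensor-type block, and the
  magnetometer–gradiometer cross-covariance can be zeroed first.
* **Whitening**: the full-mode whitener is the inverse square root of the
  noise covariance from its eigendecomposition, truncated at Meff; block
  mode does the same per sensor-type block with cross terms zeroed.
  Whitening requires a valid noise estimate: with literally zero noise the
  covariance degenerates to the filter-leakage subspace and the truncation
  collapses the scan — zero-noise data are outside the model class.

## Beamformer

Weights, output power, orientation optimization and the neural activity
index (NAI) follow the standard minimum-variance formulation; both the data
and noise covariances are inverted via eigendecomposition after loading,
and a non-positive-definite matrix raises instead of being pseudo-inverted.
At each grid point the local leadfield is reduced to its non-silent column
space (batched SVD, tolerance 1e-8 relative); in a sphere this drops
exactly the radial direction.  Scalar mode solves the 2×2 generalized
eigenproblem {LᵀC⁻²L, LᵀC⁻¹L} in closed form for the orientation with
maximum output SNR (sign fixed by making the largest-magnitude component
positive) and evaluates NAI = (lᵀCn⁻¹l)/(lᵀC⁻¹l) at that orientation.
C⁻² is computed as the square of the loaded inverse, keeping the
regularization consistent between the two Gram matrices.  Note that the
generalized eigenvector maximizes the Rayleigh quotient
(lᵀC⁻¹l)/(lᵀC⁻²l) exactly; the Cn-normalized NAI is then evaluated at that
orientation, as the toolboxes do, and the orientation oracle in the tests
checks the quantity that is exactly optimized.  Vector mode reports the
trace-ratio NAI, Trace[(LᵀC⁻¹L)⁻¹]/Trace[(LᵀCn⁻¹L)⁻¹] — the sum of
per-orientation output powers under the data covariance normalized by the
same sum under the noise covariance.  This reduces to 1 when C = Cn at
every point.  An alternative reading (summing per-orientation NAI ratios)
would instead give the number of orientations under C = Cn; it is not
implemented.  Fully silent points (e.g. the sphere origin) get NAI 0 and an
undefined orientation.

Four presets mirror the sensor-combination strategies of popular toolboxes:
scalar with full prewhitening (`mne_like`); scalar with no whitening in raw
SI units, which lets the numerically larger gradiometer values dominate
(`fieldtrip_like`); scalar with no whitening after rescaling channels to
fT and fT/mm, which lets magnetometers dominate (`spm_like`); and vector
with per-type block whitening, zeroed cross-sensor covariance and per-type
λ (`brainstorm_like`).  The deliberate unit mis-scaling is the point: it
reproduces how unwhitened pipelines implicitly weight sensor types.

The scan is organized as a model/results pair: `LCMVBeamformer` holds the
covariances, leadfield, array and configuration; `fit()` returns
`LCMVResults` with the NAI map, per-point orientations, peak, diagnostics
(λ used, effective rank, condition number), `summary()`, metric helpers
and an optional quick-look plot.

## Metrics

* **Localization error**: Euclidean distance (mm) between the map peak and
  the true source.
* **Point-spread volume**: number of grid points at or above 50% of the map
  maximum times 125 mm³.
* **Input SNR**: the evoked average is whitened with the noise covariance
  of the average (single-sample noise covariance divided by the number of
  averaged trials, rank-truncated at Meff); t_max is the sample with
  maximum absolute whitened amplitude across channels (ties → earliest),
  and SNR = 10·log₁₀ of the mean squared whitened value over the Meff
  retained components at t_max.  The nave scaling is what places the
  pure-noise null near 0 dB.  Two small biases are inherent to the
  estimator and documented rather than corrected: maximizing over time
  selects high-noise samples (≈ +1 dB at M ≈ 100), and window-demeaned
  covariances slightly underestimate band-limited noise (≈ +0.5 dB), so
  the practical null floor is ~1–2 dB rather than 0.

## Sweeps and the mismatch knob

`run_sweep` iterates locations × amplitudes × seeds, evaluates every
requested variant on shared covariances, and writes incremental,
resumable, bit-reproducible CSV rows; `summarize` bins rows by input SNR
(left-closed edges, default −∞/3/15/+∞ dB) into mean LE (mm) and mean PSV
(cm³) per variant.  Dipole locations are drawn uniformly in the upper
half-ball between 30 mm and 10 mm below the surface with z ≥ 5 mm, with
random tangential orientations, from a dedicated seed.

With a matched forward model, high SNR cannot produce mislocalization, so
the sweep has a mismatch knob: `sensor_jitter_mm` displaces every sensor
site of the *scanning* forward model by an isotropic Gaussian offset
(channels of a site move together; simulation keeps the true geometry).
1.5-mm jitter perturbs the leadfields by ~7% in a commensurate norm, with
most of the perturbation in the rapidly varying gradiometer patterns.

## Problem sizes and observed behavior

The standard benchmark configuration is 10 locations × 4 amplitudes × 2
noise seeds on the 102-channel array with a 5-mm grid (~9900 points), and
the phantom suite is 8 dipoles × 3 amplitudes on the 306-channel array.
Under these conditions the scalar pipeline's mean localization error in the
3–15 dB band is a few mm, every rank-reduced phantom dataset above 3 dB
localizes within the lattice distance (≤ ~2 mm, maximum bounded by the
half-diagonal 4.3 mm), and the 3–12 dB full-rank band stays within 15 mm
for at least 90% of datasets.  Under 1.5-mm sensor jitter with rank
reduction, the high-SNR (>15 dB) degradation is clearly reproduced for the
gradiometer-dominated variant; for the magnetometer-dominated variant the
same inequality only emerges at ~3-mm jitter, because position jitter
barely perturbs the smooth magnetometer patterns — a mechanism difference
from head-model/coregistration error, which affects both sensor types.

## What passing tests do and do not show

The generator emulates evoked bursts on spatially correlated, temporally
band-limited noise with two sensor types and optional rank reduction.  It
does not contain real environmental interference, artifacts (blinks,
cardiac, movement), head-model error beyond the jitter knob, cHPI or
movement compensation, or the true SSS multipole geometry.  Passing
benchmarks therefore demonstrate correctness and the SNR-dependence of the
implementations under controlled conditions — not performance on real
recordings.  Known limitations: the SNR estimator's selection bias (above),
the two-point gradiometer model, and the surrogate nature of both the
noise and the rank-reduction step.
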