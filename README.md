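# lcmvbench

Benchmarking LCMV beamformer source localization on synthetic MEG.

MEG source imaging with a linearly constrained minimum-variance (LCMV)
beamformer estimates, for every candidate location **r** on a scanning
grid, a spatial filter

    Wᵀ(r) = [Lᵀ(r) C⁻¹ L(r)]⁻¹ Lᵀ(r) C⁻¹

where L(r) is the local leadfield and C the data covariance, and maps the
noise-normalized output power — the neural activity index,
NAI(r) = Trace[LᵀC⁻¹L]⁻¹ / Trace[LᵀCₙ⁻¹L]⁻¹ (vector form) or
NAI(r) = (lᵀCₙ⁻¹l)/(lᵀC⁻¹l) with l = L·η_opt at the SNR-optimal
orientation η_opt = v_min{LᵀC⁻²L, LᵀC⁻¹L} (scalar form).  In practice the
result depends heavily on choices the major analysis toolboxes make
differently: prewhitening versus raw mixed units when combining
magnetometers with planar gradiometers, Tikhonov loading
λ = 0.05·Trace(C)/M globally or per sensor type, zeroing cross-sensor
covariance, and scalar versus vector output.

`lcmvbench` is for methodologists who want to study these pipeline
variants under controlled conditions.  It provides

* a closed-form spherical-conductor forward model (current dipole in a
  homogeneous sphere) and a synthetic 306-channel triple-sensor helmet;
* a seeded generator of evoked datasets — cortical-style 10-Hz bursts on
  spatially correlated background noise, and a static-phantom suite of
  tangential dipoles at 34–64 mm radius — plus an SSS-like rank-reduction
  surrogate;
* the preprocessing conventions shared by the toolboxes (zero-phase 2–40 Hz
  band-pass, variance-based trial rejection, trial-pooled covariances over
  baseline/active windows);
* vector and scalar LCMV scanning with four toolbox-style presets
  (`mne_like`, `fieldtrip_like`, `spm_like`, `brainstorm_like`), organized
  as a model/results pair (`LCMVBeamformer(...).fit() -> LCMVResults`);
* the three benchmark metrics: localization error (mm), point-spread
  volume at 50% of the map maximum (mm³), and input SNR of the whitened
  evoked response (dB), with sweep drivers that bin results by SNR.

## Worked example

Simulate one 300-nAm dipole on realistic background noise, preprocess, and
scan with the prewhitened scalar variant:

```python
import numpy as np
from lcmvbench import (
    DipoleSource, LCMVBeamformer, NAM, NoiseModel, SphereModel,
    bandpass_zero_phase, build_grid, build_helmet_array, compute_covariance,
    compute_leadfield, input_snr, reject_trials_by_variance, simulate_trials,
)

sphere = SphereModel(conductor_radius=0.09)     # 9-cm conducting sphere
array = build_helmet_array(n_sites=34)          # 102-channel triple-sensor helmet
grid = build_grid(sphere, spacing=0.005, region="upper_half")
leadfield = compute_leadfield(grid, array, sphere)

loc = np.array([0.0, 0.035, 0.055])
ori = np.array([0.0, 0.844, -0.537])            # tangential at loc
source = DipoleSource(loc, ori / np.linalg.norm(ori), 300 * NAM)
epochs = simulate_trials(source, array, sphere, NoiseModel(), seed=7,
                         epoch_window=(-0.35, 0.35))
epochs = bandpass_zero_phase(epochs, 2, 40).crop((-0.2, 0.2))
epochs, _ = reject_trials_by_variance(epochs)

results = LCMVBeamformer.from_epochs(epochs, leadfield, config="mne_like").fit()
print(results.summary())
noise_cov = compute_covariance(epochs, epochs.noise_window, "noise")
print(f"input SNR (dB):     {input_snr(epochs, noise_cov)[0]:.2f}")
print(f"localization (mm):  {results.localization_error(loc):.2f}")
```

Output:

```
LCMV beamformer scan results
============================================
variant:            mne_like (scalar)
whitening:          full
regularization:     ratio=0.05 lambda_data=0.05845909189185383
channels used:      102
noise eff. rank:    102
grid points:        9857 (spacing 5.0 mm)
peak NAI:           8.221
peak location (mm): [0.0, 35.0, 55.0]
PSV at 50% (mm^3):  8750
input SNR (dB):     12.78
localization (mm):  0.00
```

The NAI map peaks exactly at the simulated source (the source sits on a
grid point, so the localization error is 0 mm); at 12.8 dB input SNR the
half-maximum region spans 70 voxels (8750 mm³), and the loading λ is 5% of
the mean whitened channel variance.

A command-line interface wraps the same pipeline:
`lcmvbench simulate`, `localize`, `sweep`, `phantom`, and `report`
(see `lcmvbench --help`); sweep outputs are resumable CSV row files plus a
per-variant, per-SNR-bin summary table.

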