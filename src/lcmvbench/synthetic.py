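"""Synthetic evoked MEG datasets with known dipolar sources.

Two dataset families are emulated:

* *simulation-style*: a single cortical-depth dipole driven by a 10-Hz,
  200-ms (2-cycle) burst, ~110 trials, superimposed on ongoing background
  activity, 1-kHz sampling, epochs -200..+200 ms around burst onset;
* *phantom-style*: tangential dipoles at 34/44/54/64 mm from the sphere
  origin driven by a 20-Hz sinusoid, 500 ms on / 500 ms off, ~100 trials,
  epochs -500..+500 ms.

Ongoing activity is surrogated by white sensor noise (separate SD per
channel type) plus band-limited 1/f random interior dipoles that give the
noise a realistic spatial correlation structure.  Everything is seedable and
bit-reproducible.  An SSS-like cleaning step is emulated by projecting the
data onto the subspace spanned by interior-source field patterns, which
reproduces the rank reduction (typically to < 80 of 306 channels) that real
signal-space separation causes, without implementing the multipole
expansion itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import DomainError, InvalidArgumentError
from .forward import compute_leadfield_points, point_gain
from .geometry import SensorArray, SphereModel, build_grid, build_helmet_array

#: nAm -> A*m
NAM = 1e-9

#: phantom dipole radii (m), indexed like the physical device
PHANTOM_RADII = {5: 0.064, 6: 0.054, 7: 0.044, 8: 0.034,
                 9: 0.064, 10: 0.054, 11: 0.044, 12: 0.034}


@dataclass
class DipoleSource:
    """A current dipole with a unit-peak waveform scaled by ``amplitude``.

    ``amplitude`` is the peak moment in A*m (use ``nAm * NAM``).
    """

    location: np.ndarray
    orientation: np.ndarray
    amplitude: float
    waveform: str = "sim_burst"

    def __post_init__(self):
        self.location = np.asarray(self.location, float)
        self.orientation = np.asarray(self.orientation, float)
        n = np.linalg.norm(self.orientation)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise InvalidArgumentError("source orientation must be a unit vector")


@dataclass
class NoiseModel:
    """Surrogate for ongoing background MEG activity.

    ``white_sd_mag``/``white_sd_grad`` are per-sample white-noise SDs in
    channel units (T, T/m).  ``n_background_sources`` random interior
    dipoles with band-limited random time courses of RMS ``background_sd``
    (A*m) provide spatially correlated noise.  Defaults place the
    10-800 nAm amplitude sweep across roughly 0-25 dB input SNR.
    """

    white_sd_mag: float = 3.5e-12
    white_sd_grad: float = 2e-10
    n_background_sources: int = 100
    background_sd: float = 45e-9
    background_band: tuple = (2.0, 45.0)
    seed: Optional[int] = None

    def __post_init__(self):
        if self.white_sd_mag < 0 or self.white_sd_grad < 0:
            raise InvalidArgumentError("white noise SDs must be >= 0")


def quiet_noise() -> NoiseModel:
    """Shielded-room phantom environment: sensor/environment noise only.

    White-noise SDs correspond to roughly one picotesla within a 2-40 Hz
    analysis band (gradiometers scaled accordingly): residual environmental
    interference in a shielded room, set high enough that the anti-causal
    tail a zero-phase filter smears from the strongest burst into the
    baseline window stays below the noise floor (the covariance model
    breaks down otherwise; real interference levels satisfy this easily).
    No brain-like background sources."""
    return NoiseModel(white_sd_mag=4e-12, white_sd_grad=2.4e-10,
                      n_background_sources=0, background_sd=0.0)


@dataclass
class EpochedData:
    """trials x channels x samples, with covariance-window markers."""

    data: np.ndarray
    sfreq: float
    tmin: float
    noise_window: tuple
    data_window: tuple
    array: Optional[SensorArray] = None
    rank_reduced: bool = False
    rank_retained: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise InvalidArgumentError("data must be (trials, channels, samples)")
        t0, t1 = self.times[0], self.times[-1]
        for w in (self.noise_window, self.data_window):
            if w[0] < t0 - 1e-9 or w[1] > t1 + 1.0 / self.sfreq + 1e-9:
                raise InvalidArgumentError("covariance window outside the epoch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.n_samples) / self.sfreq

    def window_slice(self, window: tuple) -> slice:
        """Samples with window[0] <= t < window[1] (half-open)."""
        t = self.times
        idx = np.flatnonzero((t >= window[0] - 1e-12) & (t < window[1] - 1e-12))
        if idx.size == 0:
            raise InvalidArgumentError("window contains no samples")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def average(self) -> np.ndarray:
        """Evoked response: mean over trials, (channels, samples)."""
        return self.data.mean(axis=0)

    def crop(self, window: tuple) -> "EpochedData":
        """Trim the epoch to ``window`` (half-open); covariance windows kept.

        Used to discard filter-padding samples after zero-phase filtering,
        emulating the filter-then-epoch order of continuous-data pipelines.
        """
        sl = self.window_slice(window)
        return replace(
            self,
            data=self.data[:, :, sl],
            tmin=float(self.times[sl.start]),
        )


def make_waveform(kind: str, sfreq: float) -> np.ndarray:
    """Unit-peak source waveform.

    ``sim_burst``: 10-Hz sine, 200 ms (exactly 2 cycles), nothing after.
    ``phantom_burst``: 20-Hz sine for 500 ms followed by 500 ms of zeros.
    Samples are taken at half-sample offsets so no sample falls exactly on a
    zero crossing; the burst is renormalized to peak 1.
    """
    if kind == "sim_burst":
        f, dur, total = 10.0, 0.2, 0.2
    elif kind == "phantom_burst":
        f, dur, total = 20.0, 0.5, 1.0
    else:
        raise InvalidArgumentError(f"unknown waveform kind {kind!r}")
    if sfreq < 4 * f:
        raise InvalidArgumentError("sampling rate must be >= 4x carrier frequency")
    n_total = int(round(total * sfreq))
    n_on = int(round(dur * sfreq))
    k = np.arange(n_on)
    burst = np.sin(2 * np.pi * f * (k + 0.5) / sfreq)
    burst /= np.abs(burst).max()
    w = np.zeros(n_total)
    w[:n_on] = burst
    return w


def _shaped_background(rng, n_sources, n_trials, n_samples, sfreq, band):
    """Unit-RMS 1/f band-limited time courses, (n_sources, n_trials, n_samples).

    Trials are drawn independently: the jittered inter-trial interval of a
    real recording decorrelates ongoing activity across epochs, so averaging
    must suppress it by 1/sqrt(n_trials)."""
    white = rng.standard_normal((n_sources, n_trials, n_samples))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    gain = np.zeros_like(freqs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    # flat within the band: short correlation time, so that window-demeaned
    # covariances remain representative of the noise at every epoch sample
    gain[in_band] = 1.0
    spec = np.fft.rfft(white, axis=-1) * gain
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    rms = x.std(axis=(1, 2), keepdims=True)
    rms[rms == 0] = 1.0
    return x / rms


def _noise_trials(noise, array, sphere, n_trials, n_samples, sfreq, rng):
    """White + background noise, (n_trials, M, n_samples)."""
    M = array.n_channels
    sd = np.where(array.magnetometer_mask, noise.white_sd_mag, noise.white_sd_grad)
    out = rng.standard_normal((n_trials, M, n_samples)) * sd[None, :, None]
    if noise.n_background_sources > 0 and noise.background_sd > 0:
        nb = noise.n_background_sources
        # random interior dipoles, kept off the surface and the origin
        radius = sphere.conductor_radius * np.cbrt(rng.uniform(0.02, 0.85**3, nb))
        v = rng.standard_normal((nb, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        positions = sphere.origin + radius[:, None] * v
        moments = rng.standard_normal((nb, 3))
        moments /= np.linalg.norm(moments, axis=1, keepdims=True)
        gains = compute_leadfield_points(positions, array, sphere)  # (nb, M, 3)
        mix = np.einsum("bmk,bk->mb", gains, moments)  # (M, nb)
        tc = _shaped_background(
            rng, nb, n_trials, n_samples, sfreq, noise.background_band
        )
        out += np.einsum("mb,bnt->nmt", mix, tc) * noise.background_sd
    return out


def simulate_trials(
    source: DipoleSource,
    array: SensorArray,
    sphere: SphereModel,
    noise: NoiseModel,
    n_trials: int = 110,
    epoch_window: tuple = (-0.2, 0.2),
    sfreq: float = 1000.0,
    seed: Optional[int] = None,
    noise_window: tuple = (-0.2, -0.02),
    data_window: tuple = (0.02, 0.2),
) -> EpochedData:
    """Evoked trials: leadfield * (amplitude * waveform) + noise.

    The source burst starts at t = 0.  Noise draws do not depend on the
    amplitude, so runs differing only in amplitude share identical noise
    (exact superposition).  Reproducible bit-for-bit given the seed.
    """
    if n_trials < 1:
        raise InvalidArgumentError("n_trials must be >= 1")
    rel = np.linalg.norm(source.location - sphere.origin)
    if rel >= sphere.conductor_radius:
        raise DomainError("source outside the conducting sphere")
    if seed is None:
        seed = noise.seed
    rng = np.random.default_rng(seed)
    n_samples = int(round((epoch_window[1] - epoch_window[0]) * sfreq))
    times = epoch_window[0] + np.arange(n_samples) / sfreq

    w = make_waveform(source.waveform, sfreq)
    tc = np.zeros(n_samples)
    k0 = int(np.searchsorted(times, -1e-9))
    n_fit = min(w.size, n_samples - k0)
    tc[k0 : k0 + n_fit] = w[:n_fit]

    gain = point_gain(source.location, array, sphere)  # (M, 3)
    pattern = gain @ source.orientation  # (M,)
    signal = source.amplitude * pattern[:, None] * tc[None, :]

    data = _noise_trials(noise, array, sphere, n_trials, n_samples, sfreq, rng)
    data += signal[None, :, :]
    return EpochedData(
        data,
        sfreq,
        epoch_window[0],
        noise_window,
        data_window,
        array=array,
        meta={
            "seed": seed,
            "amplitude": source.amplitude,
            "source_location": source.location.tolist(),
            "source_orientation": source.orientation.tolist(),
        },
    )


def interior_signal_basis(
    array: SensorArray,
    sphere: SphereModel,
    rank_r: int,
    grid_spacing: float = 0.01,
) -> np.ndarray:
    """Leading left singular vectors of a dense interior-grid leadfield.

    Gradiometer rows are scaled to field units (multiplied by their baseline
    length) before the SVD so both sensor types contribute on a common
    scale; the returned basis is in the original mixed units.  Columns span
    the 'interior signal subspace' that the SSS surrogate retains.
    """
    grid = build_grid(sphere, spacing=grid_spacing, inside_margin=0.005, region="full")
    # pass ``basis`` to sss_like_rank_reduction to avoid recomputing this
    gains = compute_leadfield_points(grid.points, array, sphere)
    M = array.n_channels
    A = gains.transpose(1, 0, 2).reshape(M, -1)
    scale = np.ones(M)
    grad = array.gradiometer_mask
    scale[grad] = np.linalg.norm(array.gradiometer_baseline[grad], axis=1)
    U, s, _ = np.linalg.svd(A * scale[:, None], full_matrices=False)
    U_r = U[:, :rank_r]
    # projector in original units: D^-1 U U^T D
    return (U_r / scale[:, None], U_r * scale[:, None])


def sss_like_rank_reduction(
    epochs: EpochedData,
    array: SensorArray,
    sphere: SphereModel,
    rank_r: int = 80,
    basis: Optional[tuple] = None,
) -> EpochedData:
    """Project every sample onto the rank-``rank_r`` interior signal subspace.

    Dipolar signals from inside the sphere pass with small distortion
    (< 2% for rank_r >= 80 on a 306-channel array) while the data rank drops
    to ``rank_r``, emulating what SSS cleaning does to the eigenspectrum.
    """
    M = epochs.n_channels
    if not 1 <= rank_r < M:
        raise InvalidArgumentError("rank_r must satisfy 1 <= rank_r < n_channels")
    left, right = basis if basis is not None else interior_signal_basis(
        array, sphere, rank_r)
    if left.shape[1] != rank_r:
        raise InvalidArgumentError("precomputed basis rank does not match rank_r")
    flat = epochs.data.transpose(1, 0, 2).reshape(M, -1)
    proj = left @ (right.T @ flat)
    out = replace(
        epochs,
        data=proj.reshape(M, epochs.n_trials, epochs.n_samples).transpose(1, 0, 2),
        rank_reduced=True,
        rank_retained=rank_r,
    )
    return out


def phantom_positions(origin: np.ndarray | None = None) -> dict:
    """Location and tangential orientation of the 8 phantom dipoles.

    All dipoles sit on the x-z meridian, 15 degrees apart in polar angle,
    at the radii of the physical device; orientations point along +y
    (tangential by construction).
    """
    origin = np.zeros(3) if origin is None else np.asarray(origin, float)
    out = {}
    for i, idx in enumerate(sorted(PHANTOM_RADII)):
        theta = np.deg2rad(15.0 * (i - 3.5))
        direction = np.array([np.sin(theta), 0.0, np.cos(theta)])
        out[idx] = {
            "location": origin + PHANTOM_RADII[idx] * direction,
            "orientation": np.array([0.0, 1.0, 0.0]),
        }
    return out


def phantom_dataset(
    dipole_index: int,
    amplitude_nam: float,
    noise: Optional[NoiseModel] = None,
    seed: Optional[int] = None,
    n_trials: int = 100,
    array: Optional[SensorArray] = None,
    sphere: Optional[SphereModel] = None,
):
    """Static-phantom style dataset for one dipole.

    Returns ``(EpochedData, DipoleSource)`` with the ground-truth source.
    Epochs span -650..+650 ms at 1 kHz (150 ms of padding per side for the
    zero-phase filter, to be cropped to -500..+500 ms after filtering);
    20-Hz burst in 0..500 ms; covariance windows -500..-50 and 50..500 ms.
    """
    if dipole_index not in PHANTOM_RADII:
        raise InvalidArgumentError(
            f"unknown phantom dipole {dipole_index!r}; valid: {sorted(PHANTOM_RADII)}"
        )
    if amplitude_nam <= 0:
        raise InvalidArgumentError("amplitude must be positive")
    sphere = sphere or SphereModel(conductor_radius=0.075)
    array = array or build_helmet_array()
    noise = noise or quiet_noise()
    spec = phantom_positions(sphere.origin)[dipole_index]
    source = DipoleSource(
        spec["location"], spec["orientation"], amplitude_nam * NAM, "phantom_burst"
    )
    epochs = simulate_trials(
        source,
        array,
        sphere,
        noise,
        n_trials=n_trials,
        epoch_window=(-0.65, 0.65),
        sfreq=1000.0,
        seed=seed,
        noise_window=(-0.5, -0.05),
        data_window=(0.05, 0.5),
    )
    epochs.meta["dipole_index"] = dipole_index
    return epochs, source
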