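"""Benchmark metrics: localization error, point-spread volume, input SNR.

* LE: Euclidean distance (mm) between estimated and reference locations.
* PSV: number of grid points with NAI >= 50% of the map maximum times the
  voxel volume (mm^3); an integer multiple of the voxel volume by
  construction (125 mm^3 on a 5-mm grid).
* input SNR (dB): the averaged evoked response is whitened with the noise
  whitener of the *average* (single-sample noise covariance divided by the
  number of averaged trials, rank-truncated at the effective rank Meff);
  t_max is the sample of maximum absolute whitened amplitude across
  channels, and SNR = 10 log10 of the mean squared whitened value over the
  Meff retained components at t_max.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .beamformer import NAIMap
from .errors import DegenerateDataError, InvalidArgumentError
from .preprocessing import CovarianceEstimate, build_whitener
from .synthetic import EpochedData


@dataclass
class MetricsRecord:
    """One dataset x variant evaluation row."""

    dataset_id: str
    variant_id: str
    localization_error: float  # mm
    psv: float  # mm^3
    input_snr: float  # dB
    t_max: float  # s
    amplitude_nam: Optional[float] = None
    seed: Optional[int] = None


def localization_error(estimated: np.ndarray, reference: np.ndarray) -> float:
    """Euclidean distance between two locations given in meters, in mm."""
    est = np.asarray(estimated, float)
    ref = np.asarray(reference, float)
    if not (np.all(np.isfinite(est)) and np.all(np.isfinite(ref))):
        raise InvalidArgumentError("locations must be finite")
    return float(np.linalg.norm(est - ref) * 1e3)


def point_spread_volume(nai_map: NAIMap, threshold_fraction: float = 0.5) -> float:
    """Volume (mm^3) of grid points at or above a fraction of the peak NAI."""
    nai = nai_map.nai
    if nai.size == 0:
        raise InvalidArgumentError("empty NAI map")
    thr = threshold_fraction * nai.max()
    count = int((nai >= thr).sum())
    return count * nai_map.grid.voxel_volume * 1e9  # m^3 -> mm^3


def input_snr(
    epochs: EpochedData,
    noise_cov: CovarianceEstimate,
    nave: Optional[int] = None,
):
    """Input SNR (dB) of the averaged evoked response, and t_max (s).

    ``nave`` defaults to the trial count of ``epochs``; pass it explicitly
    when handing in an already-averaged single-trial container.
    """
    if noise_cov.effective_rank == 0:
        raise DegenerateDataError("noise covariance has zero effective rank")
    if epochs.n_channels != noise_cov.n_channels:
        raise InvalidArgumentError("evoked and noise covariance channel mismatch")
    nave = epochs.n_trials if nave is None else nave
    evoked = epochs.average()
    whitener = build_whitener(noise_cov, "full")
    white = np.sqrt(nave) * (whitener.matrix @ evoked)
    meff = noise_cov.effective_rank
    flat_max = np.abs(white).max(axis=0)  # over channels, per sample
    t_idx = int(np.argmax(flat_max))  # ties -> earliest sample
    t_max = float(epochs.times[t_idx])
    power = float((white[:, t_idx] ** 2).sum() / meff)
    if power <= 0:
        raise DegenerateDataError("whitened evoked response is identically zero")
    return 10.0 * np.log10(power), t_max
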