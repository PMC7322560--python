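"""Filtering, trial rejection, covariance estimation and whitening.

Conventions:

* covariances pool per-trial scatter matrices over a half-open time window
  and normalize by the total number of pooled samples Ns (not Ns - 1);
  per-trial, per-channel window means are removed by default;
* the effective rank Meff = M - (number of near-zero eigenvalues) is always
  recorded from the *unregularized* spectrum, and regularized copies carry
  it forward -- whiteners truncate there;
* Tikhonov regularization uses lambda = ratio * Trace(C) / M with ratio
  0.05 by default, optionally per sensor-type block, optionally after
  zeroing magnetometer-gradiometer cross terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import signal as sp_signal

from .errors import DegenerateDataError, InvalidArgumentError
from .geometry import SensorArray
from .synthetic import EpochedData

DEFAULT_REG_RATIO = 0.05
DEFAULT_RANK_TOL = 1e-8


def bandpass_zero_phase(
    epochs: EpochedData,
    low: float = 2.0,
    high: float = 40.0,
    design: str = "butter",
    order: int = 4,
) -> EpochedData:
    """Zero-phase (forward-backward) band-pass filter applied per trial.

    ``design='butter'`` applies the squared magnitude response of a
    4th-order IIR Butterworth band-pass (the steady state of a
    forward-backward ``filtfilt`` run) in the frequency domain, which is
    exact for circularly extended data and free of per-epoch edge
    transients; epochs meant for covariance analysis should still be
    simulated with temporal padding and cropped afterwards (see
    ``EpochedData.crop``).  ``design='fir'`` runs a linear-phase window FIR
    through ``filtfilt``.  The per-trial, per-channel mean (DC) is removed
    first.
    """
    sfreq = epochs.sfreq
    if not (0 < low < high < sfreq / 2):
        raise InvalidArgumentError("need 0 < low < high < Nyquist")
    x = epochs.data - epochs.data.mean(axis=-1, keepdims=True)
    if design == "butter":
        sos = sp_signal.butter(order, [low, high], btype="bandpass", fs=sfreq, output="sos")
        freqs = np.fft.rfftfreq(epochs.n_samples, d=1.0 / sfreq)
        _, h = sp_signal.sosfreqz(sos, worN=freqs, fs=sfreq)
        y = np.fft.irfft(np.fft.rfft(x, axis=-1) * np.abs(h) ** 2,
                         n=epochs.n_samples, axis=-1)
    elif design == "fir":
        padlen = int(min(epochs.n_samples - 2, max(27, 3 * sfreq / (2 * np.pi * low))))
        numtaps = int(round(3 * sfreq / low))
        numtaps += 1 - numtaps % 2  # odd
        numtaps = min(numtaps, max(3, 2 * (epochs.n_samples // 3) - 1))
        b = sp_signal.firwin(numtaps, [low, high], pass_zero=False, fs=sfreq)
        y = sp_signal.filtfilt(b, [1.0], x, axis=-1, padlen=padlen)
    else:
        raise InvalidArgumentError(f"unknown filter design {design!r}")
    return replace(epochs, data=y)


def reject_trials_by_variance(
    epochs: EpochedData,
    lower_pct: float = 2.0,
    upper_pct: float = 98.0,
):
    """Drop trials whose max-over-channels variance is extreme.

    The per-trial statistic is the maximum over channels of the per-channel
    variance across samples.  Trials strictly above the ``upper_pct``
    percentile or strictly below the ``lower_pct`` percentile of that
    statistic (linear-interpolation percentiles) are removed; with a
    degenerate (all-equal) distribution nothing is removed.
    Returns ``(epochs, report)`` where the report lists dropped indices.
    """
    if epochs.n_trials < 5:
        raise DegenerateDataError("need at least 5 trials for variance rejection")
    stat = epochs.data.var(axis=-1).max(axis=-1)  # (trials,)
    hi = np.percentile(stat, upper_pct)
    lo = np.percentile(stat, lower_pct)
    drop = (stat > hi) | (stat < lo)
    if drop.all():
        raise DegenerateDataError("variance rejection removed every trial")
    kept = replace(epochs, data=epochs.data[~drop])
    report = {
        "dropped": np.flatnonzero(drop).tolist(),
        "n_kept": int((~drop).sum()),
        "lower_threshold": float(lo),
        "upper_threshold": float(hi),
    }
    return kept, report


@dataclass
class CovarianceEstimate:
    """Sample covariance with its spectrum and effective rank.

    ``effective_rank`` (Meff) counts eigenvalues at or above
    ``rank_tol * max eigenvalue`` of the *unregularized* matrix;
    ``near_zero_count`` is the complement.  ``lambda_used`` records any
    Tikhonov loading added (scalar, or dict per sensor type).
    """

    matrix: np.ndarray
    n_samples: int
    n_trials_used: int
    kind: str = "data"
    lambda_used: object = 0.0
    rank_tol: float = DEFAULT_RANK_TOL
    eigenvalues: np.ndarray = field(init=False)
    near_zero_count: int = field(init=False)
    effective_rank: int = field(init=False)
    _inherit_rank: Optional[tuple] = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float)
        M = self.matrix.shape[0]
        if self.matrix.shape != (M, M):
            raise InvalidArgumentError("covariance must be square")
        sym_err = np.abs(self.matrix - self.matrix.T).max()
        scale = max(np.abs(self.matrix).max(), 1e-300)
        if sym_err > 1e-10 * scale:
            raise InvalidArgumentError("covariance must be symmetric")
        self.matrix = 0.5 * (self.matrix + self.matrix.T)
        self.eigenvalues = np.linalg.eigvalsh(self.matrix)[::-1]  # descending
        if self._inherit_rank is not None:
            self.near_zero_count, self.effective_rank = self._inherit_rank
        else:
            top = self.eigenvalues[0]
            if top <= 0:
                self.near_zero_count = M
            else:
                self.near_zero_count = int(
                    (self.eigenvalues < self.rank_tol * top).sum()
                )
            self.effective_rank = M - self.near_zero_count

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]


def compute_covariance(
    epochs: EpochedData,
    window: tuple,
    kind: str = "data",
    demean: bool = True,
    rank_tol: float = DEFAULT_RANK_TOL,
) -> CovarianceEstimate:
    """Trial-pooled sample covariance over a time window.

    C = (sum_i C_i) / Ns where C_i is the scatter of trial i over the
    window samples (after per-trial, per-channel demeaning when ``demean``)
    and Ns is the total number of pooled samples.
    """
    sl = epochs.window_slice(window)
    x = epochs.data[:, :, sl]
    if demean:
        x = x - x.mean(axis=-1, keepdims=True)
    n_trials, M, n_win = x.shape
    ns = n_trials * n_win
    flat = x.transpose(1, 0, 2).reshape(M, ns)
    C = (flat @ flat.T) / ns
    return CovarianceEstimate(C, ns, n_trials, kind=kind, rank_tol=rank_tol)


def _type_blocks(array: SensorArray):
    return {
        "magnetometer": np.flatnonzero(array.magnetometer_mask),
        "planar_gradiometer": np.flatnonzero(array.gradiometer_mask),
    }


def zero_cross_sensor_terms(matrix: np.ndarray, array: SensorArray) -> np.ndarray:
    """Zero the magnetometer-gradiometer off-blocks; diagonal blocks kept."""
    out = matrix.copy()
    mag = array.magnetometer_mask
    grad = array.gradiometer_mask
    out[np.ix_(mag, grad)] = 0.0
    out[np.ix_(grad, mag)] = 0.0
    return out


def regularize(
    cov: CovarianceEstimate,
    ratio: float = DEFAULT_REG_RATIO,
    per_sensor_type: bool = False,
    zero_cross_terms: bool = False,
    array: Optional[SensorArray] = None,
) -> CovarianceEstimate:
    """Tikhonov-load a covariance: C + lambda*I, lambda = ratio*Trace(C)/M.

    With ``per_sensor_type`` the loading is computed and added separately for
    the magnetometer and gradiometer blocks (lambda_t = ratio*Trace(C_t)/M_t).
    ``zero_cross_terms`` removes the magnetometer-gradiometer covariance
    before loading.  The effective rank of the input (pre-regularization
    spectrum) is carried forward unchanged.
    """
    if ratio < 0:
        raise InvalidArgumentError("regularization ratio must be >= 0")
    if (per_sensor_type or zero_cross_terms) and array is None:
        raise InvalidArgumentError("sensor-type-aware regularization needs the array")
    C = cov.matrix
    if zero_cross_terms:
        C = zero_cross_sensor_terms(C, array)
    M = C.shape[0]
    if per_sensor_type:
        lam = {}
        C = C.copy()
        for name, idx in _type_blocks(array).items():
            if idx.size == 0:
                continue
            lam_t = ratio * np.trace(C[np.ix_(idx, idx)]) / idx.size
            C[idx, idx] += lam_t
            lam[name] = float(lam_t)
    else:
        lam = float(ratio * np.trace(C) / M)
        C = C + lam * np.eye(M)
    return CovarianceEstimate(
        C,
        cov.n_samples,
        cov.n_trials_used,
        kind=cov.kind,
        lambda_used=lam,
        rank_tol=cov.rank_tol,
        _inherit_rank=(cov.near_zero_count, cov.effective_rank),
    )


@dataclass
class WhiteningOperator:
    """M x M whitener derived from a noise covariance.

    In ``full`` mode the matrix is the rank-truncated inverse square root of
    Cn (truncation at the covariance's effective rank); applying it to data
    drawn from Cn yields identity covariance on the retained subspace.
    ``block_by_sensor_type`` does the same per sensor-type block with cross
    terms ignored.  ``none`` is the identity.
    """

    matrix: np.ndarray
    mode: str
    rank_truncation: int

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Whiten data with channels on the second-to-last axis... or first.

        Accepts (M,), (M, T) or (trials, M, T)."""
        if x.ndim <= 2:
            return self.matrix @ x
        return np.einsum("ij,njt->nit", self.matrix, x)


def _inv_sqrt(matrix: np.ndarray, rank: int) -> np.ndarray:
    w, V = np.linalg.eigh(matrix)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    r = min(rank, (w > 0).sum())
    if r == 0:
        raise DegenerateDataError("noise covariance has no positive eigenvalues")
    Vr = V[:, :r]
    return (Vr / np.sqrt(w[:r])) @ Vr.T


def build_whitener(
    noise_cov: CovarianceEstimate,
    mode: str = "full",
    array: Optional[SensorArray] = None,
) -> WhiteningOperator:
    """Whitener from a noise covariance (see :class:`WhiteningOperator`)."""
    M = noise_cov.n_channels
    if mode == "none":
        return WhiteningOperator(np.eye(M), "none", M)
    if noise_cov.eigenvalues[0] <= 0:
        raise DegenerateDataError("noise covariance is zero or negative")
    if mode == "full":
        W = _inv_sqrt(noise_cov.matrix, noise_cov.effective_rank)
        return WhiteningOperator(W, "full", noise_cov.effective_rank)
    if mode == "block_by_sensor_type":
        if array is None:
            raise InvalidArgumentError("block whitening needs the sensor array")
        W = np.zeros((M, M))
        total_rank = 0
        top = noise_cov.eigenvalues[0]
        for name, idx in _type_blocks(array).items():
            if idx.size == 0:
                continue
            block = noise_cov.matrix[np.ix_(idx, idx)]
            wb = np.linalg.eigvalsh(block)
            rank_b = int((wb >= noise_cov.rank_tol * wb.max()).sum())
            W[np.ix_(idx, idx)] = _inv_sqrt(block, rank_b)
            total_rank += rank_b
        return WhiteningOperator(W, "block_by_sensor_type", total_rank)
    raise InvalidArgumentError(f"unknown whitening mode {mode!r}")
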