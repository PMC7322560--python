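"""LCMV beamformer scanning: vector and scalar neural-activity-index maps.

The linearly constrained minimum-variance (LCMV) filter for a source at r_j
with local leadfield L (M x 3) and data covariance C is

    W^T = (L^T C^-1 L)^-1 L^T C^-1          (unit gain: W^T L = I)

with output power Var = Trace[(L^T C^-1 L)^-1] and, normalized by the same
quantity under the noise covariance Cn, the neural activity index (NAI).
The scalar variant first finds the orientation maximizing output SNR via
the generalized eigenproblem

    eta_opt = v_min{ L^T C^-2 L,  L^T C^-1 L }

and evaluates NAI = (l^T Cn^-1 l) / (l^T C^-1 l) with l = L eta_opt.

In a spherical conductor L has rank 2 (radial silence), so scanning reduces
each local leadfield to its numerically non-silent column space before
inverting any Gram matrix; nothing is silently pseudo-inverted.

Four named presets mirror how popular analysis toolboxes combine the two
MEG sensor types:

* ``mne_like``       -- scalar, full noise-covariance prewhitening;
* ``fieldtrip_like`` -- scalar, no whitening, raw SI units (T, T/m), which
  makes the numerically larger gradiometer channels dominate;
* ``spm_like``       -- scalar, no whitening, channels rescaled to fT and
  fT/mm, which makes the magnetometers dominate;
* ``brainstorm_like`` -- vector, per-sensor-type block whitening, cross
  sensor-type covariance zeroed, per-type regularization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import (
    DegenerateDataError,
    InvalidArgumentError,
    SilentSourceError,
    SingularModelError,
)
from .forward import Leadfield
from .geometry import SensorArray, SourceGrid
from .preprocessing import (
    DEFAULT_REG_RATIO,
    CovarianceEstimate,
    build_whitener,
    compute_covariance,
    regularize,
    zero_cross_sensor_terms,
)
from .synthetic import EpochedData

_COND_LIMIT = 1e12


# ---------------------------------------------------------------------------
# low-level operations (leadfield columns k may be 3, or 2 after reduction)
# ---------------------------------------------------------------------------

def _gram(L, C_inv):
    return L.T @ C_inv @ L


def _solve_gram(G, rhs):
    try:
        cond = np.linalg.cond(G)
    except np.linalg.LinAlgError:  # pragma: no cover
        raise SingularModelError("leadfield Gram matrix is not finite")
    if not np.isfinite(cond) or cond > 1 / np.finfo(float).eps:
        raise SingularModelError(
            "leadfield Gram matrix is singular; reduce to the non-silent "
            "column space before inverting"
        )
    return np.linalg.solve(G, rhs)


def vector_weights(L: np.ndarray, C_inv: np.ndarray) -> np.ndarray:
    """Unit-gain LCMV weights, W^T = (L^T C^-1 L)^-1 L^T C^-1 (k x M)."""
    LtC = L.T @ C_inv
    return _solve_gram(LtC @ L, LtC)


def vector_power(L: np.ndarray, C_inv: np.ndarray) -> float:
    """Output variance Trace[(L^T C^-1 L)^-1]."""
    G = _gram(L, C_inv)
    return float(np.trace(_solve_gram(G, np.eye(G.shape[0]))))


def vector_nai(L: np.ndarray, C_inv: np.ndarray, Cn_inv: np.ndarray) -> float:
    """Trace-ratio neural activity index of the vector beamformer."""
    return vector_power(L, C_inv) / vector_power(L, Cn_inv)


def optimal_orientation(L: np.ndarray, C_inv: np.ndarray) -> np.ndarray:
    """Orientation maximizing output SNR (smallest generalized eigenvector
    of L^T C^-2 L versus L^T C^-1 L), unit length, largest component
    positive."""
    X = C_inv @ L
    A = X.T @ X          # L^T C^-2 L
    B = L.T @ X          # L^T C^-1 L
    for G in (A, B):
        c = np.linalg.cond(G)
        if not np.isfinite(c):
            raise SingularModelError("orientation Gram matrices are singular")
        if c > _COND_LIMIT:
            warnings.warn(
                "orientation Gram condition number exceeds 1e12; "
                "result may be unreliable",
                RuntimeWarning,
            )
    try:
        vals, vecs = scipy.linalg.eigh(A, B)
    except scipy.linalg.LinAlgError as err:
        raise SingularModelError(f"generalized eigenproblem failed: {err}")
    eta = vecs[:, int(np.argmin(vals))]
    eta = eta / np.linalg.norm(eta)
    if eta[int(np.argmax(np.abs(eta)))] < 0:
        eta = -eta
    return eta


def scalar_nai(
    L: np.ndarray, eta: np.ndarray, C_inv: np.ndarray, Cn_inv: np.ndarray
) -> float:
    """NAI of the scalar beamformer at orientation eta:
    (l^T Cn^-1 l)/(l^T C^-1 l) with l = L eta."""
    l = L @ eta
    scale = np.linalg.norm(L, ord="fro")
    if np.linalg.norm(l) < 1e-12 * max(scale, 1e-300):
        raise SilentSourceError("orientation is magnetically silent at this point")
    return float((l @ Cn_inv @ l) / (l @ C_inv @ l))


# ---------------------------------------------------------------------------
# configuration and presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeamformerConfig:
    """How a scan combines sensors, regularizes and normalizes.

    ``unit_scale='si'`` keeps T and T/m; ``'fT_fTmm'`` rescales channels to
    fT and fT/mm (magnetometers x1e15, gradiometers x1e12) before any
    covariance arithmetic -- the deliberate mis-scaling through which
    unwhitened pipelines favor one sensor type.
    """

    type: str = "scalar"  # scalar | vector
    reg_ratio: float = DEFAULT_REG_RATIO
    whitening: str = "full"  # full | block_by_sensor_type | none
    zero_cross_terms: bool = False
    per_sensor_type_lambda: bool = False
    sensor_selection: str = "all"  # all | magnetometers | gradiometers
    unit_scale: str = "si"  # si | fT_fTmm
    vector_nai_combine: str = "sum"
    name: str = "custom"

    def __post_init__(self):
        if self.type not in ("scalar", "vector"):
            raise InvalidArgumentError("type must be 'scalar' or 'vector'")
        if self.whitening not in ("full", "block_by_sensor_type", "none"):
            raise InvalidArgumentError(f"unknown whitening {self.whitening!r}")
        if self.sensor_selection not in ("all", "magnetometers", "gradiometers"):
            raise InvalidArgumentError("bad sensor_selection")
        if self.vector_nai_combine != "sum":
            raise InvalidArgumentError("only 'sum' combination is implemented")


PRESETS = {
    "mne_like": BeamformerConfig(type="scalar", whitening="full", name="mne_like"),
    "fieldtrip_like": BeamformerConfig(
        type="scalar", whitening="none", unit_scale="si", name="fieldtrip_like"
    ),
    "spm_like": BeamformerConfig(
        type="scalar", whitening="none", unit_scale="fT_fTmm", name="spm_like"
    ),
    "brainstorm_like": BeamformerConfig(
        type="vector",
        whitening="block_by_sensor_type",
        zero_cross_terms=True,
        per_sensor_type_lambda=True,
        name="brainstorm_like",
    ),
}


def get_config(name_or_config) -> BeamformerConfig:
    if isinstance(name_or_config, BeamformerConfig):
        return name_or_config
    try:
        return PRESETS[name_or_config]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown preset {name_or_config!r}; available: {sorted(PRESETS)}"
        )


# ---------------------------------------------------------------------------
# map container
# ---------------------------------------------------------------------------

@dataclass
class NAIMap:
    """NAI value per grid point, with scalar-mode orientations and the peak."""

    grid: SourceGrid
    nai: np.ndarray
    orientation: Optional[np.ndarray]  # (N, 3) unit vectors or None (vector mode)
    peak_index: int = field(init=False)

    def __post_init__(self):
        self.nai = np.asarray(self.nai, float)
        finite_max = np.nanmax(self.nai)
        at_max = np.flatnonzero(self.nai == finite_max)
        if at_max.size > 1:
            warnings.warn(
                f"{at_max.size} grid points tie at the NAI maximum; "
                "taking the lowest index",
                RuntimeWarning,
            )
        self.peak_index = int(at_max[0])

    @property
    def peak_location(self) -> np.ndarray:
        return self.grid.points[self.peak_index]

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.to_table()
        df["nai"] = self.nai
        if self.orientation is not None:
            df[["eta_x", "eta_y", "eta_z"]] = self.orientation
        return df


# ---------------------------------------------------------------------------
# vectorized scanning helpers
# ---------------------------------------------------------------------------

def _reduce_leadfields(gain: np.ndarray, tol: float = 1e-8):
    """Batched SVD reduction of (N, M, 3) gains to their non-silent span.

    Returns U2*s2 (N, M, 2) reduced leadfields, V2 (N, 3, 2) back-rotation,
    and a validity mask (points with < 2 usable columns are flagged).  In a
    sphere the discarded direction is the local radial one.
    """
    U, s, Vt = np.linalg.svd(gain, full_matrices=False)
    smax = s[:, 0]
    ok = smax > 0
    rank2 = np.ones_like(smax, dtype=bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        rank2 &= (s[:, 1] > tol * smax) & ok
    L2 = U[:, :, :2] * s[:, None, :2]
    V2 = Vt.transpose(0, 2, 1)[:, :, :2]
    return L2, V2, rank2


def _gen_eig_min_2x2(A: np.ndarray, B: np.ndarray):
    """Smallest generalized eigenvector of the 2x2 pencils (A, B), batched.

    Solves det(A - lam B) = 0 in closed form; B must be positive definite.
    Returns unit eigenvectors (N, 2).
    """
    a00, a01, a11 = A[:, 0, 0], A[:, 0, 1], A[:, 1, 1]
    b00, b01, b11 = B[:, 0, 0], B[:, 0, 1], B[:, 1, 1]
    c2 = b00 * b11 - b01**2
    c1 = a00 * b11 + a11 * b00 - 2.0 * a01 * b01
    c0 = a00 * a11 - a01**2
    disc = np.sqrt(np.clip(c1**2 - 4.0 * c2 * c0, 0.0, None))
    lam = (c1 - disc) / (2.0 * c2)
    m00 = a00 - lam * b00
    m01 = a01 - lam * b01
    m11 = a11 - lam * b11
    # v is orthogonal to the larger row of (A - lam B)
    row0 = np.stack([m00, m01], axis=1)
    row1 = np.stack([m01, m11], axis=1)
    use0 = np.linalg.norm(row0, axis=1) >= np.linalg.norm(row1, axis=1)
    rows = np.where(use0[:, None], row0, row1)
    v = np.stack([-rows[:, 1], rows[:, 0]], axis=1)
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    degenerate = norm[:, 0] == 0
    v[degenerate] = np.array([1.0, 0.0])  # isotropic pencil: any orientation
    norm[degenerate] = 1.0
    return v / norm


def _inv_pd(matrix: np.ndarray) -> np.ndarray:
    """Inverse of a symmetric positive-definite matrix via eigendecomposition."""
    w, V = np.linalg.eigh(matrix)
    if w[0] <= 0:
        raise DegenerateDataError(
            "regularized covariance is not positive definite"
        )
    return (V / w) @ V.T


# ---------------------------------------------------------------------------
# the model / results pair
# ---------------------------------------------------------------------------

class LCMVBeamformer:
    """LCMV scanning model built from covariances and a leadfield.

    Parameters
    ----------
    data_cov, noise_cov : CovarianceEstimate
        Unregularized sample covariances (active and baseline windows).
    leadfield : Leadfield
        Scanning-grid gains consistent with ``array``.
    array : SensorArray
        Channel geometry/types, used for sensor selection, unit scaling,
        cross-term zeroing and per-type regularization.
    config : BeamformerConfig or preset name
    """

    def __init__(self, data_cov, noise_cov, leadfield, array, config="mne_like"):
        self.config = get_config(config)
        if data_cov.n_channels != array.n_channels:
            raise InvalidArgumentError("covariance/array channel mismatch")
        if leadfield.n_channels != array.n_channels:
            raise InvalidArgumentError("leadfield/array channel mismatch")
        self.data_cov = data_cov
        self.noise_cov = noise_cov
        self.leadfield = leadfield
        self.array = array

    @classmethod
    def from_epochs(cls, epochs: EpochedData, leadfield, array=None,
                    config="mne_like", demean=True):
        """Build covariances from the epochs' marked noise/data windows."""
        array = array if array is not None else epochs.array
        if array is None:
            raise InvalidArgumentError("no sensor array available")
        C = compute_covariance(epochs, epochs.data_window, "data", demean=demean)
        Cn = compute_covariance(epochs, epochs.noise_window, "noise", demean=demean)
        return cls(C, Cn, leadfield, array, config)

    # -- pipeline pieces ---------------------------------------------------

    def _selection_mask(self):
        sel = self.config.sensor_selection
        if sel == "all":
            return np.ones(self.array.n_channels, bool)
        if sel == "magnetometers":
            return self.array.magnetometer_mask
        return self.array.gradiometer_mask

    def _prepared(self):
        """Apply selection, unit scaling, cross zeroing, whitening and
        regularization; return (C_inv, Cn_inv, gains, diagnostics)."""
        cfg = self.config
        mask = self._selection_mask()
        sub = self.array.subset(mask)
        C = self.data_cov.matrix[np.ix_(mask, mask)]
        Cn = self.noise_cov.matrix[np.ix_(mask, mask)]
        G = self.leadfield.gain[:, mask, :]

        if cfg.unit_scale == "fT_fTmm":
            d = np.where(sub.magnetometer_mask, 1e15, 1e12)
            C = C * np.outer(d, d)
            Cn = Cn * np.outer(d, d)
            G = G * d[None, :, None]
        elif cfg.unit_scale != "si":
            raise InvalidArgumentError(f"unknown unit_scale {cfg.unit_scale!r}")

        if cfg.zero_cross_terms:
            C = zero_cross_sensor_terms(C, sub)
            Cn = zero_cross_sensor_terms(Cn, sub)

        C_est = CovarianceEstimate(
            C, self.data_cov.n_samples, self.data_cov.n_trials_used,
            kind="data", rank_tol=self.data_cov.rank_tol)
        Cn_est = CovarianceEstimate(
            Cn, self.noise_cov.n_samples, self.noise_cov.n_trials_used,
            kind="noise", rank_tol=self.noise_cov.rank_tol)

        if cfg.whitening != "none":
            whitener = build_whitener(Cn_est, cfg.whitening, array=sub)
            W = whitener.matrix
            C = W @ C @ W.T
            C = 0.5 * (C + C.T)  # exact symmetry lost to rounding
            Cn = W @ Cn @ W.T
            Cn = 0.5 * (Cn + Cn.T)
            G = np.einsum("ij,njk->nik", W, G)
            C_est = CovarianceEstimate(C, C_est.n_samples, C_est.n_trials_used,
                                       kind="data", rank_tol=C_est.rank_tol)
            Cn_est = CovarianceEstimate(Cn, Cn_est.n_samples, Cn_est.n_trials_used,
                                        kind="noise", rank_tol=Cn_est.rank_tol)
        else:
            whitener = None

        C_reg = regularize(C_est, cfg.reg_ratio,
                           per_sensor_type=cfg.per_sensor_type_lambda,
                           array=sub if cfg.per_sensor_type_lambda else None)
        Cn_reg = regularize(Cn_est, cfg.reg_ratio,
                            per_sensor_type=cfg.per_sensor_type_lambda,
                            array=sub if cfg.per_sensor_type_lambda else None)
        C_inv = _inv_pd(C_reg.matrix)
        Cn_inv = _inv_pd(Cn_reg.matrix)
        diag = {
            "lambda_data": C_reg.lambda_used,
            "lambda_noise": Cn_reg.lambda_used,
            "effective_rank_noise": self.noise_cov.effective_rank
            if cfg.sensor_selection == "all" else Cn_est.effective_rank,
            "cond_data": float(C_reg.eigenvalues[0] / C_reg.eigenvalues[-1]),
            "n_channels_used": int(mask.sum()),
            "whitener_rank": whitener.rank_truncation if whitener else None,
        }
        return C_inv, Cn_inv, G, diag

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "LCMVResults":
        """Scan every grid point and return the NAI map results object."""
        cfg = self.config
        C_inv, Cn_inv, G, diag = self._prepared()
        N, M, _ = G.shape
        L2, V2, ok = _reduce_leadfields(G)

        # two dense M x (2N) products do nearly all of the work
        flat = L2.transpose(1, 0, 2).reshape(M, 2 * N)
        X = (C_inv @ flat).reshape(M, N, 2).transpose(1, 0, 2)   # C^-1 L
        Y = (Cn_inv @ flat).reshape(M, N, 2).transpose(1, 0, 2)  # Cn^-1 L
        B = np.einsum("nmi,nmj->nij", L2, X)    # L^T C^-1 L
        Bn = np.einsum("nmi,nmj->nij", L2, Y)   # L^T Cn^-1 L
        nai = np.zeros(N)
        orientation = None
        with np.errstate(invalid="ignore", divide="ignore"):
            if cfg.type == "vector":
                # trace of 2x2 inverses -> trace-ratio NAI
                detB = B[:, 0, 0] * B[:, 1, 1] - B[:, 0, 1] ** 2
                detBn = Bn[:, 0, 0] * Bn[:, 1, 1] - Bn[:, 0, 1] ** 2
                tr_inv_B = (B[:, 0, 0] + B[:, 1, 1]) / detB
                tr_inv_Bn = (Bn[:, 0, 0] + Bn[:, 1, 1]) / detBn
                vals = tr_inv_B / tr_inv_Bn
            else:
                A = np.einsum("nmi,nmj->nij", X, X)  # L^T C^-2 L
                eta2 = _gen_eig_min_2x2(A, B)
                num = np.einsum("ni,nij,nj->n", eta2, Bn, eta2)
                den = np.einsum("ni,nij,nj->n", eta2, B, eta2)
                vals = num / den
                orientation = np.full((N, 3), np.nan)
                eta3 = np.einsum("nij,nj->ni", V2, eta2)
                eta3 /= np.linalg.norm(eta3, axis=1, keepdims=True)
                flip = np.take_along_axis(
                    eta3, np.argmax(np.abs(eta3), axis=1)[:, None], axis=1
                )[:, 0] < 0
                eta3[flip] *= -1
                orientation[ok] = eta3[ok]
        nai[ok] = vals[ok]
        nai[~ok] = 0.0  # silent points (e.g. the sphere origin)
        if not np.all(np.isfinite(nai)):
            raise DegenerateDataError("non-finite NAI values in the scan")
        nmap = NAIMap(self.leadfield.grid, nai, orientation)
        return LCMVResults(self, nmap, diag)


class LCMVResults:
    """Fitted NAI map with its peak, diagnostics and summary table."""

    def __init__(self, model: LCMVBeamformer, nai_map: NAIMap, diagnostics: dict):
        self.model = model
        self.map = nai_map
        self.diagnostics = diagnostics

    @property
    def peak_location(self) -> np.ndarray:
        return self.map.peak_location

    @property
    def peak_nai(self) -> float:
        return float(self.map.nai[self.map.peak_index])

    def point_spread_volume(self, threshold_fraction: float = 0.5) -> float:
        from .metrics import point_spread_volume

        return point_spread_volume(self.map, threshold_fraction)

    def localization_error(self, reference: np.ndarray) -> float:
        from .metrics import localization_error

        return localization_error(self.peak_location, reference)

    def to_frame(self) -> pd.DataFrame:
        return self.map.to_frame()

    def summary(self) -> str:
        cfg = self.model.config
        d = self.diagnostics
        peak = self.peak_location
        lines = [
            "LCMV beamformer scan results",
            "=" * 44,
            f"variant:            {cfg.name} ({cfg.type})",
            f"whitening:          {cfg.whitening}",
            f"regularization:     ratio={cfg.reg_ratio}"
            f" lambda_data={d['lambda_data']}",
            f"channels used:      {d['n_channels_used']}",
            f"noise eff. rank:    {d['effective_rank_noise']}",
            f"grid points:        {self.map.grid.n_points}"
            f" (spacing {self.map.grid.spacing * 1e3:.1f} mm)",
            f"peak NAI:           {self.peak_nai:.4g}",
            f"peak location (mm): [{peak[0]*1e3:.1f}, {peak[1]*1e3:.1f},"
            f" {peak[2]*1e3:.1f}]",
            f"PSV at 50% (mm^3):  {self.point_spread_volume():.0f}",
        ]
        return "\n".join(lines)

    def plot_map(self, axis="z", ax=None):  # pragma: no cover - optional viz
        """Quick-look scatter of the NAI map in the peak's axial plane."""
        import matplotlib.pyplot as plt

        k = {"x": 0, "y": 1, "z": 2}[axis]
        pts = self.map.grid.points
        plane = np.isclose(pts[:, k], self.peak_location[k])
        if ax is None:
            _, ax = plt.subplots()
        other = [i for i in range(3) if i != k]
        sc = ax.scatter(pts[plane, other[0]] * 1e3, pts[plane, other[1]] * 1e3,
                        c=self.map.nai[plane], s=12)
        ax.plot(self.peak_location[other[0]] * 1e3,
                self.peak_location[other[1]] * 1e3, "r+")
        ax.set_xlabel("xyz"[other[0]] + " (mm)")
        ax.set_ylabel("xyz"[other[1]] + " (mm)")
        plt.colorbar(sc, ax=ax, label="NAI")
        return ax


def scan(data_or_covs, leadfield, config="mne_like", noise_cov=None, array=None):
    """Functional wrapper: scan epochs or (C, Cn) into an NAI map.

    ``scan(epochs, leadfield, config)`` or
    ``scan(data_cov, leadfield, config, noise_cov=..., array=...)``.
    """
    if isinstance(data_or_covs, EpochedData):
        model = LCMVBeamformer.from_epochs(data_or_covs, leadfield,
                                           array=array, config=config)
    else:
        model = LCMVBeamformer(data_or_covs, noise_cov, leadfield, array, config)
    return model.fit()
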