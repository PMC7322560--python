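"""Forward model: current dipole in a homogeneous conducting sphere.

The magnetic field outside a spherically symmetric conductor due to a
primary current dipole has a closed form (Sarvas).  With the sphere centred
at the origin, source at r0, sensing point at r, moment Q:

    a = r - r0,   a = |a|,   R = |r|
    F = a (a R + R^2 - r0 . r)
    grad F = (a^2/R + a.r/a + 2a + 2R) r - (a + 2R + a.r/a) r0
    B(r) = mu0 / (4 pi F^2) * ( F (Q x r0) - (Q x r0 . r) grad F )

Only the tangential part of the moment contributes: a radial dipole is
magnetically silent, which is why the local leadfield at any grid point has
numerical rank 2.  Volume currents are fully accounted for by the formula;
the conductor radius never enters the field values, only the validity checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import DomainError, InvalidArgumentError
from .geometry import SensorArray, SourceGrid, SphereModel

MU0 = 4e-7 * np.pi
_OVER_4PI = MU0 / (4.0 * np.pi)


def _dipole_transfer(sources: np.ndarray, sensors: np.ndarray) -> np.ndarray:
    """(P, S, 3, 3) tensor T with B = T @ Q, origin-centred coordinates.

    B = c/F^2 (F I - gradF r^T) K Q with K Q = Q x r0, i.e.
    K = -skew(r0).  Fully vectorized over source points P and sensing
    points S.
    """
    r0 = np.asarray(sources, float)  # (P, 3)
    r = np.asarray(sensors, float)  # (S, 3)
    a_vec = r[None, :, :] - r0[:, None, :]  # (P, S, 3)
    a = np.linalg.norm(a_vec, axis=-1)  # (P, S)
    R = np.linalg.norm(r, axis=-1)  # (S,)
    r0_dot_r = r0 @ r.T  # (P, S)
    a_dot_r = np.einsum("psk,sk->ps", a_vec, r)
    F = a * (a * R[None, :] + R[None, :] ** 2 - r0_dot_r)
    with np.errstate(divide="raise", invalid="raise"):
        gF = (
            (a**2 / R[None, :] + a_dot_r / a + 2.0 * a + 2.0 * R[None, :])[..., None]
            * r[None, :, :]
            - (a + 2.0 * R[None, :] + a_dot_r / a)[..., None] * r0[:, None, :]
        )
    # K[p] @ Q = Q x r0[p]  =>  K = -skew(r0)
    P = r0.shape[0]
    K = np.zeros((P, 3, 3))
    K[:, 0, 1] = r0[:, 2]
    K[:, 0, 2] = -r0[:, 1]
    K[:, 1, 0] = -r0[:, 2]
    K[:, 1, 2] = r0[:, 0]
    K[:, 2, 0] = r0[:, 1]
    K[:, 2, 1] = -r0[:, 0]
    rK = np.einsum("sj,pjk->psk", r, K)  # (P, S, 3) row vector r^T K
    T = F[..., None, None] * K[:, None, :, :] - gF[..., :, None] * rK[..., None, :]
    T *= (_OVER_4PI / F**2)[..., None, None]
    return T


def dipole_field(
    source_pos: np.ndarray,
    moment: np.ndarray,
    sensor_pos: np.ndarray,
    sphere: SphereModel,
) -> np.ndarray:
    """Magnetic field (T) of a current dipole in a conducting sphere.

    Parameters
    ----------
    source_pos, sensor_pos : (3,) arrays, m, head coordinates.
    moment : (3,) array, A*m.
    """
    source_pos = np.asarray(source_pos, float) - sphere.origin
    sensor_pos = np.asarray(sensor_pos, float) - sphere.origin
    if np.linalg.norm(sensor_pos) <= sphere.conductor_radius:
        raise DomainError("sensor position lies inside the conducting sphere")
    if np.linalg.norm(source_pos) < 1e-12:
        raise DomainError("source at the sphere origin (formula singular)")
    if np.linalg.norm(sensor_pos - source_pos) < 1e-12:
        raise DomainError("source and sensor coincide")
    T = _dipole_transfer(source_pos[None, :], sensor_pos[None, :])[0, 0]
    return T @ np.asarray(moment, float)


def channel_response(
    field_sampler: Callable[[np.ndarray], np.ndarray],
    array: SensorArray,
    index: int,
) -> float:
    """Reading of one channel given a field sampler position -> B (T).

    Magnetometer: B(pos) . n  (T).  Planar gradiometer: two-point finite
    difference of (B . n) across the baseline, divided by its length (T/m).
    """
    pos = array.channel_position[index]
    n = array.channel_orientation[index]
    if array.channel_type[index] == "magnetometer":
        return float(np.dot(field_sampler(pos), n))
    b = array.gradiometer_baseline[index]
    blen = np.linalg.norm(b)
    if blen <= 0:
        raise InvalidArgumentError("gradiometer has zero-length baseline")
    f_plus = np.dot(field_sampler(pos + 0.5 * b), n)
    f_minus = np.dot(field_sampler(pos - 0.5 * b), n)
    return float((f_plus - f_minus) / blen)


@dataclass
class Leadfield:
    """Per-grid-point M x 3 gain matrices, unit-moment convention.

    ``gain[j, m, k]`` is the reading of channel m for a unit dipole
    (1 A*m) at grid point j with moment along Cartesian axis k
    (T per A*m for magnetometers, T/m per A*m for gradiometers).
    """

    gain: np.ndarray  # (N, M, 3)
    grid: SourceGrid
    array: SensorArray

    @property
    def n_points(self) -> int:
        return self.gain.shape[0]

    @property
    def n_channels(self) -> int:
        return self.gain.shape[1]


def _eval_positions(array: SensorArray):
    """Field-evaluation positions for all channels and the recombination plan.

    Magnetometers need one sample; planar gradiometers two (baseline
    endpoints).  Returns (E,3) positions plus index arrays for assembly.
    """
    mag = array.magnetometer_mask
    grad = array.gradiometer_mask
    mag_idx = np.flatnonzero(mag)
    grad_idx = np.flatnonzero(grad)
    pos_m = array.channel_position[mag_idx]
    b = array.gradiometer_baseline[grad_idx]
    pos_gp = array.channel_position[grad_idx] + 0.5 * b
    pos_gm = array.channel_position[grad_idx] - 0.5 * b
    eval_pos = np.vstack([pos_m, pos_gp, pos_gm])
    return eval_pos, mag_idx, grad_idx


def point_gain(
    source_pos: np.ndarray, array: SensorArray, sphere: SphereModel
) -> np.ndarray:
    """M x 3 gain matrix for a single source location."""
    return compute_leadfield_points(
        np.asarray(source_pos, float)[None, :], array, sphere
    )[0]


def compute_leadfield_points(
    sources: np.ndarray,
    array: SensorArray,
    sphere: SphereModel,
    chunk: int = 512,
) -> np.ndarray:
    """(P, M, 3) gains for arbitrary source positions (vectorized Sarvas)."""
    sources = np.atleast_2d(np.asarray(sources, float)) - sphere.origin
    rad = np.linalg.norm(sources, axis=1)
    if np.any(rad > sphere.conductor_radius + 1e-12):
        raise DomainError("source point outside the conducting sphere")
    eval_pos, mag_idx, grad_idx = _eval_positions(array)
    eval_pos = eval_pos - sphere.origin
    if np.any(np.linalg.norm(eval_pos, axis=1) <= sphere.conductor_radius):
        raise DomainError("sensor integration point inside the conducting sphere")
    n_mag, n_grad = mag_idx.size, grad_idx.size
    M = array.n_channels
    ori_m = array.channel_orientation[mag_idx]
    ori_g = array.channel_orientation[grad_idx]
    blen = np.linalg.norm(array.gradiometer_baseline[grad_idx], axis=1)

    out = np.empty((sources.shape[0], M, 3))
    for start in range(0, sources.shape[0], chunk):
        sl = slice(start, start + chunk)
        src = sources[sl]
        origin_like = np.linalg.norm(src, axis=1) < 1e-12
        T = _dipole_transfer(src[~origin_like] if origin_like.any() else src, eval_pos)
        if origin_like.any():
            Tfull = np.zeros((src.shape[0], eval_pos.shape[0], 3, 3))
            Tfull[~origin_like] = T
            T = Tfull  # a dipole exactly at the origin is silent
        gm = np.einsum("mi,pmik->pmk", ori_m, T[:, :n_mag])
        Tp = T[:, n_mag : n_mag + n_grad]
        Tm = T[:, n_mag + n_grad :]
        gg = np.einsum("mi,pmik->pmk", ori_g, Tp - Tm) / blen[None, :, None]
        block = np.empty((src.shape[0], M, 3))
        block[:, mag_idx] = gm
        block[:, grad_idx] = gg
        out[sl] = block
    return out


def compute_leadfield(
    grid: SourceGrid, array: SensorArray, sphere: SphereModel, chunk: int = 512
) -> Leadfield:
    """Leadfield for every grid point (unit-moment convention)."""
    gain = compute_leadfield_points(grid.points, array, sphere, chunk=chunk)
    return Leadfield(gain, grid, array)
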