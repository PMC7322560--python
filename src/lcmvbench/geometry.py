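"""Sensor-array, conductor and source-grid geometry.

The synthetic MEG system mimics a 306-channel triple-sensor helmet: sites on
a spherical cap, each carrying one magnetometer (field component along the
site normal, unit T) and two perpendicular planar gradiometers (tangential
derivative of that component, unit T/m).  The head is a homogeneous
conducting sphere; the scanning space is an axis-aligned rectangular grid
inside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyGridError, InvalidArgumentError

MAGNETOMETER = "magnetometer"
PLANAR_GRADIOMETER = "planar_gradiometer"

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class SphereModel:
    """Homogeneous spherical volume conductor.

    Parameters
    ----------
    origin : (3,) array
        Center of the sphere in head coordinates (m).
    conductor_radius : float
        Radius of the conducting volume (m); sources must lie inside.
    """

    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    conductor_radius: float = 0.09

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        if self.origin.shape != (3,):
            raise InvalidArgumentError("sphere origin must be a 3-vector")
        if not self.conductor_radius > 0:
            raise InvalidArgumentError("conductor_radius must be positive")


@dataclass
class SensorArray:
    """Geometry and type of M channels.

    ``channel_position`` is the sensing location (m), ``channel_orientation``
    the unit vector whose field component the channel senses.  For planar
    gradiometers ``gradiometer_baseline`` is the in-plane vector (m) across
    which the two-point difference is taken; it is the zero vector for
    magnetometers.
    """

    channel_position: np.ndarray
    channel_orientation: np.ndarray
    channel_type: np.ndarray
    gradiometer_baseline: np.ndarray

    def __post_init__(self):
        self.channel_position = np.atleast_2d(np.asarray(self.channel_position, float))
        self.channel_orientation = np.atleast_2d(
            np.asarray(self.channel_orientation, float)
        )
        self.channel_type = np.asarray(self.channel_type, dtype=object)
        self.gradiometer_baseline = np.atleast_2d(
            np.asarray(self.gradiometer_baseline, float)
        )
        M = self.n_channels
        if M == 0:
            raise InvalidArgumentError("sensor array must have at least one channel")
        norms = np.linalg.norm(self.channel_orientation, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-12):
            raise InvalidArgumentError("channel orientations must be unit vectors")
        grad = self.gradiometer_mask
        dots = np.einsum(
            "ij,ij->i", self.gradiometer_baseline[grad], self.channel_orientation[grad]
        )
        if np.any(np.abs(dots) > 1e-9):
            raise InvalidArgumentError(
                "gradiometer baselines must be orthogonal to channel orientations"
            )
        if np.any(np.linalg.norm(self.gradiometer_baseline[grad], axis=1) <= 0):
            raise InvalidArgumentError("gradiometer baselines must be nonzero")

    @property
    def n_channels(self) -> int:
        return self.channel_position.shape[0]

    @property
    def magnetometer_mask(self) -> np.ndarray:
        return self.channel_type == MAGNETOMETER

    @property
    def gradiometer_mask(self) -> np.ndarray:
        return self.channel_type == PLANAR_GRADIOMETER

    @property
    def channel_unit(self) -> np.ndarray:
        """'T' for magnetometers, 'T/m' for planar gradiometers."""
        return np.where(self.magnetometer_mask, "T", "T/m")

    def subset(self, mask: np.ndarray) -> "SensorArray":
        """Return a new array restricted to the channels selected by ``mask``."""
        mask = np.asarray(mask)
        return SensorArray(
            self.channel_position[mask],
            self.channel_orientation[mask],
            self.channel_type[mask],
            self.gradiometer_baseline[mask],
        )

    def to_table(self) -> pd.DataFrame:
        """One row per channel, SI units; round-trips with :func:`array_from_table`."""
        df = pd.DataFrame(
            {
                "type": self.channel_type,
                "pos_x": self.channel_position[:, 0],
                "pos_y": self.channel_position[:, 1],
                "pos_z": self.channel_position[:, 2],
                "ori_x": self.channel_orientation[:, 0],
                "ori_y": self.channel_orientation[:, 1],
                "ori_z": self.channel_orientation[:, 2],
                "base_x": self.gradiometer_baseline[:, 0],
                "base_y": self.gradiometer_baseline[:, 1],
                "base_z": self.gradiometer_baseline[:, 2],
                "unit": self.channel_unit,
            }
        )
        return df


def array_from_table(df: pd.DataFrame) -> SensorArray:
    return SensorArray(
        df[["pos_x", "pos_y", "pos_z"]].to_numpy(),
        df[["ori_x", "ori_y", "ori_z"]].to_numpy(),
        df["type"].to_numpy(),
        df[["base_x", "base_y", "base_z"]].to_numpy(),
    )


def build_helmet_array(
    n_sites: int = 102,
    helmet_radius: float = 0.12,
    cap_half_angle_deg: float = 120.0,
    baseline_length: float = 0.017,
    origin: np.ndarray | None = None,
) -> SensorArray:
    """Quasi-uniform triple-sensor helmet on a spherical cap.

    Sites are placed with a Fibonacci lattice on the cap of half-angle
    ``cap_half_angle_deg`` about +z; each site holds one magnetometer and two
    perpendicular planar gradiometers whose baselines lie in the tangent
    plane.  Deterministic for fixed arguments.
    """
    if n_sites < 4:
        raise InvalidArgumentError("n_sites must be >= 4")
    if helmet_radius <= 0:
        raise InvalidArgumentError("helmet_radius must be positive")
    if baseline_length <= 0:
        raise InvalidArgumentError("baseline_length must be positive")
    if not 0 < cap_half_angle_deg <= 180:
        raise InvalidArgumentError("cap_half_angle_deg must be in (0, 180]")
    origin = np.zeros(3) if origin is None else np.asarray(origin, float)

    cos_cap = np.cos(np.deg2rad(cap_half_angle_deg))
    i = np.arange(n_sites)
    # uniform in solid angle over the cap
    cos_theta = 1.0 - (1.0 - cos_cap) * (i + 0.5) / n_sites
    sin_theta = np.sqrt(np.clip(1.0 - cos_theta**2, 0.0, None))
    phi = i * _GOLDEN_ANGLE
    normals = np.column_stack(
        [sin_theta * np.cos(phi), sin_theta * np.sin(phi), cos_theta]
    )
    positions = origin + helmet_radius * normals

    # tangent frame per site; reference axis chosen away from the normal
    ref = np.tile(np.array([0.0, 0.0, 1.0]), (n_sites, 1))
    near_pole = np.abs(normals[:, 2]) > 0.9
    ref[near_pole] = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(ref, normals)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(normals, e1)

    pos, ori, typ, base = [], [], [], []
    for s in range(n_sites):
        for b in (None, e1[s], e2[s]):
            pos.append(positions[s])
            ori.append(normals[s])
            if b is None:
                typ.append(MAGNETOMETER)
                base.append(np.zeros(3))
            else:
                typ.append(PLANAR_GRADIOMETER)
                base.append(baseline_length * b)
    return SensorArray(np.array(pos), np.array(ori), np.array(typ), np.array(base))


@dataclass
class SourceGrid:
    """Axis-aligned scanning grid inside the conductor.

    Points are ordered lexicographically by (z, y, x) ascending; this fixes
    the argmax tie-break of downstream peak picking.
    """

    points: np.ndarray
    spacing: float
    inside_margin: float
    origin: np.ndarray

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def voxel_volume(self) -> float:
        """Volume per grid point, ``spacing**3`` (m^3)."""
        return float(self.spacing) ** 3

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["x", "y", "z"])

    def nearest_index(self, location: np.ndarray) -> int:
        d = np.linalg.norm(self.points - np.asarray(location, float), axis=1)
        return int(np.argmin(d))


def build_grid(
    sphere: SphereModel,
    spacing: float = 0.005,
    inside_margin: float = 0.0075,
    region: str = "full",
) -> SourceGrid:
    """Rectangular lattice of candidate source points inside the sphere.

    ``region='upper_half'`` keeps points with z >= origin_z (the scanning
    volume used for the phantom).  The lattice is anchored at the sphere
    origin.
    """
    if spacing <= 0:
        raise InvalidArgumentError("spacing must be positive")
    if inside_margin >= sphere.conductor_radius:
        raise EmptyGridError("inside_margin leaves no interior volume")
    if region not in ("full", "upper_half"):
        raise InvalidArgumentError(f"unknown region {region!r}")
    rmax = sphere.conductor_radius - inside_margin
    kmax = int(np.floor(rmax / spacing))
    ax = np.arange(-kmax, kmax + 1) * spacing
    # lexicographic (z, y, x): z outermost
    Z, Y, X = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    keep = np.linalg.norm(pts, axis=1) <= rmax + 1e-12
    if region == "upper_half":
        keep &= pts[:, 2] >= -1e-12
    pts = pts[keep] + sphere.origin
    if pts.shape[0] == 0:
        raise EmptyGridError("no grid point satisfies the constraints")
    return SourceGrid(pts, float(spacing), float(inside_margin), sphere.origin.copy())
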