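"""Forward modelling: sensor arrays, dipole grids, spherical-conductor leadfields.

The forward model maps dipolar current sources inside a homogeneous conducting
sphere to the magnetic field sampled by an array of point magnetometers placed
outside the conductor.  The closed-form field of a current dipole in a
spherical conductor (Sarvas' formula) is used, which has the well-known
property that radially oriented dipoles are magnetically silent.

Conventions: SI units (meters, tesla per A*m of dipole moment), right-handed
coordinates, conductor centered at the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SensorArray",
    "SourceGrid",
    "Leadfield",
    "build_sensor_array",
    "build_source_grid",
    "sphere_leadfield",
    "screen_candidate_sources",
]

#: mu_0 / (4 pi) in T*m/A
_MU0_4PI = 1e-7


class ConfigurationError(ValueError):
    """Raised for physically inconsistent forward-model parameters."""


@dataclass(frozen=True)
class SensorArray:
    """A set of point magnetometers on (the upper part of) a sphere.

    Attributes
    ----------
    positions : (n, 3) float array, meters.
    orientations : (n, 3) float array, unit sensor normals (field is measured
        as the projection of B onto this direction).
    labels : list of channel names.
    """

    positions: np.ndarray
    orientations: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        ori = np.asarray(self.orientations, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] < 2:
            raise ConfigurationError("need at least 2 sensors with 3-D positions")
        if ori.shape != pos.shape:
            raise ConfigurationError("orientations must match positions in shape")
        norms = np.linalg.norm(ori, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ConfigurationError("sensor orientations must be unit vectors")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "orientations", ori)
        if not self.labels:
            object.__setattr__(
                self, "labels", [f"MEG{i:04d}" for i in range(pos.shape[0])]
            )

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class SourceGrid:
    """Axis-aligned regular dipole grid clipped to the conductor interior.

    The lattice is offset by half a spacing along each axis so that no dipole
    coincides with the sphere center, where every leadfield vanishes.

    Attributes
    ----------
    positions : (n, 3) float array of the retained (inside) dipole positions.
    spacing : lattice constant in meters.
    lattice_indices : (n, 3) int array; position = (index + 0.5) * spacing.
    orientations : optional (n, 3) unit vectors (set for simulation sources).
    """

    positions: np.ndarray
    spacing: float
    lattice_indices: np.ndarray
    orientations: np.ndarray | None = None

    @property
    def n_sources(self) -> int:
        return self.positions.shape[0]

    def pairwise_distances(self) -> np.ndarray:
        """Euclidean distance matrix between all grid dipoles (n x n)."""
        d = self.positions[:, None, :] - self.positions[None, :, :]
        return np.sqrt((d**2).sum(-1))


@dataclass(frozen=True)
class Leadfield:
    """Gain of unit dipoles at grid locations, per sensor.

    ``gain`` has shape (n_channels, n_sources, n_ori) with n_ori = 3 for
    free-orientation dipoles (unit moments along x, y, z) or squeezed to
    (n_channels, n_sources) once an orientation has been fixed.
    """

    gain: np.ndarray
    grid: SourceGrid
    n_ori: int
    valid: np.ndarray  # (n_sources,) bool

    def oriented(self, orientations: np.ndarray) -> np.ndarray:
        """Collapse the free-orientation gain with per-dipole unit orientations.

        Returns a (n_channels, n_sources) matrix.
        """
        if self.n_ori != 3:
            raise ValueError("leadfield orientation already fixed")
        q = np.asarray(orientations, dtype=float)
        if q.shape != (self.gain.shape[1], 3):
            raise ValueError("need one 3-vector per source")
        return np.einsum("csk,sk->cs", self.gain, q)


def build_sensor_array(
    n_channels: int = 275,
    radius: float = 0.12,
    seed: int = 0,
    cap_degrees: float = 105.0,
) -> SensorArray:
    """Quasi-uniform magnetometer array on the upper part of a sphere.

    A Fibonacci lattice covers the spherical cap down to polar angle
    ``cap_degrees`` (the helmet-like coverage of a whole-head MEG system).
    The seed randomizes the azimuthal registration and adds a small angular
    jitter, so different seeds give different (but statistically equivalent)
    arrays.  Sensor normals point radially outward.
    """
    if n_channels < 2:
        raise ConfigurationError("need at least 2 channels")
    if radius <= 0:
        raise ConfigurationError("sensor radius must be positive")
    rng = np.random.default_rng(seed)
    z_min = np.cos(np.deg2rad(cap_degrees))
    # Fibonacci spiral on the cap z in [z_min, 1]
    i = np.arange(n_channels)
    z = 1.0 - (1.0 - z_min) * (i + 0.5) / n_channels
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i + rng.uniform(0, 2 * np.pi)
    theta = np.arccos(np.clip(z, -1, 1))
    # small angular jitter (~0.3 deg) to decorrelate arrays across seeds
    theta = theta + rng.normal(scale=5e-3, size=n_channels)
    phi = phi + rng.normal(scale=5e-3, size=n_channels)
    theta = np.clip(theta, 0.0, np.pi)
    unit = np.column_stack(
        [
            np.sin(theta) * np.cos(phi),
            np.sin(theta) * np.sin(phi),
            np.cos(theta),
        ]
    )
    return SensorArray(positions=radius * unit, orientations=unit)


def build_source_grid(spacing: float, conductor_radius: float) -> SourceGrid:
    """Regular 3-D dipole grid strictly inside the conductor sphere.

    Lattice points sit at ``(k + 0.5) * spacing`` per axis; points with
    ``|r| >= conductor_radius`` are discarded.
    """
    if spacing <= 0 or conductor_radius <= 0:
        raise ConfigurationError("spacing and radius must be positive")
    if spacing >= conductor_radius:
        raise ConfigurationError(
            "grid spacing must be smaller than the conductor radius"
        )
    kmax = int(np.ceil(conductor_radius / spacing)) + 1
    k = np.arange(-kmax, kmax)
    kx, ky, kz = np.meshgrid(k, k, k, indexing="ij")
    idx = np.column_stack([kx.ravel(), ky.ravel(), kz.ravel()])
    pos = (idx + 0.5) * spacing
    inside = np.linalg.norm(pos, axis=1) < conductor_radius
    if not inside.any():
        raise ConfigurationError("no grid points inside the conductor")
    return SourceGrid(
        positions=pos[inside], spacing=float(spacing), lattice_indices=idx[inside]
    )


def _sarvas_gain(
    sensors: SensorArray, sources: np.ndarray, center: np.ndarray
) -> np.ndarray:
    """Sarvas leadfield: field along each sensor normal per unit moment (x,y,z).

    Returns (n_channels, n_sources, 3).
    """
    r = sensors.positions - center  # (M, 3)
    o = sensors.orientations  # (M, 3)
    r0 = sources - center  # (N, 3)
    a_vec = r[:, None, :] - r0[None, :, :]  # (M, N, 3)
    a = np.linalg.norm(a_vec, axis=2)  # (M, N)
    R = np.linalg.norm(r, axis=1)[:, None]  # (M, 1)
    r0_dot_r = r @ r0.T  # (M, N) -> wrong orientation; fix below
    r0_dot_r = np.einsum("mk,nk->mn", r, r0)
    a_dot_r = np.einsum("mnk,mk->mn", a_vec, r)
    F = a * (R * a + R**2 - r0_dot_r)  # (M, N)
    c1 = a**2 / R + a_dot_r / a + 2.0 * a + 2.0 * R  # (M, N)
    c2 = a + 2.0 * R + a_dot_r / a  # (M, N)
    # gradF = c1 * r - c2 * r0  (M, N, 3)
    o_dot_r = np.einsum("mk,mk->m", o, r)[:, None]  # o.gradF needs o.r and o.r0
    o_dot_r0 = np.einsum("mk,nk->mn", o, r0)
    o_dot_gradF = c1 * o_dot_r - c2 * o_dot_r0  # (M, N)
    gain = np.empty((r.shape[0], r0.shape[0], 3))
    eye = np.eye(3)
    for k in range(3):
        ck = np.cross(np.broadcast_to(eye[k], r0.shape), r0)  # (N, 3)
        o_dot_ck = np.einsum("mk,nk->mn", o, ck)
        ck_dot_r = np.einsum("nk,mk->mn", ck, r)
        gain[:, :, k] = _MU0_4PI * (F * o_dot_ck - ck_dot_r * o_dot_gradF) / F**2
    return gain


def sphere_leadfield(
    grid: SourceGrid,
    sensors: SensorArray,
    center: np.ndarray | tuple = (0.0, 0.0, 0.0),
    conductor_radius: float | None = None,
) -> Leadfield:
    """Free-orientation leadfield of the grid dipoles in a conducting sphere.

    Sources at the sphere center (silent everywhere) or outside the conductor
    are flagged invalid and carry zero gain columns.  Sensors must lie outside
    the conductor.
    """
    center = np.asarray(center, dtype=float)
    src = grid.positions
    depth = np.linalg.norm(src - center, axis=1)
    valid = depth > 1e-9
    if conductor_radius is not None:
        valid &= depth < conductor_radius
        sens_r = np.linalg.norm(sensors.positions - center, axis=1)
        if np.any(sens_r <= conductor_radius):
            raise ConfigurationError("sensors must lie outside the conductor")
    gain = np.zeros((sensors.n_channels, grid.n_sources, 3))
    if valid.any():
        gain[:, valid, :] = _sarvas_gain(sensors, src[valid], center)
    if not np.isfinite(gain).all():
        raise FloatingPointError("non-finite leadfield entries")
    return Leadfield(gain=gain, grid=grid, n_ori=3, valid=valid)


def screen_candidate_sources(lead: Leadfield, keep_fraction: float = 0.4) -> np.ndarray:
    """Indices of dipoles to which the array is most sensitive.

    Ranks dipoles by gain norm (Frobenius norm over channels x orientations
    for free-orientation leadfields) and keeps the top ``keep_fraction``.
    This mirrors the exclusion of candidate source locations for which the
    sensor array is relatively insensitive (deep or unfavorably oriented
    dipoles).  Ties at the cut are resolved by the lower dipole index.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    g = lead.gain
    if g.ndim == 3:
        norms = np.sqrt((g**2).sum(axis=(0, 2)))
    else:
        norms = np.sqrt((g**2).sum(axis=0))
    norms = np.where(lead.valid, norms, 0.0)
    if np.all(norms == 0):
        raise ValueError("leadfield is identically zero")
    n_keep = max(1, int(round(keep_fraction * norms.size)))
    # sort by descending norm, ascending index for ties
    order = np.lexsort((np.arange(norms.size), -norms))
    return np.sort(order[:n_keep])
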