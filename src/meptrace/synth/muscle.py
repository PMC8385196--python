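"""Synthetic muscle volumes and 3D motor-endplate (MEP) distributions.

The generator produces a voxelized muscle occupancy mask (an axis-aligned
ellipsoid by default) together with a normalized 3D density of motor
endplates and a point sample drawn from it.  Two stylized distributions are
provided, matching the two muscles most often used for retrograde tracing:

* ``m_sheet`` (gastrocnemius): endplates lie on a thin lamellar sheet that is
  oblique to the muscle surface (shallow rostrally, deep caudally) and whose
  mass is concentrated in two medio-lateral humps — the "M" band seen from
  above.
* ``triangular_pyramid`` (tibialis anterior): endplates lie on three oblique
  planar faces that meet at a deep apex, with an extra cluster of mass at the
  apex itself.

Axis convention, used throughout the package: axis 0 = depth (μm below the
most superficial voxel of the mask), axis 1 = row (rostro-caudal /
proximo-distal), axis 2 = col (medio-lateral).  Physical coordinates are in
μm; a continuous coordinate maps to a voxel by ``floor(coord / voxel_size)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

GASTROCNEMIUS = "gastrocnemius"
TIBIALIS_ANTERIOR = "tibialis_anterior"
MUSCLE_KINDS = (GASTROCNEMIUS, TIBIALIS_ANTERIOR)

M_SHEET = "m_sheet"
TRIANGULAR_PYRAMID = "triangular_pyramid"


@dataclass(frozen=True)
class MuscleGeometry:
    """Voxelized muscle volume.

    Attributes
    ----------
    mask : (depth, row, col) bool array
        Occupancy of the muscle; a single connected component.
    voxel_size_um : float
        Isotropic voxel edge length in μm.
    muscle_kind : str
        One of ``gastrocnemius`` / ``tibialis_anterior``.
    """

    mask: np.ndarray
    voxel_size_um: float
    muscle_kind: str

    def __post_init__(self) -> None:
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        if self.mask.ndim != 3 or self.mask.dtype != bool:
            raise ValueError("mask must be a 3D boolean array")

    @property
    def surface_z_um(self) -> float:
        """z coordinate (μm) of the most superficial mask voxel centre."""
        zidx = np.where(self.mask.any(axis=(1, 2)))[0]
        return (zidx[0] + 0.5) * self.voxel_size_um

    def depth_of(self, z_um: np.ndarray | float) -> np.ndarray | float:
        """Depth below the muscle surface for a z coordinate."""
        return z_um - self.surface_z_um

    def contains_point(self, point_um) -> bool:
        """True if the continuous μm coordinate falls in a mask voxel."""
        idx = np.floor(np.asarray(point_um) / self.voxel_size_um).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(self.mask.shape)):
            return False
        return bool(self.mask[tuple(idx)])


@dataclass(frozen=True)
class MEPMap:
    """Normalized 3D endplate density plus a point sample drawn from it.

    ``density`` lives on the muscle grid, is zero outside the mask, and sums
    to 1 over the mask.  ``points`` are continuous μm coordinates (depth,
    row, col), all inside the mask.
    """

    density: np.ndarray
    points: np.ndarray  # (n, 3) μm
    shape_kind: str


@dataclass(frozen=True)
class MSheetParams:
    """Parameters of the oblique "M"-sheet endplate distribution.

    Depths are μm below the muscle surface.  The sheet rises obliquely:
    shallow at its rostral edge and deep caudally, so surface staining
    preferentially reveals the rostral edge.
    """

    band_rostral_depth_um: float = 800.0
    slope: float = 0.4  # μm depth gained per μm of row
    band_row_extent_um: float = 3000.0
    row_mass_sigma_um: float = 700.0
    hump_offset: float = 0.55  # hump centres, units of col scale
    hump_sigma: float = 0.30
    hump_weight: float = 1.0
    base_weight: float = 0.3
    col_scale_um: float = 2000.0
    col_extent: float = 1.1  # band support, units of col scale
    sheet_sigma_um: float = 120.0
    half_thickness_um: float = 240.0  # hard truncation of the sheet


@dataclass(frozen=True)
class PyramidParams:
    """Parameters of the triangular-pyramid endplate distribution."""

    apex_depth_um: float = 1400.0
    face_end_depth_um: float = 650.0
    face_azimuths_deg: tuple[float, ...] = (0.0, 135.0, 225.0)
    face_lengths_um: tuple[float, ...] = (1800.0, 1400.0, 1400.0)
    face_base_halfwidth_um: float = 100.0
    face_end_halfwidth_um: float = 600.0
    face_sigma_um: float = 100.0
    half_thickness_um: float = 200.0
    apex_sigma_um: float = 200.0
    apex_mass_fraction: float = 0.30


#: default ellipsoid semi-axes (depth, row, col) in μm and voxel size
_GEOMETRY_DEFAULTS = {
    GASTROCNEMIUS: dict(semi_axes_um=(1300.0, 4000.0, 2500.0), voxel_size_um=50.0),
    TIBIALIS_ANTERIOR: dict(semi_axes_um=(850.0, 3000.0, 1250.0), voxel_size_um=50.0),
}

_SHAPE_FOR_MUSCLE = {GASTROCNEMIUS: M_SHEET, TIBIALIS_ANTERIOR: TRIANGULAR_PYRAMID}

_PAD_VOXELS = 2


def make_muscle_geometry(
    muscle_kind: str,
    semi_axes_um: tuple[float, float, float] | None = None,
    voxel_size_um: float | None = None,
) -> MuscleGeometry:
    """Build the default ellipsoidal muscle mask for a muscle kind."""
    if muscle_kind not in MUSCLE_KINDS:
        raise ValueError(f"unknown muscle_kind: {muscle_kind!r}")
    defaults = _GEOMETRY_DEFAULTS[muscle_kind]
    semi = np.asarray(semi_axes_um or defaults["semi_axes_um"], dtype=float)
    vox = float(voxel_size_um or defaults["voxel_size_um"])
    shape = tuple(int(math.ceil(2 * s / vox)) + 2 * _PAD_VOXELS for s in semi)
    centre = np.array([n * vox / 2 for n in shape])
    zz, yy, xx = np.meshgrid(*(
        (np.arange(n) + 0.5) * vox for n in shape), indexing="ij")
    r2 = (((zz - centre[0]) / semi[0]) ** 2
          + ((yy - centre[1]) / semi[1]) ** 2
          + ((xx - centre[2]) / semi[2]) ** 2)
    return MuscleGeometry(mask=r2 <= 1.0, voxel_size_um=vox, muscle_kind=muscle_kind)


def _grid_coords(geometry: MuscleGeometry):
    vox = geometry.voxel_size_um
    nz, ny, nx = geometry.mask.shape
    z = (np.arange(nz) + 0.5) * vox
    y = (np.arange(ny) + 0.5) * vox
    x = (np.arange(nx) + 0.5) * vox
    return np.meshgrid(z, y, x, indexing="ij")


def _m_sheet_density(geometry: MuscleGeometry, p: MSheetParams) -> np.ndarray:
    zz, yy, xx = _grid_coords(geometry)
    depth = geometry.depth_of(zz)
    ny = geometry.mask.shape[1]
    nx = geometry.mask.shape[2]
    row_c = ny * geometry.voxel_size_um / 2
    col_c = nx * geometry.voxel_size_um / 2

    row_start = row_c - p.band_row_extent_um / 2
    sheet_depth = p.band_rostral_depth_um + p.slope * (yy - row_start)
    # row position where the sheet crosses mid-band depth carries most mass
    mid_depth = p.band_rostral_depth_um + p.slope * p.band_row_extent_um / 2
    row_star = row_start + (mid_depth - p.band_rostral_depth_um) / p.slope
    u = (xx - col_c) / p.col_scale_um
    humps = (np.exp(-0.5 * ((u - p.hump_offset) / p.hump_sigma) ** 2)
             + np.exp(-0.5 * ((u + p.hump_offset) / p.hump_sigma) ** 2))
    w_col = (p.base_weight + p.hump_weight * humps) * (np.abs(u) <= p.col_extent)
    w_row = np.exp(-0.5 * ((yy - row_star) / p.row_mass_sigma_um) ** 2)
    w_row *= (yy >= row_start) & (yy <= row_start + p.band_row_extent_um)
    dz = depth - sheet_depth
    w_z = np.exp(-0.5 * (dz / p.sheet_sigma_um) ** 2)
    w_z *= np.abs(dz) <= p.half_thickness_um
    return w_col * w_row * w_z


def _pyramid_density(geometry: MuscleGeometry, p: PyramidParams) -> np.ndarray:
    zz, yy, xx = _grid_coords(geometry)
    depth = geometry.depth_of(zz)
    ny, nx = geometry.mask.shape[1:]
    apex = np.array([ny * geometry.voxel_size_um / 2, nx * geometry.voxel_size_um / 2])

    dy = yy - apex[0]
    dx = xx - apex[1]
    dens = np.zeros_like(zz)
    for az_deg, length in zip(p.face_azimuths_deg, p.face_lengths_um):
        az = math.radians(az_deg)
        d_row, d_col = math.cos(az), math.sin(az)
        t = (dy * d_row + dx * d_col) / length
        s = -dy * d_col + dx * d_row
        halfwidth = p.face_base_halfwidth_um + t * (
            p.face_end_halfwidth_um - p.face_base_halfwidth_um)
        on_face = (t >= 0.0) & (t <= 1.0) & (np.abs(s) <= halfwidth)
        z_face = p.apex_depth_um - (p.apex_depth_um - p.face_end_depth_um) * t
        dz = depth - z_face
        w_z = np.exp(-0.5 * (dz / p.face_sigma_um) ** 2)
        w_z *= np.abs(dz) <= p.half_thickness_um
        dens += on_face * w_z
    # explicit endplate cluster at the apex where the faces meet
    r2 = ((depth - p.apex_depth_um) ** 2 + dy**2 + dx**2) / p.apex_sigma_um**2
    apex_blob = np.exp(-0.5 * r2)
    face_mass = dens.sum()
    blob_mass = apex_blob.sum()
    if face_mass > 0 and blob_mass > 0 and p.apex_mass_fraction > 0:
        dens = (1 - p.apex_mass_fraction) * dens / face_mass \
            + p.apex_mass_fraction * apex_blob / blob_mass
    return dens


def generate_mep_map(
    muscle_kind: str,
    shape_params: MSheetParams | PyramidParams | None = None,
    n_points: int = 2000,
    seed: int = 0,
    geometry: MuscleGeometry | None = None,
) -> tuple[MuscleGeometry, MEPMap]:
    """Generate a muscle volume with a normalized MEP density and point sample.

    Parameters
    ----------
    muscle_kind : str
        ``gastrocnemius`` (M-sheet distribution) or ``tibialis_anterior``
        (triangular-pyramid distribution).
    shape_params : MSheetParams or PyramidParams, optional
        Distribution parameters; muscle-appropriate defaults if omitted.
    n_points : int
        Number of endplate points to sample (i.i.d. from the density).
    seed : int
        Seed for the point sampler; identical seeds give identical output.
    geometry : MuscleGeometry, optional
        Pre-built muscle volume (defaults per muscle kind).

    Returns
    -------
    (MuscleGeometry, MEPMap)
    """
    if muscle_kind not in MUSCLE_KINDS:
        raise ValueError(f"unknown muscle_kind: {muscle_kind!r}")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    geometry = geometry or make_muscle_geometry(muscle_kind)
    shape_kind = _SHAPE_FOR_MUSCLE[muscle_kind]
    if shape_kind == M_SHEET:
        params = shape_params or MSheetParams()
        if not isinstance(params, MSheetParams):
            raise TypeError("gastrocnemius expects MSheetParams")
        dens = _m_sheet_density(geometry, params)
    else:
        params = shape_params or PyramidParams()
        if not isinstance(params, PyramidParams):
            raise TypeError("tibialis_anterior expects PyramidParams")
        dens = _pyramid_density(geometry, params)

    dens = np.where(geometry.mask, dens, 0.0)
    total = dens.sum()
    if total <= 0:
        raise ValueError("endplate density vanishes inside the muscle mask")
    dens = dens / total

    rng = np.random.default_rng(seed)
    flat_p = dens.ravel()
    idx = rng.choice(flat_p.size, size=n_points, p=flat_p)
    vox_idx = np.column_stack(np.unravel_index(idx, dens.shape)).astype(float)
    jitter = rng.uniform(0.0, 1.0, size=vox_idx.shape)
    points = (vox_idx + jitter) * geometry.voxel_size_um
    return geometry, MEPMap(density=dens, points=points, shape_kind=shape_kind)
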