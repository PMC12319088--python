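"""Synthetic 3D phantoms: bead cubes, filament volumes, point grids, two-layer.

All generators are deterministic per seed and return non-negative volumes in
(z, y, x) order with an anisotropic voxel (dz, dy, dx) in nm.  The default
voxel (150, 65, 65) nm matches the camera pixel and axial step of the
instrument the simulator models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .optics import InvalidParameterError

__all__ = [
    "Phantom3D",
    "bead_phantom",
    "filament_phantom",
    "point_grid_phantom",
    "two_layer_phantom",
    "PackingError",
]

DEFAULT_VOXEL = (150.0, 65.0, 65.0)


class PackingError(RuntimeError):
    """Raised when non-overlapping bead placement is infeasible."""


@dataclass
class Phantom3D:
    values: np.ndarray  # (z, y, x), non-negative
    voxel: tuple[float, float, float]  # (dz, dy, dx) nm
    kind: str
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


def _check_shape(shape) -> tuple[int, int, int]:
    if len(shape) != 3 or any(int(s) < 1 for s in shape):
        raise InvalidParameterError("shape must be (nz, ny, nx) with positive sizes")
    return tuple(int(s) for s in shape)


def bead_phantom(
    shape: tuple[int, int, int],
    voxel: tuple[float, float, float] = DEFAULT_VOXEL,
    n_beads: int = 50,
    bead_diameter: float = 200.0,
    min_separation: float = 600.0,
    seed: int = 0,
    margin_nm: float | None = None,
    max_tries: int = 10_000,
) -> Phantom3D:
    """Uniform-intensity spheres at random non-overlapping positions.

    ``bead_diameter`` and ``min_separation`` (center-to-center) are in nm.
    Spheres are rasterized with a one-voxel antialiasing ramp so centroids
    land on the exact sub-voxel positions.  Raises PackingError when the
    requested packing cannot be placed within ``max_tries`` draws.
    """
    nz, ny, nx = _check_shape(shape)
    dz, dy, dx = voxel
    if bead_diameter < min(voxel):
        raise InvalidParameterError("bead_diameter must be at least one voxel")
    rng = np.random.default_rng(seed)
    extent = np.array([nz * dz, ny * dy, nx * dx])
    margin = bead_diameter / 2.0 + max(voxel) if margin_nm is None else margin_nm
    # degenerate (thin) axes pin the coordinate to the mid-plane instead
    lo = np.where(extent > 2 * margin, margin, extent / 2.0)
    hi = np.where(extent > 2 * margin, extent - margin, extent / 2.0)
    if n_beads > 0 and np.all(hi <= lo):
        raise PackingError("volume too small for the requested bead size")
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n_beads:
        if tries >= max_tries:
            raise PackingError(
                f"could not place {n_beads} beads with separation {min_separation} nm"
            )
        tries += 1
        c = rng.uniform(lo, hi)
        if all(np.linalg.norm(c - p) >= min_separation for p in centers):
            centers.append(c)
    vol = np.zeros((nz, ny, nx), dtype=np.float64)
    r = bead_diameter / 2.0
    ramp = min(voxel)
    for c in centers:
        _paint_sphere(vol, c, r, voxel, ramp)
    return Phantom3D(
        values=vol,
        voxel=voxel,
        kind="beads",
        meta={
            "centers_nm": [list(map(float, c)) for c in centers],
            "bead_diameter": bead_diameter,
            "seed": seed,
        },
    )


def _paint_sphere(vol, center_nm, radius_nm, voxel, ramp) -> None:
    nz, ny, nx = vol.shape
    dz, dy, dx = voxel
    cz, cy, cx = center_nm
    lo = [
        max(0, int((c - radius_nm - ramp) / d)) for c, d in zip(center_nm, voxel)
    ]
    hi = [
        min(n, int((c + radius_nm + ramp) / d) + 2)
        for c, d, n in zip(center_nm, voxel, vol.shape)
    ]
    if any(l >= h for l, h in zip(lo, hi)):
        return
    z = (np.arange(lo[0], hi[0]) + 0.5) * dz - cz
    y = (np.arange(lo[1], hi[1]) + 0.5) * dy - cy
    x = (np.arange(lo[2], hi[2]) + 0.5) * dx - cx
    dist = np.sqrt(
        z[:, None, None] ** 2 + y[None, :, None] ** 2 + x[None, None, :] ** 2
    )
    vol[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += np.clip(
        (radius_nm - dist) / ramp + 0.5, 0.0, 1.0
    )


def filament_phantom(
    shape: tuple[int, int, int],
    voxel: tuple[float, float, float] = DEFAULT_VOXEL,
    n_filaments: int = 10,
    persistence: float = 5000.0,
    thickness: float = 300.0,
    seed: int = 0,
    step_nm: float | None = None,
) -> Phantom3D:
    """Smooth 3D random-walk filaments with a Gaussian cross-section.

    Centerlines are persistent random walks (angular diffusion with standard
    deviation sqrt(step/persistence) per step); points are splatted with
    trilinear weights and blurred to the requested cross-section FWHM
    (``thickness``, nm).  An infinite persistence yields straight rods.
    """
    nz, ny, nx = _check_shape(shape)
    dz, dy, dx = voxel
    if thickness < min(voxel):
        raise InvalidParameterError("thickness must be at least one voxel")
    rng = np.random.default_rng(seed)
    step = min(dy, dx) / 2.0 if step_nm is None else step_nm
    extent = np.array([nz * dz, ny * dy, nx * dx])
    vol = np.zeros((nz, ny, nx), dtype=np.float64)
    sigma_ang = 0.0 if np.isinf(persistence) else np.sqrt(step / persistence)
    n_steps = int(2.0 * max(extent) / step)
    for _ in range(n_filaments):
        p = rng.uniform(0.2, 0.8, 3) * extent
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        for _ in range(n_steps):
            _splat(vol, p, voxel)
            if sigma_ang > 0:
                d = d + sigma_ang * rng.normal(size=3)
                d /= np.linalg.norm(d)
            p = p + step * d
            if np.any(p < 0) or np.any(p >= extent):
                break
    sig_vox = [thickness / 2.3548 / v for v in voxel]
    vol = gaussian_filter(vol, sigma=sig_vox, mode="constant")
    return Phantom3D(
        values=vol,
        voxel=voxel,
        kind="filaments",
        meta={"thickness": thickness, "persistence": persistence, "seed": seed},
    )


def _splat(vol, p_nm, voxel) -> None:
    """Trilinear deposit of a unit point at a sub-voxel position."""
    f = [p / v - 0.5 for p, v in zip(p_nm, voxel)]
    i0 = [int(np.floor(x)) for x in f]
    w = [x - i for x, i in zip(f, i0)]
    for bz in (0, 1):
        for by in (0, 1):
            for bx in (0, 1):
                iz, iy, ix = i0[0] + bz, i0[1] + by, i0[2] + bx
                if 0 <= iz < vol.shape[0] and 0 <= iy < vol.shape[1] and 0 <= ix < vol.shape[2]:
                    wt = (
                        (w[0] if bz else 1 - w[0])
                        * (w[1] if by else 1 - w[1])
                        * (w[2] if bx else 1 - w[2])
                    )
                    vol[iz, iy, ix] += wt


def point_grid_phantom(
    shape: tuple[int, int, int],
    voxel: tuple[float, float, float] = DEFAULT_VOXEL,
    spacing_nm: float = 2000.0,
    z_plane: int | None = None,
) -> Phantom3D:
    """Single-voxel point emitters on a square lateral grid in one z plane."""
    nz, ny, nx = _check_shape(shape)
    dz, dy, dx = voxel
    zp = nz // 2 if z_plane is None else z_plane
    vol = np.zeros((nz, ny, nx), dtype=np.float64)
    sy = max(1, int(round(spacing_nm / dy)))
    sx = max(1, int(round(spacing_nm / dx)))
    vol[zp, sy // 2 :: sy, sx // 2 :: sx] = 1.0
    return Phantom3D(values=vol, voxel=voxel, kind="point-grid", meta={"z_plane": zp})


def two_layer_phantom(
    shape: tuple[int, int, int],
    voxel: tuple[float, float, float] = DEFAULT_VOXEL,
    lattice_period_nm: float = 648.0,
    background_intensity: float = 5.0,
    layer_offset_planes: int | None = None,
) -> Phantom3D:
    """In-focus point lattice plus a defocused uniform bright plane.

    The structured focal plane emulates the multifocal excitation readout
    while the bright off-focus layer supplies the out-of-focus background the
    spinning disk is designed to reject.
    """
    nz, ny, nx = _check_shape(shape)
    if nz < 3:
        raise InvalidParameterError("need at least 3 z planes for two layers")
    dz, dy, dx = voxel
    zf = nz // 2
    off = (nz - 1 - zf) if layer_offset_planes is None else layer_offset_planes
    zb = zf + off
    if not (0 <= zb < nz) or zb == zf:
        raise InvalidParameterError("background layer outside the volume")
    vol = np.zeros((nz, ny, nx), dtype=np.float64)
    sy = max(1, int(round(lattice_period_nm / dy)))
    sx = max(1, int(round(lattice_period_nm / dx)))
    vol[zf, sy // 2 :: sy, sx // 2 :: sx] = 1.0
    vol[zb, :, :] = background_intensity
    return Phantom3D(
        values=vol,
        voxel=voxel,
        kind="two-layer",
        meta={"focal_plane": zf, "background_plane": zb},
    )
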