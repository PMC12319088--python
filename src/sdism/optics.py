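"""Optical configuration, 3D point-spread-function models and unit conversions.

The PSF model is a scalar 3D Gaussian approximation,

    sigma_xy = 0.21 * lambda / NA
    sigma_z  = 0.75 * n * lambda / NA**2

which keeps every width-based readout closed-form.  A confocal PSF is built
from an excitation and a detection PSF by filtering the detection PSF with a
uniform pinhole disk per axial plane and multiplying with the excitation PSF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "OpticalConfig",
    "PSF3D",
    "DEFAULT_CONFIG",
    "airy_unit",
    "make_psf3d",
    "make_confocal_psf",
    "measure_fwhm",
    "radial_profile",
    "gaussian_spot_fwhm",
    "gaussian_spot_fit",
    "InvalidParameterError",
    "FWHMError",
]

_GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


class InvalidParameterError(ValueError):
    """Raised when an optical parameter is outside its physical domain."""


class FWHMError(ValueError):
    """Raised when a profile has no well-defined full width at half maximum."""


@dataclass(frozen=True)
class OpticalConfig:
    """Optical and geometric constants of the instrument.

    All lengths are in the units noted per field; sample-plane projections of
    DMD/disk lengths are always ``length / magnification``.

    Parameters
    ----------
    na : numerical aperture (dimensionless)
    magnification : total objective x relay magnification
    wavelength_ex, wavelength_em : excitation / emission wavelengths (nm)
    camera_pixel_sample : camera pixel size projected to the sample plane (nm)
    dmd_pixel : DMD mirror pitch (um)
    z_step : axial step (nm)
    disk_pinhole_diameter, disk_pinhole_pitch : pinhole diameter / spacing at
        the disk plane (um)
    refractive_index : immersion refractive index
    """

    na: float = 1.49
    magnification: float = 100.0
    wavelength_ex: float = 640.0
    wavelength_em: float = 680.0
    camera_pixel_sample: float = 65.0
    dmd_pixel: float = 5.4
    z_step: float = 150.0
    disk_pinhole_diameter: float = 50.0
    disk_pinhole_pitch: float = 250.0
    refractive_index: float = 1.515

    def __post_init__(self) -> None:
        for name in (
            "na",
            "magnification",
            "wavelength_ex",
            "wavelength_em",
            "camera_pixel_sample",
            "dmd_pixel",
            "z_step",
            "disk_pinhole_diameter",
            "disk_pinhole_pitch",
            "refractive_index",
        ):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        if self.na > self.refractive_index:
            raise InvalidParameterError(
                "numerical aperture cannot exceed the immersion refractive index"
            )

    # --- sample-plane projections -------------------------------------
    @property
    def dmd_pixel_sample(self) -> float:
        """DMD mirror pitch projected to the sample plane (nm)."""
        return self.dmd_pixel * 1000.0 / self.magnification

    @property
    def pinhole_diameter_sample(self) -> float:
        """Disk pinhole diameter projected to the sample plane (nm)."""
        return self.disk_pinhole_diameter * 1000.0 / self.magnification

    @property
    def pinhole_pitch_sample(self) -> float:
        """Disk pinhole spacing projected to the sample plane (nm)."""
        return self.disk_pinhole_pitch * 1000.0 / self.magnification

    def to_dict(self) -> dict:
        return {
            "na": self.na,
            "magnification": self.magnification,
            "wavelength_ex": self.wavelength_ex,
            "wavelength_em": self.wavelength_em,
            "camera_pixel_sample": self.camera_pixel_sample,
            "dmd_pixel": self.dmd_pixel,
            "z_step": self.z_step,
            "disk_pinhole_diameter": self.disk_pinhole_diameter,
            "disk_pinhole_pitch": self.disk_pinhole_pitch,
            "refractive_index": self.refractive_index,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalConfig":
        return cls(**d)


DEFAULT_CONFIG = OpticalConfig()


@dataclass
class PSF3D:
    """Normalized 3D intensity PSF on a regular (z, y, x) grid.

    ``values`` sums to 1; ``voxel`` is (dz, dy, dx) in nm.  ``kind`` is one of
    ``widefield-excitation``, ``widefield-detection`` or ``confocal``.
    """

    values: np.ndarray
    voxel: tuple[float, float, float]
    kind: str
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def focal_index(self) -> int:
        return self.values.shape[0] // 2

    def slice_at(self, dz_planes: int) -> np.ndarray:
        """Lateral slice at a signed axial offset (planes) from focus.

        Offsets beyond the grid return a zero slice (no light modeled there).
        """
        i = self.focal_index + dz_planes
        if 0 <= i < self.values.shape[0]:
            return self.values[i]
        return np.zeros(self.values.shape[1:], dtype=self.values.dtype)


def airy_unit(config: OpticalConfig, wavelength: float) -> float:
    """Airy-disk diameter 1.22*lambda/NA in nm.

    The wavelength is explicit (no hidden excitation/emission default) so the
    caller decides which line the Airy unit refers to.
    """
    if wavelength <= 0:
        raise InvalidParameterError("wavelength must be strictly positive")
    if config.na <= 0:
        raise InvalidParameterError("NA must be strictly positive")
    return 1.22 * wavelength / config.na


def gaussian_sigmas(config: OpticalConfig, wavelength: float) -> tuple[float, float]:
    """(sigma_z, sigma_xy) of the Gaussian PSF model, in nm."""
    sigma_xy = 0.21 * wavelength / config.na
    sigma_z = 0.75 * config.refractive_index * wavelength / config.na**2
    return sigma_z, sigma_xy


def make_psf3d(
    config: OpticalConfig,
    wavelength: float,
    kind: str,
    grid_shape: tuple[int, int, int],
    voxel: tuple[float, float, float],
) -> PSF3D:
    """Build a normalized Gaussian 3D PSF centered on the grid.

    Grid dimensions must be odd so the peak sits on a voxel and the PSF is
    exactly mirror-symmetric.  A single axial plane (nz == 1) produces a 2D
    (in-focus) PSF for purely lateral simulations.
    """
    if kind not in ("widefield-excitation", "widefield-detection", "confocal"):
        raise InvalidParameterError(f"unknown PSF kind {kind!r}")
    nz, ny, nx = grid_shape
    dz, dy, dx = voxel
    if any(v <= 0 for v in voxel):
        raise InvalidParameterError("voxel pitches must be positive")
    if any(n % 2 == 0 for n in grid_shape):
        raise InvalidParameterError("grid dimensions must be odd (centered peak)")
    sigma_z, sigma_xy = gaussian_sigmas(config, wavelength)
    fwhm_xy = _GAUSS_FWHM * sigma_xy
    fwhm_z = _GAUSS_FWHM * sigma_z
    if ny * dy < 4 * fwhm_xy or nx * dx < 4 * fwhm_xy:
        raise InvalidParameterError(
            f"lateral grid too small: need >= 4 FWHM = {4 * fwhm_xy:.0f} nm"
        )
    if nz > 1 and nz * dz < 4 * fwhm_z:
        raise InvalidParameterError(
            f"axial grid too small: need >= 4 FWHM = {4 * fwhm_z:.0f} nm"
        )
    if max(dy, dx) > sigma_xy:
        warnings.warn(
            f"voxel pitch {max(dy, dx):.0f} nm undersamples the PSF "
            f"(sigma_xy = {sigma_xy:.0f} nm)",
            stacklevel=2,
        )
    z = (np.arange(nz) - nz // 2) * dz
    y = (np.arange(ny) - ny // 2) * dy
    x = (np.arange(nx) - nx // 2) * dx
    if nz > 1:
        # defocus model: per-plane energy follows the axial Gaussian while the
        # lateral width grows hyperbolically, sigma(z) = sigma_xy *
        # sqrt(1 + (z/sigma_z)^2) — a Gaussian-beam-like spread without which
        # a separable model would image every depth equally sharply
        gz = np.exp(-0.5 * (z / sigma_z) ** 2)
        sig_l = sigma_xy * np.sqrt(1.0 + (z / sigma_z) ** 2)
        gy = np.exp(-0.5 * (y[None, :] / sig_l[:, None]) ** 2)
        gx = np.exp(-0.5 * (x[None, :] / sig_l[:, None]) ** 2)
        vals = gz[:, None, None] * gy[:, :, None] * gx[:, None, :]
        # per-plane energy proportional to gz regardless of lateral spread
        plane_sum = vals.sum(axis=(1, 2), keepdims=True)
        vals = vals * np.where(plane_sum > 0, gz[:, None, None] / plane_sum, 0.0)
    else:
        gy = np.exp(-0.5 * (y / sigma_xy) ** 2)
        gx = np.exp(-0.5 * (x / sigma_xy) ** 2)
        vals = (gy[:, None] * gx[None, :])[None]
    vals /= vals.sum()
    return PSF3D(
        values=vals,
        voxel=voxel,
        kind=kind,
        meta={"wavelength": wavelength, "sigma_xy": sigma_xy, "sigma_z": sigma_z},
    )


def _pinhole_disk(diameter_nm: float, voxel_yx: tuple[float, float]) -> np.ndarray:
    """Antialiased binary pinhole disk kernel on the lateral grid (sums to area)."""
    dy, dx = voxel_yx
    r = diameter_nm / 2.0
    ny = max(1, int(np.ceil(2 * r / dy)) + 3)
    nx = max(1, int(np.ceil(2 * r / dx)) + 3)
    ny += 1 - ny % 2
    nx += 1 - nx % 2
    yy = (np.arange(ny) - ny // 2) * dy
    xx = (np.arange(nx) - nx // 2) * dx
    dist = np.hypot(yy[:, None], xx[None, :])
    # linear edge ramp over one pixel approximates area coverage
    edge = min(dy, dx)
    return np.clip((r - dist) / edge + 0.5, 0.0, 1.0)


def make_confocal_psf(
    psf_exc: PSF3D, psf_det: PSF3D, pinhole_diameter_sample: float
) -> PSF3D:
    """Confocal PSF: excitation times pinhole-filtered detection, renormalized.

    Per axial plane, h_conf = h_exc * (h_det (x)2D P) where P is a uniform disk
    of the given sample-plane diameter.  A zero diameter degenerates to the
    pointwise product h_exc * h_det (closed-pinhole limit).
    """
    if psf_exc.values.shape != psf_det.values.shape or psf_exc.voxel != psf_det.voxel:
        raise InvalidParameterError("excitation/detection PSFs must share grid and voxel")
    if pinhole_diameter_sample < 0:
        raise InvalidParameterError("pinhole diameter must be non-negative")
    det = psf_det.values
    if pinhole_diameter_sample == 0:
        filtered = det
    else:
        P = _pinhole_disk(pinhole_diameter_sample, psf_det.voxel[1:])
        filtered = np.stack(
            [fftconvolve(det[z], P, mode="same") for z in range(det.shape[0])]
        )
    vals = psf_exc.values * filtered
    vals = np.clip(vals, 0.0, None)
    s = vals.sum()
    if s <= 0:
        raise InvalidParameterError("confocal PSF vanished; check grids")
    return PSF3D(
        values=vals / s,
        voxel=psf_exc.voxel,
        kind="confocal",
        meta={
            "pinhole_diameter_sample": pinhole_diameter_sample,
            "exc": dict(psf_exc.meta),
            "det": dict(psf_det.meta),
        },
    )


def _profile_through_peak(image: np.ndarray, axis: int) -> np.ndarray:
    peak = np.unravel_index(int(np.argmax(image)), image.shape)
    idx = list(peak)
    idx[axis] = slice(None)
    return image[tuple(idx)]


def measure_fwhm(
    profile_or_image: np.ndarray,
    axis: int = 0,
    sub_sample: bool = True,
    pixel_size: float = 1.0,
) -> float:
    """Full width at half maximum of the dominant peak of a profile.

    For a 2D input the 1D profile through the global maximum along ``axis`` is
    used.  The baseline is the median of the profile's outer 10% of samples
    (5% at each end), which tolerates a non-zero simulation background.  With
    ``sub_sample`` the half-maximum crossings are located by linear
    interpolation between samples.
    """
    arr = np.asarray(profile_or_image, dtype=float)
    if arr.ndim == 2:
        arr = _profile_through_peak(arr, axis)
    elif arr.ndim != 1:
        raise InvalidParameterError("expected a 1D profile or 2D image")
    n = arr.size
    if n < 5:
        raise FWHMError("profile too short")
    k = max(1, int(np.ceil(0.05 * n)))
    baseline = float(np.median(np.concatenate([arr[:k], arr[-k:]])))
    peak_idx = int(np.argmax(arr))
    peak = arr[peak_idx]
    if peak - baseline <= 0 or not np.isfinite(peak):
        raise FWHMError("flat profile: FWHM undefined")
    half = baseline + 0.5 * (peak - baseline)

    # walk left
    i = peak_idx
    while i > 0 and arr[i] > half:
        i -= 1
    if arr[i] > half:
        raise FWHMError("half-maximum level not reached on the left")
    if sub_sample and arr[i + 1] != arr[i]:
        left = i + (half - arr[i]) / (arr[i + 1] - arr[i])
    else:
        left = float(i)

    j = peak_idx
    while j < n - 1 and arr[j] > half:
        j += 1
    if arr[j] > half:
        raise FWHMError("half-maximum level not reached on the right")
    if sub_sample and arr[j - 1] != arr[j]:
        right = j - (half - arr[j]) / (arr[j - 1] - arr[j])
    else:
        right = float(j)
    return (right - left) * pixel_size


def gaussian_spot_fit(
    image: np.ndarray,
    center: tuple[float, float],
    r_max: float,
    mask: np.ndarray | None = None,
    fit_center: bool = True,
) -> tuple[float, tuple[float, float]]:
    """Least-squares Gaussian fit of an isolated spot.

    Treats every pixel within ``r_max`` of the (sub-pixel) ``center`` as a
    point sample of the continuous image and fits A*exp(-r^2/(2 sigma^2)) + b,
    optionally refining the center.  Unlike profile interpolation this stays
    unbiased when the grid pitch approaches the spot width.  Returns
    (FWHM in pixels, fitted (cy, cx)).
    """
    from scipy.optimize import curve_fit

    img = np.asarray(image, dtype=float)
    cy, cx = center
    yy, xx = np.indices(img.shape)
    sel = np.hypot(yy - cy, xx - cx) <= r_max
    if mask is not None:
        sel &= mask
    if sel.sum() < 8:
        raise FWHMError("too few samples around the spot")
    y, x, v = yy[sel].astype(float), xx[sel].astype(float), img[sel]

    if fit_center:

        def model(coords, A, sigma, b, cy0, cx0):
            yv, xv = coords
            r2 = (yv - cy0) ** 2 + (xv - cx0) ** 2
            return A * np.exp(-r2 / (2 * sigma**2)) + b

        p0 = (float(v.max() - v.min()), max(r_max / 3, 0.5), float(v.min()), cy, cx)
        popt, _ = curve_fit(model, (y, x), v, p0=p0, maxfev=20_000)
        return _GAUSS_FWHM * abs(popt[1]), (float(popt[3]), float(popt[4]))

    def model(coords, A, sigma, b):
        yv, xv = coords
        r2 = (yv - cy) ** 2 + (xv - cx) ** 2
        return A * np.exp(-r2 / (2 * sigma**2)) + b

    p0 = (float(v.max() - v.min()), max(r_max / 3, 0.5), float(v.min()))
    popt, _ = curve_fit(model, (y, x), v, p0=p0, maxfev=20_000)
    return _GAUSS_FWHM * abs(popt[1]), (float(cy), float(cx))


def gaussian_spot_fwhm(
    image: np.ndarray,
    center: tuple[float, float],
    r_max: float,
    mask: np.ndarray | None = None,
    fit_center: bool = True,
) -> float:
    """FWHM (pixels) of an isolated spot; see :func:`gaussian_spot_fit`."""
    return gaussian_spot_fit(image, center, r_max, mask, fit_center)[0]


def radial_profile(
    image: np.ndarray,
    center: tuple[float, float],
    r_max: float,
    bin_width: float = 0.25,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Radially binned intensity profile around a sub-pixel center.

    Every pixel is treated as a true point sample of the underlying continuous
    image at its exact distance from ``center`` (y, x in pixels), which makes
    width measurements robust even when the grid pitch approaches the feature
    width.  Returns (bin centers, mean intensity per bin); empty bins are
    filled by linear interpolation.
    """
    img = np.asarray(image, dtype=float)
    cy, cx = center
    yy, xx = np.indices(img.shape)
    r = np.hypot(yy - cy, xx - cx).ravel()
    v = img.ravel()
    if mask is not None:
        keep = mask.ravel()
        r, v = r[keep], v[keep]
    sel = r <= r_max
    r, v = r[sel], v[sel]
    nbins = max(2, int(np.ceil(r_max / bin_width)))
    edges = np.linspace(0.0, r_max, nbins + 1)
    idx = np.clip(np.digitize(r, edges) - 1, 0, nbins - 1)
    sums = np.bincount(idx, weights=v, minlength=nbins)
    counts = np.bincount(idx, minlength=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    prof = np.full(nbins, np.nan)
    nz = counts > 0
    prof[nz] = sums[nz] / counts[nz]
    if not nz.all():
        prof = np.interp(centers, centers[nz], prof[nz])
    return centers, prof
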