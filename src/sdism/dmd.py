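"""Binary DMD mask sequences and a blazed-grating model of the mirror array.

Two pattern families are generated: a multifocal lattice of square apertures
stepped over every lattice phase (the raw-data scan for ISM reconstruction),
and stripe patterns for projection structured illumination.  The grating
model treats the micromirror array as a 1D blazed grating along the mirror
tilt diagonal and predicts the exit angle and scalar diffraction efficiency
per order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optics import InvalidParameterError, OpticalConfig

__all__ = [
    "MaskSequence",
    "GratingGeometry",
    "multifocal_sequence",
    "stripe_sequence",
    "sample_plane_length",
    "grating_exit_angle",
    "grating_efficiency",
]

DEFAULT_DMD_SHAPE = (1024, 1024)


@dataclass
class MaskSequence:
    """An ordered sequence of binary DMD masks with commanded offsets.

    ``offsets`` are per-mask (dx, dy) shifts in DMD pixels relative to the
    first mask.  For the multifocal kind the offsets raster row-major over the
    (period/step)^2 phase grid; the order is recorded here so downstream code
    never assumes it.
    """

    masks: list[np.ndarray]
    offsets: list[tuple[int, int]]
    aperture: int | None
    period: int
    step: int
    pattern_kind: str
    orientation_index: list[int] | None = None
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.masks)

    @property
    def n_phases(self) -> int:
        return self.period // self.step


def multifocal_sequence(
    aperture: int = 4,
    period: int = 12,
    step: int = 2,
    dmd_shape: tuple[int, int] = DEFAULT_DMD_SHAPE,
) -> MaskSequence:
    """Square-lattice multifocal masks stepped over every lattice phase.

    Each mask is a lattice of ``aperture`` x ``aperture`` ON blocks with pitch
    ``period``; successive masks shift by ``step`` pixels, raster (row-major)
    over the (period/step)^2 phase grid.  The default 4:12 mask with two-pixel
    steps yields a 36-frame (6 x 6) scan.
    """
    if not (0 < aperture <= period):
        raise InvalidParameterError("need 0 < aperture <= period")
    if step <= 0 or period % step != 0:
        raise InvalidParameterError("step must divide period")
    ny, nx = dmd_shape
    n = period // step
    y = np.arange(ny)[:, None]
    x = np.arange(nx)[None, :]
    masks: list[np.ndarray] = []
    offsets: list[tuple[int, int]] = []
    for ky in range(n):
        for kx in range(n):
            ox, oy = kx * step, ky * step
            m = (((x - ox) % period) < aperture) & (((y - oy) % period) < aperture)
            masks.append(m.astype(np.uint8))
            offsets.append((ox, oy))
    return MaskSequence(
        masks=masks,
        offsets=offsets,
        aperture=aperture,
        period=period,
        step=step,
        pattern_kind="multifocal",
        meta={"raster": "row-major", "dmd_shape": dmd_shape},
    )


# Stripe orientations as (a, b): pattern coordinate t = a*x + b*y.  Dir.1 is
# vertical stripes (0 deg); Dir.2/3 are digital lines of slope 2:1, the
# rational approximation of +-60 degrees on the square mirror grid.
STRIPE_ORIENTATIONS: tuple[tuple[int, int], ...] = ((1, 0), (1, 2), (1, -2))


def stripe_sequence(
    period: int = 8,
    shift: int = 2,
    n_orientations: int = 3,
    dmd_shape: tuple[int, int] = DEFAULT_DMD_SHAPE,
    orientations: tuple[tuple[int, int], ...] | None = None,
) -> MaskSequence:
    """Half-duty stripe masks at three phases per orientation.

    Phases are {0, shift, 2*shift} pixels along the pattern coordinate; the
    phase step in radians is 2*pi*shift/period (pi/2 for the default 8-pixel
    period with two-pixel shifts).
    """
    if period % 2 != 0:
        raise InvalidParameterError("period must be even (half duty cycle)")
    if not (0 < shift <= period):
        raise InvalidParameterError("need 0 < shift <= period")
    if n_orientations < 1:
        raise InvalidParameterError("need at least one orientation")
    dirs = orientations if orientations is not None else STRIPE_ORIENTATIONS
    if n_orientations > len(dirs):
        raise InvalidParameterError(
            f"only {len(dirs)} orientations configured; pass `orientations`"
        )
    ny, nx = dmd_shape
    y = np.arange(ny)[:, None]
    x = np.arange(nx)[None, :]
    masks: list[np.ndarray] = []
    offsets: list[tuple[int, int]] = []
    orientation_index: list[int] = []
    for d in range(n_orientations):
        a, b = dirs[d]
        t = a * x + b * y
        for k in range(3):
            m = ((t - k * shift) % period) < period // 2
            masks.append(m.astype(np.uint8))
            offsets.append((k * shift, 0))
            orientation_index.append(d)
    return MaskSequence(
        masks=masks,
        offsets=offsets,
        aperture=None,
        period=period,
        step=shift,
        pattern_kind="stripes",
        orientation_index=orientation_index,
        meta={
            "phase_step_rad": 2.0 * np.pi * shift / period,
            "orientations": list(dirs[:n_orientations]),
            "dmd_shape": dmd_shape,
        },
    )


def sample_plane_length(config: OpticalConfig, n_dmd_px: float) -> float:
    """Sample-plane length (nm) of ``n_dmd_px`` DMD pixels.

    4 px at 5.4 um pitch under 100x project to 216 nm — the excitation spot
    side; 2 px give the 108 nm scan step.
    """
    if n_dmd_px <= 0:
        raise InvalidParameterError("n_dmd_px must be positive")
    return n_dmd_px * config.dmd_pixel * 1000.0 / config.magnification


@dataclass(frozen=True)
class GratingGeometry:
    """Blazed-grating view of the DMD mirror array.

    ``diagonal_mode`` selects the effective period along the mirror-tilt
    diagonal (pitch/sqrt(2)) instead of the row pitch; ``order`` forces a
    diffraction order instead of auto-selecting the one nearest the blaze
    (single-mirror specular) direction.
    """

    pitch: float  # mirror pitch d, um
    tilt: float = 12.0  # micromirror tilt, deg
    diagonal_mode: bool = True
    order: int | None = None

    def __post_init__(self) -> None:
        if self.pitch <= 0:
            raise InvalidParameterError("pitch must be positive")
        if abs(self.tilt) >= 45:
            raise InvalidParameterError("|tilt| must be < 45 deg")

    @property
    def effective_period_nm(self) -> float:
        d = self.pitch * 1000.0
        return d / np.sqrt(2.0) if self.diagonal_mode else d


def _propagating_orders(geom: GratingGeometry, incidence_deg: float, wavelength_nm: float):
    d = geom.effective_period_nm
    sin_a = np.sin(np.radians(incidence_deg))
    m_lo = int(np.floor((-1.0 + sin_a) * d / wavelength_nm))
    m_hi = int(np.ceil((1.0 + sin_a) * d / wavelength_nm))
    orders, sines = [], []
    for m in range(m_lo, m_hi + 1):
        s = m * wavelength_nm / d - sin_a
        if -1.0 <= s <= 1.0:
            orders.append(m)
            sines.append(s)
    return np.array(orders), np.array(sines)


def grating_exit_angle(
    geom: GratingGeometry, incidence_deg: float, wavelength_nm: float
) -> tuple[float, int]:
    """Exit angle (deg) and diffraction order of the blaze-selected order.

    Solves the grating equation sin(beta_m) = m*lambda/d_eff - sin(alpha) over
    integer orders and returns the order whose direction is nearest the
    single-mirror specular (blaze) direction beta = 2*tilt - alpha; a forced
    ``geom.order`` overrides the selection.  The m = 0 order is the specular
    reflection off the array plane, beta_0 = -alpha.
    """
    if abs(incidence_deg) >= 90:
        raise InvalidParameterError("|incidence| must be < 90 deg")
    if wavelength_nm <= 0:
        raise InvalidParameterError("wavelength must be positive")
    orders, sines = _propagating_orders(geom, incidence_deg, wavelength_nm)
    if geom.order is not None:
        if geom.order not in orders:
            raise InvalidParameterError(
                f"order {geom.order} does not propagate at alpha={incidence_deg}, "
                f"lambda={wavelength_nm}"
            )
        m = geom.order
        beta = np.degrees(np.arcsin(sines[list(orders).index(m)]))
        return float(beta), int(m)
    if orders.size == 0:
        raise InvalidParameterError("no propagating diffraction order")
    betas = np.degrees(np.arcsin(sines))
    beta_blaze = 2.0 * geom.tilt - incidence_deg
    i = int(np.argmin(np.abs(betas - beta_blaze)))
    return float(betas[i]), int(orders[i])


def grating_efficiency(
    geom: GratingGeometry, incidence_deg: float, wavelength_nm: float
) -> float:
    """Scalar single-mirror sinc^2 envelope efficiency of the selected order.

    The envelope peaks at 1 exactly at the blaze condition, and the sum over
    all propagating orders never exceeds 1 (the envelope samples a unit
    partition: sum_m sinc^2(pi(m - c)) = 1 over the integers).
    """
    beta, m = grating_exit_angle(geom, incidence_deg, wavelength_nm)
    d = geom.effective_period_nm
    sin_a = np.sin(np.radians(incidence_deg))
    sin_blaze = np.sin(np.radians(2.0 * geom.tilt - incidence_deg))
    # fractional blaze order: the envelope center in order space
    c = d / wavelength_nm * (sin_blaze + sin_a)
    return float(np.sinc(m - c) ** 2)
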