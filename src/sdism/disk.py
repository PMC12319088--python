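"""Archimedean multi-spiral pinhole disk geometry and coverage simulation.

A disk with N interleaved sub-spirals advances N*pitch in radius per 2*pi
along each sub-spiral, with sub-spiral k rotated by 2*pi*k/N, so a rotation
of only 2*pi/N sweeps the whole field.  Pinholes sit at equal arc-length
steps (the pinhole spacing) along each sub-spiral.  All disk-plane lengths
are in micrometers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .optics import InvalidParameterError

__all__ = [
    "DiskLayout",
    "CoverageReport",
    "build_disk",
    "scan_line_spacing",
    "coverage_period",
    "valid_exposures",
    "coverage_map",
]


@dataclass
class DiskLayout:
    """Pinhole polar coordinates of an N-sub-spiral Archimedean disk."""

    radii: np.ndarray  # um
    angles: np.ndarray  # rad, unwrapped
    sub_spiral: np.ndarray  # int index 0..N-1
    n_sub_spirals: int
    pitch: float  # pinhole spacing along the spiral, um
    pinhole_diameter: float  # um
    r_min: float
    r_max: float

    def __len__(self) -> int:
        return self.radii.size

    def to_xy(self) -> np.ndarray:
        """(n, 2) Cartesian pinhole centers (x, y) in um."""
        return np.column_stack(
            [self.radii * np.cos(self.angles), self.radii * np.sin(self.angles)]
        )

    def to_records(self) -> np.ndarray:
        xy = self.to_xy()
        return np.column_stack(
            [xy[:, 0], xy[:, 1], self.radii, self.angles, self.sub_spiral]
        )


@dataclass
class CoverageReport:
    """Accumulated exposure dose over a FOV rectangle and its uniformity."""

    accumulated_map: np.ndarray
    cv: float  # coefficient of variation of the dose; nan if map is empty
    rotation_span: float  # rad
    center_offset: float  # um
    pixel_size: float  # um
    n_steps: int
    warnings: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not np.any(self.accumulated_map > 0)


def build_disk(
    n_sub_spirals: int,
    pitch: float,
    pinhole_diameter: float,
    r_min: float,
    r_max: float,
) -> DiskLayout:
    """Place pinholes along N interleaved Archimedean sub-spirals.

    Sub-spiral k follows r(theta) = r_min + N*pitch*theta/(2*pi) with a start
    angle 2*pi*k/N; pinholes advance in equal arc-length steps of ``pitch``
    until the radius exceeds ``r_max``.
    """
    N = n_sub_spirals
    if N < 1:
        raise InvalidParameterError("need at least one sub-spiral")
    if not (0 < r_min < r_max):
        raise InvalidParameterError("need 0 < r_min < r_max")
    if pitch <= pinhole_diameter:
        raise InvalidParameterError("pitch must exceed the pinhole diameter")
    if (r_max - r_min) < N * pitch:
        raise InvalidParameterError(
            "annulus too thin: needs at least one full turn per sub-spiral "
            f"(r_max - r_min >= N*pitch = {N * pitch})"
        )
    b = N * pitch / (2.0 * np.pi)  # radial advance per radian
    radii, angles, subs = [], [], []
    # One sub-spiral is generated and replicated by rotation, which makes the
    # rotational-copy invariant exact by construction.
    phi = 0.0
    r = r_min
    phis, rs = [], []
    while r <= r_max:
        phis.append(phi)
        rs.append(r)
        # arc-length step: dphi such that ds = pitch, refined at the midpoint
        dphi = pitch / np.hypot(r, b)
        r_mid = r_min + b * (phi + 0.5 * dphi)
        dphi = pitch / np.hypot(r_mid, b)
        phi += dphi
        r = r_min + b * phi
    phis = np.asarray(phis)
    rs = np.asarray(rs)
    for k in range(N):
        radii.append(rs)
        angles.append(phis + 2.0 * np.pi * k / N)
        subs.append(np.full(rs.size, k, dtype=int))
    return DiskLayout(
        radii=np.concatenate(radii),
        angles=np.concatenate(angles),
        sub_spiral=np.concatenate(subs),
        n_sub_spirals=N,
        pitch=pitch,
        pinhole_diameter=pinhole_diameter,
        r_min=r_min,
        r_max=r_max,
    )


def scan_line_spacing(r: float, n_sub_spirals: int, pitch: float) -> float:
    """Radial spacing (um) between adjacent scan lines swept at radius r.

    Consecutive pinholes along a sub-spiral advance N*pitch^2/(2*pi*r) in
    radius, which is the pitch of the concentric annuli each pinhole traces;
    larger N or smaller radius coarsens the radial sampling (the Nyquist
    consideration limiting N).
    """
    if r <= 0:
        raise InvalidParameterError("radius must be positive")
    return n_sub_spirals * pitch**2 / (2.0 * np.pi * r)


def coverage_period(rpm: float, n_sub_spirals: int) -> float:
    """Seconds for one complete uniform full-field coverage: 60/(rpm*N).

    A single-spiral disk needs a full 2*pi turn (12 ms at 5000 rpm); N
    sub-spirals divide the field into N interleaved sections scanned in
    parallel, cutting the period to 2*pi/N of rotation.
    """
    if rpm <= 0:
        raise InvalidParameterError("rpm must be positive")
    if n_sub_spirals < 1:
        raise InvalidParameterError("need at least one sub-spiral")
    return 60.0 / (rpm * n_sub_spirals)


def valid_exposures(rpm: float, n_sub_spirals: int, k_max: int) -> list[float]:
    """Exposure times (s) that are integer multiples of the coverage period.

    Exposing for any of these guarantees the disk sweeps the field a whole
    number of times, so every frame is uniformly illuminated.
    """
    if k_max < 1:
        raise InvalidParameterError("k_max must be >= 1")
    base = coverage_period(rpm, n_sub_spirals)
    return [k * base for k in range(1, k_max + 1)]


def _paint_disks(
    acc: np.ndarray,
    centers: np.ndarray,
    radius_px: float,
    x0: float,
    y0: float,
    pixel: float,
) -> None:
    """Accumulate antialiased unit disks (centers in um) into ``acc``."""
    h, w = acc.shape
    half = int(np.ceil(radius_px)) + 1
    for cx, cy in centers:
        px = (cx - x0) / pixel
        py = (cy - y0) / pixel
        ix, iy = int(round(px)), int(round(py))
        xlo, xhi = max(0, ix - half), min(w, ix + half + 1)
        ylo, yhi = max(0, iy - half), min(h, iy + half + 1)
        if xlo >= xhi or ylo >= yhi:
            continue
        yy = np.arange(ylo, yhi)[:, None] - py
        xx = np.arange(xlo, xhi)[None, :] - px
        dist = np.hypot(yy, xx)
        acc[ylo:yhi, xlo:xhi] += np.clip(radius_px - dist + 0.5, 0.0, 1.0)


def coverage_map(
    layout: DiskLayout,
    fov_center_radius: float,
    fov_size: tuple[float, float],
    rotation_span: float,
    n_steps: int | None = None,
    center_offset: float = 0.0,
    pixel_size: float | None = None,
) -> CoverageReport:
    """Accumulated exposure dose over a FOV rectangle during a rotation.

    The FOV is an axis-aligned rectangle of size (width, height) um centered
    at (fov_center_radius, 0) in the lab frame; the disk rotates about the
    lab origin.  ``center_offset`` displaces the spiral pattern center from
    the rotation axis, emulating mechanical decentration.  Pinholes are
    rasterized as antialiased hard-edged disks at each of ``n_steps``
    rotation steps.
    """
    if rotation_span <= 0:
        raise InvalidParameterError("rotation_span must be positive")
    wfov, hfov = fov_size
    pixel = pixel_size if pixel_size is not None else layout.pinhole_diameter / 5.0
    msgs: list[str] = []
    if n_steps is None:
        n_steps = int(np.ceil(rotation_span * layout.r_max / (layout.pinhole_diameter / 4.0)))
    else:
        step_arc = rotation_span / n_steps * layout.r_max
        if step_arc > layout.pinhole_diameter / 2.0:
            msg = (
                f"rotation undersampled: {step_arc:.1f} um arc per step exceeds "
                f"half the pinhole diameter"
            )
            msgs.append(msg)
            warnings.warn(msg, stacklevel=2)
    w = int(np.ceil(wfov / pixel))
    h = int(np.ceil(hfov / pixel))
    acc = np.zeros((h, w))
    x0 = fov_center_radius - wfov / 2.0
    y0 = -hfov / 2.0
    radius_px = layout.pinhole_diameter / 2.0 / pixel
    # pattern coordinates relative to the pattern center, which sits at
    # (center_offset, 0) from the rotation axis at angle zero
    base_xy = layout.to_xy()
    margin = layout.pinhole_diameter
    r_lab_max = layout.radii.max() + center_offset + margin
    angles = rotation_span * (np.arange(n_steps) + 0.5) / n_steps
    for a in angles:
        ca, sa = np.cos(a), np.sin(a)
        off = np.array([center_offset * ca, center_offset * sa])
        x = base_xy[:, 0] * ca - base_xy[:, 1] * sa + off[0]
        y = base_xy[:, 0] * sa + base_xy[:, 1] * ca + off[1]
        sel = (
            (x > x0 - margin)
            & (x < x0 + wfov + margin)
            & (y > y0 - margin)
            & (y < y0 + hfov + margin)
        )
        if not np.any(sel):
            continue
        _paint_disks(acc, np.column_stack([x[sel], y[sel]]), radius_px, x0, y0, pixel)
    if acc.size == 0 or not np.any(acc > 0):
        cv = float("nan")
        msgs.append("empty coverage: no pinhole crossed the FOV")
    else:
        cv = float(acc.std() / acc.mean())
    return CoverageReport(
        accumulated_map=acc,
        cv=cv,
        rotation_span=rotation_span,
        center_offset=center_offset,
        pixel_size=pixel,
        n_steps=n_steps,
        warnings=msgs,
    )
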