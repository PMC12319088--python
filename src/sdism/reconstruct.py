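"""Pixel-reassignment reconstruction with a dynamic (scan-synchronized) 5x5
virtual detector array.

Pipeline stages, each an independent operation:

1. ``suppress_scan_dc``     remove the static background by zeroing the
                            temporal (scan-axis) DC of every pixel;
2. ``estimate_lattice``     recover the illumination lattice basis from the
                            Fourier spectrum and its absolute origin from the
                            offset between predicted and detected peaks;
3. ``sample_vda``           interpolate a 5x5 virtual detector array around
                            every excitation spot in every frame and
                            rearrange the samples into 25 confocal sub-images
                            on the scan grid (one site per scan position);
4. ``register_subimages``   phase cross-correlation of each sub-image against
                            the central one, sub-pixel shifts applied in the
                            Fourier domain;
5. ``superpose``            weighted sum of the registered sub-images — the
                            sqrt(2) resolution step;
6. ``rl_deconvolve``        optional Richardson-Lucy sharpening toward the
                            two-fold improvement.

``pr_baseline`` applies the classical fixed-1/2 reassignment instead of
estimated shifts; ``confocal_reference`` exposes the small-pinhole (central
element) and open-pinhole (plain sum) comparator images.

Coordinates are (y, x) camera pixels, 0-based, origin top-left.  Sub-image
shifts are content translations in scan-grid pixels: translating sub-image
(u, v) by +(v/2, u/2) aligns it with the central one in the ideal symmetric
case (the classical half-offset reassignment, expressed in the grid whose
pitch equals the scan step).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from skimage.restoration import richardson_lucy

from .optics import InvalidParameterError
from .simulate import RawStack

__all__ = [
    "LatticeModel",
    "SubImageSet",
    "ReconResult",
    "LatticeNotFoundError",
    "suppress_scan_dc",
    "estimate_lattice",
    "sample_vda",
    "register_subimages",
    "superpose",
    "pr_baseline",
    "confocal_reference",
    "rl_deconvolve",
    "run_dpa_pr",
]


class LatticeNotFoundError(RuntimeError):
    """Raised when no illumination-lattice peaks are detected in the spectrum."""


@dataclass
class LatticeModel:
    """Estimated illumination lattice: two basis vectors and an absolute origin.

    ``basis`` columns are b1 (x-dominant) and b2 (y-dominant) as (dy, dx)
    camera-pixel vectors; ``origin`` is the (y, x) position of one lattice
    point of the first frame, sub-pixel.  ``per_frame_offsets`` are the
    commanded (dy, dx) offsets in camera pixels for every frame.
    """

    basis: np.ndarray  # (2, 2); column j is basis vector j as (dy, dx)
    origin: np.ndarray  # (2,) (y, x)
    per_frame_offsets: np.ndarray | None = None  # (n_frames, 2) (dy, dx)
    meta: dict = field(default_factory=dict)

    @property
    def b1(self) -> np.ndarray:
        return self.basis[:, 0]

    @property
    def b2(self) -> np.ndarray:
        return self.basis[:, 1]

    def validate(self, expected_period_px: float, tolerance: float = 0.05) -> None:
        for b in (self.b1, self.b2):
            if abs(np.linalg.norm(b) - expected_period_px) > tolerance * expected_period_px:
                raise LatticeNotFoundError(
                    f"basis length {np.linalg.norm(b):.3f} px deviates more than "
                    f"{tolerance:.0%} from the design period {expected_period_px:.3f} px"
                )
        det = abs(np.linalg.det(self.basis))
        if det < 0.5 * np.linalg.norm(self.b1) * np.linalg.norm(self.b2):
            raise LatticeNotFoundError("degenerate lattice basis")

    def reduced_origin(self) -> np.ndarray:
        """Origin folded into the fundamental cell nearest (0, 0)."""
        n = np.round(np.linalg.solve(self.basis, self.origin))
        return self.origin - self.basis @ n


@dataclass
class SubImageSet:
    """The 25 confocal sub-images extracted by VDA sampling.

    ``images[v + 2, u + 2]`` is the sub-image of virtual detector element
    (u, v), u along x, v along y, each on the scan grid (pitch = scan step).
    ``site00_yx`` anchors scan-grid site (0, 0) in camera pixels for mapping
    between grids.  ``shifts`` are filled by registration (content
    translations, scan-grid px); ``valid`` masks sites whose samples left the
    frame (never extrapolated).
    """

    images: np.ndarray  # (5, 5, H, W)
    valid: np.ndarray  # (5, 5, H, W) bool
    grid_pitch_px: float  # camera px per scan-grid site
    grid_pitch_nm: float
    site00_yx: np.ndarray  # (2,) camera px
    shifts: np.ndarray | None = None  # (5, 5, 2) (dy, dx) grid px
    weights: np.ndarray | None = None  # (5, 5)
    registered: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def half_width(self) -> int:
        return (self.images.shape[0] - 1) // 2

    @property
    def central(self) -> np.ndarray:
        c = self.half_width
        return self.images[c, c]

    def to_grid(self, pos_yx_px: np.ndarray) -> np.ndarray:
        """Map camera-pixel positions to scan-grid coordinates."""
        return (np.asarray(pos_yx_px, dtype=float) - self.site00_yx) / self.grid_pitch_px


@dataclass
class ReconResult:
    """A 2D reconstruction plus the provenance needed to regenerate it."""

    image: np.ndarray
    method: str  # dpa_pr | pr | confocal_open | confocal_small
    shift_table: np.ndarray | None = None
    parameters: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _stack_frames(stack) -> np.ndarray:
    return stack.frames if isinstance(stack, RawStack) else np.asarray(stack)


def suppress_scan_dc(stack) -> np.ndarray:
    """Zero the per-pixel temporal mean across the frame (scan) axis.

    Static background — out-of-focus haze, camera offset — is constant over
    the scan and lands entirely in the scan-direction DC component, while the
    stepped lattice moves frame to frame; subtracting the temporal mean
    therefore strips background without touching the lattice's own spatial
    spectrum.  Output feeds lattice estimation only, never VDA sampling.
    """
    frames = _stack_frames(stack).astype(np.float64)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise InvalidParameterError("need at least two frames to suppress the scan DC")
    return frames - frames.mean(axis=0, keepdims=True)


def _quadratic_peak(power: np.ndarray, iy: int, ix: int) -> tuple[float, float]:
    """Sub-bin peak location via a separable quadratic fit on log power."""

    def refine(fm, f0, fp):
        denom = fm - 2 * f0 + fp
        return 0.0 if denom == 0 else 0.5 * (fm - fp) / denom

    h, w = power.shape
    ys = [(iy + d) % h for d in (-1, 0, 1)]
    xs = [(ix + d) % w for d in (-1, 0, 1)]
    win = np.log(power[np.ix_(ys, xs)] + 1e-300)
    dy = refine(win[0, 1], win[1, 1], win[2, 1])
    dx = refine(win[1, 0], win[1, 1], win[1, 2])
    return iy + np.clip(dy, -0.5, 0.5), ix + np.clip(dx, -0.5, 0.5)


def _dft_at(image: np.ndarray, f: np.ndarray) -> complex:
    """Single-frequency DFT of an image at a continuous (fy, fx)."""
    h, w = image.shape
    ey = np.exp(-2j * np.pi * f[0] * np.arange(h))
    ex = np.exp(-2j * np.pi * f[1] * np.arange(w))
    return complex(ey @ image @ ex)


def _zoom_refine(
    image: np.ndarray, f_coarse: np.ndarray, halfspan_bins: float = 1.0, upsample: int = 10
) -> np.ndarray:
    """Refine a spectral peak by a local fine-grid DFT around ``f_coarse``.

    Evaluates |DFT| of ``image`` on a (2*upsample+1)^2 grid spanning
    +-``halfspan_bins`` frequency bins around the coarse peak and returns the
    (fy, fx) of the maximum, plus a final quadratic sub-step.
    """
    h, w = image.shape
    dy = np.linspace(-halfspan_bins / h, halfspan_bins / h, 2 * upsample + 1)
    dx = np.linspace(-halfspan_bins / w, halfspan_bins / w, 2 * upsample + 1)
    fy = f_coarse[0] + dy
    fx = f_coarse[1] + dx
    y = np.arange(h)
    x = np.arange(w)
    Ey = np.exp(-2j * np.pi * np.outer(fy, y))  # (nf, h)
    Ex = np.exp(-2j * np.pi * np.outer(x, fx))  # (w, nf)
    Z = Ey @ image @ Ex  # (nf, nf)
    P = np.abs(Z) ** 2
    iy, ix = np.unravel_index(int(np.argmax(P)), P.shape)
    ry, rx = float(iy), float(ix)
    if 0 < iy < P.shape[0] - 1 and 0 < ix < P.shape[1] - 1:
        ry, rx = _quadratic_peak(P, iy, ix)
    step_y = dy[1] - dy[0]
    step_x = dx[1] - dx[0]
    return np.array([fy[0] + ry * step_y, fx[0] + rx * step_x])


def _find_fundamental_peaks(power: np.ndarray, expected_period_px: float):
    """Two non-collinear fundamental peaks near the expected frequency ring."""
    h, w = power.shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    fr = np.hypot(fy, fx)
    f0 = 1.0 / expected_period_px
    # the design period is a hard prior (the lattice invariant bounds the
    # basis within 5% of it), so the search ring can be tight — essential for
    # sparse objects whose own spectrum is speckled across the plane
    annulus = (fr > 0.90 * f0) & (fr < 1.10 * f0)
    if not np.any(annulus):
        raise LatticeNotFoundError(
            f"no spectral support near frequency {f0:.4f} cycles/px"
        )
    masked = np.where(annulus, power, 0.0)
    i1 = np.unravel_index(int(np.argmax(masked)), power.shape)
    p1 = masked[i1]
    if p1 <= 0:
        raise LatticeNotFoundError("empty spectrum in the search annulus")
    v1 = np.array([fy[i1[0], 0], fx[0, i1[1]]])
    # exclude directions within 30 deg of +-v1
    u1 = v1 / np.linalg.norm(v1)
    cosang = np.abs((fy * u1[0] + fx * u1[1]) / np.where(fr > 0, fr, np.inf))
    masked2 = np.where(annulus & (cosang < np.cos(np.radians(60))), power, 0.0)
    i2 = np.unravel_index(int(np.argmax(masked2)), power.shape)
    p2 = masked2[i2]
    if p2 <= 0 or p2 < 1e-6 * p1:
        raise LatticeNotFoundError(
            f"second lattice fundamental below detection threshold near "
            f"frequency {f0:.4f} cycles/px"
        )
    peaks = []
    for iy, ix in (i1, i2):
        ry, rx = _quadratic_peak(power, iy, ix)
        peaks.append(
            np.array(
                [
                    (ry if ry < h / 2 else ry - h) / h,
                    (rx if rx < w / 2 else rx - w) / w,
                ]
            )
        )
    return peaks


def _detect_spots(frame: np.ndarray, period_px: float, margin: float):
    """Sub-pixel intensity maxima of one frame via windowed centroids."""
    smoothed = ndimage.gaussian_filter(frame, 1.0)
    size = max(3, int(round(period_px / 2)))
    local_max = smoothed == ndimage.maximum_filter(smoothed, size=size)
    threshold = 0.3 * smoothed.max()
    ys, xs = np.nonzero(local_max & (smoothed > threshold))
    h, w = frame.shape
    clipped = np.clip(frame, 0.0, None)
    win = max(2, int(round(period_px / 3)))
    centers, amps = [], []
    for y0, x0 in zip(ys, xs):
        if not (margin <= y0 < h - margin and margin <= x0 < w - margin):
            continue
        cy, cx = float(y0), float(x0)
        for _ in range(2):
            iy, ix = int(round(cy)), int(round(cx))
            patch = clipped[iy - win : iy + win + 1, ix - win : ix + win + 1]
            if patch.size == 0 or patch.sum() <= 0:
                break
            yy, xx = np.mgrid[iy - win : iy + win + 1, ix - win : ix + win + 1]
            cy = float((patch * yy).sum() / patch.sum())
            cx = float((patch * xx).sum() / patch.sum())
        centers.append((cy, cx))
        amps.append(float(smoothed[y0, x0]))
    return np.asarray(centers), np.asarray(amps)


def estimate_lattice(
    stack,
    expected_period_px: float | None = None,
    validate: bool = True,
) -> LatticeModel:
    """Estimate the illumination lattice from a raw multifocal stack.

    Basis vectors come from the two fundamental peaks of the scan-DC-
    suppressed power spectrum (averaged over frames, sub-bin refined); the
    absolute origin comes from averaging the offset between basis-predicted
    lattice points and detected illumination peaks of the first frame.  Both
    are then jointly refined by a least-squares fit of peak positions to
    integer lattice indices, iterated with re-assignment.
    """
    frames = _stack_frames(stack)
    if expected_period_px is None:
        if not isinstance(stack, RawStack):
            raise InvalidParameterError(
                "expected_period_px required when not passing a RawStack"
            )
        expected_period_px = stack.lattice_period_px
    if expected_period_px <= 2:
        raise InvalidParameterError("expected period must exceed 2 px (Nyquist)")
    dc = suppress_scan_dc(frames)
    h, w = dc.shape[1:]
    wy = np.hanning(h)[:, None]
    wx = np.hanning(w)[None, :]
    offsets_known = isinstance(stack, RawStack)
    if offsets_known:
        # matched-filter average: compensating each frame's spectrum with the
        # phase of its commanded offset makes the moving lattice fundamental
        # add coherently while object structure (which does not move with the
        # scan) averages out — essential for sparse objects whose own
        # spectrum otherwise drowns the lattice peaks.
        offs = _frame_offsets_px(stack)
        fy = np.fft.fftfreq(h)[:, None]
        fx = np.fft.fftfreq(w)[None, :]
        G = np.zeros((h, w), dtype=complex)
        for fr, (oy, ox) in zip(dc, offs):
            G += np.fft.fft2(fr * wy * wx) * np.exp(2j * np.pi * (fy * oy + fx * ox))
        power = np.abs(G) ** 2
    else:
        power = np.zeros((h, w))
        for fr in dc:
            power += np.abs(np.fft.fft2(fr * wy * wx)) ** 2
    if offsets_known:
        # the commanded scan geometry provides the design frequencies; seed
        # the refinement there instead of a blind ring search, which sparse
        # objects can derail with their own spectral speckle
        f_design = 1.0 / expected_period_px
        f1 = np.array([0.0, f_design])
        f2 = np.array([f_design, 0.0])
    else:
        f1, f2 = _find_fundamental_peaks(power, expected_period_px)
    # order: f1 x-dominant, f2 y-dominant; fix signs to a right-handed basis
    if abs(f1[1]) < abs(f2[1]):
        f1, f2 = f2, f1
    if f1[1] < 0:
        f1 = -f1
    if f2[0] < 0:
        f2 = -f2
    # sub-bin refinement by local fine-grid DFT of the (phase-compensated)
    # frame sum; the compensation phase is locked at each coarse peak.  The
    # complex value at the refined peak carries the lattice phase:
    # G(f_k) ~ e^(-2*pi*i f_k . o), the standard structured-illumination
    # phase readout, which pins the absolute origin without peak detection.
    refined, values = [], []
    basis_fallback = False
    for fpk in (f1, f2):
        if offsets_known:
            c = np.exp(2j * np.pi * (offs[:, 0] * fpk[0] + offs[:, 1] * fpk[1]))
            S = np.tensordot(c, dc, axes=(0, 0)) * wy * wx
        else:
            S = dc.sum(axis=0) * wy * wx
        f_ref = _zoom_refine(S, fpk)
        if offsets_known and abs(np.linalg.norm(f_ref) - np.linalg.norm(fpk)) > 0.02 * np.linalg.norm(fpk):
            # a refined frequency drifting percent-scale from the commanded
            # design means the scene lacks the structure to constrain it
            # (e.g. a single emitter); keep the design frequency, flagged
            f_ref = fpk
            basis_fallback = True
        refined.append(f_ref)
        values.append(_dft_at(S, f_ref))
    f1, f2 = refined
    # detection threshold: the fundamentals must stand out of the spectral
    # floor on the expected frequency ring
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    ring = (np.hypot(fy, fx) > 0.9 / expected_period_px) & (
        np.hypot(fy, fx) < 1.1 / expected_period_px
    )
    floor = float(np.median(power[ring]))
    for f_ref, v in zip(refined, values):
        prominence = abs(v) ** 2 / floor if floor > 0 else float("nan")
        if not np.isfinite(prominence) or prominence < 0.1:
            raise LatticeNotFoundError(
                f"lattice fundamental at ({f_ref[0]:.4f}, {f_ref[1]:.4f}) cycles/px "
                f"below detection threshold (prominence {prominence:.3g})"
            )
    F = np.vstack([f1, f2])  # rows: frequencies; f_i . b_j = delta_ij
    try:
        B = np.linalg.inv(F)
    except np.linalg.LinAlgError as exc:
        raise LatticeNotFoundError("collinear lattice fundamentals") from exc
    phases = np.array([np.angle(v) for v in values])
    origin_phase = B @ (-phases / (2.0 * np.pi))

    # Real-space peaks are collected from every frame and mapped back to the
    # first frame by subtracting the commanded offset: sparse objects light up
    # few lattice points per frame, and averaging over the full phase grid
    # cancels the pull of object structure on the detected maxima.
    margin = expected_period_px
    offsets = (
        _frame_offsets_px(stack)
        if isinstance(stack, RawStack)
        else np.zeros((len(frames), 2))
    )
    all_spots, all_weights = [], []
    for i in range(dc.shape[0]):
        s, a = _detect_spots(dc[i], expected_period_px, margin)
        if s.size:
            all_spots.append(s - offsets[i])
            all_weights.append(a)
    # fold the phase origin to the lattice point nearest the field center
    center = np.array([h / 2, w / 2])
    origin = origin_phase + B @ np.round(np.linalg.solve(B, center - origin_phase))
    # refinement: average offset between basis-predicted lattice points and
    # detected intensity maxima, matched by nearest neighbor within a quarter
    # period and weighted by peak brightness (object structure pulls single
    # peaks but the pulls cancel over the scan-phase grid)
    n_used = 0
    resid = np.zeros((0, 2))
    if all_spots:
        spots = np.vstack(all_spots)
        wts = np.concatenate(all_weights)
        n = np.round(np.linalg.solve(B, (spots - origin).T)).T
        d = spots - (origin + (B @ n.T).T)
        gate = np.all(np.abs(d) < expected_period_px / 4.0, axis=1)
        n_used = int(gate.sum())
        if n_used >= 10:
            w_g = wts[gate]
            origin = origin + (d[gate] * w_g[:, None]).sum(axis=0) / w_g.sum()
            n = np.round(np.linalg.solve(B, (spots - origin).T)).T
            d = spots - (origin + (B @ n.T).T)
            gate = np.all(np.abs(d) < expected_period_px / 4.0, axis=1)
        resid = d[gate]
    model = LatticeModel(
        basis=B,
        origin=origin,
        per_frame_offsets=_frame_offsets_px(stack) if isinstance(stack, RawStack) else None,
        meta={
            "n_spots": n_used,
            "rms_residual_px": float(np.sqrt((resid**2).sum(axis=1).mean()))
            if resid.size
            else float("nan"),
            "origin_phase_estimate": origin_phase.tolist(),
            "basis_fallback": basis_fallback,
            "expected_period_px": float(expected_period_px),
        },
    )
    if validate:
        model.validate(expected_period_px)
    return model


def _frame_offsets_px(stack: RawStack) -> np.ndarray:
    pix = stack.config.camera_pixel_sample
    return np.array([(oy / pix, ox / pix) for ox, oy in stack.offsets_nm])


def sample_vda(
    stack: RawStack,
    lattice: LatticeModel,
    step_px: float | None = None,
    half_width: int = 2,
    interpolation: str = "cubic",
) -> SubImageSet:
    """Extract the (2h+1)^2 confocal sub-images by virtual-detector sampling.

    For every frame and every lattice point of that frame (origin + integer
    basis combinations + commanded offset), the frame is interpolated at the
    point plus (u, v) * step for (u, v) in {-h..h}^2, and the value is written
    into sub-image (u, v) at the scan-grid site of that point.  Each site is
    written exactly once per sub-image; sites whose sampling neighborhood
    leaves the frame are masked, never extrapolated.
    """
    if interpolation not in ("cubic", "bilinear"):
        raise InvalidParameterError("interpolation must be 'cubic' or 'bilinear'")
    order = 3 if interpolation == "cubic" else 1
    frames = stack.frames
    n_frames, h, w = frames.shape
    step = stack.scan_step_px if step_px is None else float(step_px)
    n_phases = int(round(np.sqrt(n_frames)))
    if n_phases**2 != n_frames:
        raise InvalidParameterError("frame count is not a square phase grid")
    offsets = (
        lattice.per_frame_offsets
        if lattice.per_frame_offsets is not None
        else _frame_offsets_px(stack)
    )
    if len(offsets) != n_frames:
        raise InvalidParameterError("offset table does not match the frame count")
    phases = np.round(np.asarray(offsets) / step).astype(int)  # (ky, kx)
    if not _phases_complete(phases, n_phases):
        raise InvalidParameterError("offsets do not enumerate the phase grid exactly once")

    B, origin = lattice.basis, lattice.origin
    # candidate lattice cells: generous index range from the frame corners
    corners = np.array([[0, 0], [0, w], [h, 0], [h, w]], dtype=float)
    nij = np.linalg.solve(B, (corners - origin).T).T
    n1_rng = np.arange(int(np.floor(nij[:, 0].min())) - 1, int(np.ceil(nij[:, 0].max())) + 2)
    n2_rng = np.arange(int(np.floor(nij[:, 1].min())) - 1, int(np.ceil(nij[:, 1].max())) + 2)
    n1g, n2g = np.meshgrid(n1_rng, n2_rng, indexing="ij")
    npairs = np.column_stack([n1g.ravel(), n2g.ravel()])
    base = origin + (B @ npairs.T).T  # frame-0 lattice points, (n_cells, 2)

    # keep cells whose full VDA neighborhood stays inside the frame for every
    # commanded offset (interior sites); boundary sites get masked per sample
    spline_margin = 2 if order == 3 else 1
    reach = half_width * step + spline_margin
    off_min, off_max = offsets.min(axis=0), offsets.max(axis=0)
    ok = (
        (base[:, 0] + off_min[0] - reach >= 0)
        & (base[:, 0] + off_max[0] + reach <= h - 1)
        & (base[:, 1] + off_min[1] - reach >= 0)
        & (base[:, 1] + off_max[1] + reach <= w - 1)
    )
    npairs = npairs[ok]
    base = base[ok]
    if npairs.shape[0] == 0:
        raise InvalidParameterError("no lattice cell fits the frame with the VDA margin")
    n1_min, n2_min = npairs.min(axis=0)
    gx = (npairs[:, 0] - n1_min).astype(int)
    gy = (npairs[:, 1] - n2_min).astype(int)
    W = int(gx.max()) + 1
    H = int(gy.max()) + 1

    side = 2 * half_width + 1
    images = np.zeros((side, side, H * n_phases, W * n_phases))
    valid = np.zeros((side, side, H * n_phases, W * n_phases), dtype=bool)
    uu = np.arange(-half_width, half_width + 1)
    for i in range(n_frames):
        ky, kx = phases[i]
        if order == 3:
            coeffs = ndimage.spline_filter(frames[i], order=3, mode="mirror")
        else:
            coeffs = frames[i]
        pts = base + offsets[i]  # (n_cells, 2) (y, x)
        row = gy * n_phases + ky
        col = gx * n_phases + kx
        for iv, v in enumerate(uu):
            for iu, u in enumerate(uu):
                sy = pts[:, 0] + v * step
                sx = pts[:, 1] + u * step
                inside = (
                    (sy >= spline_margin)
                    & (sy <= h - 1 - spline_margin)
                    & (sx >= spline_margin)
                    & (sx <= w - 1 - spline_margin)
                )
                vals = ndimage.map_coordinates(
                    coeffs,
                    np.vstack([sy, sx]),
                    order=order,
                    prefilter=False,
                    mode="mirror",
                )
                images[iv, iu, row, col] = np.where(inside, vals, 0.0)
                valid[iv, iu, row, col] = inside
    pix = stack.config.camera_pixel_sample
    site00 = origin + B @ np.array([n1_min, n2_min])
    return SubImageSet(
        images=images,
        valid=valid,
        grid_pitch_px=step,
        grid_pitch_nm=step * pix,
        site00_yx=site00,
        meta={
            "n_phases": n_phases,
            "n_cells": int(npairs.shape[0]),
            "half_width": half_width,
            "interpolation": interpolation,
        },
    )


def _phases_complete(phases: np.ndarray, n_phases: int) -> bool:
    seen = {(int(ky) % n_phases, int(kx) % n_phases) for ky, kx in phases}
    return len(seen) == len(phases) == n_phases**2


def _norm_xcorr_peak(a: np.ndarray, b: np.ndarray) -> float:
    """Peak of the normalized phase cross-correlation surface, in [0, 1]."""
    Fa, Fb = np.fft.fft2(a), np.fft.fft2(b)
    cross = Fa * np.conj(Fb)
    mag = np.abs(cross)
    cross = np.where(mag > 0, cross / np.where(mag > 0, mag, 1.0), 0.0)
    cc = np.abs(np.fft.ifft2(cross))
    return float(cc.max())


def _fourier_translate(image: np.ndarray, shift_yx) -> np.ndarray:
    return np.real(
        np.fft.ifft2(ndimage.fourier_shift(np.fft.fft2(image), shift_yx))
    )


def theoretical_shifts(half_width: int = 2) -> np.ndarray:
    """Fixed-1/2 reassignment translations, scan-grid px, indexed [v+h, u+h]."""
    side = 2 * half_width + 1
    t = np.zeros((side, side, 2))
    for iv, v in enumerate(range(-half_width, half_width + 1)):
        for iu, u in enumerate(range(-half_width, half_width + 1)):
            t[iv, iu] = (v / 2.0, u / 2.0)
    return t


def register_subimages(
    sset: SubImageSet,
    upsample_factor: int = 100,
    confidence_threshold: float = 0.05,
) -> SubImageSet:
    """Register every sub-image to the central one by phase cross-correlation.

    Shifts are estimated at sub-pixel precision (DFT upsampling) and applied
    as Fourier-domain translations.  A sub-image whose normalized correlation
    peak falls below ``confidence_threshold`` (very dim edge elements) falls
    back to the theoretical half-offset shift and is flagged.
    """
    c = sset.half_width
    ref = sset.images[c, c]
    if sset.valid[c, c].mean() < 0.10:
        raise InvalidParameterError("central sub-image has under 10% valid sites")
    side = sset.images.shape[0]
    theo = theoretical_shifts(c)
    shifts = np.zeros((side, side, 2))
    fallbacks = []
    out = np.empty_like(sset.images)
    for iv in range(side):
        for iu in range(side):
            img = sset.images[iv, iu]
            if iv == c and iu == c:
                shifts[iv, iu] = 0.0
                out[iv, iu] = img
                continue
            conf = _norm_xcorr_peak(ref, img)
            if conf < confidence_threshold:
                shift = theo[iv, iu]
                fallbacks.append((iu - c, iv - c))
            else:
                shift, _, _ = phase_cross_correlation(
                    ref, img, upsample_factor=upsample_factor, normalization="phase"
                )
            shifts[iv, iu] = shift
            out[iv, iu] = _fourier_translate(img, shift)
    meta = dict(sset.meta)
    meta["registration_fallbacks"] = fallbacks
    meta["upsample_factor"] = upsample_factor
    return replace(
        sset, images=out, shifts=shifts, registered=True, meta=meta
    )


def superpose(sset: SubImageSet, weighting: str = "uniform") -> ReconResult:
    """Weighted superposition of the registered sub-images.

    ``snr`` weighting sets w_uv proportional to the sub-image total intensity
    (dim edge elements contribute less), normalized to sum to the number of
    elements so uniform-intensity sets reduce exactly to uniform weighting.
    """
    if not sset.registered or sset.shifts is None:
        raise InvalidParameterError("register_subimages must run before superposition")
    side = sset.images.shape[0]
    n = side * side
    if weighting == "uniform":
        w = np.ones((side, side))
    elif weighting == "snr":
        totals = sset.images.sum(axis=(2, 3))
        s = totals.sum()
        w = totals / s * n if s > 0 else np.ones((side, side))
    else:
        raise InvalidParameterError("weighting must be 'uniform' or 'snr'")
    image = np.tensordot(w, sset.images, axes=([0, 1], [0, 1]))
    return ReconResult(
        image=image,
        method="dpa_pr",
        shift_table=sset.shifts.copy(),
        parameters={"weighting": weighting},
        provenance={"fallbacks": sset.meta.get("registration_fallbacks", [])},
    )


def pr_baseline(sset: SubImageSet, scale: float = 0.5) -> ReconResult:
    """Classical fixed-scale pixel reassignment: no estimation, fixed shifts.

    Element (u, v) is translated by scale * (v, u) grid pixels (the classical
    half-offset for the default 1/2).  A zero scale degenerates to the plain
    unshifted sum.
    """
    c = sset.half_width
    theo = theoretical_shifts(c) * (scale / 0.5)
    side = sset.images.shape[0]
    image = np.zeros_like(sset.images[c, c])
    for iv in range(side):
        for iu in range(side):
            if scale == 0:
                image += sset.images[iv, iu]
            else:
                image += _fourier_translate(sset.images[iv, iu], theo[iv, iu])
    return ReconResult(
        image=image, method="pr", shift_table=theo, parameters={"scale": scale}
    )


def confocal_reference(sset: SubImageSet, kind: str = "open") -> ReconResult:
    """Confocal comparator images from the same sub-image set.

    ``small``: the central element alone — a nearly closed (~0.2 AU) pinhole
    confocal image.  ``open``: the unshifted sum of all elements — the ~1 AU
    open-pinhole confocal image used as the fidelity reference.
    """
    c = sset.half_width
    if kind == "small":
        image = sset.images[c, c].copy()
    elif kind == "open":
        image = sset.images.sum(axis=(0, 1))
    else:
        raise InvalidParameterError("kind must be 'open' or 'small'")
    return ReconResult(image=image, method=f"confocal_{kind}")


def rl_deconvolve(result: ReconResult, psf: np.ndarray, n_iter: int = 20) -> ReconResult:
    """Richardson-Lucy sharpening of a reconstruction.

    The PSF must be normalized (unit sum); the image is clipped to
    non-negative before iterating (recorded in provenance).  Flux is
    conserved to well under a percent away from the image borders.
    """
    if n_iter < 1:
        raise InvalidParameterError("n_iter must be >= 1")
    psf = np.asarray(psf, dtype=float)
    if abs(psf.sum() - 1.0) > 1e-6:
        raise InvalidParameterError("PSF must be normalized to unit sum")
    clipped = np.clip(result.image, 0.0, None)
    deconv = richardson_lucy(clipped, psf, num_iter=n_iter, clip=False)
    prov = dict(result.provenance)
    prov["rl_iterations"] = n_iter
    prov["clipped_negative_fraction"] = float((result.image < 0).mean())
    return ReconResult(
        image=deconv,
        method=result.method,
        shift_table=result.shift_table,
        parameters={**result.parameters, "rl_iterations": n_iter},
        provenance=prov,
    )


def run_dpa_pr(
    stack: RawStack,
    expected_period_px: float | None = None,
    weighting: str = "uniform",
    upsample_factor: int = 100,
    interpolation: str = "cubic",
    deconvolve_psf: np.ndarray | None = None,
    deconvolve_iterations: int = 20,
) -> ReconResult:
    """Full reconstruction: lattice estimation, VDA sampling, registration,
    superposition and optional Richardson-Lucy sharpening.

    Deterministic: the same stack and options give a bit-identical result.
    Stage errors propagate with their stage names; full provenance (input
    hash, lattice, shifts, options) is recorded on the result.
    """
    try:
        lattice = estimate_lattice(stack, expected_period_px)
    except Exception as exc:
        raise RuntimeError(f"lattice estimation failed: {exc}") from exc
    try:
        sset = sample_vda(stack, lattice, interpolation=interpolation)
    except Exception as exc:
        raise RuntimeError(f"VDA sampling failed: {exc}") from exc
    try:
        registered = register_subimages(sset, upsample_factor=upsample_factor)
    except Exception as exc:
        raise RuntimeError(f"registration failed: {exc}") from exc
    result = superpose(registered, weighting=weighting)
    if deconvolve_psf is not None:
        result = rl_deconvolve(result, deconvolve_psf, deconvolve_iterations)
    result.provenance.update(
        {
            "input_sha256": hashlib.sha256(
                np.ascontiguousarray(stack.frames).tobytes()
            ).hexdigest(),
            "mode": stack.mode,
            "lattice": {
                "basis": lattice.basis.tolist(),
                "origin": lattice.origin.tolist(),
                "rms_residual_px": lattice.meta.get("rms_residual_px"),
            },
            "options": {
                "weighting": weighting,
                "upsample_factor": upsample_factor,
                "interpolation": interpolation,
                "deconvolve_iterations": deconvolve_iterations
                if deconvolve_psf is not None
                else 0,
            },
            "seed": stack.meta.get("seed"),
        }
    )
    result.parameters["sub_image_set"] = {
        "grid_pitch_nm": sset.grid_pitch_nm,
        "shape": list(sset.images.shape),
    }
    # keep a reference for callers needing the sub-images (metrics, references)
    result.provenance["n_subimages"] = int(sset.images.shape[0] * sset.images.shape[1])
    result.parameters["site00_yx"] = sset.site00_yx.tolist()
    return result
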