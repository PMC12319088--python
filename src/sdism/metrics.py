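"""Quantitative evaluation suite for reconstructions and raw patterns.

Contrast measures (Michelson, RMS local contrast, fringe contrast from the
spectrum sidebands, adjacency-difference contrast ratio), fidelity measures
(MSE/PSNR, a single-window SSIM, resolution-scaled error and Pearson), and
the RSF-degradation linearity protocol (fit a Gaussian resolution scaling
function plus linear intensity map, then R^2 on randomly sampled foreground
points).

Conventions: images compared by PSNR/SSIM are normalized to [0, 1]
(I_max = 1).  SSIM uses the global single-window statistics with the additive
constants C1 = 0.01 and C2 = 0.03; a windowed variant is opt-in.  The R^2
orientation puts the residual against the reference in the numerator and the
degraded image's variance in the denominator (its native convention); pass
``textbook=True`` for the conventional coefficient of determination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import minimize_scalar

from .optics import InvalidParameterError

__all__ = [
    "ImagePair",
    "AdjacencyHistogram",
    "michelson_contrast",
    "local_contrast",
    "fringe_contrast",
    "contrast_ratio",
    "adjacency_histogram",
    "psnr",
    "ssim",
    "rsf_degrade",
    "r2_linearity",
    "rse_rsp",
    "normalize01",
    "PSNR_CAP_DB",
]

PSNR_CAP_DB = 99.0


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given input."""


def normalize01(image: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; constant images map to zeros."""
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


@dataclass
class ImagePair:
    """Two equal-shape images normalized to [0, 1] for PSNR/SSIM."""

    X: np.ndarray
    Y: np.ndarray
    I_max: float = 1.0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.shape != self.Y.shape:
            raise InvalidParameterError("image shapes must match")
        if self.I_max <= 0:
            raise InvalidParameterError("I_max must be positive")

    @classmethod
    def from_images(cls, X, Y, normalize: bool = True) -> "ImagePair":
        if normalize:
            return cls(normalize01(X), normalize01(Y), 1.0)
        return cls(X, Y, float(max(np.max(X), np.max(Y), 1e-12)))


@dataclass
class AdjacencyHistogram:
    """Empirical distribution of gray-level differences of adjacent pixels."""

    deltas: np.ndarray
    p: np.ndarray
    connectivity: int

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise InvalidParameterError("connectivity must be 4 or 8")


def michelson_contrast(image) -> float:
    """(I_max - I_min) / (I_max + I_min) of an image or region."""
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise InvalidParameterError("empty image")
    hi, lo = float(img.max()), float(img.min())
    if hi + lo == 0:
        raise UndefinedMetricError("max + min is zero: contrast undefined")
    return (hi - lo) / (hi + lo)


def local_contrast(sub_image) -> float:
    """Root-mean-square contrast of a sub-image containing a single spot."""
    img = np.asarray(sub_image, dtype=float)
    if img.size < 2:
        raise InvalidParameterError("need at least two pixels")
    return float(np.sqrt(np.mean((img - img.mean()) ** 2)))


def fringe_contrast(
    image,
    sideband_frequency: tuple[float, float],
    sideband_radius: int = 2,
) -> float:
    """Sideband-to-(DC+sideband) spectral energy ratio of a stripe image.

    ``sideband_frequency`` is (fy, fx) in cycles/pixel of the stripe pattern;
    energies are summed over disks of ``sideband_radius`` frequency bins
    around the +- pattern frequency, and the DC energy is the squared modulus
    of the zero-frequency bin.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    fy, fx = sideband_frequency
    if abs(fy) > 0.5 or abs(fx) > 0.5:
        raise InvalidParameterError("sideband frequency beyond Nyquist")
    ky, kx = fy * h, fx * w
    if np.hypot(ky, kx) <= sideband_radius:
        raise InvalidParameterError("sideband region overlaps the DC bin")
    F = np.fft.fft2(img)
    P = np.abs(F) ** 2
    e_dc = P[0, 0]
    iy = np.fft.fftfreq(h) * h
    ix = np.fft.fftfreq(w) * w
    e_side = 0.0
    for sy, sx in ((ky, kx), (-ky, -kx)):
        d = np.hypot(iy[:, None] - sy, ix[None, :] - sx)
        e_side += P[d <= sideband_radius].sum()
    return float(e_side / (e_dc + e_side))


def adjacency_histogram(
    image, connectivity: int = 4, n_gray_levels: int = 256
) -> AdjacencyHistogram:
    """Distribution of absolute gray differences between adjacent pixels.

    The image is min-max quantized to ``n_gray_levels`` integer levels;
    4-connectivity counts right and down neighbor pairs, 8-connectivity adds
    the two diagonals.
    """
    img = np.asarray(image, dtype=float)
    if img.size < 2:
        raise InvalidParameterError("image too small")
    lo, hi = img.min(), img.max()
    if hi == lo:
        q = np.zeros(img.shape, dtype=np.int64)
    else:
        q = np.round((img - lo) / (hi - lo) * (n_gray_levels - 1)).astype(np.int64)
    diffs = [np.abs(q[:, 1:] - q[:, :-1]).ravel(), np.abs(q[1:, :] - q[:-1, :]).ravel()]
    if connectivity == 8:
        diffs.append(np.abs(q[1:, 1:] - q[:-1, :-1]).ravel())
        diffs.append(np.abs(q[1:, :-1] - q[:-1, 1:]).ravel())
    elif connectivity != 4:
        raise InvalidParameterError("connectivity must be 4 or 8")
    d = np.concatenate(diffs)
    deltas, counts = np.unique(d, return_counts=True)
    return AdjacencyHistogram(
        deltas=deltas.astype(float), p=counts / d.size, connectivity=connectivity
    )


def contrast_ratio(image, connectivity: int = 4, n_gray_levels: int = 256) -> float:
    """Sum of squared adjacent-pixel gray differences weighted by probability."""
    hist = adjacency_histogram(image, connectivity, n_gray_levels)
    return float(np.sum(hist.deltas**2 * hist.p))


def psnr(pair: ImagePair) -> float:
    """Peak signal-to-noise ratio, dB; identical images cap at 99 dB.

    MSE is the mean squared difference (X - Y)^2.
    """
    mse = float(np.mean((pair.X - pair.Y) ** 2))
    if mse == 0:
        return PSNR_CAP_DB
    return float(min(10.0 * np.log10(pair.I_max**2 / mse), PSNR_CAP_DB))


def ssim(pair: ImagePair, windowed: bool = False, window: int = 7) -> float:
    """Structural similarity with global single-window statistics.

    SSIM = (2 mu_X mu_Y + C1)(2 sigma_XY + C2) /
           ((mu_X^2 + mu_Y^2 + C1)(sigma_X^2 + sigma_Y^2 + C2))
    with C1 = 0.01, C2 = 0.03.  ``windowed=True`` averages the same statistic
    over local uniform windows (an extension, not the default).
    """
    C1, C2 = 0.01, 0.03
    X, Y = pair.X, pair.Y
    if not windowed:
        mx, my = X.mean(), Y.mean()
        vx, vy = X.var(), Y.var()
        cov = ((X - mx) * (Y - my)).mean()
        return float(
            (2 * mx * my + C1)
            * (2 * cov + C2)
            / ((mx**2 + my**2 + C1) * (vx + vy + C2))
        )
    from scipy.ndimage import uniform_filter

    mx = uniform_filter(X, window)
    my = uniform_filter(Y, window)
    vx = uniform_filter(X**2, window) - mx**2
    vy = uniform_filter(Y**2, window) - my**2
    cov = uniform_filter(X * Y, window) - mx * my
    s = (
        (2 * mx * my + C1)
        * (2 * cov + C2)
        / ((mx**2 + my**2 + C1) * (vx + vy + C2))
    )
    return float(s.mean())


def rsf_degrade(
    sr_image, reference, sigma_bounds: tuple[float, float] = (1e-3, 20.0)
):
    """Degrade a super-resolution image to the reference resolution.

    Fits a Gaussian resolution scaling function of width sigma plus a linear
    intensity map (gain alpha, offset beta) minimizing the RMSE against the
    reference; alpha and beta are closed-form per sigma, sigma by bounded
    scalar optimization.  Returns (degraded image, sigma, alpha, beta).
    """
    sr = np.asarray(sr_image, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if sr.shape != ref.shape:
        raise InvalidParameterError("resample the SR image to the reference grid first")

    def fit_linear(blurred):
        x = blurred.ravel()
        y = ref.ravel()
        vx = x.var()
        if vx == 0:
            return 0.0, float(y.mean())
        alpha = float(np.cov(x, y, bias=True)[0, 1] / vx)
        beta = float(y.mean() - alpha * x.mean())
        return alpha, beta

    def cost(sigma):
        blurred = gaussian_filter(sr, sigma)
        alpha, beta = fit_linear(blurred)
        return float(np.sqrt(np.mean((alpha * blurred + beta - ref) ** 2)))

    res = minimize_scalar(cost, bounds=sigma_bounds, method="bounded")
    if not res.success:
        raise RuntimeError(f"RSF fit did not converge: {res}")
    sigma = float(res.x)
    # accept the no-blur solution when it is at least as good (identical pair)
    if cost(0.0) <= res.fun:
        sigma = 0.0
    blurred = gaussian_filter(sr, sigma)
    alpha, beta = fit_linear(blurred)
    return alpha * blurred + beta, sigma, alpha, beta


def r2_linearity(
    reference,
    degraded,
    n_points: int = 10_000,
    threshold_fraction: float = 0.05,
    seed: int = 0,
    textbook: bool = False,
) -> float:
    """Linear-correlation R^2 between a reference and an RSF-degraded image.

    Both images are offset-corrected by subtracting their own minima;
    ``n_points`` positions are sampled uniformly at random (seeded, without
    replacement when possible) and positions whose reference value falls
    below ``threshold_fraction`` of the reference maximum are discarded as
    background.
    """
    ref = np.asarray(reference, dtype=float).ravel()
    deg = np.asarray(degraded, dtype=float).ravel()
    if ref.shape != deg.shape:
        raise InvalidParameterError("image shapes must match")
    ref = ref - ref.min()
    deg = deg - deg.min()
    rng = np.random.default_rng(seed)
    if n_points < ref.size:
        idx = rng.choice(ref.size, size=n_points, replace=False)
    else:
        idx = np.arange(ref.size)
    keep = ref[idx] >= threshold_fraction * ref.max()
    idx = idx[keep]
    if idx.size < 10:
        raise UndefinedMetricError(
            f"fewer than 10 points survive the {threshold_fraction:.2f} threshold"
        )
    r, d = ref[idx], deg[idx]
    ss_res = np.sum((d - r) ** 2)
    denom = np.sum((r - r.mean()) ** 2) if textbook else np.sum((d - d.mean()) ** 2)
    if denom == 0:
        raise UndefinedMetricError("zero variance in the sampled points")
    return float(1.0 - ss_res / denom)


def rse_rsp(reference, degraded) -> tuple[float, float]:
    """Resolution-scaled error (RMSE) and Pearson coefficient of two images."""
    ref = np.asarray(reference, dtype=float).ravel()
    deg = np.asarray(degraded, dtype=float).ravel()
    if ref.shape != deg.shape:
        raise InvalidParameterError("image shapes must match")
    rse = float(np.sqrt(np.mean((ref - deg) ** 2)))
    if ref.std() == 0 or deg.std() == 0:
        raise UndefinedMetricError("zero-variance input: Pearson undefined")
    rsp = float(np.corrcoef(ref, deg)[0, 1])
    return rse, rsp
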