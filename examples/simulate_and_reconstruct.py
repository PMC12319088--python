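"""Simulate a multifocal bead acquisition and reconstruct it four ways.

Generates a sparse bead phantom, images it through the forward model with
matched Gaussian excitation/detection PSFs, then compares the widths of the
open-pinhole confocal reference, the central-element (closed-pinhole)
image, the adaptive pixel-reassignment superposition, and its
Richardson-Lucy-sharpened version.
"""

import numpy as np

from sdism import (
    OpticalConfig,
    bead_phantom,
    confocal_reference,
    estimate_lattice,
    multifocal_sequence,
    register_subimages,
    rl_deconvolve,
    sample_vda,
    simulate_stack,
    superpose,
)
from sdism.optics import gaussian_spot_fwhm

cfg = OpticalConfig(wavelength_ex=500.0, wavelength_em=500.0)
seq = multifocal_sequence(aperture=1, period=12, step=2, dmd_shape=(248, 248))
phantom = bead_phantom((1, 192, 192), (150.0, 65.0, 65.0), n_beads=8,
                       bead_diameter=80.0, min_separation=2000.0, seed=0)
stack = simulate_stack(phantom, seq, cfg, mode="wf", seed=1)
print(f"simulated {len(stack)} raw frames of {stack.frames.shape[1:]} px")

lattice = estimate_lattice(stack)
print(f"estimated lattice period: {np.linalg.norm(lattice.b1) * 65.0:.1f} nm "
      f"(design 648 nm)")

sset = sample_vda(stack, lattice)
registered = register_subimages(sset)
dpa = superpose(registered)
open_ref = confocal_reference(sset, "open")
small_ref = confocal_reference(sset, "small")
g = np.exp(-0.5 * ((np.arange(15) - 7) / 1.0) ** 2)
psf = np.outer(g, g)
sharp = rl_deconvolve(dpa, psf / psf.sum(), 15)

centers = np.array([[c[1], c[2]] for c in phantom.meta["centers_nm"]]) / 65.0 - 0.5
grid = [c for c in sset.to_grid(centers)
        if 7 < c[0] < dpa.image.shape[0] - 7 and 7 < c[1] < dpa.image.shape[1] - 7]

def mean_fwhm(img):
    return np.mean([gaussian_spot_fwhm(img, tuple(c), 5.0) for c in grid]) * sset.grid_pitch_nm

f_open = mean_fwhm(open_ref.image)
f_small = mean_fwhm(small_ref.image)
f_dpa = mean_fwhm(dpa.image)
f_sharp = mean_fwhm(sharp.image)
print(f"bead FWHM, open-pinhole confocal reference: {f_open:.0f} nm")
print(f"bead FWHM, closed-pinhole (central element): {f_small:.0f} nm")
print(f"bead FWHM, adaptive reassignment:            {f_dpa:.0f} nm "
      f"(open/reassigned = {f_open / f_dpa:.2f}, theory sqrt(2) = 1.41)")
print(f"bead FWHM, after Richardson-Lucy sharpening: {f_sharp:.0f} nm")
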