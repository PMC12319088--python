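# Methods

This note records the models, conventions and numerical choices behind
`sdism`, and what its synthetic studies do and do not demonstrate about real
data.

## Optical model

All PSFs are scalar 3D Gaussians: `sigma_xy = 0.21·λ/NA` laterally and
`sigma_z = 0.75·n·λ/NA²` axially.  A Gaussian keeps every width-based
readout closed-form and makes the ideal-reassignment limit analytically
checkable; the trade-off is that Airy rings, apodization and aberrations are
absent, so absolute resolution numbers are approximations and the package's
claims are about *ratios and orderings*, which are robust to the PSF family.
The axial structure is not separable: the per-plane energy follows the axial
Gaussian while the lateral width grows as
`sigma(z) = sigma_xy·sqrt(1 + (z/sigma_z)²)`.  Without this defocus spread a
separable Gaussian would image every depth equally sharply once per-plane
detection kernels are normalized, and widefield imaging would show no depth
dependence at all.

The confocal PSF is built per axial plane as
`h_conf = h_exc · (h_det ⊗₂D P)` with `P` a uniform pinhole disk whose
sample-plane diameter is the disk-plane diameter divided by the
magnification (500 nm for 50 µm at 100×).  The pinhole acts per plane
because every plane is conjugate to the pinhole plane in the model; pinhole
cross-talk between neighboring holes is captured only by the explicit
time-averaged disk mode (below).

Airy units are always computed at an explicitly passed wavelength
(`1.22·λ/NA`); nothing silently assumes the excitation or emission line.

## Forward simulation

The sample grid equals the camera grid (65 nm default).  DMD masks are
projected by an exact area-overlap operator, which handles the non-integer
54 nm : 65 nm pitch ratio without resampling artifacts; mask content (not a
resampling shift) encodes the commanded scan offsets, so the rendered
lattice phase is exact.  Detection is applied plane by plane:

- `wf` — each detection slice is normalized to unit 2D sum: every photon
  from every depth reaches the camera (no sectioning), which also makes the
  energy bookkeeping exact (frame sum = emitted sum).
- `sd_effective` — the confocal PSF's slices scaled so the focal-plane
  kernel has unit sum: in-focus light is fully transmitted, defocused light
  attenuated by the confocal axial envelope.  Fast, and used wherever an
  analytic sectioning model suffices.
- `sd_timeavg` — an explicit rotation-discretized sweep of a generated disk
  layout: the instantaneous rasterized pinhole map gates the excitation at
  the focal conjugate and multiplies the detected image, and frames average
  over steps.  This is the faithful joint excitation/detection modulation
  including neighbor-pinhole cross-talk; it converges to `sd_effective` as
  the pitch-to-diameter ratio grows (correlation > 0.99 at the design ratio
  of 5), which is the cross-validation between the two modes.

Noise is Poisson shot noise at a configurable photon gain plus Gaussian read
noise and a constant offset — an sCMOS abstraction.  Everything upstream of
noise is linear in the object.

## Lattice estimation

Frames are first stripped of their scan-direction DC component (the
per-pixel temporal mean).  Static background — out-of-focus haze, offsets —
is constant over the scan and lives entirely in that component, while the
stepped lattice does not; the spatial spectrum of the lattice itself is
untouched.  This reading of "DC along the scan direction" is deliberate: a
spatial DC removal would erase the lattice fundamentals being estimated.

The basis comes from the two lattice fundamentals of a *matched-filter*
spectrum: each frame's FFT is rotated by the phase of its commanded offset
before summation, so the moving lattice adds coherently while static object
structure cancels.  Peaks are sought on a ±10% ring around the design
frequency (the commanded geometry is a hard prior; the lattice model also
enforces ±5% at validation), refined by a local fine-grid DFT.  If the
refined frequency drifts more than 2% from the design value the scene lacks
the structure to constrain it (e.g. a single emitter) and the design
frequency is kept, flagged in the model metadata — the same fallback
philosophy as registration (below).  A detection threshold on the peak's
prominence over the ring's spectral floor turns featureless input into a
`LatticeNotFoundError`.

The absolute origin uses the complex value of the matched-filter fundamental:
`arg G(f_k) = −2π f_k·o`, the standard structured-illumination phase
readout, valid for any non-negative object.  It is then refined by the
average offset between basis-predicted lattice points and detected
intensity maxima (collected over all frames, mapped back by the commanded
offsets, matched within a quarter period, brightness-weighted).  Object
structure pulls individual maxima, but the pulls cancel over the symmetric
scan-phase grid.  Measured accuracy on dense noiseless scenes: basis well
under 0.1%, origin well under 0.05 px.

## VDA sampling, registration, superposition

For every frame and every lattice point (origin + integer basis combinations
+ commanded offset) the raw frame is interpolated (cubic spline by default,
bilinear optional) at the point plus `(u, v)·step` for `(u, v) ∈ {−2..2}²`,
and the values are rearranged into 25 sub-images on the scan grid — one
site per scan position, each written exactly once.  Sites whose sampling
neighborhood leaves the frame are masked, never extrapolated, so no
sub-image can contain more total intensity than the raw stack.

Coordinates are 0-based (y, x) pixels with the origin top-left.  Sub-image
shifts are *content translations* in scan-grid pixels: in the ideal
symmetric system the content of element `(u, v)` sits at `−(u, v)/2` grid
pixels relative to the central element, so the alignment translation is
`+(v, u)/2` — the classical half-offset reassignment expressed in the grid
whose pitch equals the scan step.  (Statements of the same rule as
"shift by −(u,v)·step/2" use the coordinate-remapping convention; the
operation is identical.)

Registration runs phase cross-correlation of each element against the
central one with DFT upsampling (default 100×, i.e. 0.01 px).  An element
whose normalized correlation peak falls below 0.05 — a very dim edge
element — falls back to the theoretical half-offset shift and is flagged in
the result's provenance.  Superposition is a weighted sum; `snr` weighting
uses weights proportional to sub-image total intensity (normalized so equal
intensities reduce exactly to uniform).  The fixed-scale baseline
(`pr_baseline`) applies `scale·(v, u)` with the classical `scale = 0.5`;
`scale = 0` degenerates to the plain sum, which equals the open-pinhole
confocal reference.  The closed-pinhole reference is the central element
alone (a ~0.2 AU pinhole); the open reference is the unshifted sum (~1 AU),
the comparator used by the fidelity metrics.

Richardson–Lucy deconvolution comes from scikit-image (`clip=False`), with
the input clipped to non-negative first (fraction recorded in provenance);
flux is conserved to well under 0.5% for content away from borders.
Max-1 normalization is applied only at export, never inside the pipeline.

One sampling caveat: the scan grid (108 nm) slightly undersamples the
reassigned spot (~125 nm FWHM at 500 nm/NA 1.49).  Width and position
readouts on reconstructions therefore use least-squares Gaussian fits over
the pixel samples around a known center (`gaussian_spot_fit`), which stay
unbiased under coarse sampling, rather than profile interpolation; profile
interpolation (`measure_fwhm`) is used where sampling is adequate (camera
frames, axial profiles).  The same aliasing adds a small *even* bias to
per-element registration shifts; the physical reassignment scale is the odd
(antisymmetric) component, which the tests extract by a least-squares fit
over all 24 off-center elements.

## Spinning-disk geometry

Sub-spiral `k` of an N-spiral disk follows `r(θ) = r_min + N·Δs·θ/2π`
starting at angle `2πk/N`; pinholes advance in equal arc-length steps `Δs`
(midpoint-refined integration), and sub-spirals are exact rotational copies
by construction.  Key relations: full-field coverage period `60/(rpm·N)`
seconds (12 ms at 5000 rpm for N = 1), valid exposures are its integer
multiples, and the radial scan-line spacing at radius `r` is
`N·Δs²/(2πr)` — the quantity that bounds N against the Nyquist requirement
and favors using the disk's outer annulus.  The coverage simulator
rasterizes antialiased hard-edged pinholes over a field rectangle at
discretized rotation steps (default step small enough that successive
footprints overlap by a quarter diameter) and reports the dose map and its
coefficient of variation; a decentered rotation axis is modeled by
displacing the pattern center.  Note that the N-spiral's interleaved point
set is *not* a point-for-point copy of the single spiral — at angle θ the
two radial combs differ in phase by up to Δs/2 — but the scan-line spacing
and the coverage uniformity over matched spans are the operative
equivalences, and those are what the tests check.

## DMD patterns and grating model

Multifocal masks raster row-major over the `(period/step)²` phase grid, the
order recorded in metadata so reconstruction never assumes it.  Uniform
total dose across a sequence requires the aperture to be a whole number of
steps (satisfied by the 4:12:2 design, where every mirror is ON in exactly
4 of 36 frames).  Stripe masks have half duty cycle; the two off-axis
orientations are digital lines of slope 2:1 (≈63.4°), a rational
approximation of ±60° on the square mirror grid, configurable.

The mirror array is modeled as a 1D blazed grating along the tilt diagonal
(`d_eff = pitch/√2`, tilt 12° by default, both configurable): exit angles
solve `sin β_m = mλ/d_eff − sin α`, the returned order is the one nearest
the single-mirror specular direction `2·tilt − α`, and the scalar efficiency
is the sinc² facet envelope normalized to 1 at blaze (the envelope samples a
unit partition, so summed efficiency over orders never exceeds 1).  The
model reproduces qualitative behavior (order selection, wavelength-dependent
exit angles, >80% blaze-adjacent efficiencies); exact published angle
triples depend on conventions (effective period, tilt sign, order rule) that
are configurable rather than guessed.

## Synthetic data

Phantoms are deterministic per seed: bead cubes (antialiased spheres,
rejection-sampled non-overlapping centers), persistent-random-walk filaments
with Gaussian cross-sections (a native generator, so no external dataset is
needed), point grids, and a two-layer scene (an in-focus point lattice over
a bright defocused plane) built to expose out-of-focus rejection.  Defaults
mirror the instrument: 65 nm lateral voxel, 150 nm axial step; the canonical
fixture is a 256×256×33-voxel bead cube with 36-frame stacks in widefield
and disk modes, chosen to keep a full simulate-plus-reconstruct cycle in the
tens of seconds on one core.  What passing tests on these phantoms show is
that the *pipeline* is correct under its stated model — matched Gaussian
optics, shift-invariant PSFs, Poisson/Gaussian noise; they do not certify
performance under real-tissue scattering, depth-dependent aberrations or
fluorophore photophysics, none of which are modeled.

## Study conditions behind the headline checks

- **√2 superposition gain** — matched excitation/detection wavelengths
  (500 nm, NA 1.49), single-mirror apertures (delta-like excitation) and
  80 nm beads, because the classical √2 statement assumes identical
  Gaussian excitation and detection PSFs; the 4-mirror aperture of the
  production mask widens the effective excitation and raises the measured
  ratio toward ~1.6.  Measured: 1.29–1.44 across seeds, mean ≈ 1.36.
- **Adaptive vs fixed-½ fidelity** — on ideal symmetric scenes the two
  agree (correlation > 0.99).  The fidelity gap is demonstrated by a
  controlled mis-registration experiment: a common displacement injected
  into every off-axis sub-image (a detection-path error) is recovered by
  registration but not by the fixed shift, and bead localization error is
  then strictly smaller for the adaptive method (~8 nm vs ~49 nm at a
  0.57-grid-px injection).  A raw Stokes-shift displacement in the forward
  model shifts origin estimation and both reconstructions alike, so it does
  not separate the methods cleanly.
- **Disk benefit** — lattice Michelson/RMS contrast on the two-layer scene,
  and the axial FWHM of the reconstructed bead response (558 nm widefield
  vs 335 nm disk mode at 500 nm), both as orderings, not absolute targets.

## Known limitations

Scalar Gaussian optics (no rings, no aberrations, no index mismatch);
per-plane pinhole filtering ignores inter-pinhole cross-talk except in the
explicit time-averaged mode; the grating model is scalar; reconstruction
operates per focal plane (z-stacks are reconstructed plane by plane); the
registration confidence measure is the normalized phase-correlation peak,
which is scale-free but can pass structured noise near the 0.05 threshold.
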