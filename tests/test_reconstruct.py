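import numpy as np
import pytest
from dataclasses import replace

from sdism import (
    OpticalConfig,
    SubImageSet,
    bead_phantom,
    confocal_reference,
    estimate_lattice,
    multifocal_sequence,
    pr_baseline,
    register_subimages,
    rl_deconvolve,
    run_dpa_pr,
    sample_vda,
    simulate_stack,
    superpose,
    suppress_scan_dc,
)
from sdism.metrics import r2_linearity, rsf_degrade
from sdism.optics import InvalidParameterError, gaussian_spot_fit, gaussian_spot_fwhm
from sdism.phantoms import Phantom3D
from sdism.reconstruct import (
    LatticeNotFoundError,
    ReconResult,
    _fourier_translate,
    theoretical_shifts,
)
from tests.conftest import SIZE, VOXEL, interior_grid_centers

PERIOD_PX = 12 * 54.0 / 65.0


class TestSuppressScanDc:
    def test_identical_frames_vanish(self):
        frames = np.broadcast_to(np.random.default_rng(0).random((32, 32)), (5, 32, 32))
        assert np.allclose(suppress_scan_dc(frames), 0.0)

    def test_temporal_mean_is_zero(self, uniform_stack):
        out = suppress_scan_dc(uniform_stack)
        assert np.allclose(out.mean(axis=0), 0.0, atol=1e-9)

    def test_single_frame_rejected(self):
        with pytest.raises(InvalidParameterError):
            suppress_scan_dc(np.ones((1, 16, 16)))

    def test_lattice_peak_snr_improves_with_background(self, uniform_stack):
        frames = uniform_stack.frames + 5.0 * uniform_stack.frames.mean()
        def peak_snr(stack3d):
            p = np.abs(np.fft.fft2(stack3d[0])) ** 2
            p[0, 0] = 0
            k = int(round(stack3d.shape[1] / PERIOD_PX))
            return p[0, k] / np.median(p[p > 0])
        assert peak_snr(suppress_scan_dc(frames)) > peak_snr(frames)


class TestEstimateLattice:
    def test_uniform_scene_recovers_design_lattice(self, uniform_stack):
        lat = estimate_lattice(uniform_stack)
        assert np.linalg.norm(lat.b1) == pytest.approx(PERIOD_PX, rel=0.005)
        assert np.linalg.norm(lat.b2) == pytest.approx(PERIOD_PX, rel=0.005)
        # ground truth: aperture centers at (k*period + 2) DMD px
        truth = (2 * 54.0) / 65.0 - 0.5
        err = (lat.origin - truth) % PERIOD_PX
        err = np.minimum(err, PERIOD_PX - err)
        assert np.all(err < 0.05)

    def test_transpose_equivariance(self, uniform_stack):
        lat = estimate_lattice(uniform_stack)
        swapped = replace(
            uniform_stack,
            frames=uniform_stack.frames.transpose(0, 2, 1).copy(),
            offsets_nm=[(oy, ox) for ox, oy in uniform_stack.offsets_nm],
            offsets_dmd_px=[(oy, ox) for ox, oy in uniform_stack.offsets_dmd_px],
        )
        lat_t = estimate_lattice(swapped)
        assert np.linalg.norm(lat_t.b1) == pytest.approx(np.linalg.norm(lat.b1), rel=1e-3)
        assert lat_t.origin[0] == pytest.approx(lat.origin[1], abs=0.05)
        assert lat_t.origin[1] == pytest.approx(lat.origin[0], abs=0.05)

    def test_featureless_stack_raises(self):
        frames = np.random.default_rng(0).normal(size=(36, 64, 64)) * 1e-12
        with pytest.raises((LatticeNotFoundError, InvalidParameterError)):
            estimate_lattice(frames, expected_period_px=PERIOD_PX)

    def test_nyquist_guard(self, uniform_stack):
        with pytest.raises(InvalidParameterError):
            estimate_lattice(uniform_stack, expected_period_px=1.5)


class TestSampleVda:
    def test_exactly_25_subimages(self, bead_subimages):
        _, sset, _ = bead_subimages
        assert sset.images.shape[:2] == (5, 5)
        assert sset.valid.shape == sset.images.shape

    def test_interior_sites_fully_valid_with_expected_counts(self, bead_subimages):
        _, sset, _ = bead_subimages
        n_cells = sset.meta["n_cells"]
        assert sset.valid[2, 2].sum() == n_cells * 36 / 36 * 36  # every site written once
        # grid dimensions are multiples of the 6-phase scan
        assert sset.images.shape[2] % 6 == 0
        assert sset.images.shape[3] % 6 == 0

    def test_central_element_dominates_on_lattice_point(self, cfg_matched, seq_point):
        # a bead placed exactly on a lattice point of frame 0
        c_grid = 1.0 * 9  # lattice index 9 along both axes
        c_px = (0.5 * 54.0) / 65.0 - 0.5 + c_grid * PERIOD_PX
        center_nm = ((c_px + 0.5) * 65.0,) * 2
        vol = np.zeros((1, SIZE, SIZE))
        ph = bead_phantom(
            (1, SIZE, SIZE), VOXEL, n_beads=0, seed=0
        )  # empty, then paint one bead at the lattice point
        from sdism.phantoms import _paint_sphere

        _paint_sphere(ph.values, (75.0, center_nm[0], center_nm[1]), 40.0, VOXEL, 65.0)
        stack = simulate_stack(ph, seq_point, cfg_matched, mode="wf", seed=0)
        lat = estimate_lattice(stack)
        sset = sample_vda(stack, lat)
        g = np.round(sset.to_grid(np.array([c_px, c_px]))).astype(int)
        vals = sset.images[:, :, g[0], g[1]]
        assert vals[2, 2] == vals.max()

    def test_masked_sites_never_invent_intensity(self, bead_scene, bead_subimages):
        _, _, stack = bead_scene
        _, sset, _ = bead_subimages
        for iv in range(5):
            for iu in range(5):
                assert sset.images[iv, iu].sum() <= stack.frames.sum()

    def test_bad_offset_table_rejected(self, bead_scene):
        _, _, stack = bead_scene
        lat = estimate_lattice(stack)
        bad = replace(stack, offsets_nm=stack.offsets_nm[:-1] + [stack.offsets_nm[0]])
        lat2 = replace(lat, per_frame_offsets=None)
        with pytest.raises(InvalidParameterError, match="phase grid"):
            sample_vda(bad, lat2)


def _synthetic_set(shifts_fn, shape=(64, 64)):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    ref = np.exp(-((yy - 30.2) ** 2 + (xx - 33.7) ** 2) / (2 * 3.0**2)) + 0.7 * np.exp(
        -((yy - 15) ** 2 + (xx - 50) ** 2) / (2 * 2.5**2)
    )
    imgs = np.stack(
        [
            [_fourier_translate(ref, shifts_fn(u - 2, v - 2)) for u in range(5)]
            for v in range(5)
        ]
    )
    return ref, SubImageSet(
        images=imgs,
        valid=np.ones_like(imgs, dtype=bool),
        grid_pitch_px=108.0 / 65.0,
        grid_pitch_nm=108.0,
        site00_yx=np.zeros(2),
    )


class TestRegistration:
    def test_identical_subimages_register_to_zero(self):
        _, sset = _synthetic_set(lambda u, v: (0.0, 0.0))
        reg = register_subimages(sset)
        assert np.abs(reg.shifts).max() < 1e-3

    def test_known_subpixel_shift_recovered_to_005px(self):
        t = (1.37, -0.81)
        _, sset = _synthetic_set(lambda u, v: t if (u, v) != (0, 0) else (0.0, 0.0))
        reg = register_subimages(sset, upsample_factor=100)
        # recorded shift undoes the injected content translation
        assert np.allclose(reg.shifts[0, 0], (-t[0], -t[1]), atol=0.05)

    def test_ideal_simulation_shifts_match_half_offset_theory(self, bead_subimages):
        # the antisymmetric (pairwise) component of the estimated shifts is
        # the physical reassignment scale; sub-Nyquist sampling of the scan
        # grid adds a small even bias that cancels between opposite elements
        _, _, reg = bead_subimages
        theo = theoretical_shifts()
        sym = 0.5 * (reg.shifts - reg.shifts[::-1, ::-1])
        # least-squares reassignment scale over all 24 off-center elements,
        # relative to the classical 1/2 (theo encodes shift = 0.5 * (v, u))
        num = float((sym * theo).sum())
        den = float((theo**2).sum())
        scale = 0.5 * num / den
        assert scale == pytest.approx(0.5, rel=0.10)
        # and no element strays far from the fitted linear law
        resid = np.linalg.norm(sym - (scale / 0.5) * theo, axis=-1)
        assert resid.max() < 0.1

    def test_dim_subimage_falls_back_to_theory(self):
        _, sset = _synthetic_set(lambda u, v: (0.0, 0.0))
        imgs = sset.images.copy()
        imgs[0, 0] = 0.0  # a fully dark edge element
        sset = replace(sset, images=imgs)
        reg = register_subimages(sset)
        assert (-2, -2) in reg.meta["registration_fallbacks"]
        assert np.allclose(reg.shifts[0, 0], theoretical_shifts()[0, 0])

    def test_empty_central_subimage_rejected(self):
        _, sset = _synthetic_set(lambda u, v: (0.0, 0.0))
        valid = sset.valid.copy()
        valid[2, 2] = False
        with pytest.raises(InvalidParameterError, match="valid sites"):
            register_subimages(replace(sset, valid=valid))


class TestSuperposition:
    def test_uniform_weighting_conserves_total_intensity(self, bead_subimages):
        _, sset, reg = bead_subimages
        result = superpose(reg)
        assert result.image.sum() == pytest.approx(sset.images.sum(), rel=1e-3)

    def test_snr_weighting_reduces_to_uniform_for_equal_subimages(self):
        _, sset = _synthetic_set(lambda u, v: (0.0, 0.0))
        reg = register_subimages(sset)
        a = superpose(reg, weighting="uniform")
        b = superpose(reg, weighting="snr")
        assert np.allclose(a.image, b.image, rtol=1e-6, atol=1e-9)

    def test_requires_registration(self, bead_subimages):
        _, sset, _ = bead_subimages
        with pytest.raises(InvalidParameterError):
            superpose(sset)

    def test_ideal_case_matches_fixed_half_baseline(self, bead_subimages):
        _, sset, reg = bead_subimages
        dpa = superpose(reg)
        pr = pr_baseline(sset)
        c = np.corrcoef(dpa.image.ravel(), pr.image.ravel())[0, 1]
        assert c > 0.99

    def test_zero_scale_baseline_is_plain_sum(self, bead_subimages):
        _, sset, _ = bead_subimages
        pr0 = pr_baseline(sset, scale=0.0)
        assert np.allclose(pr0.image, sset.images.sum(axis=(0, 1)))


class TestConfocalReferences:
    def test_open_reference_total_is_25x_mean_subimage(self, bead_subimages):
        _, sset, _ = bead_subimages
        open_ref = confocal_reference(sset, "open")
        assert open_ref.image.sum() == pytest.approx(
            25 * sset.images.sum(axis=(2, 3)).mean(), rel=1e-9
        )

    def test_small_pinhole_is_sharper_than_open(self, bead_subimages):
        centers, sset, _ = bead_subimages
        open_ref = confocal_reference(sset, "open").image
        small_ref = confocal_reference(sset, "small").image
        for c in interior_grid_centers(sset, centers)[:3]:
            assert gaussian_spot_fwhm(small_ref, tuple(c), 5.0) <= gaussian_spot_fwhm(
                open_ref, tuple(c), 5.0
            )

    def test_unknown_kind_rejected(self, bead_subimages):
        _, sset, _ = bead_subimages
        with pytest.raises(InvalidParameterError):
            confocal_reference(sset, "medium")


class TestRichardsonLucy:
    @pytest.fixture()
    def bead_image(self, bead_subimages):
        _, _, reg = bead_subimages
        return superpose(reg)

    def test_delta_psf_is_identity(self, bead_image):
        psf = np.zeros((11, 11))
        psf[5, 5] = 1.0
        out = rl_deconvolve(bead_image, psf, 5)
        assert np.allclose(out.image, np.clip(bead_image.image, 0, None))

    def test_flux_conserved_over_50_iterations(self, bead_image):
        g = np.exp(-0.5 * ((np.arange(15) - 7) / 1.2) ** 2)
        psf = np.outer(g, g)
        psf /= psf.sum()
        out = rl_deconvolve(bead_image, psf, 50)
        clipped = np.clip(bead_image.image, 0, None)
        assert out.image.sum() == pytest.approx(clipped.sum(), rel=0.005)

    def test_fwhm_shrinks_monotonically_with_iterations(self, bead_subimages, bead_image):
        centers, sset, _ = bead_subimages
        g = np.exp(-0.5 * ((np.arange(15) - 7) / 1.0) ** 2)
        psf = np.outer(g, g)
        psf /= psf.sum()
        c = interior_grid_centers(sset, centers)[0]
        widths = [
            gaussian_spot_fwhm(rl_deconvolve(bead_image, psf, n).image, tuple(c), 5.0)
            for n in (1, 10, 30)
        ]
        assert widths[0] > widths[1] > widths[2]

    def test_parameter_validation(self, bead_image):
        psf = np.ones((5, 5)) / 25.0
        with pytest.raises(InvalidParameterError):
            rl_deconvolve(bead_image, psf, 0)
        with pytest.raises(InvalidParameterError):
            rl_deconvolve(bead_image, np.ones((5, 5)), 5)


class TestRunDpaPr:
    def test_pipeline_completes_and_normalizes(self, bead_scene):
        _, _, stack = bead_scene
        result = run_dpa_pr(stack)
        assert result.method == "dpa_pr"
        assert result.provenance["n_subimages"] == 25
        normalized = result.image / result.image.max()
        assert normalized.max() == pytest.approx(1.0)

    def test_bit_identical_reruns(self, bead_scene):
        _, _, stack = bead_scene
        a = run_dpa_pr(stack)
        b = run_dpa_pr(stack)
        assert np.array_equal(a.image, b.image)
        assert a.provenance["input_sha256"] == b.provenance["input_sha256"]

    def test_fidelity_protocol_against_open_reference(self, bead_scene):
        _, _, stack = bead_scene
        result = run_dpa_pr(stack)
        lat = estimate_lattice(stack)
        sset = sample_vda(stack, lat)
        ref = confocal_reference(sset, "open").image
        degraded, sigma, _, _ = rsf_degrade(result.image, ref)
        assert r2_linearity(ref, degraded, n_points=5000, threshold_fraction=0.05, seed=0) > 0.9

    def test_stage_errors_carry_stage_names(self):
        cfg = OpticalConfig()
        frames = np.zeros((36, 64, 64))
        seq = multifocal_sequence(dmd_shape=(96, 96))
        ph = Phantom3D(values=np.zeros((1, 64, 64)), voxel=VOXEL, kind="empty")
        stack = simulate_stack(ph, seq, cfg, seed=0)
        with pytest.raises(RuntimeError, match="lattice estimation failed"):
            run_dpa_pr(stack)


class TestResolutionOrdering:
    def test_rl_sharpened_beats_plain_dpa_beats_open_confocal(self, bead_subimages):
        centers, sset, reg = bead_subimages
        dpa = superpose(reg)
        g = np.exp(-0.5 * ((np.arange(15) - 7) / 1.0) ** 2)
        psf = np.outer(g, g)
        psf /= psf.sum()
        sharp = rl_deconvolve(dpa, psf, 15)
        open_ref = confocal_reference(sset, "open")
        for c in interior_grid_centers(sset, centers)[:3]:
            f_sharp = gaussian_spot_fwhm(sharp.image, tuple(c), 5.0)
            f_dpa = gaussian_spot_fwhm(dpa.image, tuple(c), 5.0)
            f_open = gaussian_spot_fwhm(open_ref.image, tuple(c), 5.0)
            assert f_sharp < f_dpa < f_open
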