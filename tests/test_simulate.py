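import numpy as np
import pytest
from dataclasses import replace

from sdism import (
    OpticalConfig,
    add_noise,
    bead_phantom,
    build_disk,
    default_psfs,
    multifocal_sequence,
    render_illumination,
    simulate_stack,
    two_layer_phantom,
)
from sdism.metrics import local_contrast, michelson_contrast
from sdism.optics import InvalidParameterError, measure_fwhm
from sdism.phantoms import Phantom3D
from sdism.simulate import resample_mask
from sdism.reconstruct import _dft_at

VOXEL = (150.0, 65.0, 65.0)


@pytest.fixture(scope="module")
def cfg():
    return OpticalConfig(wavelength_ex=500.0, wavelength_em=500.0)


@pytest.fixture(scope="module")
def psfs_2d(cfg):
    return default_psfs(cfg, 1, VOXEL)


def one_mask_sequence(seq):
    return replace(seq, masks=seq.masks[:1], offsets=seq.offsets[:1])


class TestRenderIllumination:
    def test_all_on_mask_gives_uniform_field(self, cfg, psfs_2d):
        mask = np.ones((120, 120), dtype=np.uint8)
        field = render_illumination(mask, (0, 0), cfg, psfs_2d[0], np.array([0]), (96, 96))
        central = field.values[0, 24:72, 24:72]
        assert central.std() / central.mean() < 0.01

    def test_two_pixel_mask_shift_moves_peaks_108nm(self, cfg, psfs_2d):
        seq = multifocal_sequence(4, 12, 2, dmd_shape=(160, 160))
        shape = (96, 96)
        f0 = render_illumination(seq.masks[0], seq.offsets[0], cfg, psfs_2d[0], np.array([0]), shape)
        f1 = render_illumination(seq.masks[1], seq.offsets[1], cfg, psfs_2d[0], np.array([0]), shape)
        # windowed fundamental phase measures the pattern shift sub-pixel
        # (windowing removes the edge-truncation bias of the finite field)
        w = np.outer(np.hanning(96), np.hanning(96))
        f = np.array([0.0, 65.0 / (12 * 54.0)])  # cycles per camera px, x
        ph0 = np.angle(_dft_at(f0.values[0] * w, f))
        ph1 = np.angle(_dft_at(f1.values[0] * w, f))
        dx_px = (ph0 - ph1) / (2 * np.pi * f[1])
        dx_px = (dx_px + 6.0) % 12.0 - 6.0  # fold into one period
        assert dx_px * 65.0 == pytest.approx(108.0, abs=2.0)

    def test_single_aperture_spot_width_matches_convolution_oracle(self, cfg, psfs_2d):
        mask = np.zeros((120, 120), dtype=np.uint8)
        mask[40:44, 40:44] = 1  # one 4x4 aperture = 216 nm square
        field = render_illumination(mask, (0, 0), cfg, psfs_2d[0], np.array([0]), (96, 96))
        measured = measure_fwhm(field.values[0], axis=1, pixel_size=65.0)
        # oracle: 1D analytic convolution of a 216 nm box with the Gaussian
        from scipy.special import erf

        sigma = 0.21 * 500.0 / 1.49
        x = np.linspace(-600, 600, 4001)
        dx = x[1] - x[0]
        prof = erf((x + 108.0) / (np.sqrt(2) * sigma)) - erf((x - 108.0) / (np.sqrt(2) * sigma))
        # account for the 65 nm camera-cell averaging of the rendered grid
        box = np.ones(int(round(65.0 / dx)))
        prof = np.convolve(prof, box / box.size, mode="same")
        expected = measure_fwhm(prof, pixel_size=dx)
        assert measured == pytest.approx(expected, rel=0.05)

    def test_mask_too_small_errors_with_guidance(self, cfg, psfs_2d):
        with pytest.raises(InvalidParameterError, match="too small"):
            render_illumination(
                np.ones((40, 40), dtype=np.uint8), (0, 0), cfg, psfs_2d[0], np.array([0]), (96, 96)
            )

    def test_resample_conserves_first_moment(self, cfg):
        mask = np.zeros((120, 120))
        mask[50:54, 60:64] = 1
        field = resample_mask(mask, cfg, (96, 96))
        yy, xx = np.indices(field.shape)
        cx = (field * xx).sum() / field.sum()
        # aperture center: columns 60..64 DMD px -> 62*54 nm -> camera px
        assert (cx + 0.5) * 65.0 == pytest.approx(62 * 54.0, abs=1.0)


class TestSimulateStack:
    def test_impulse_response_is_detection_psf(self, cfg, psfs_2d):
        vol = np.zeros((1, 96, 96))
        vol[0, 48, 48] = 1.0
        ph = Phantom3D(values=vol, voxel=VOXEL, kind="point")
        seq = multifocal_sequence(6, 6, 6, dmd_shape=(120, 120))  # all-ON
        stack = simulate_stack(ph, seq, cfg, mode="wf", psfs=psfs_2d)
        frame = stack.frames[0]
        det = psfs_2d[1].values[0]
        patch = frame[48 - 16 : 48 + 17, 48 - 16 : 48 + 17]
        c = np.corrcoef(patch.ravel(), det.ravel())[0, 1]
        assert c > 0.999

    def test_linear_in_object_before_noise(self, cfg, psfs_2d):
        ph = bead_phantom((1, 64, 64), VOXEL, n_beads=3, bead_diameter=150.0, min_separation=700.0, seed=0)
        seq = one_mask_sequence(multifocal_sequence(dmd_shape=(96, 96)))
        s1 = simulate_stack(ph, seq, cfg, psfs=psfs_2d)
        ph2 = Phantom3D(values=2 * ph.values, voxel=VOXEL, kind="beads")
        s2 = simulate_stack(ph2, seq, cfg, psfs=psfs_2d)
        assert np.allclose(s2.frames, 2 * s1.frames)

    def test_energy_conserved_in_widefield(self, cfg, psfs_2d):
        # content well inside the frame: 2D convolution loses nothing
        vol = np.zeros((1, 96, 96))
        vol[0, 40:56, 40:56] = 1.0
        ph = Phantom3D(values=vol, voxel=VOXEL, kind="block")
        seq = one_mask_sequence(multifocal_sequence(dmd_shape=(140, 140)))
        stack = simulate_stack(ph, seq, cfg, psfs=psfs_2d)
        illum = resample_mask(seq.masks[0], cfg, (96, 96))
        from scipy.signal import fftconvolve

        exc = psfs_2d[0].values[0] / psfs_2d[0].values[0].sum()
        emitted = (vol[0] * fftconvolve(illum, exc, mode="same")).sum()
        assert stack.frames[0].sum() == pytest.approx(emitted, rel=1e-6)

    def test_sd_transmission_never_exceeds_widefield(self, cfg):
        ph = two_layer_phantom((9, 64, 64), VOXEL, background_intensity=2.0)
        seq = one_mask_sequence(multifocal_sequence(dmd_shape=(96, 96)))
        wf = simulate_stack(ph, seq, cfg, mode="wf", seed=0)
        sd = simulate_stack(ph, seq, cfg, mode="sd_effective", seed=0)
        assert sd.frames[0].sum() <= wf.frames[0].sum() * (1 + 1e-9)

    def test_frame_sum_cancels_the_lattice(self, cfg, psfs_2d):
        ph = Phantom3D(values=np.ones((1, 128, 128)), voxel=VOXEL, kind="uniform")
        seq = multifocal_sequence(4, 12, 2, dmd_shape=(168, 168))
        stack = simulate_stack(ph, seq, cfg, psfs=psfs_2d)
        total = stack.frames.sum(axis=0)
        central = total[32:96, 32:96]
        assert central.std() / central.mean() < 0.02

    def test_time_averaged_disk_converges_to_effective_model(self, cfg):
        layout = build_disk(12, 250.0, 50.0, 5000.0, 11000.0)
        seq = one_mask_sequence(multifocal_sequence(dmd_shape=(140, 140)))
        ph = bead_phantom(
            (1, 96, 96), VOXEL, n_beads=6, bead_diameter=150.0, min_separation=900.0, seed=5
        )
        f_eff = simulate_stack(ph, seq, cfg, mode="sd_effective", seed=0).frames[0]
        f_avg = simulate_stack(
            ph,
            seq,
            cfg,
            mode="sd_timeavg",
            seed=0,
            sd_options={"layout": layout, "fov_center_radius_um": 8000.0},
        ).frames[0]
        assert np.corrcoef(f_eff.ravel(), f_avg.ravel())[0, 1] > 0.99

    def test_two_layer_lattice_contrast_higher_with_disk(self, cfg):
        ph = two_layer_phantom(
            (9, 96, 96), VOXEL, lattice_period_nm=1296.0, background_intensity=3.0
        )
        seq = one_mask_sequence(multifocal_sequence(dmd_shape=(140, 140)))
        fr_wf = simulate_stack(ph, seq, cfg, mode="wf", seed=0).frames[0]
        fr_sd = simulate_stack(ph, seq, cfg, mode="sd_effective", seed=0).frames[0]
        region = np.s_[20:76, 20:76]
        assert michelson_contrast(fr_sd[region]) > michelson_contrast(fr_wf[region])
        assert local_contrast(fr_sd[region] / fr_sd[region].mean()) > local_contrast(
            fr_wf[region] / fr_wf[region].mean()
        )

    def test_focal_plane_outside_volume_errors(self, cfg, psfs_2d):
        ph = Phantom3D(values=np.ones((1, 64, 64)), voxel=VOXEL, kind="uniform")
        seq = one_mask_sequence(multifocal_sequence(dmd_shape=(96, 96)))
        with pytest.raises(InvalidParameterError, match="focal plane"):
            simulate_stack(ph, seq, cfg, focal_plane_index=3, psfs=psfs_2d)

    def test_frame_count_and_offsets_match_sequence(self, cfg, psfs_2d):
        ph = Phantom3D(values=np.ones((1, 96, 96)), voxel=VOXEL, kind="uniform")
        seq = multifocal_sequence(4, 12, 2, dmd_shape=(140, 140))
        stack = simulate_stack(ph, seq, cfg, psfs=psfs_2d)
        assert len(stack) == 36
        assert stack.offsets_nm[1] == (2 * 54.0, 0.0)
        assert stack.scan_step_px == pytest.approx(108.0 / 65.0)


class TestAddNoise:
    def test_mean_matches_expectation(self):
        frame = np.full((40, 40), 3.0)
        draws = np.stack(
            [add_noise(frame, 50.0, read_noise_sd=2.0, offset=100.0, seed=s) for s in range(100)]
        )
        expected = 50.0 * 3.0 + 100.0
        se = np.sqrt(50.0 * 3.0 + 4.0) / np.sqrt(100 * 1600)
        assert draws.mean() == pytest.approx(expected, abs=3 * se * 40)

    def test_relative_error_vanishes_in_shot_noise_limit(self):
        frame = np.full((64, 64), 1.0)
        out = add_noise(frame, 1e6, seed=0)
        rel = np.abs(out / 1e6 - 1.0)
        assert np.sqrt((rel**2).mean()) < 0.005

    def test_deterministic_per_seed(self):
        frame = np.random.default_rng(0).random((32, 32))
        assert np.array_equal(add_noise(frame, 100.0, 1.0, 10.0, seed=5),
                              add_noise(frame, 100.0, 1.0, 10.0, seed=5))

    def test_negative_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            add_noise(np.ones((4, 4)), -1.0)
        with pytest.raises(InvalidParameterError):
            add_noise(-np.ones((4, 4)), 10.0)
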