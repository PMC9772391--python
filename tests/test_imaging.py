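"""Fourier-optics image formation: conservation, weak-object response,
anisotropy, spectral handling and the Zernike reference path."""

import numpy as np
import pytest

from nlmscope import gmr, imaging, phantoms, retrieval
from nlmscope.transfer import TransferFunction


def _flat_tf(value=1.0, n_ang=4001, wavelengths=(630.0,)):
    angles = np.linspace(-89.9, 89.9, n_ang)
    t = np.full((len(wavelengths), n_ang), value, dtype=complex)
    return TransferFunction(list(wavelengths), angles, t)


def _smooth_blob(n=128, pitch=0.5, eps=0.3, sigma_um=6.0):
    """Band-limited pure-phase blob: spectrum negligible beyond the pupil."""
    y, x = np.mgrid[0:n, 0:n]
    r2 = ((x - n / 2) ** 2 + (y - n / 2) ** 2) * pitch**2
    return imaging.PhaseObject(eps * np.exp(-r2 / (2 * sigma_um**2)), pitch)


class TestFormImage:
    def test_flat_phase_gives_uniform_h0_squared(self, published_params):
        tf = gmr.sample_transfer_function(
            published_params, None, [630.0], np.linspace(-89.0, 89.0, 4001)
        )
        obj = imaging.PhaseObject(np.zeros((48, 48)), 0.1)
        img = imaging.form_image(obj, tf, imaging.ImagingConfig(630.0, 0.0, 1, 0.45))
        h0 = tf.at_wavelength(630.0)[tf.angles_deg.size // 2]
        assert np.allclose(img.intensity, abs(h0) ** 2, atol=1e-10)

    def test_parseval_open_pupil(self):
        # with H = 1 and NA = 1 a band-limited object passes unchanged
        obj = _smooth_blob(n=256, pitch=0.15)
        cfg = imaging.ImagingConfig(630.0, 0.0, 1, na=1.0, apodization="none")
        img = imaging.form_image(obj, _flat_tf(), cfg)
        total_in = np.sum(np.abs(obj.transmission) ** 2)
        assert np.sum(img.intensity) == pytest.approx(total_in, rel=1e-8)

    def test_weak_sinusoid_modulation_depth(self):
        # notch filter with H(0) = i*b, H(+-f0) = 1: intensity modulation 2*eps*b
        eps, b, f0 = 0.01, 0.2, 0.25  # cycles/um
        n, pitch = 512, 0.25
        x = np.arange(n) * pitch
        obj = imaging.PhaseObject(
            np.tile(eps * np.sin(2 * np.pi * f0 * x), (32, 1)), pitch
        )
        angles = np.linspace(-89.9, 89.9, 8001)
        fx = np.sin(np.deg2rad(angles)) / 0.63
        H = np.where(np.abs(fx) < f0 / 2, 1j * b, 1.0)
        tf = TransferFunction([630.0], angles, H[None, :])
        cfg = imaging.ImagingConfig(630.0, 0.0, 1, 0.45, pad_factor=1, apodization="none")
        img = imaging.form_image(obj, tf, cfg)
        profile = img.intensity[16]
        # I(x) = b^2 + 2*b*phi(x) to first order: sinusoid amplitude 2*eps*b
        depth = (profile.max() - profile.min()) / 2
        assert depth == pytest.approx(2 * eps * b, rel=0.02)

    def test_weak_object_linearity(self):
        def depth(eps):
            n, pitch, f0 = 512, 0.25, 0.25
            x = np.arange(n) * pitch
            obj = imaging.PhaseObject(
                np.tile(eps * np.sin(2 * np.pi * f0 * x), (16, 1)), pitch
            )
            angles = np.linspace(-89.9, 89.9, 8001)
            fx = np.sin(np.deg2rad(angles)) / 0.63
            H = np.where(np.abs(fx) < f0 / 2, 0.2j, 1.0)
            tf = TransferFunction([630.0], angles, H[None, :])
            cfg = imaging.ImagingConfig(630.0, 0.0, 1, 0.45, pad_factor=1,
                                        apodization="none")
            p = imaging.form_image(obj, tf, cfg).intensity[8]
            return p.max() - p.min()

        assert depth(0.02) / depth(0.01) == pytest.approx(2.0, rel=0.01)

    def test_filter_acts_along_one_axis_only(self, published_params, cfg_mono):
        # bars varying along the unfiltered axis produce almost no contrast
        tf = gmr.sample_transfer_function(
            published_params, None, [630.0], np.linspace(-89.0, 89.0, 6001)
        )
        # a phase step uniform along the filtered axis is invisible; the same
        # step across the filtered axis produces strong contrast (periodic
        # embedding keeps the rotated object exactly uniform along x)
        cfg = imaging.ImagingConfig(630.0, 0.0, 1, 0.45, pad_factor=1,
                                    apodization="none")
        obj = phantoms.make_edge_phantom(0.1 * np.pi, field_size_um=100.0)
        img_para = imaging.form_image(obj, tf, cfg)
        obj_rot = imaging.PhaseObject(obj.phase.T, obj.pitch_um)
        img_perp = imaging.form_image(obj_rot, tf, cfg)
        n = obj.phase.shape[0]
        feat = np.s_[n // 4 : 3 * n // 4, 3 * n // 4 :]
        bg = np.s_[n // 4 : 3 * n // 4, : n // 4]

        s_para = abs(img_para.intensity[feat].mean() / img_para.intensity[bg].mean() - 1.0)
        feat_r = np.s_[3 * n // 4 :, n // 4 : 3 * n // 4]
        bg_r = np.s_[: n // 4, n // 4 : 3 * n // 4]
        s_perp = abs(img_perp.intensity[feat_r].mean() / img_perp.intensity[bg_r].mean() - 1.0)
        assert s_perp < 0.05 * s_para

    def test_single_spectral_sample_equals_monochromatic(self, published_params):
        tf = gmr.sample_transfer_function(
            published_params, None, np.linspace(620, 640, 41), np.linspace(-89, 89, 2001)
        )
        obj = _smooth_blob(n=96, pitch=0.3)
        img_a = imaging.form_image(
            obj, tf, imaging.ImagingConfig(630.0, 0.0, 1, 0.45)
        )
        img_b = imaging.form_image(
            obj, tf, imaging.ImagingConfig(630.0, 6.0, 1, 0.45)
        )
        np.testing.assert_array_equal(img_a.intensity, img_b.intensity)

    def test_pitch_nyquist_guard(self):
        obj = imaging.PhaseObject(np.zeros((32, 32)), 0.5)
        with pytest.raises(ValueError, match="Nyquist|pitch"):
            imaging.form_image(obj, _flat_tf(), imaging.ImagingConfig(630.0, 0.0, 1, 0.45))

    def test_band_coverage_guard(self):
        angles = np.linspace(-5.0, 5.0, 501)  # far short of NA 0.45
        tf = TransferFunction([630.0], angles, np.ones((1, 501)))
        obj = imaging.PhaseObject(np.zeros((32, 32)), 0.1)
        with pytest.raises(ValueError, match="cycles/um"):
            imaging.form_image(obj, tf, imaging.ImagingConfig(630.0, 0.0, 1, 0.45))


class TestDetunedPair:
    def test_contrast_sign_flips(self, published_params, cfg_mono):
        from scipy.ndimage import binary_erosion

        obj = phantoms.make_bar_target([10.0], 0.2, phase_rad=0.1 * np.pi)
        lo, hi = imaging.detuned_image_pair(obj, published_params, cfg_mono, 3.0)
        bars = binary_erosion(obj.phase > 0.1, iterations=5)
        bg = binary_erosion(obj.phase < 0.1, iterations=5)
        s_lo = lo.intensity[bars].mean() - lo.intensity[bg].mean()
        s_hi = hi.intensity[bars].mean() - hi.intensity[bg].mean()
        assert np.sign(s_lo) == -np.sign(s_hi)

    def test_zero_detuning_dark_background(self, cfg_mono):
        from scipy.ndimage import binary_erosion

        params = gmr.published_resonance(t_min=0.0)  # exact zero on resonance
        obj = phantoms.make_bar_target([10.0], 0.2, phase_rad=0.1 * np.pi)
        a, b = imaging.detuned_image_pair(obj, params, cfg_mono, 0.0)
        bars = binary_erosion(obj.phase > 0.1, iterations=5)
        bg = binary_erosion(obj.phase < 0.1, iterations=5)
        for img in (a, b):
            assert img.intensity[bars].mean() > img.intensity[bg].mean()

    def test_contrast_decreases_with_detuning(self, published_params, cfg_mono):
        from scipy.ndimage import binary_erosion

        obj = phantoms.make_bar_target([10.0], 0.2, phase_rad=0.1 * np.pi)
        bars = binary_erosion(obj.phase > 0.1, iterations=5)
        bg = binary_erosion(obj.phase < 0.1, iterations=5)

        def strength(delta):
            lo, hi = imaging.detuned_image_pair(obj, published_params, cfg_mono, delta)
            return abs(
                lo.intensity[bars].mean() / lo.intensity[bg].mean() - 1.0
            )

        assert strength(3.0) > strength(10.0)


class TestZernikeReference:
    def test_identity_annulus_is_bright_field(self, cfg_mono):
        obj = _smooth_blob(n=96, pitch=0.3)
        ann = {"inner": 0.0, "outer": 0.1, "attenuation": 1.0, "phase_shift": 0.0}
        img_z = imaging.zernike_reference_image(obj, ann, cfg_mono)
        img_bf = imaging.form_image(obj, _flat_tf(), cfg_mono)
        np.testing.assert_allclose(img_z.intensity, img_bf.intensity, atol=1e-12)

    def test_narrow_annulus_linear_in_phase(self, cfg_mono):
        # pi/2-shifted background: intensity deviation linear in phi
        def signal(eps):
            obj = _smooth_blob(n=128, pitch=0.3, eps=eps, sigma_um=4.0)
            ann = {"inner": 0.0, "outer": 0.02, "attenuation": 0.5,
                   "phase_shift": np.pi / 2}
            img = imaging.zernike_reference_image(obj, ann, cfg_mono)
            centre = img.intensity[64, 64]
            corner = img.intensity[4, 4]
            return centre - corner

        assert signal(0.02) / signal(0.01) == pytest.approx(2.0, abs=0.1)

    def test_wide_annulus_shade_off(self, cfg_mono):
        # a wide filtered ring suppresses the interior of a large uniform
        # object toward the background level
        obj, _ = phantoms.make_disk_phantom(0.2 * np.pi, 40.0, pitch_um=0.25,
                                            field_size_um=120.0)
        narrow = {"inner": 0.0, "outer": 0.015, "attenuation": 0.5,
                  "phase_shift": np.pi / 2}
        wide = {"inner": 0.0, "outer": 0.06, "attenuation": 0.5,
                "phase_shift": np.pi / 2}
        img_n = imaging.zernike_reference_image(obj, narrow, cfg_mono)
        img_w = imaging.zernike_reference_image(obj, wide, cfg_mono)
        n = img_n.intensity.shape[0]
        bg_n = img_n.intensity[4, 4]
        bg_w = img_w.intensity[4, 4]
        dev_n = abs(img_n.intensity[n // 2, n // 2] - bg_n)
        dev_w = abs(img_w.intensity[n // 2, n // 2] - bg_w)
        assert dev_w < 0.7 * dev_n

    def test_invalid_annulus(self, cfg_mono):
        obj = _smooth_blob(n=64)
        with pytest.raises(ValueError):
            imaging.zernike_reference_image(
                obj, {"inner": 0.1, "outer": 0.05}, cfg_mono
            )


class TestUtilities:
    def test_ripple_period_on_synthetic_train(self):
        x = np.arange(0, 100, 0.2)
        profile = 0.1 + 0.01 * np.cos(2 * np.pi * x / 16.0) * np.exp(-x / 60.0)
        assert imaging.ripple_period(profile, 0.2) == pytest.approx(16.0, rel=0.05)

    def test_ripple_period_needs_two_peaks(self):
        with pytest.raises(ValueError):
            imaging.ripple_period(np.exp(-np.arange(100) / 30.0), 0.2)

    def test_poisson_noise_hook_is_seeded(self):
        img = imaging.IntensityImage(np.full((16, 16), 2.0), 0.2)
        a = img.with_poisson_noise(1000.0, seed=7)
        b = img.with_poisson_noise(1000.0, seed=7)
        c = img.with_poisson_noise(1000.0, seed=8)
        np.testing.assert_array_equal(a.intensity, b.intensity)
        assert not np.array_equal(a.intensity, c.intensity)

    def test_intensity_image_rejects_negative(self):
        with pytest.raises(ValueError):
            imaging.IntensityImage(np.full((4, 4), -1.0), 0.2)

    def test_spectral_samples_normalized(self):
        cfg = imaging.ImagingConfig(630.0, 6.0, 7, 0.45)
        lams, ws = zip(*cfg.spectral_samples())
        assert sum(ws) == pytest.approx(1.0)
        assert lams[0] == pytest.approx(630.0 - 9.0)
        assert lams[-1] == pytest.approx(630.0 + 9.0)
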