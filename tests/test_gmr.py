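"""Closed-form checks of the coupled-mode (Fano) filter model and the
transfer-function utilities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nlmscope import gmr
from nlmscope.transfer import TransferFunction

P0 = gmr.published_resonance(t_min=0.0)
P17 = gmr.published_resonance()  # t_min = 0.17
GAMMA = P0.gamma_nm


class TestFanoTransmission:
    def test_far_detuned_limit_is_unity(self):
        t = gmr.fano_transmission(630.0 + 50 * GAMMA, 0.0, P0)
        assert abs(t) == pytest.approx(1.0, abs=1e-3)
        assert np.angle(t) == pytest.approx(0.0, abs=0.02)

    def test_on_resonance_zero(self):
        assert gmr.fano_transmission(630.0, 0.0, P0) == 0.0

    def test_half_linewidth_point(self):
        # detuning = gamma/2 gives |t|^2 = 1/2 and phase -pi/4
        t = gmr.fano_transmission(630.0 + GAMMA / 2, 0.0, P0)
        assert abs(t) ** 2 == pytest.approx(0.5, abs=1e-12)
        assert np.angle(t) == pytest.approx(-np.pi / 4, abs=1e-12)

    def test_residual_is_in_quadrature(self):
        # 97% blocking floor transmits in phase quadrature with the background
        t = gmr.fano_transmission(630.0, 0.0, P17)
        assert abs(t) == pytest.approx(0.17, abs=1e-12)
        assert abs(abs(np.angle(t)) - np.pi / 2) < 0.05 * np.pi

    def test_branch_center_quadrature_off_axis(self):
        lam = 630.0 + 390.0 * np.sin(np.deg2rad(5.0))
        t = gmr.fano_transmission(lam, 5.0, P17)
        assert abs(t) == pytest.approx(0.17, rel=0.05)
        assert abs(abs(np.angle(t)) - np.pi / 2) < 0.05 * np.pi

    def test_theta_symmetry_exact(self):
        lam = np.linspace(600.0, 660.0, 31)[:, None]
        th = np.linspace(0.1, 60.0, 13)[None, :]
        np.testing.assert_array_equal(
            gmr.fano_transmission(lam, th, P17), gmr.fano_transmission(lam, -th, P17)
        )

    @given(
        lam=st.floats(580.0, 680.0),
        th=st.floats(-89.0, 89.0),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_energy_bound_lossless(self, lam, th):
        # strict passivity for t_min = 0 with unit background
        assert abs(gmr.fano_transmission(lam, th, P0)) <= 1.0 + 1e-9

    def test_energy_bound_with_slab_background(self):
        bg = gmr.published_slab_background()
        lam = np.linspace(580.0, 680.0, 401)[:, None]
        th = np.linspace(-60.0, 60.0, 121)[None, :]
        mag = np.abs(gmr.fano_transmission(lam, th, P0, bg=bg))
        assert mag.max() <= 1.0 + 1e-9
        # the phenomenological quadrature floor adds a bounded Fano wing
        mag17 = np.abs(gmr.fano_transmission(lam, th, P17, bg=bg))
        assert mag17.max() <= gmr.cmt_passivity_bound(P17)

    @pytest.mark.parametrize("t_min", [0.0, 0.05])
    def test_fwhm_matches_q(self, t_min):
        params = gmr.published_resonance(t_min=t_min)
        wl = np.linspace(580.0, 680.0, 8001)
        T = np.abs(gmr.fano_transmission(wl, 0.0, params)) ** 2
        fwhm = gmr.extract_fwhm(T, wl)
        assert fwhm / params.lambda0_nm == pytest.approx(1 / params.q_factor, rel=0.02)

    def test_rejects_nonphysical_inputs(self):
        with pytest.raises(ValueError):
            gmr.fano_transmission(np.nan, 0.0, P0)
        with pytest.raises(ValueError):
            gmr.fano_transmission(630.0, 90.0, P0)
        with pytest.raises(ValueError):
            gmr.ResonanceParams(630.0, 60.0, 390.0, t_min=1.0)
        with pytest.raises(ValueError):
            gmr.ResonanceParams(-630.0, 60.0, 390.0)


class TestSampleTransferFunction:
    def test_on_resonance_angular_dip_with_shoulders(self, published_params):
        tf = gmr.sample_transfer_function(
            published_params, None, [630.0], np.linspace(-10.0, 10.0, 2001)
        )
        T = np.abs(tf.t[0]) ** 2
        i0 = T.size // 2
        assert T[i0] == pytest.approx(0.17**2, rel=1e-6)
        assert T[0] > 0.95 and T[-1] > 0.95

    def test_branch_map_slope_is_grating_period(self):
        # upper-branch dips in the (lambda, theta) map follow lambda0 + p*sin(theta)
        th = np.linspace(2.0, 4.2, 12)
        wl = np.linspace(625.0, 660.0, 7001)
        tf = gmr.sample_transfer_function(P0, None, wl, th)
        sel = wl > 632.0
        upper = wl[sel][np.argmin(np.abs(tf.t[sel]), axis=0)]
        slope, intercept = np.polyfit(np.sin(np.deg2rad(th)), upper, 1)
        assert slope == pytest.approx(390.0, rel=0.02)
        assert intercept == pytest.approx(630.0, abs=0.5)

    def test_near_axis_phase_sign_flips_across_resonance(self, published_params):
        tf = gmr.sample_transfer_function(
            published_params, None, [627.0, 633.0], np.linspace(-30.0, 30.0, 601)
        )
        rel = []
        for row in tf.t:
            i0, i_out = row.size // 2, -1
            rel.append(np.angle(row[i0] * np.conj(row[i_out])))
        assert np.sign(rel[0]) != np.sign(rel[1])

    def test_empty_grid_rejected(self, published_params):
        with pytest.raises(ValueError):
            gmr.sample_transfer_function(published_params, None, [], [0.0])


class TestExtractFwhm:
    def test_lorentzian_dip_closed_form(self):
        gh = 2.5
        x = np.linspace(-60.0, 60.0, 4001)
        curve = 1.0 - 1.0 / (1.0 + (x / gh) ** 2)
        assert gmr.extract_fwhm(curve, x) == pytest.approx(2 * gh, rel=5e-3)

    def test_triangle_dip_interpolated_width(self):
        # piecewise-linear dip: half-depth crossings computed by hand
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 1.0, 0.0, 1.0, 1.0])
        assert gmr.extract_fwhm(y, x) == pytest.approx(1.0)

    def test_peak_flag(self):
        x = np.linspace(-80, 80, 6401)
        y = 1.0 / (1.0 + x**2)
        assert gmr.extract_fwhm(y, x, kind="peak") == pytest.approx(2.0, rel=5e-3)

    def test_truncated_feature_raises(self):
        x = np.linspace(0.0, 3.0, 31)
        y = 1.0 - 1.0 / (1.0 + x**2)  # dip centred at the window edge
        with pytest.raises(ValueError, match="truncated"):
            gmr.extract_fwhm(y, x)

    def test_multiple_features_raise(self):
        x = np.linspace(-20, 20, 801)
        y = 1.0 - np.exp(-((x - 8) ** 2)) - np.exp(-((x + 8) ** 2))
        with pytest.raises(ValueError, match="narrower window"):
            gmr.extract_fwhm(y, x)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            gmr.extract_fwhm([1, 0, 1], [0, 1, 2])


class TestSpatialKernel:
    def _flat_tf(self, n=201, max_deg=60.0):
        angles = np.linspace(-max_deg, max_deg, n)
        return TransferFunction([630.0], angles, np.ones((1, n)))

    def test_identity_filter_gives_delta(self):
        tf = self._flat_tf(n=2001)
        x, k = gmr.tf_to_spatial_kernel(tf, pitch_um=0.4, n_points=1024)
        i0 = np.argmax(np.abs(k))
        assert x[i0] == 0.0
        assert abs(k[i0]) == pytest.approx(1.0, abs=1e-9)
        assert np.abs(np.delete(k, i0)).max() < 1e-9

    def test_roundtrip_recovers_filter(self, published_params):
        angles = np.linspace(-65.0, 65.0, 20001)
        tf = gmr.sample_transfer_function(published_params, None, [630.0], angles)
        n = 4096
        _, k = gmr.tf_to_spatial_kernel(tf, pitch_um=0.4, n_points=n)
        H_back = np.fft.fft(np.fft.ifftshift(k))
        fx = np.fft.fftfreq(n, d=0.4)
        H_direct = tf.sample_on_fx(630.0, fx)
        assert np.abs(H_back - H_direct).max() < 1e-10

    def test_tophat_notch_ripple_spacing(self):
        # 1 minus a box notch of half-width sin(1 deg)/lambda: the kernel tail
        # is a sinc whose intensity maxima repeat every ~18 um
        n, pitch = 8192, 0.4
        angles = np.linspace(-65.0, 65.0, 40001)
        fx = np.sin(np.deg2rad(angles)) / 0.63
        notch = np.abs(fx) <= np.sin(np.deg2rad(1.0)) / 0.63
        tf = TransferFunction([630.0], angles, np.where(notch, 0.0, 1.0)[None, :])
        x, k = gmr.tf_to_spatial_kernel(tf, pitch_um=pitch, n_points=n)
        tail = np.abs(k[(x > 5.0) & (x < 120.0)]) ** 2
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(tail, prominence=tail.max() * 0.001)
        spacing = np.mean(np.diff(peaks)) * pitch
        assert spacing == pytest.approx(18.1, rel=0.1)

    def test_coarse_angle_grid_raises(self, published_params):
        tf = gmr.sample_transfer_function(
            published_params, None, [630.0], np.linspace(-60, 60, 41)
        )
        with pytest.raises(ValueError, match="too coarse"):
            gmr.tf_to_spatial_kernel(tf, pitch_um=0.4, n_points=4096)


class TestTransferFunctionContainer:
    def test_csv_roundtrip(self, tmp_path, published_params):
        tf = gmr.sample_transfer_function(
            published_params, None, np.linspace(625, 635, 5), np.linspace(-5, 5, 11)
        )
        path = tmp_path / "tf.csv"
        tf.to_csv(path)
        back = TransferFunction.from_csv(path)
        np.testing.assert_allclose(back.t, tf.t, atol=1e-12)

    def test_binary_roundtrip(self, tmp_path, published_params):
        tf = gmr.sample_transfer_function(
            published_params, None, np.linspace(625, 635, 5), np.linspace(-5, 5, 11)
        )
        path = tmp_path / "tf.bin"
        tf.to_binary(path)
        back = TransferFunction.from_binary(path)
        np.testing.assert_array_equal(back.t, tf.t)
        np.testing.assert_array_equal(back.angles_deg, tf.angles_deg)

    def test_validate_flags_gain(self):
        tf = TransferFunction([630.0], [0.0, 1.0], np.array([[1.0, 1.1]]))
        with pytest.raises(ValueError, match="bound"):
            tf.validate()

    def test_fx_mapping_is_exact_sine(self):
        tf = TransferFunction([630.0], [30.0, 60.0], np.ones((1, 2)))
        np.testing.assert_allclose(
            tf.fx_per_um(630.0), np.sin(np.deg2rad([30.0, 60.0])) / 0.63
        )
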