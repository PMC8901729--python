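"""Temperature model fits, PRF conversion, temporal filtering, ROI stats."""

import dataclasses

import numpy as np
import pytest

from radialtherm import (AcquisitionParams, FitConfig, build_trajectory,
                         golden_angle_sequence, image_domain_fit, kspace_fit,
                         make_scene, phase_to_temperature, roi_uncertainty,
                         run_series, temporal_filter)
from radialtherm.library import BaselineLibrary, polynomial_basis
from radialtherm.nufft import RadialDFT
from radialtherm.simulate import default_params, prf_rad_per_degC
from radialtherm.thermometry import TemperatureSeries


@pytest.fixture(scope="module")
def hot_setup():
    """Static single-channel scene with a 20 degC plateau hotspot."""
    scene = make_scene({"matrix": 48, "fov_mm": 96.0, "snr": 0,
                        "n_imaging_channels": 1,
                        "motion": {"kind": "static"},
                        "hotspot": {"t_start_s": 0.0, "t_stop_s": 10.0,
                                    "peak_degC": 20.0},
                        "drift_rad_per_s": 0.01})
    params = default_params(scene)
    gx, gy = scene.grids()
    phi0 = scene.background_phase_model.phase_map(gx, gy, 0.0)
    baseline = (scene.magnitude * scene.sensitivities[:, :, 0]
                * np.exp(1j * phi0))
    lib = BaselineLibrary(images=baseline[:, :, None][None, ...],
                          counts=np.array([100]),
                          spoke_indices=[np.arange(100)],
                          matrix_size=48, fov_mm=96.0)
    fit_mask = np.abs(baseline) > 0.005 * np.abs(baseline).max()
    basis = polynomial_basis(48, 6, fit_mask)
    t_frame = 20.0
    frame_img = (scene.magnitude * scene.sensitivities[:, :, 0]
                 * np.exp(1j * scene.object_phase(t_frame, params)))
    truth_theta = prf_rad_per_degC(params) * scene.delta_t_map(t_frame)
    interior = np.abs(baseline) > 0.2 * np.abs(baseline).max()
    return dict(scene=scene, params=params, lib=lib, basis=basis,
                frame_img=frame_img, truth_theta=truth_theta,
                interior=interior, baseline=baseline)


class TestPhaseToTemperature:
    def test_zero_phase_zero_temperature(self):
        params = AcquisitionParams()
        assert np.all(phase_to_temperature(np.zeros((4, 4)), params) == 0)

    def test_known_constant_product(self):
        # TE 20 ms, B0 1.5 T, gamma 42.577 MHz/T, alpha -0.01 ppm/degC:
        # -0.08026 rad corresponds to +1.000 degC
        params = AcquisitionParams()
        dt = phase_to_temperature(np.array(-0.0802558), params)
        assert dt == pytest.approx(1.000, abs=1e-3)

    def test_linearity(self):
        params = AcquisitionParams()
        th = np.array(-0.1)
        assert phase_to_temperature(2 * th, params) == \
            2 * phase_to_temperature(th, params)

    def test_zero_alpha_rejected(self):
        params = AcquisitionParams(prf_alpha_ppm_per_degC=0.0)
        with pytest.raises(ValueError, match="alpha"):
            phase_to_temperature(np.zeros(3), params)


class TestImageDomainFit:
    def test_identity_baseline(self, hot_setup):
        lib, basis = hot_setup["lib"], hot_setup["basis"]
        res = image_domain_fit(hot_setup["baseline"], lib, basis)
        assert res.w == pytest.approx([1.0], abs=1e-6)
        assert np.max(np.abs(res.theta)) < 1e-6
        assert np.max(np.abs(res.c)) < 1e-6

    def test_recovers_injected_hotspot_phase(self, hot_setup):
        res = image_domain_fit(hot_setup["frame_img"], hot_setup["lib"],
                               hot_setup["basis"], max_iter=60)
        err = np.abs(res.theta - hot_setup["truth_theta"])
        assert np.max(err[hot_setup["interior"]]) < 0.05

    def test_background_only_absorbed_by_polynomial(self, hot_setup):
        basis = hot_setup["basis"]
        gx, gy = hot_setup["scene"].grids()
        smooth = 0.2 * gx + 0.1 * gy * gy
        y = hot_setup["baseline"] * np.exp(1j * smooth)
        res = image_domain_fit(y, hot_setup["lib"], basis)
        assert np.max(np.abs(res.theta[hot_setup["interior"]])) < 0.02

    def test_all_zero_library_rejected(self, hot_setup):
        lib = dataclasses.replace(hot_setup["lib"],
                                  images=np.zeros_like(hot_setup["lib"].images))
        with pytest.raises(ValueError, match="zero"):
            image_domain_fit(hot_setup["frame_img"], lib, hot_setup["basis"])


class TestKspaceFit:
    def test_oracle_equivalence_at_full_sampling(self, hot_setup):
        """With lambda = beta = 0 on a fully sampled window the direct
        k-space fit matches the image-domain fit within 1e-2 rad."""
        params = hot_setup["params"]
        n_spokes = int(np.ceil(np.pi / 2 * 48)) + 1
        traj = build_trajectory(golden_angle_sequence(n_spokes), params, 48)
        y = RadialDFT(traj).forward(hot_setup["frame_img"])
        cfg = FitConfig(lambda_sparsity=0, beta_roughness=0,
                        enforce_sign=False, max_iter=120, tol=1e-6)
        res_k = kspace_fit(y, traj, hot_setup["lib"], hot_setup["basis"], cfg)
        res_i = image_domain_fit(hot_setup["frame_img"], hot_setup["lib"],
                                 hot_setup["basis"], max_iter=60)
        gap = np.abs(res_k.theta - res_i.theta)[hot_setup["interior"]]
        assert np.max(gap) < 1e-2

    def test_no_heating_window_theta_small_w_matches_bin(self, hot_setup):
        params = hot_setup["params"]
        traj = build_trajectory(golden_angle_sequence(40), params, 48)
        y = RadialDFT(traj).forward(hot_setup["baseline"])
        cfg = FitConfig(lambda_sparsity=0.5, beta_roughness=0.05)
        res = kspace_fit(y, traj, hot_setup["lib"], hot_setup["basis"], cfg)
        assert np.max(np.abs(res.theta)) < 0.05
        assert res.w == pytest.approx([1.0], abs=0.05)

    def test_undersampled_hotspot_recovery(self, hot_setup):
        """40-spoke window at the 3 mm-class regularization recovers the
        plateau peak within 10% on noiseless data."""
        params = hot_setup["params"]
        traj = build_trajectory(golden_angle_sequence(40), params, 48)
        y = RadialDFT(traj).forward(hot_setup["frame_img"])
        cfg = FitConfig(lambda_sparsity=0.2, beta_roughness=0.05)
        res = kspace_fit(y, traj, hot_setup["lib"], hot_setup["basis"], cfg)
        peak = phase_to_temperature(res.theta, params).max()
        assert peak == pytest.approx(20.0, rel=0.10)

    def test_all_zero_library_rejected(self, hot_setup):
        params = hot_setup["params"]
        traj = build_trajectory(golden_angle_sequence(4), params, 48)
        lib = dataclasses.replace(hot_setup["lib"],
                                  images=np.zeros_like(hot_setup["lib"].images))
        y = np.zeros((4, 96), complex)
        with pytest.raises(ValueError, match="zero"):
            kspace_fit(y, traj, lib, hot_setup["basis"], FitConfig())


class TestRunSeries:
    def test_frame_spacing_matches_printed_rates(self, phantom_run):
        from radialtherm import assign_bins_1d, build_library

        run = phantom_run
        nl = run["n_learning"]
        pair = np.repeat(np.arange(run["k"].n_spokes // 2), 2)
        drive = run["traces"]["filtered"].x_mm[pair[:nl]]
        labels = assign_bins_1d(drive, 10)
        from radialtherm.recon import truncate_readout
        k3 = truncate_readout(run["k_corr"], 3.0)
        lib = build_library(k3.subset(np.arange(nl)), labels, 32)
        basis = polynomial_basis(32, 6, lib.object_mask())
        for win, spacing in ((40, 0.9656), (20, 0.4828)):
            cfg = FitConfig(lambda_sparsity=0.5, beta_roughness=0.05,
                            window_spokes=win)
            ser = run_series(k3, lib, basis, cfg, start_spoke=nl,
                             max_frames=4)
            assert ser.frame_spacing_s == pytest.approx(spacing, abs=1e-4)
            assert round(ser.frame_spacing_s, 2) in (0.97, 0.48)

    def test_window_larger_than_data_stops_cleanly(self, phantom_run):
        from radialtherm import assign_bins_1d, build_library
        from radialtherm.recon import truncate_readout

        run = phantom_run
        k3 = truncate_readout(run["k_corr"], 3.0)
        lib = build_library(k3.subset(np.arange(200)),
                            np.zeros(200, int), 32)
        basis = polynomial_basis(32, 6, lib.object_mask())
        ser = run_series(k3, lib, basis, FitConfig(window_spokes=40),
                         start_spoke=k3.n_spokes - 10)
        assert ser.n_frames == 0


class TestTemporalFilter:
    @staticmethod
    def _series(values, spacing=0.97):
        n = len(values)
        maps = np.tile(np.asarray(values)[:, None, None], (1, 4, 4))
        return TemperatureSeries(times_s=np.arange(n) * spacing,
                                 theta=maps * -0.08, delta_t=maps,
                                 window_spokes=40, stride_spokes=40)

    def test_constant_series_unchanged(self):
        ser = self._series(np.full(40, 3.0))
        out = temporal_filter(ser, 0.14)
        assert np.allclose(out.delta_t, 3.0, atol=1e-9)

    def test_aliased_cardiac_contamination_attenuated(self):
        from scipy.signal import butter, freqz

        spacing = 0.9656
        fs = 1.0 / spacing
        alias = abs(0.825 - round(0.825 / fs) * fs)
        t = np.arange(120) * spacing
        contaminated = np.sin(2 * np.pi * 0.825 * t)
        out = temporal_filter(self._series(contaminated, spacing), 0.14)
        b, a = butter(4, 0.14, fs=fs)
        _, h = freqz(b, a, worN=[alias], fs=fs)
        expected_gain = np.abs(h[0]) ** 2  # forward-backward: squared
        mid = out.delta_t[30:-30, 0, 0]
        assert np.max(np.abs(mid)) < max(2.5 * expected_gain, 0.05)

    def test_step_response_no_excess_overshoot(self):
        step = np.concatenate([np.zeros(60), np.ones(60)])
        out = temporal_filter(self._series(step), 0.14)
        assert out.delta_t.max() < 1.15

    def test_cutoff_above_frame_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            temporal_filter(self._series(np.zeros(30)), 1.0)


class TestRoiUncertainty:
    @staticmethod
    def _series(stack, spacing=0.97):
        return TemperatureSeries(times_s=np.arange(len(stack)) * spacing,
                                 theta=stack * -0.08, delta_t=stack,
                                 window_spokes=40, stride_spokes=40)

    def test_constant_series_zero_uncertainty(self):
        ser = self._series(np.ones((30, 8, 8)))
        roi = np.ones((8, 8), bool)
        stats = roi_uncertainty(ser, roi, 2.0, 25.0)
        assert stats.mean_degC == 0.0 and stats.sd_degC == 0.0

    def test_iid_gaussian_matches_sample_sd_distribution(self):
        rng = np.random.default_rng(0)
        s = 0.8
        stack = s * rng.standard_normal((200, 10, 10))
        ser = self._series(stack)
        stats = roi_uncertainty(ser, np.ones((10, 10), bool), 10.0, 180.0)
        # E[sample SD] for chi distribution with n ~ 175 is ~ s
        assert stats.mean_degC == pytest.approx(s, rel=0.05)

    def test_empty_span_rejected(self):
        ser = self._series(np.ones((30, 4, 4)))
        with pytest.raises(ValueError, match="frames"):
            roi_uncertainty(ser, np.ones((4, 4), bool), 25.0, 26.0)
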