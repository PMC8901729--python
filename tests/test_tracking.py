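"""Micro-coil localization, motion filtering and projection gating."""

import dataclasses

import numpy as np
import pytest

from radialtherm import (MotionModel, coil_profile, decompose_motion,
                         gaussian_lowpass, localize_pair, make_scene,
                         simulate_acquisition, smooth_and_locate, track)
from radialtherm.simulate import default_params
from radialtherm.tracking import (MotionTrace, backprojection_map,
                                  debias_positions, select_projections)


def _gauss_gain(f, fc):
    sigma_f = fc / np.sqrt(np.log(2.0))
    return np.exp(-f ** 2 / (2 * sigma_f ** 2))


class TestCoilProfile:
    def test_pure_exponential_gives_single_pixel_peak(self):
        r, matrix, fov = 96, 48, 96.0
        radii = (np.arange(r) - r // 2) * (matrix / r)
        pos_mm = 12.0
        spoke = np.exp(-2j * np.pi * radii * pos_mm / fov)
        prof = coil_profile(spoke, 0.0, fov, matrix)
        peak_idx = np.argmax(prof.magnitude)
        assert prof.positions_mm[peak_idx] == pytest.approx(pos_mm, abs=1.0)

    def test_simulated_coil_peak_matches_projection_geometry(
            self, static_scene, static_params):
        k = simulate_acquisition(static_scene, static_params, 2)
        x0, y0 = static_scene.microcoil_positions[0]
        for s in range(2):
            prof = coil_profile(k.data[s, :, 4], k.angles_deg[s],
                                static_params.fov_mm,
                                static_params.matrix_size)
            pos, _ = smooth_and_locate(prof)
            rho = np.deg2rad(k.angles_deg[s] % 360)
            expect = x0 * np.cos(rho) + y0 * np.sin(rho)
            assert pos == pytest.approx(expect, abs=0.5 * 2.0)  # half a pixel

    def test_zero_spoke_flagged_invalid(self):
        prof = coil_profile(np.zeros(64, complex), 0.0, 96.0, 32)
        pos, inten = smooth_and_locate(prof)
        assert not prof.valid
        assert np.isnan(pos) and inten == 0.0


class TestSmoothAndLocate:
    def test_split_peak_barycenter_at_midpoint(self):
        # brute-force oracle: weighted mean over the above-half-max support
        mag = np.zeros(64)
        mag[30] = 1.0
        mag[32] = 1.0
        positions = np.arange(64) - 32.0
        prof = dataclasses.replace(
            coil_profile(np.ones(64, complex), 0.0, 64.0, 32),
            magnitude=mag, positions_mm=positions)
        pos, _ = smooth_and_locate(prof, sigma_px=2.0)
        assert pos == pytest.approx(-1.0, abs=0.05)

    def test_delta_located_exactly(self):
        mag = np.zeros(64)
        mag[40] = 3.0
        positions = np.arange(64) - 32.0
        prof = dataclasses.replace(
            coil_profile(np.ones(64, complex), 0.0, 64.0, 32),
            magnitude=mag, positions_mm=positions)
        pos, inten = smooth_and_locate(prof, sigma_px=1.5)
        assert pos == pytest.approx(8.0, abs=1e-9)


class TestLocalizePair:
    def test_orthogonal_pair_is_identity(self):
        assert localize_pair(3.0, -4.0, 0.0, 90.0) == pytest.approx((3.0, -4.0))

    def test_center_coil_for_any_angles(self):
        for a1, a2 in ((10.0, 121.25), (45.0, 156.25)):
            x, y = localize_pair(0.0, 0.0, a1, a2)
            assert abs(x) < 1e-12 and abs(y) < 1e-12

    def test_forward_project_then_solve_round_trips(self):
        x0, y0 = 10.0, -5.0
        r1, r2 = np.deg2rad(0.0), np.deg2rad(111.25)
        p1 = x0 * np.cos(r1) + y0 * np.sin(r1)
        p2 = x0 * np.cos(r2) + y0 * np.sin(r2)
        x, y = localize_pair(p1, p2, 0.0, 111.25)
        assert x == pytest.approx(x0, abs=1e-9)
        assert y == pytest.approx(y0, abs=1e-9)

    def test_near_parallel_rejected(self):
        assert localize_pair(1.0, 1.0, 10.0, 12.0) is None

    def test_backprojection_map_argmax_agrees(self, static_scene,
                                              static_params):
        k = simulate_acquisition(static_scene, static_params, 2)
        profs = [coil_profile(k.data[s, :, 4], k.angles_deg[s],
                              static_params.fov_mm, static_params.matrix_size)
                 for s in range(2)]
        ps = [smooth_and_locate(p)[0] for p in profs]
        alg = localize_pair(ps[0], ps[1], k.angles_deg[0], k.angles_deg[1])
        bp = backprojection_map(profs[0], profs[1], 48, 96.0)
        iy, ix = np.unravel_index(np.argmax(bp), bp.shape)
        px = 96.0 / 48
        assert abs((ix - 24) * px - alg[0]) <= px
        assert abs((iy - 24) * px - alg[1]) <= px


class TestGaussianLowpass:
    def test_constant_unchanged(self):
        out = gaussian_lowpass(np.full(500, 2.5), 0.883, 20.0)
        assert np.allclose(out, 2.5, atol=1e-9)

    @pytest.mark.parametrize("fc", [0.377, 0.883])
    def test_minus_3db_at_cutoff(self, fc):
        fs = 1.0 / (2 * 0.02414)
        t = np.arange(0, 80, 1 / fs)
        sig = np.sin(2 * np.pi * fc * t)
        out = gaussian_lowpass(sig, fc, fs)
        mid = out[len(out) // 4: -len(out) // 4]
        assert np.max(np.abs(mid)) == pytest.approx(1 / np.sqrt(2), rel=0.02)

    def test_4x_cutoff_strongly_attenuated(self):
        fs = 20.0
        t = np.arange(0, 60, 1 / fs)
        out = gaussian_lowpass(np.sin(2 * np.pi * 4 * 0.883 * t), 0.883, fs)
        assert np.max(np.abs(out[100:-100])) < 0.05

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            gaussian_lowpass(np.zeros(10), 11.0, 20.0)


class TestDecompose:
    @staticmethod
    def _trace(sig_x, fs=20.71):
        n = len(sig_x)
        t = np.arange(n) / fs
        return MotionTrace(t, sig_x, np.zeros(n), np.zeros(n))

    def test_pure_resp_frequency_lands_in_respiratory(self):
        fs = 1.0 / (2 * 0.02414)
        t = np.arange(0, 60, 1 / fs)
        tr = self._trace(np.sin(2 * np.pi * 0.25 * t), fs)
        out = decompose_motion(tr)
        mid = slice(len(t) // 4, -len(t) // 4)
        resp_amp = np.max(np.abs(out["respiratory"].x_mm[mid]))
        card_amp = np.max(np.abs(out["cardiac"].x_mm[mid]))
        # closed-form Gaussian gains at 0.25 Hz
        assert resp_amp == pytest.approx(_gauss_gain(0.25, 0.377), rel=0.03)
        assert card_amp == pytest.approx(
            _gauss_gain(0.25, 0.883) - _gauss_gain(0.25, 0.377), rel=0.10)

    def test_cardiac_frequency_lands_in_cardiac(self):
        fs = 1.0 / (2 * 0.02414)
        t = np.arange(0, 60, 1 / fs)
        tr = self._trace(np.sin(2 * np.pi * 0.825 * t), fs)
        out = decompose_motion(tr)
        mid = slice(len(t) // 4, -len(t) // 4)
        expected = _gauss_gain(0.825, 0.883) - _gauss_gain(0.825, 0.377)
        assert np.max(np.abs(out["cardiac"].x_mm[mid])) == pytest.approx(
            expected, rel=0.05)

    def test_zero_trace_stays_zero(self):
        out = decompose_motion(self._trace(np.zeros(400)))
        for v in out.values():
            assert np.allclose(v.x_mm, 0) and np.allclose(v.y_mm, 0)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal(500), rng.standard_normal(500)
        da = decompose_motion(self._trace(a))
        db = decompose_motion(self._trace(b))
        dab = decompose_motion(self._trace(a + b))
        for key in ("filtered", "respiratory", "cardiac"):
            assert np.allclose(dab[key].x_mm, da[key].x_mm + db[key].x_mm,
                               atol=1e-9)

    def test_variants_mean_centered(self, phantom_run):
        for key in ("filtered", "respiratory", "cardiac"):
            tr = phantom_run["traces"][key]
            assert abs(tr.x_mm.mean()) < 1e-6
            assert abs(tr.y_mm.mean()) < 1e-6


class TestDebias:
    def test_injected_angle_bias_removed(self):
        rng = np.random.default_rng(1)
        n = 1000
        angles = np.arange(n) * 111.246
        rho = np.deg2rad(angles % 360)
        bias = 0.5 * np.sin(2 * rho + 0.3)
        x = 3.0 + bias + 0.01 * rng.standard_normal(n)
        tr = MotionTrace(np.arange(n) * 0.05, x, np.zeros(n), np.zeros(n))
        out = debias_positions(tr, angles)
        resid = out.x_mm - 3.0
        # residual angle-dependent amplitude < 0.05 mm
        assert np.percentile(np.abs(resid - resid.mean()), 95) < 0.05

    def test_bias_free_trace_unchanged_within_fit_tolerance(self):
        n = 800
        angles = np.arange(n) * 111.246
        x = np.full(n, 2.0)
        tr = MotionTrace(np.arange(n) * 0.05, x, x.copy(), np.zeros(n))
        out = debias_positions(tr, angles)
        assert np.allclose(out.x_mm, 2.0, atol=1e-9)

    def test_insufficient_coverage_warns_and_passes_through(self):
        tr = MotionTrace(np.arange(5) * 0.05, np.ones(5), np.ones(5),
                         np.zeros(5))
        with pytest.warns(UserWarning, match="coverage"):
            out = debias_positions(tr, np.arange(5) * 1.0)
        assert np.array_equal(out.x_mm, tr.x_mm)


class TestTrack:
    def test_square_wave_levels_26mm_apart(self, phantom_run):
        x = phantom_run["traces"]["raw"].x_mm
        hi = np.median(x[x > x.mean()])
        lo = np.median(x[x < x.mean()])
        assert hi - lo == pytest.approx(26.0, abs=0.5)

    def test_noiseless_center_coil_sd_below_1e6_mm(self):
        scene = make_scene({"matrix": 48, "fov_mm": 96.0, "snr": 0,
                            "motion": {"kind": "static"},
                            "microcoil_positions_mm": [(0.0, 0.0), (0.0, 0.0)],
                            "hotspot": {"t_start_s": 500, "t_stop_s": 600}})
        params = default_params(scene)
        k = simulate_acquisition(scene, params, 200)
        tr = track(k)["raw"]
        assert tr.x_mm.std() < 1e-6
        assert tr.y_mm.std() < 1e-6

    def test_noisy_static_coil_sd_below_0p3_px(self, noisy_static_run):
        scene, params, k = noisy_static_run
        tr = track(k)["raw"]
        px = params.fov_mm / params.matrix_size
        assert tr.x_mm.std() / px <= 0.3
        assert tr.y_mm.std() / px <= 0.3

    def test_translation_equivariance(self, static_params):
        """Rigidly translating the scene shifts the tracked mean position."""
        base = {"matrix": 48, "fov_mm": 96.0, "snr": 0,
                "motion": {"kind": "static"},
                "hotspot": {"t_start_s": 500, "t_stop_s": 600}}
        a, b = 6.0, -4.5
        s0 = make_scene(base)
        s1 = make_scene({**base, "microcoil_positions_mm":
                         [(x + a, y + b) for x, y in s0.microcoil_positions]})
        k0 = simulate_acquisition(s0, static_params, 120)
        k1 = simulate_acquisition(s1, static_params, 120)
        t0m = track(k0)["raw"]
        t1m = track(k1)["raw"]
        px = 96.0 / 48
        assert t1m.x_mm.mean() - t0m.x_mm.mean() == pytest.approx(a, abs=px / 2)
        assert t1m.y_mm.mean() - t0m.y_mm.mean() == pytest.approx(b, abs=px / 2)

    def test_missing_microcoil_channels_rejected(self, phantom_run):
        k = phantom_run["k"]
        imaging_only = k.replace_data(k.data[:, :, k.imaging_idx],
                                      ["imaging"] * len(k.imaging_idx))
        with pytest.raises(ValueError, match="micro-coil"):
            track(imaging_only)


class TestSelectProjections:
    @staticmethod
    def _ztrace(z, fs=20.0):
        n = len(z)
        return MotionTrace(np.arange(n) / fs, np.zeros(n), np.zeros(n), z)

    def test_keep_fraction_one_keeps_all(self):
        mask = select_projections(self._ztrace(np.random.default_rng(0)
                                               .standard_normal(100)), 1.0)
        assert mask.all() and len(mask) == 200

    def test_constant_z_keeps_earliest_on_ties(self):
        mask = select_projections(self._ztrace(np.ones(100)), 0.7)
        pair_mask = mask[::2]
        assert pair_mask.sum() == 70
        assert pair_mask[:70].all()

    def test_discards_steep_flanks_of_z_cycle(self):
        fs = 20.0
        t = np.arange(0, 30, 1 / fs)
        z = np.sin(2 * np.pi * 0.825 * t)
        mask = select_projections(self._ztrace(z, fs), 0.70)
        pair_mask = mask[::2]
        dz = np.abs(np.gradient(z, t))
        # discarded samples concentrate where |dz/dt| is large
        assert dz[~pair_mask].mean() > 1.5 * dz[pair_mask].mean()

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError, match="keep_fraction"):
            select_projections(self._ztrace(np.ones(10)), 0.0)
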