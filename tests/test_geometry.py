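"""Surface detection, alignment, angle estimation, compensation, warping."""

import dataclasses
import math

import numpy as np
import pytest

from corrdop import (AcquisitionParams, DopplerConfig, PhantomSpec,
                     align_to_surface, backshift, compensate, detect_surface,
                     estimate_angles, make_pulse, reject_outliers,
                     simulate_rotational_scan, to_polar)
from corrdop import pipeline
from corrdop.preprocess import envelope, noise_floor
from corrdop.types import SurfaceProfile, VelocityMap


def _profile(arrival, valid=None):
    arrival = np.asarray(arrival, dtype=float)
    valid = np.ones(arrival.shape, bool) if valid is None else np.asarray(valid)
    return SurfaceProfile(arrival=arrival, valid=valid)


class TestDetectSurface:
    def _frame_with_echo(self, center, n=2000, m=3, amp=100.0, sigma=1.0, seed=0):
        rng = np.random.default_rng(seed)
        frame = rng.normal(0.0, sigma, (n, m))
        pulse = make_pulse(15e6, 1.15, 180e6) * amp
        k = len(pulse) // 2
        for j in range(m):
            frame[center - k:center + k + 1, j] += pulse
        return frame

    def test_echo_crossing_matches_threshold_oracle(self, params, cfg):
        center = 800
        frame = self._frame_with_echo(center)
        prof = detect_surface(frame, params, cfg)
        assert prof.valid.all()
        # independent oracle: first index where the trailing 31-sample mean
        # envelope crosses floor * 10^(10/20)
        env = envelope(frame)
        thr = noise_floor(frame, (0, 200)) * 10 ** (cfg.toa_threshold_db / 20)
        for j in range(frame.shape[1]):
            sm = np.convolve(env[:, j], np.ones(31) / 31)[:frame.shape[0]]
            oracle = int(np.argmax(sm >= thr))
            assert prof.arrival[j] == oracle
        # the crossing sits on the echo rise, never before the onset
        onset = center - len(make_pulse(15e6, 1.15, 180e6)) // 2
        assert np.all(prof.arrival >= onset)
        assert np.all(prof.arrival <= center)

    def test_all_noise_line_is_invalid(self, params, cfg):
        rng = np.random.default_rng(1)
        frame = rng.normal(size=(1500, 4))
        frame[:, :3] = self._frame_with_echo(700, n=1500, m=3)
        with pytest.warns(UserWarning):
            # 1 of 4 invalid -> no warning; make 3 of 4 noise to trigger it
            noisy = rng.normal(size=(1500, 4))
            noisy[:, 0] = frame[:, 0]
            prof = detect_surface(noisy, params, cfg)
        assert prof.valid[0]
        assert not prof.valid[1:].any()

    def test_constant_radius_lumen_profile_is_flat(self, lumen_scan, rparams, cfg):
        prof = detect_surface(lumen_scan.us, rparams, cfg)
        arr = prof.arrival[prof.valid]
        med = np.median(arr)
        assert np.mean(np.abs(arr - med) <= 2) > 0.98


class TestRejectOutliers:
    def test_smooth_profile_unchanged(self, rparams):
        arr = 500 + 10 * np.sin(np.linspace(0, 2 * np.pi, 100, endpoint=False))
        out = reject_outliers(_profile(arr), rparams)
        np.testing.assert_allclose(out.arrival, arr)

    def test_single_spike_replaced_by_local_median(self, rparams):
        arr = np.full(100, 400.0)
        arr[37] += 200
        out = reject_outliers(_profile(arr), rparams)
        np.testing.assert_allclose(out.arrival, 400.0)
        assert out.interpolated[37]

    def test_circular_equivariance_on_full_revolution(self):
        params = AcquisitionParams(scan_mode="rotational", lines_per_rev=64,
                                   dphi=360.0 / 64)
        rng = np.random.default_rng(2)
        arr = 500 + np.cumsum(rng.normal(size=64))
        arr -= np.linspace(0, arr[-1] - arr[0], 64)  # close the loop
        arr[10] += 300
        out = reject_outliers(_profile(arr), params)
        rolled = reject_outliers(_profile(np.roll(arr, 17)), params)
        np.testing.assert_allclose(rolled.arrival, np.roll(out.arrival, 17))

    def test_invalid_lines_filled(self, rparams):
        arr = np.full(60, 300.0)
        valid = np.ones(60, bool)
        valid[5] = False
        arr[5] = np.nan
        out = reject_outliers(_profile(arr, valid), rparams)
        assert out.arrival[5] == 300.0
        assert out.valid.all()

    def test_no_surface_is_an_error(self, rparams):
        with pytest.raises(ValueError, match="no surface"):
            reject_outliers(_profile(np.full(10, np.nan), np.zeros(10, bool)),
                            rparams)


class TestAlignment:
    def test_constant_profile_is_identity(self):
        rng = np.random.default_rng(3)
        frame = rng.normal(size=(200, 5))
        aligned, shifts = align_to_surface(frame, _profile(np.full(5, 80.0)))
        assert np.all(shifts == 0)
        np.testing.assert_array_equal(aligned, frame)

    def test_two_line_shift_arithmetic(self):
        frame = np.zeros((300, 2))
        frame[100, 0] = 1.0
        frame[110, 1] = 1.0
        aligned, shifts = align_to_surface(frame, _profile([100, 110]))
        # reference is the median 105; line 2 shifts by -5, line 1 by +5
        assert shifts.tolist() == [5, -5]
        assert aligned[105, 0] == 1.0 and aligned[105, 1] == 1.0

    def test_backshift_inverts_alignment_on_centers(self, cfg):
        shifts = np.array([3, -2, 0, 7])
        vm = VelocityMap(pshift=np.zeros((4, 3)), rho=np.ones((4, 3)),
                         valid=np.ones((4, 3), bool),
                         window_centers=np.array([60, 90, 120, 150]), nres=3)
        out = backshift(vm, shifts)
        assert out.window_centers.shape == (4, 3)
        # pair p uses the first line's shift: center - shift * nres
        expect = vm.window_centers[:, None] - shifts[:3][None, :] * 3
        np.testing.assert_array_equal(out.window_centers, expect)
        # zero shifts = identity
        out0 = backshift(vm, np.zeros(4, int))
        np.testing.assert_array_equal(out0.window_centers,
                                      np.broadcast_to(vm.window_centers[:, None], (4, 3)))

    def test_oversized_shift_rejected(self):
        # arrivals from a longer frame than the one being aligned
        frame = np.zeros((100, 2))
        with pytest.raises(ValueError, match="half"):
            align_to_surface(frame, _profile([0, 200]))


class TestEstimateAngles:
    def test_constant_radius_caps_at_70(self, rparams, cfg):
        prof = _profile(np.full(1000, 500.0))
        out = estimate_angles(prof, rparams, cfg)
        # isosceles chord angle (180 - 0.36)/2 = 89.82 deg, capped
        np.testing.assert_allclose(out.theta_raw, 89.82, atol=1e-6)
        np.testing.assert_allclose(out.theta, 70.0)

    def test_planar_trig_example(self, rparams, cfg):
        # adjacent radii 10 and 10.1 mm, 0.36 deg apart -> 32.1 deg
        dphi = math.radians(0.36)
        A = np.array([10e-3, 0.0])
        B = 10.1e-3 * np.array([math.cos(dphi), math.sin(dphi)])
        bhat = B / np.linalg.norm(B)
        oracle = math.degrees(math.acos(abs((B - A) @ bhat) / np.linalg.norm(B - A)))
        # express the radii through arrival samples
        k = [rparams.sample_of_depth(r - rparams.probe_offset)
             for r in (10e-3, 10.1e-3)]
        prof = _profile(np.array(k))
        sp = dataclasses.replace(rparams, scan_mode="rotational")
        out = estimate_angles(prof, sp, cfg)
        assert out.theta_raw[1] == pytest.approx(oracle, abs=1e-9)
        assert out.theta_raw[1] == pytest.approx(32.1, abs=0.1)

    def test_exact_mode_satisfies_law_of_sines(self, rparams, cfg):
        rng = np.random.default_rng(4)
        arr = 500 + np.cumsum(rng.normal(0, 2, 64))
        prof = _profile(arr)
        out = estimate_angles(prof, rparams, cfg)
        radii = np.asarray(rparams.radius_of_sample(arr))
        dphi = rparams.dphi
        for i in range(1, 64):
            th = out.theta_raw[i]
            # interior angle at vertex i (obtuse when the radius grows)
            r_prev, r_i = radii[i - 1], radii[i]
            for cand in (th, 180.0 - th):
                lhs = r_prev / math.sin(math.radians(cand))
                rhs = r_i / math.sin(math.radians(180.0 - dphi - cand))
                if abs(lhs - rhs) / lhs < 1e-9:
                    break
            else:
                raise AssertionError(f"law of sines violated at line {i}")

    def test_recursive_mode_tracks_exact_on_steep_surface(self, rparams, cfg):
        # log-spiral arc (45 deg tangent): the small-angle recursion stays
        # within a few degrees of the closed-form chord solution
        phi = np.arange(100) * rparams.dphi
        radii = 7.2e-3 * np.exp(np.radians(phi))
        arr = np.asarray(rparams.sample_of_depth(radii - rparams.probe_offset))
        prof = _profile(arr)
        exact = estimate_angles(prof, rparams, cfg, mode="exact")
        rec = estimate_angles(prof, rparams, cfg, mode="recursive")
        sel = exact.theta_raw[5:] < 65
        diff = np.abs(rec.theta_raw[5:][sel] - exact.theta_raw[5:][sel])
        assert np.median(diff) < 5.0

    def test_lumen_surface_slope_angle_recovered(self, rparams, cfg):
        # log-spiral arc r = r0 exp(phi) has constant 45 deg tangent angle
        spec = PhantomSpec(kind="lumen", seed=6, flow_speed=0.0, snr_db=20.0,
                           n_lines=80, wobble_amp=0.0,
                           lumen_radius_fn=lambda phi:
                           7.2e-3 * np.exp(np.radians(phi)))
        scan = simulate_rotational_scan(spec, rparams)
        assert np.allclose(scan.ground_truth.flow_angle[2:-2], 45.0, atol=0.1)
        prof = detect_surface(scan.us, rparams, cfg)
        prof = reject_outliers(prof, rparams)
        out = estimate_angles(prof, rparams, cfg)
        got = out.theta[5:-5]
        assert np.median(np.abs(got - 45.0)) <= 2.0


class TestCompensate:
    def _map(self, vc):
        vm = VelocityMap(pshift=np.zeros((1, 1)), rho=np.ones((1, 1)),
                         valid=np.ones((1, 1), bool),
                         window_centers=np.array([50]), nres=3)
        vm.vc = np.array([[vc]], dtype=float)
        return vm

    def test_60_degrees_doubles(self, cfg):
        out = compensate(self._map(1e-3), 60.0, cfg)
        assert out.v[0, 0] == pytest.approx(2e-3)

    def test_zero_angle_is_identity(self, cfg):
        out = compensate(self._map(1.5e-3), 0.0, cfg)
        assert out.v[0, 0] == 1.5e-3

    def test_cap_applies_above_70(self, cfg):
        out = compensate(self._map(1.0), 80.0, cfg)
        assert out.v[0, 0] == pytest.approx(1.0 / math.cos(math.radians(70)), rel=1e-6)
        assert out.v[0, 0] == pytest.approx(2.9238, abs=1e-3)

    def test_angle_bounds_enforced(self, cfg):
        with pytest.raises(ValueError):
            compensate(self._map(1.0), 90.0, cfg)
        with pytest.raises(ValueError):
            compensate(self._map(1.0), -5.0, cfg)

    def test_factor_bounded_and_monotone(self, cfg):
        vals = []
        for th in np.linspace(0, 89.9, 60):
            th = min(th, 89.0)
            out = compensate(self._map(1.0), float(th), cfg)
            vals.append(out.v[0, 0])
        vals = np.asarray(vals)
        assert np.all(vals >= 1.0 - 1e-12)
        assert np.all(vals <= 1.0 / math.cos(math.radians(cfg.angle_cap)) + 1e-9)
        assert np.all(np.diff(vals) >= -1e-12)


class TestEndToEnd:
    def test_lumen_surface_flow_recovered_within_20pct(self, rparams):
        spec = PhantomSpec(kind="lumen", seed=8, flow_speed=4e-3, snr_db=20.0,
                           n_lines=120, wobble_amp=0.0,
                           lumen_radius_fn=lambda phi:
                           7.2e-3 * np.exp(np.radians(phi)))
        scan = simulate_rotational_scan(spec, rparams)
        cfg = DopplerConfig()
        res = pipeline.process_scanset(scan, cfg, angle="surface",
                                       subsample_refine=True)
        est = pipeline.mean_speed(res.vmap)
        assert est == pytest.approx(4e-3, rel=0.20)


class TestToPolar:
    def test_constant_image_fills_annulus(self, rparams):
        img = np.full((600, 1000), 3.5)
        out = to_polar(img, None, rparams, out_px=256)
        vals = out[np.isfinite(out)]
        assert vals.size > 0
        np.testing.assert_allclose(vals, 3.5)

    def test_bright_sample_lands_at_expected_pixel(self, rparams):
        img = np.zeros((600, 1000))
        k = 300
        img[k, 0] = 100.0
        out_px = 501
        out = to_polar(img, None, rparams, out_px=out_px)
        iy, ix = np.unravel_index(np.nanargmax(out), out.shape)
        r_out = rparams.radius_of_sample(599)
        # pixel centre coordinates used by the warp
        x = (ix + 0.5) / out_px * 2 * r_out - r_out
        y = -((iy + 0.5) / out_px * 2 * r_out - r_out)
        rho = math.hypot(x, y)
        phi = math.degrees(math.atan2(y, x)) % 360
        r_expect = rparams.radius_of_sample(k)
        px_size = 2 * r_out / out_px
        assert abs(rho - r_expect) <= 1.5 * px_size
        assert phi <= 1.0 or phi >= 359.0

    def test_finite_area_matches_annulus(self, rparams):
        img = np.ones((600, 1000))
        out_px = 600
        out = to_polar(img, None, rparams, out_px=out_px)
        frac = np.isfinite(out).mean()
        r_out = rparams.radius_of_sample(599)
        r_in = rparams.probe_offset
        expect = math.pi * (r_out ** 2 - r_in ** 2) / (2 * r_out) ** 2
        assert frac == pytest.approx(expect, rel=0.02)
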