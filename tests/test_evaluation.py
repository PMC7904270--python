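"""Metrics, screen geometry, the session protocol and parameter sweeps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gazekit as gk
from gazekit.errors import EvaluationError, ValidationError
from gazekit.evaluation import (
    DEFAULT_W_GRID,
    screen_3d_to_por,
    sweep_fusion_weight,
    sweep_iris_parameters,
)
from gazekit.fixtures import SyntheticSessionSpec, random_eye_specs, render_eye_pair, simulate_session


class TestNormalizedError:
    def test_perfect_estimates_give_zero(self):
        assert gk.normalized_error((0, 0), (100, 0), (0, 0), (100, 0)) == 0.0

    def test_benchmark_boundary_case(self):
        """Both eyes off by 5% of the inter-center distance: e = 0.05."""
        e = gk.normalized_error((5, 0), (105, 0), (0, 0), (100, 0))
        assert e == pytest.approx(0.05)

    def test_worst_eye_dominates(self):
        e = gk.normalized_error((3, 4), (100, 0), (0, 0), (100, 0))
        assert e == pytest.approx(0.05)  # left off by 5 px, right perfect, d=100

    def test_coincident_ground_truth_rejected(self):
        with pytest.raises(ValidationError):
            gk.normalized_error((0, 0), (0, 0), (50, 50), (50, 50))

    @given(st.floats(-300, 300), st.floats(-300, 300),
           st.floats(0, 2 * np.pi), st.floats(0.1, 10))
    @settings(max_examples=100, deadline=None)
    def test_similarity_invariance(self, tx, ty, theta, scale):
        pts = {"el": np.array([3.0, 4.0]), "er": np.array([98.0, 1.0]),
               "gl": np.array([0.0, 0.0]), "gr": np.array([100.0, 0.0])}
        e0 = gk.normalized_error(pts["el"], pts["er"], pts["gl"], pts["gr"])
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        t = np.array([tx, ty])
        moved = {k: scale * (R @ v) + t for k, v in pts.items()}
        e1 = gk.normalized_error(moved["el"], moved["er"], moved["gl"], moved["gr"])
        assert e1 == pytest.approx(e0, rel=1e-9, abs=1e-12)


class TestAngularErrors:
    def test_estimate_equals_target(self):
        assert gk.angular_errors((0, 0, 600), (50, 50, 0), (50, 50, 0)) == (0, 0, 0)

    def test_three_four_five_triangle(self):
        H, V, C = 3.0, 4.0, 5.0
        got = np.hypot(H, V)
        assert got == pytest.approx(C)

    def test_pure_azimuth_offset(self):
        eye = (0.0, 0.0, 0.0)
        target = (0.0, 0.0, 100.0)
        est = (np.tan(np.deg2rad(5.0)) * 100.0, 0.0, 100.0)
        H, V, C = gk.angular_errors(eye, target, est)
        assert H == pytest.approx(5.0, abs=1e-9)
        assert V == pytest.approx(0.0, abs=1e-9)
        assert C == pytest.approx(5.0, abs=1e-9)

    def test_combined_is_root_sum_square(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            eye = rng.uniform(-50, 50, 3) + (0, 0, 600)
            target = rng.uniform(0, 300, 3) * (1, 1, 0)
            est = target + rng.normal(0, 30, 3) * (1, 1, 0)
            H, V, C = gk.angular_errors(eye, target, est)
            assert C == pytest.approx(np.hypot(H, V), rel=1e-12)

    def test_zero_length_ray_rejected(self):
        with pytest.raises(ValidationError):
            gk.angular_errors((1, 2, 3), (1, 2, 3), (5, 5, 5))


class TestScreenGeometry:
    def geometry(self):
        return gk.ScreenGeometry(origin=(-215.0, 30.0, 0.0), size=(430.0, 270.0))

    def test_screen_origin_maps_to_plane_origin(self):
        geom = self.geometry()
        np.testing.assert_allclose(gk.por_to_screen_3d((0, 0), geom), geom.origin)

    def test_screen_center_maps_to_plane_center(self):
        geom = self.geometry()
        center = gk.por_to_screen_3d((215.0, 135.0), geom)
        np.testing.assert_allclose(center, (0.0, 165.0, 0.0))

    def test_round_trip_identity(self):
        geom = self.geometry()
        for por in [(0.0, 0.0), (430.0, 270.0), (123.4, 56.7)]:
            back = screen_3d_to_por(gk.por_to_screen_3d(por, geom), geom)
            np.testing.assert_allclose(back, por, atol=1e-9)

    def test_missing_geometry_rejected(self):
        with pytest.raises(ValidationError):
            gk.por_to_screen_3d((0, 0), None)


def _session(seed=0, noise=0.0, n_calib=80, n_test=60):
    return simulate_session(SyntheticSessionSpec(
        n_calib_frames=n_calib, n_test_frames=n_test,
        pixel_noise_sigma=noise, seed=seed))


class TestEvaluateSession:
    def test_zero_noise_mean_error_is_negligible(self):
        report = gk.evaluate_session(_session(), gk.EvalConfig(n_calib=80))
        assert report.means["C_F"] < 0.01
        assert report.means["C_L"] < 0.01 and report.means["C_R"] < 0.01

    def test_w_one_reproduces_pure_left_bit_for_bit(self):
        session = _session(seed=3, noise=1.0)
        r1 = gk.evaluate_session(session, gk.EvalConfig(n_calib=80, w=1.0))
        t = r1.frame_table
        assert t["gh_F"].tolist() == t["gh_L"].tolist()
        assert t["C_F"].tolist() != t["C_L"].tolist()  # different eyeball vertex
        r0 = gk.evaluate_session(session, gk.EvalConfig(n_calib=80, w=0.0))
        assert r0.frame_table["gv_F"].tolist() == r0.frame_table["gv_R"].tolist()

    def test_undetected_frames_counted_in_tf_only(self):
        session = _session(seed=5)
        for f in session.frames[::7]:
            f.detected = False
        n_undetected = sum(1 for f in session.frames if not f.detected)
        report = gk.evaluate_session(session, gk.EvalConfig(n_calib=60))
        assert report.tf == 140
        assert report.df == 140 - n_undetected
        assert report.n_calib_used + report.n_test == report.df
        assert report.detection_rate == pytest.approx(report.df / report.tf)

    def test_insufficient_calibration_frames_raise(self):
        with pytest.raises(EvaluationError, match="usable"):
            gk.evaluate_session(_session(), gk.EvalConfig(n_calib=200))

    def test_fusion_reduces_error_under_symmetric_noise(self):
        fused, best_single = [], []
        for seed in range(5):
            report = gk.evaluate_session(_session(seed=seed, noise=1.0, n_calib=200,
                                                  n_test=100),
                                         gk.EvalConfig(n_calib=200))
            fused.append(report.means["C_F"])
            best_single.append(min(report.means["C_L"], report.means["C_R"]))
        assert np.mean(fused) <= np.mean(best_single)

    def test_random_split_mode_still_calibrates(self):
        report = gk.evaluate_session(
            _session(seed=1), gk.EvalConfig(n_calib=80, random_split=True, split_seed=4)
        )
        assert report.n_calib_used == 80
        assert report.means["C_F"] < 0.01


class TestSweeps:
    def test_iris_sweep_optimum_is_grid_argmax(self):
        specs_l = random_eye_specs(6, seed=0, noise_sigma=8.0, eyelid_cover_fraction=0.2)
        specs_r = random_eye_specs(6, seed=1, noise_sigma=8.0, eyelid_cover_fraction=0.2)
        pairs = [render_eye_pair(a, b) for a, b in zip(specs_l, specs_r)]
        table = sweep_iris_parameters(pairs, alphas=(0.23, 0.25), betas=(1.4,),
                                      deltas=(1, 2))
        best = table["count"].max()
        assert np.all(table["count"] <= best)
        assert table.loc[table["count"].idxmax(), "rate"] == best / 6

    def test_w_sweep_flat_at_zero_noise(self):
        """With exact per-eye PORs every fusion weight performs identically."""
        from gazekit.fixtures import default_true_coeffs

        # identical left/right ground-truth coefficients: copy the left defaults
        coeffs = {(eye, ax): default_true_coeffs(4 if ax == "h" else 2, ax, "left")
                  for eye in ("left", "right") for ax in ("h", "v")}
        session = simulate_session(SyntheticSessionSpec(
            n_calib_frames=60, n_test_frames=30, seed=2, coeffs=coeffs))
        table = sweep_fusion_weight(session, ws=(0.0, 0.5, 1.0),
                                    config=gk.EvalConfig(n_calib=60))
        assert table["C"].max() - table["C"].min() < 1e-8

    def test_default_w_grid_matches_protocol(self):
        assert DEFAULT_W_GRID == tuple(np.round(np.arange(0, 1.01, 0.1), 1))


class TestSessionIo:
    def test_directory_round_trip(self, tmp_path):
        session = _session(seed=8, noise=1.0, n_calib=30, n_test=10)
        session.frames[3].detected = False
        gk.write_session(session, tmp_path / "sess")
        loaded = gk.read_session(tmp_path / "sess")
        assert loaded.tf == session.tf and loaded.df == session.df
        f0, g0 = session.frames[10], loaded.frames[10]
        assert g0.eye_left.eh == pytest.approx(f0.eye_left.eh)
        assert g0.target_3d == pytest.approx(f0.target_3d)
        np.testing.assert_allclose(loaded.geometry.origin, session.geometry.origin)
        # evaluation of the loaded session matches the original
        r_orig = gk.evaluate_session(session, gk.EvalConfig(n_calib=25))
        r_load = gk.evaluate_session(loaded, gk.EvalConfig(n_calib=25))
        assert r_load.means["C_F"] == pytest.approx(r_orig.means["C_F"], rel=1e-9)
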