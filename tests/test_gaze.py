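"""Eye vectors, mapping presets, least-squares fitting and binocular fusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gazekit as gk
from gazekit.errors import FitError, ValidationError
from gazekit.fixtures import SyntheticSessionSpec, default_true_coeffs, simulate_session
from gazekit.gaze import PRESETS, design_row


def _ev(eh, ev):
    return gk.EyeVector(eh, ev)


def _pose(p=0.0, y=0.0, r=0.0):
    return gk.HeadPose(p, y, r)


class TestEyeVector:
    def test_subtraction(self):
        anchor = gk.AnchorPoint(110.0, 60.0)
        e = gk.eye_vector((120.0, 51.0), anchor)
        assert (e.eh, e.ev) == (10.0, -9.0)

    def test_iris_at_anchor_gives_zero(self):
        anchor = gk.AnchorPoint(110.0, 60.0)
        e = gk.eye_vector((110.0, 60.0), anchor)
        assert (e.eh, e.ev) == (0.0, 0.0)

    def test_translation_invariance(self):
        a = gk.eye_vector((120.0, 51.0), gk.AnchorPoint(110.0, 60.0))
        b = gk.eye_vector((127.0, 48.0), gk.AnchorPoint(117.0, 57.0))
        assert (a.eh, a.ev) == (b.eh, b.ev)

    def test_roi_coordinates_rejected(self):
        """An iris result without a full-image center is a frame mismatch."""
        from gazekit.iris import IrisResult

        res = IrisResult((30, 24), (30, 24), 1.0, 1.0, None, 0.25, 1.4, 2, 15)
        with pytest.raises(ValidationError):
            gk.eye_vector(res, gk.AnchorPoint(110.0, 60.0))


class TestDesignRow:
    def test_preset_1_linear_terms(self):
        row = design_row(_ev(2, 3), _pose(), 1)
        assert row.tolist() == [1, 2, 3]

    def test_preset_2_adds_cross_and_squares(self):
        row = design_row(_ev(2, 3), _pose(), 2)
        assert row.tolist() == [1, 2, 3, 6, 4, 9]

    def test_preset_4_zero_inputs_leave_only_constant(self):
        row = design_row(_ev(0, 0), _pose(0, 0, 0), 4)
        assert row[0] == 1 and np.all(row[1:] == 0)

    def test_preset_6_includes_squared_head_terms(self):
        row = design_row(_ev(0, 0), _pose(2, -3, 4), 6)
        assert row.tolist() == [1, 0, 0, 0, 0, 0, 2, -3, 4, 4, 9, 16]

    def test_presets_are_nested(self):
        assert set(PRESETS[1]) < set(PRESETS[2])
        assert set(PRESETS[3]) < set(PRESETS[4])
        assert set(PRESETS[1]) < set(PRESETS[3]) and set(PRESETS[2]) < set(PRESETS[4])

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValidationError):
            design_row(_ev(1, 1), _pose(), 7)


def _frames_and_targets(preset, axis, n=80, seed=0, eye="left"):
    """Frames with targets generated exactly by the known coefficients."""
    rng = np.random.default_rng(seed)
    coeffs = default_true_coeffs(preset, axis, eye)
    frames, targets = [], []
    for _ in range(n):
        e = _ev(rng.uniform(-20, 20), rng.uniform(-15, 15))
        h = _pose(rng.uniform(-10, 10), rng.uniform(-15, 15), rng.uniform(-5, 5))
        frames.append((e, h))
        targets.append(float(coeffs @ design_row(e, h, preset)))
    return frames, targets, coeffs


class TestFitMapping:
    @pytest.mark.parametrize("preset", [1, 2, 3, 4, 5, 6])
    def test_recovers_generating_coefficients(self, preset):
        frames, targets, coeffs = _frames_and_targets(preset, "h")
        model = gk.fit_mapping(frames, targets, preset, "h")
        np.testing.assert_allclose(model.coefficients, coeffs, rtol=1e-6)

    def test_nested_preset_recovers_zero_extra_coefficients(self):
        frames, targets, _ = _frames_and_targets(1, "h")
        model = gk.fit_mapping(frames, targets, 2, "h")
        assert np.all(np.abs(model.coefficients[3:]) <= 1e-6)

    def test_single_gaze_point_is_rank_deficient(self):
        frames = [(_ev(5, 5), _pose())] * 20
        with pytest.raises(FitError, match="rank"):
            gk.fit_mapping(frames, [100.0] * 20, 2, "h")

    def test_too_few_frames_rejected(self):
        frames, targets, _ = _frames_and_targets(2, "h", n=4)
        with pytest.raises(FitError, match="frames"):
            gk.fit_mapping(frames, targets, 2, "h")

    def test_coefficient_error_shrinks_with_sample_size(self):
        """Monte-Carlo: coefficient RMSE under target noise scales ~ 1/sqrt(n)."""
        rng = np.random.default_rng(7)
        rmses = []
        for n in (50, 800):
            errs = []
            for rep in range(12):
                frames, targets, coeffs = _frames_and_targets(1, "h", n=n,
                                                              seed=100 * n + rep)
                noisy = np.array(targets) + rng.normal(0, 5.0, n)
                model = gk.fit_mapping(frames, noisy, 1, "h")
                errs.append(np.linalg.norm(model.coefficients - coeffs))
            rmses.append(np.mean(errs))
        ratio = rmses[0] / rmses[1]
        assert 2.0 < ratio < 8.0  # expect ~ sqrt(800/50) = 4

    def test_pose_free_presets_ignore_head_pose(self):
        """Shuffling head poses among frames leaves preset-1/2 fits unchanged."""
        frames, targets, _ = _frames_and_targets(2, "h")
        rng = np.random.default_rng(3)
        poses = [h for _, h in frames]
        rng.shuffle(poses)
        shuffled = [(e, p) for (e, _), p in zip(frames, poses)]
        m1 = gk.fit_mapping(frames, targets, 2, "h")
        m2 = gk.fit_mapping(shuffled, targets, 2, "h")
        np.testing.assert_array_equal(m1.coefficients, m2.coefficients)


class TestPredict:
    def test_zero_coefficients_give_zero(self):
        m = gk.MappingModel(axis="h", terms=PRESETS[1], coefficients=np.zeros(3))
        assert m.predict(_ev(5, 5), _pose()) == 0.0

    def test_generating_model_reproduces_target_exactly(self):
        frames, targets, coeffs = _frames_and_targets(4, "h", n=5)
        m = gk.MappingModel(axis="h", terms=PRESETS[4], coefficients=coeffs)
        for (e, h), t in zip(frames, targets):
            assert m.predict(e, h) == pytest.approx(t, abs=1e-12)

    def test_unfitted_model_rejected(self):
        m = gk.MappingModel.from_preset(1, "h")
        with pytest.raises(FitError):
            m.predict(_ev(1, 1))

    @given(st.floats(-10, 10), st.floats(-10, 10))
    @settings(max_examples=30, deadline=None)
    def test_prediction_linear_in_coefficients(self, eh, ev):
        c1 = np.arange(1.0, 7.0)
        c2 = np.linspace(-3, 3, 6)
        e, h = _ev(eh, ev), _pose(1, 2, 3)
        pred = lambda c: gk.MappingModel(axis="h", terms=PRESETS[2],
                                         coefficients=c).predict(e, h)
        assert pred(c1 + c2) == pytest.approx(pred(c1) + pred(c2), rel=1e-9, abs=1e-9)

    def test_default_presets(self):
        assert gk.DEFAULT_PRESET_H == 4
        assert gk.DEFAULT_PRESET_V == 2


class TestFusePor:
    def test_w_one_is_pure_left(self):
        assert gk.fuse_por((10.0, 20.0), (20.0, 10.0), w=1.0) == (10.0, 20.0)

    def test_w_zero_is_pure_right(self):
        assert gk.fuse_por((10.0, 20.0), (20.0, 10.0), w=0.0) == (20.0, 10.0)

    def test_midpoint_at_half(self):
        assert gk.fuse_por((10.0, 20.0), (20.0, 10.0), w=0.5) == (15.0, 15.0)

    def test_w_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            gk.fuse_por((0, 0), (1, 1), w=1.5)

    def test_unavailable_eye_collapses_weight(self):
        fused = gk.fuse_por((10.0, 20.0), (20.0, 10.0), w=0.5, left_available=False)
        assert fused == (20.0, 10.0)

    @given(st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_fused_por_lies_on_segment(self, w):
        left, right = (3.0, -2.0), (11.0, 6.0)
        gh, gv = gk.fuse_por(left, right, w=w)
        # collinear with the endpoints and inside the bounding box
        cross = (gh - left[0]) * (right[1] - left[1]) - (gv - left[1]) * (right[0] - left[0])
        assert abs(cross) < 1e-9
        assert min(left[0], right[0]) - 1e-9 <= gh <= max(left[0], right[0]) + 1e-9


class TestModelIo:
    def test_json_round_trip(self, tmp_path):
        frames, targets, _ = _frames_and_targets(4, "h")
        model = gk.fit_mapping(frames, targets, 4, "h")
        path = tmp_path / "model.json"
        model.save(path)
        loaded = gk.MappingModel.load(path)
        assert loaded.axis == model.axis
        assert loaded.terms == model.terms
        np.testing.assert_array_equal(loaded.coefficients, model.coefficients)
        assert loaded.residual_rms == model.residual_rms
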