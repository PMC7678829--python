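"""Active shape model: PDM algebra, intensity models, fitting, tracking."""

import numpy as np
import pytest

from myowave.asm import (
    LANDMARK_COLUMNS,
    LandmarkShape,
    ShapeModel,
    build_intensity_models,
    build_pdm,
    fit_shape,
    segment_sequence,
    train_shape_model,
)
from myowave.synthetic import BoundarySpec, ImageSequence, generate_image_sequence


def _shape(rows, frame=0):
    return LandmarkShape.from_rows(np.asarray(rows, dtype=float), frame)


def _flat_shape(row, frame=0):
    return _shape(np.full(19, float(row)), frame)


class TestPointDistributionModel:
    def test_identical_shapes_give_zero_modes(self):
        shapes = [_flat_shape(200.0, i) for i in range(5)]
        pdm = build_pdm(shapes)
        assert pdm.n_modes == 0
        assert np.allclose(pdm.mean_shape, shapes[0].vector())

    def test_rank_one_construction_recovers_mode_and_variance(self):
        rng = np.random.default_rng(0)
        base = 200.0 + 5 * np.sin(np.linspace(0, np.pi, 19))
        v = rng.standard_normal(19)
        v /= np.linalg.norm(v)
        ts = rng.normal(0, 3.0, size=12)
        shapes = [_shape(base + t * v, i) for i, t in enumerate(ts)]
        pdm = build_pdm(shapes)
        assert pdm.n_modes == 1
        mode_y = pdm.modes[19:, 0]
        assert abs(abs(mode_y @ v) - 1.0) < 1e-10
        assert pdm.variances[0] == pytest.approx(np.var(ts, ddof=1), rel=1e-10)

    def test_eigendecomposition_matches_brute_force(self):
        rng = np.random.default_rng(7)
        shapes = [_shape(250 + rng.normal(0, 4, 19), i) for i in range(20)]
        pdm = build_pdm(shapes, variance_fraction=1.0)
        # independent oracle: explicit covariance accumulation + dense eigh
        X = np.array([s.vector() for s in shapes])
        mean = X.mean(axis=0)
        C = np.zeros((38, 38))
        for x in X:
            d = x - mean
            C += np.outer(d, d)
        C /= len(X) - 1
        evals = np.sort(np.linalg.eigvalsh(C))[::-1]
        assert np.allclose(pdm.variances, evals[: pdm.n_modes], atol=1e-8)
        for i in range(pdm.n_modes):
            resid = C @ pdm.modes[:, i] - pdm.variances[i] * pdm.modes[:, i]
            assert np.linalg.norm(resid) < 1e-8

    def test_projection_is_idempotent(self):
        rng = np.random.default_rng(3)
        shapes = [_shape(250 + rng.normal(0, 4, 19), i) for i in range(10)]
        pdm = build_pdm(shapes)
        b = rng.normal(0, np.sqrt(pdm.variances))
        rec = pdm.reconstruct(b)
        assert np.allclose(pdm.project(rec), b, atol=1e-10)

    def test_needs_two_shapes(self):
        with pytest.raises(ValueError, match="two training shapes"):
            build_pdm([_flat_shape(100.0)])


def _band_sequence(row=200.0, sigma=3.0, n_frames=1, width=608, height=512):
    """Noise-free image stack with one horizontal Gaussian band."""
    rows = np.arange(height, dtype=float)[:, None]
    img = 200.0 * np.exp(-((rows - row) ** 2) / (2 * sigma**2))
    frames = np.repeat(img[None].astype(np.uint8), n_frames, axis=0)
    ts = np.arange(n_frames) / 80.0
    return ImageSequence(frames, 80.0, 0.0987, 0.0977, ts)


class TestIntensityModels:
    def test_band_crossing_has_extremal_gradient(self):
        seq = _band_sequence(row=200.0, sigma=3.0)
        model = build_intensity_models(seq, [_flat_shape(200.0)], k=6, n_levels=1)
        profile = model.means[0][9]  # a mid-image landmark
        k = model.k
        # gradient is ~0 at the band centre, extremal near +/- sigma, and
        # antisymmetric: positive approaching the band, negative leaving it
        assert abs(profile[k]) < 0.05
        assert profile[:k].max() > 0.1
        assert profile[k + 1:].min() < -0.1
        assert abs(np.argmax(profile) - (k - 3)) <= 2
        assert abs(np.argmin(profile) - (k + 3)) <= 2

    def test_constant_image_yields_zero_profiles(self):
        frames = np.full((1, 512, 608), 37, dtype=np.uint8)
        seq = ImageSequence(frames, 80.0, 0.1, 0.1, np.array([0.0]))
        model = build_intensity_models(seq, [_flat_shape(200.0)], n_levels=2)
        for lvl in range(2):
            assert np.allclose(model.means[lvl], 0.0)

    def test_single_frame_covariance_is_regulariser_only(self):
        seq = _band_sequence()
        model = build_intensity_models(seq, [_flat_shape(200.0)], k=4,
                                       n_levels=1, eps_frac=1e-6)
        cov = model.covariances[0][0]
        assert np.allclose(cov, cov[0, 0] * np.eye(cov.shape[0]))

    def test_profile_outside_image_flags_landmark(self):
        seq = _band_sequence(row=5.0)
        model = build_intensity_models(seq, [_flat_shape(5.0)], k=6, n_levels=1)
        assert model.clamped_landmarks.any()


@pytest.fixture(scope="module")
def trained(small_oscillation_scene):
    seq, scene = small_oscillation_scene
    truth = scene.landmark_truth["superficial"]
    labels = [LandmarkShape.from_rows(truth[f], f)
              for f in range(0, seq.n_frames, 7)]
    model = train_shape_model([(seq, labels)])
    return model, seq, scene


class TestFitShape:
    def test_init_at_truth_stays_within_one_px_rms(self, trained):
        model, seq, scene = trained
        truth = scene.landmark_truth["superficial"][0]
        fitted, diag = fit_shape(model, seq.frames[0],
                                 LandmarkShape.from_rows(truth, 0))
        rms = np.sqrt(np.mean((fitted.points[:, 1] - truth) ** 2))
        assert rms < 1.0

    def test_displaced_init_recovers_within_one_mm(self, trained):
        model, seq, scene = trained
        truth = scene.landmark_truth["superficial"][0]
        init = LandmarkShape.from_rows(truth + 10.0, 0)
        fitted, _ = fit_shape(model, seq.frames[0], init, n_levels=5)
        mae_mm = np.mean(np.abs(fitted.points[:, 1] - truth)) * seq.mm_per_px_y
        assert mae_mm <= 1.0

    def test_zero_mode_model_returns_mean_shape(self, trained):
        model, seq, _ = trained
        pdm = build_pdm([_flat_shape(250.0, i) for i in range(3)])
        degenerate = ShapeModel(pdm, model.intensity)
        fitted, _ = fit_shape(degenerate, seq.frames[0], _flat_shape(240.0))
        assert np.allclose(fitted.points[:, 1], 250.0)

    def test_mode_coefficients_respect_three_sd_clamp(self, trained):
        model, seq, scene = trained
        init = LandmarkShape.from_rows(
            scene.landmark_truth["superficial"][0] + 15.0, 0)
        _, diag = fit_shape(model, seq.frames[0], init, n_levels=5)
        limits = 3.0 * np.sqrt(model.pdm.variances)
        assert np.all(np.abs(diag.b) <= limits + 1e-9)


class TestSegmentSequence:
    def test_static_scene_returns_constant_shapes(self):
        sup = BoundarySpec(c0=150.0, c1=0.02)
        deep = BoundarySpec(c0=350.0)
        seq, scene = generate_image_sequence(sup, deep, n_frames=12, seed=4)
        truth = scene.landmark_truth["superficial"]
        # two slightly different labels so the covariance is well-defined
        labels = [LandmarkShape.from_rows(truth[0], 0),
                  LandmarkShape.from_rows(truth[5], 5)]
        model = train_shape_model([(seq, labels)])
        traj = segment_sequence(model, seq,
                                init=LandmarkShape.from_rows(truth[0], 0))
        rows = traj.rows()
        assert np.all(np.abs(rows - rows[0]) <= 1.0)

    def test_oscillation_recovered_with_high_correlation(
            self, small_oscillation_scene):
        seq, scene = small_oscillation_scene
        truth = scene.landmark_truth["superficial"]
        labels = [LandmarkShape.from_rows(truth[f], f)
                  for f in range(0, seq.n_frames, 7)]
        model = train_shape_model([(seq, labels)])
        traj = segment_sequence(model, seq,
                                init=LandmarkShape.from_rows(truth[0], 0))
        rows = traj.rows()
        for j in (0, 9, 18):
            r = np.corrcoef(rows[:, j], truth[:, j])[0, 1]
            assert r > 0.95

    def test_single_frame_sequence(self, small_oscillation_scene):
        seq, scene = small_oscillation_scene
        truth = scene.landmark_truth["superficial"]
        labels = [LandmarkShape.from_rows(truth[f], f) for f in (0, 10)]
        model = train_shape_model([(seq, labels)])
        one = ImageSequence(seq.frames[:1], seq.frame_rate_hz,
                            seq.mm_per_px_x, seq.mm_per_px_y,
                            seq.timestamps[:1])
        traj = segment_sequence(model, one,
                                init=LandmarkShape.from_rows(truth[0], 0))
        assert len(traj.shapes) == 1

    def test_model_round_trip_through_archive(self, tmp_path,
                                              small_oscillation_scene):
        seq, scene = small_oscillation_scene
        truth = scene.landmark_truth["superficial"]
        labels = [LandmarkShape.from_rows(truth[f], f) for f in (0, 10, 20)]
        model = train_shape_model([(seq, labels)], metadata={"participant": 3})
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = ShapeModel.load(path)
        assert np.allclose(loaded.pdm.mean_shape, model.pdm.mean_shape)
        assert np.allclose(loaded.pdm.modes, model.pdm.modes)
        for lvl in range(model.intensity.n_levels):
            assert np.allclose(loaded.intensity.means[lvl],
                               model.intensity.means[lvl])
        assert loaded.metadata["participant"] == 3


class TestLandmarkShapeInvariants:
    def test_wrong_point_count_rejected(self):
        with pytest.raises(ValueError):
            LandmarkShape(np.zeros((18, 2)))

    def test_off_column_points_rejected(self):
        pts = np.column_stack([LANDMARK_COLUMNS + 1.0, np.full(19, 100.0)])
        with pytest.raises(ValueError, match="standard columns"):
            LandmarkShape(pts)
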