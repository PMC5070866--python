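import numpy as np
import pytest

from wmsnorm.gc_model import (
    GcBiasModel,
    GcCoverageCurve,
    curves_from_tsv,
    curves_to_tsv,
    fit_gc_model,
    gaussian_term,
    normcov_pooled,
    normcov_single,
    predict_normcov,
    read_weight,
)

# planted surface kept positive over all generated (GC_R, GC_G) points
# so observations equal the raw model family exactly (no floor clamp)
THETA_STAR = (1.5, 45.0, 12.0, 3.0, 0.004, -2e-5, 1e-8, -0.7)


def _bins(rst, windows):
    """Pad per-bin vectors into the 0..100 GC-point arrays."""
    r = np.zeros(101)
    w = np.zeros(101)
    r[40 : 40 + len(rst)] = rst
    w[40 : 40 + len(windows)] = windows
    return r, w


class TestNormcovSingle:
    def test_reads_proportional_to_windows_give_unity(self):
        r, w = _bins([10, 20, 30], [1, 2, 3])
        curve = normcov_single(r, w)
        assert np.allclose(curve.normcov, 1.0)

    def test_direct_arithmetic(self):
        r, w = _bins([10, 0], [5, 5])
        curve = normcov_single(r, w)
        assert curve.normcov.tolist() == [2.0, 0.0]

    def test_single_occupied_bin_is_unity(self):
        r, w = _bins([7], [3])
        assert normcov_single(r, w).normcov.tolist() == [1.0]

    def test_conservation_identity(self, rng):
        # sum_i normcov_i * W_i * (Rst_Total/W_Total) == Rst_Total exactly
        for _ in range(25):
            w = rng.integers(0, 50, size=101).astype(float)
            r = np.where(w > 0, rng.integers(0, 1000, size=101), 0).astype(float)
            if r.sum() == 0 or w.sum() == 0:
                continue
            curve = normcov_single(r, w)
            lhs = float(np.sum(curve.normcov * curve.windows) * (r.sum() / w.sum()))
            assert lhs == pytest.approx(r.sum(), rel=1e-12)

    def test_zero_totals_rejected(self):
        with pytest.raises(ValueError):
            normcov_single(np.zeros(101), np.ones(101))


class TestNormcovPooled:
    def test_m1_reduces_to_single(self):
        r, w = _bins([3, 9, 1], [2, 2, 2])
        single = normcov_single(r, w)
        pooled = normcov_pooled(r, w, rst_total=int(r.sum()), m=1)
        assert np.allclose(single.normcov, pooled.normcov)

    def test_equal_share_arithmetic(self):
        r, w = _bins([100], [10])
        curve = normcov_pooled(r, w, rst_total=200, m=2)
        assert curve.normcov.tolist() == [1.0]

    def test_double_share_doubles_curve(self):
        # a genome receiving twice its equal share, uniform placement
        r, w = _bins([40, 80, 40], [10, 20, 10])
        curve = normcov_pooled(r, w, rst_total=320, m=4)  # share=80, got 160
        assert np.allclose(curve.normcov, 2.0)


class TestGaussianTerm:
    def test_peak_baseline_symmetry(self):
        assert gaussian_term(45.0, 2.0, 45.0, 10.0, 0.5) == pytest.approx(2.5)
        assert gaussian_term(45.0 + 1e4, 2.0, 45.0, 10.0, 0.5) == pytest.approx(0.5)
        for x in (3.0, 11.5, 40.0):
            assert gaussian_term(45 + x, 2.0, 45.0, 10.0, 0.5) == pytest.approx(
                gaussian_term(45 - x, 2.0, 45.0, 10.0, 0.5)
            )

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            gaussian_term(50.0, 1.0, 45.0, 0.0, 0.0)


class TestPredictNormcov:
    def test_floor_clamps_low_predictions(self):
        model = GcBiasModel(theta=(0.0, 50.0, 10.0, -5.0, 0.0, 0.0, 0.0, 0.0))
        assert predict_normcov(50.0, 40.0, model) == 0.01

    def test_reduces_to_gaussian_when_other_terms_zero(self):
        model = GcBiasModel(theta=(2.0, 45.0, 10.0, 0.5, 0.0, 0.0, 0.0, 0.0))
        assert predict_normcov(45.0, 33.0, model) == pytest.approx(2.5)

    def test_negative_log_coefficient_penalizes_high_genome_gc(self):
        model = GcBiasModel(theta=(2.0, 45.0, 10.0, 3.0, 0.0, 0.0, 0.0, -0.5))
        assert predict_normcov(50.0, 33.0, model) > predict_normcov(50.0, 67.0, model)

    def test_nonpositive_genome_gc_rejected(self):
        model = GcBiasModel(theta=(2.0, 45.0, 10.0, 3.0, 0.0, 0.0, 0.0, -0.5))
        with pytest.raises(ValueError):
            predict_normcov(50.0, 0.0, model)


class TestReadWeight:
    def test_reciprocal_and_cap(self):
        model = GcBiasModel(theta=(0.0, 50.0, 10.0, 2.0, 0.0, 0.0, 0.0, 0.0))
        assert read_weight(50.0, 40.0, model) == pytest.approx(0.5)
        low = GcBiasModel(theta=(0.0, 50.0, 10.0, -9.0, 0.0, 0.0, 0.0, 0.0))
        assert read_weight(50.0, 40.0, low) == pytest.approx(100.0)
        unit = GcBiasModel(theta=(0.0, 50.0, 10.0, 1.0, 0.0, 0.0, 0.0, 0.0))
        assert read_weight(50.0, 40.0, unit) == pytest.approx(1.0)


def _curves_from_theta(theta, genome_gcs, noise_sd=0.0, rng=None):
    model = GcBiasModel(theta=theta, floor=1e-9)
    curves = []
    for gg in genome_gcs:
        points = np.arange(max(5, int(gg) - 18), min(96, int(gg) + 19))
        normcov = predict_normcov(points.astype(float), gg, model)
        normcov = np.asarray(normcov, dtype=float).copy()
        if noise_sd and rng is not None:
            normcov += rng.normal(0, noise_sd, size=normcov.size)
        curves.append(
            GcCoverageCurve(
                ref_id=f"g{gg}",
                genome_gc=gg,
                gc_points=points,
                normcov=normcov,
                read_starts=np.full(points.size, 100),
                windows=np.full(points.size, 100),
            )
        )
    return curves


GENOME_GCS = [32.8, 39.7, 50.5, 57.3, 64.9, 66.7, 70.8]


class TestFitGcModel:
    def test_zero_noise_predictive_recovery(self):
        curves = _curves_from_theta(THETA_STAR, GENOME_GCS)
        model = fit_gc_model(curves)
        truth = GcBiasModel(theta=THETA_STAR, floor=1e-9)
        grid_r = np.linspace(25, 75, 21)
        for gg in (35.0, 48.0, 63.0):
            want = np.asarray(predict_normcov(grid_r, gg, truth))
            got = np.asarray(predict_normcov(grid_r, gg, GcBiasModel(theta=model.theta, floor=1e-9)))
            assert np.max(np.abs(got - want) / np.abs(want)) < 1e-6

    def test_noisy_recovery_bounds_prediction_error(self, rng):
        curves = _curves_from_theta(THETA_STAR, GENOME_GCS, noise_sd=0.05, rng=rng)
        model = fit_gc_model(curves)
        truth = GcBiasModel(theta=THETA_STAR, floor=1e-9)
        grid_r = np.linspace(28, 72, 23)
        errs = []
        for gg in GENOME_GCS:
            want = np.asarray(predict_normcov(grid_r, gg, truth))
            got = np.asarray(predict_normcov(grid_r, gg, GcBiasModel(theta=model.theta, floor=1e-9)))
            errs.append(np.abs(got - want))
        assert np.mean(np.concatenate(errs)) < 0.05

    def test_fit_is_deterministic(self):
        curves = _curves_from_theta(THETA_STAR, GENOME_GCS)
        a = fit_gc_model(curves)
        b = fit_gc_model(curves)
        assert a.theta == b.theta

    def test_single_genome_gc_rejected(self):
        curves = _curves_from_theta(THETA_STAR, [50.5])
        with pytest.raises(ValueError, match="distinct genome GC"):
            fit_gc_model(curves)

    def test_reports_diagnostics(self):
        curves = _curves_from_theta(THETA_STAR, GENOME_GCS)
        model = fit_gc_model(curves)
        assert model.dof == sum(c.gc_points.size for c in curves) - 8
        assert model.residual_se == pytest.approx(0.0, abs=1e-6)
        assert model.converged

    def test_low_support_bins_excluded(self):
        curves = _curves_from_theta(THETA_STAR, GENOME_GCS)
        # corrupt one bin but mark it low-support: fit must ignore it
        curves[0].normcov[0] = 99.0
        curves[0].windows[0] = 1
        model = fit_gc_model(curves, min_windows=5)
        assert model.residual_se == pytest.approx(0.0, abs=1e-6)


class TestCurveSerialization:
    def test_tsv_round_trip(self, tmp_path):
        curves = _curves_from_theta(THETA_STAR, [40.0, 60.0])
        path = tmp_path / "curves.tsv"
        curves_to_tsv(curves, path)
        back = curves_from_tsv(path)
        assert len(back) == 2
        assert np.allclose(back[0].normcov, curves[0].normcov)
        assert back[1].genome_gc == 60.0


class TestModelSerialization:
    def test_json_round_trip(self, tmp_path, planted_model):
        path = tmp_path / "model.json"
        planted_model.residual_se = 0.123
        planted_model.to_json(path)
        back = GcBiasModel.from_json(path)
        assert back.theta == planted_model.theta
        assert back.floor == planted_model.floor
        assert back.residual_se == 0.123
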