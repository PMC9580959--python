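"""Field-transform fitting, offset updates and drift correction."""

import numpy as np
import pytest

from prismtrack.io import LocalizationRecord, LocalizationTable
from prismtrack.register import (
    DriftTrace,
    FieldTransform,
    apply_field_transform,
    estimate_drift,
    apply_drift_correction,
    fit_field_transform,
    load_field_transform,
    polynomial_terms,
    registration_residuals,
    save_field_transform,
    update_transform_offset,
)

RANDOM_CUBIC_AX = np.array([3e-7, -2e-7, 1.5e-7, -1e-7, 2e-5, -1.5e-5, 1e-5, 0.9, 0.004, 3.2])
RANDOM_CUBIC_AY = np.array([-2.5e-7, 3.5e-7, -1.2e-7, 8e-8, -1.8e-5, 2.2e-5, -0.9e-5, -0.003, 0.9, -1.7])


def grid_7x7(lo=10.0, hi=500.0):
    g = np.linspace(lo, hi, 7)
    return np.array([(x, y) for x in g for y in g])


class TestFieldTransformModel:
    def test_exactly_ten_coefficients_per_dimension(self):
        t = FieldTransform.identity()
        assert t.ax.shape == (10,) and t.ay.shape == (10,)
        with pytest.raises(ValueError):
            FieldTransform(ax=np.zeros(9), ay=np.zeros(10))
        with pytest.raises(ValueError):
            FieldTransform(ax=np.zeros(11), ay=np.zeros(10))

    def test_identity_transform_fixes_points(self):
        t = FieldTransform.identity()
        pts = np.array([[12.5, 40.25], [0.0, 0.0], [511.0, 3.0]])
        np.testing.assert_allclose(apply_field_transform(t, pts), pts, atol=1e-12)

    def test_zero_order_terms_are_pure_translation(self):
        t = FieldTransform.identity()
        t.ax[9] += 5.0
        t.ay[9] += -3.0
        out = apply_field_transform(t, (10.0, 20.0))[0]
        np.testing.assert_allclose(out, [15.0, 17.0], atol=1e-12)

    def test_matches_term_by_term_polynomial_evaluation(self):
        t = FieldTransform(ax=RANDOM_CUBIC_AX, ay=RANDOM_CUBIC_AY)
        x, y = 12.5, 40.25
        terms = [x**3, y**3, x**2 * y, x * y**2, x**2, y**2, x * y, x, y, 1.0]
        expected = np.array([np.dot(RANDOM_CUBIC_AX, terms), np.dot(RANDOM_CUBIC_AY, terms)])
        np.testing.assert_allclose(apply_field_transform(t, (x, y))[0], expected, rtol=1e-12)


class TestFitFieldTransform:
    def test_identity_mapping_recovers_identity_pattern(self):
        pts = grid_7x7()
        t, _ = fit_field_transform([(p, p) for p in pts])
        expected_ax = np.zeros(10)
        expected_ax[7] = 1.0
        expected_ay = np.zeros(10)
        expected_ay[8] = 1.0
        np.testing.assert_allclose(t.ax, expected_ax, atol=1e-9)
        np.testing.assert_allclose(t.ay, expected_ay, atol=1e-9)

    def test_known_cubic_recovered_noiselessly(self):
        pts = grid_7x7()
        t0 = FieldTransform(ax=RANDOM_CUBIC_AX, ay=RANDOM_CUBIC_AY)
        dst = apply_field_transform(t0, pts)
        t, qc = fit_field_transform(list(zip(pts, dst)))
        np.testing.assert_allclose(t.ax, RANDOM_CUBIC_AX, rtol=1e-6)
        np.testing.assert_allclose(t.ay, RANDOM_CUBIC_AY, rtol=1e-6)
        assert qc.max_nm < 1e-6

    def test_jittered_grid_median_residual_within_budget(self):
        # 7 nm/axis localization jitter on 49 pairs: the fitted transform
        # absorbs 20 of 2x49 dof, leaving a median 2-D residual well under
        # the 12 nm channel-registration budget
        rng = np.random.default_rng(42)
        pts = grid_7x7()
        t0 = FieldTransform(ax=RANDOM_CUBIC_AX, ay=RANDOM_CUBIC_AY)
        dst = apply_field_transform(t0, pts)
        medians = []
        for _ in range(20):
            src_j = pts + rng.normal(0, 7.0 / 160.0, pts.shape)
            dst_j = dst + rng.normal(0, 7.0 / 178.0, dst.shape)
            _, qc = fit_field_transform(list(zip(src_j, dst_j)))
            medians.append(qc.median_nm)
        assert np.median(medians) <= 12.0
        assert 4.0 <= np.median(medians)  # jitter is not silently absorbed

    def test_degenerate_collinear_points_raise(self):
        pts = np.array([(float(i), 2.0 * i + 1.0) for i in range(30)])
        with pytest.raises(ValueError, match="degenerate"):
            fit_field_transform([(p, p) for p in pts])

    def test_too_few_pairs_raise(self):
        pts = grid_7x7()[:8]
        with pytest.raises(ValueError):
            fit_field_transform([(p, p) for p in pts])


class TestRegistrationResiduals:
    def test_self_fit_residuals_vanish(self):
        pts = grid_7x7()
        t0 = FieldTransform(ax=RANDOM_CUBIC_AX, ay=RANDOM_CUBIC_AY)
        dst = apply_field_transform(t0, pts)
        t, _ = fit_field_transform(list(zip(pts, dst)))
        qc = registration_residuals(t, list(zip(pts, dst)))
        assert qc.median_nm < 1e-6

    def test_constructed_offset_gives_exact_median(self):
        pts = grid_7x7()
        t = FieldTransform.identity()
        dst = pts.copy()
        dst[:, 1] += 10.0 / 178.0  # exactly 10 nm in y at spectral pixel size
        qc = registration_residuals(t, list(zip(pts, dst)), spectral_pixel_nm=178.0)
        assert qc.median_nm == pytest.approx(10.0, abs=1e-9)

    def test_empty_pairs_raise(self):
        with pytest.raises(ValueError):
            registration_residuals(FieldTransform.identity(), [])


class TestOffsetUpdate:
    def test_consistent_fiducial_leaves_transform_unchanged(self):
        t = FieldTransform(ax=RANDOM_CUBIC_AX.copy(), ay=RANDOM_CUBIC_AY.copy())
        p = (100.0, 200.0)
        q = tuple(apply_field_transform(t, p)[0])
        t2 = update_transform_offset(t, p, q, expected_distance_px=0.0)
        np.testing.assert_allclose(t2.ax, t.ax, atol=1e-12)
        np.testing.assert_allclose(t2.ay, t.ay, atol=1e-12)

    def test_session_shift_moves_only_zero_order(self):
        t = FieldTransform(ax=RANDOM_CUBIC_AX.copy(), ay=RANDOM_CUBIC_AY.copy())
        p = (100.0, 200.0)
        q = apply_field_transform(t, p)[0] + np.array([2.0, -1.0])
        t2 = update_transform_offset(t, p, tuple(q), expected_distance_px=0.0)
        assert t2.ax[9] - t.ax[9] == pytest.approx(2.0, abs=1e-12)
        assert t2.ay[9] - t.ay[9] == pytest.approx(-1.0, abs=1e-12)
        np.testing.assert_allclose(t2.ax[:9], t.ax[:9], atol=1e-15)
        np.testing.assert_allclose(t2.ay[:9], t.ay[:9], atol=1e-15)

    def test_random_shift_self_consistency(self):
        rng = np.random.default_rng(9)
        t = FieldTransform(ax=RANDOM_CUBIC_AX.copy(), ay=RANDOM_CUBIC_AY.copy())
        p = (80.0, 150.0)
        shift = rng.normal(0, 3, size=2)
        q = apply_field_transform(t, p)[0] + shift
        t2 = update_transform_offset(t, p, tuple(q), expected_distance_px=0.0)
        residual = apply_field_transform(t2, p)[0] - q
        np.testing.assert_allclose(residual, 0.0, atol=1e-9)

    def test_expected_distance_lands_fiducial_at_offset(self):
        t = FieldTransform.identity()
        p = (50.0, 60.0)
        q = (50.0, 69.69)  # spectral localization displaced along y
        t2 = update_transform_offset(t, p, q, expected_distance_px=9.69, dispersion_axis="y")
        mapped = apply_field_transform(t2, p)[0]
        assert q[1] - mapped[1] == pytest.approx(9.69, abs=1e-9)
        assert q[0] - mapped[0] == pytest.approx(0.0, abs=1e-9)


def _fiducial_table(n_frames, positions, noise_px, rng, dx=None, dy=None):
    records = []
    for f in range(n_frames):
        for x0, y0 in positions:
            x = x0 + (dx[f] if dx is not None else 0.0) + rng.normal(0, noise_px)
            y = y0 + (dy[f] if dy is not None else 0.0) + rng.normal(0, noise_px)
            records.append(
                LocalizationRecord(frame=f, x=x, y=y, sigma_x=1.3, sigma_y=1.3, photons=5000.0)
            )
    return LocalizationTable(records)


class TestDrift:
    def test_static_fiducial_gives_near_zero_trace(self):
        rng = np.random.default_rng(0)
        noise = 0.05
        table = _fiducial_table(500, [(20.0, 30.0)], noise, rng)
        trace = estimate_drift(table, smoothing_window=50)
        assert np.abs(trace.dx).max() < 3 * noise
        assert np.abs(trace.dy).max() < 3 * noise
        assert trace.dx[0] == 0.0 and trace.dy[0] == 0.0

    def test_linear_drift_endpoint_recovered(self):
        rng = np.random.default_rng(1)
        n = 1000
        dx = 0.01 * np.arange(n)
        table = _fiducial_table(n, [(20.0, 30.0)], 0.05, rng, dx=dx, dy=np.zeros(n))
        trace = estimate_drift(table, smoothing_window=50)
        assert trace.dx[-1] == pytest.approx(10.0, abs=0.5)
        assert abs(trace.dy[-1]) < 0.5

    def test_two_fiducials_average_reduces_variance(self):
        n = 600
        dx = 0.005 * np.arange(n)
        t1 = _fiducial_table(n, [(15.0, 15.0)], 0.08, np.random.default_rng(2), dx=dx, dy=np.zeros(n))
        t2 = _fiducial_table(n, [(15.0, 15.0), (45.0, 45.0)], 0.08, np.random.default_rng(2), dx=dx, dy=np.zeros(n))
        res1 = estimate_drift(t1, smoothing_window=1).dx - dx
        res2 = estimate_drift(t2, smoothing_window=1).dx - dx
        assert np.var(res2) < np.var(res1)

    def test_no_fiducial_raises(self):
        with pytest.raises(ValueError):
            estimate_drift(LocalizationTable())

    def test_zero_trace_is_identity(self, small_table):
        trace = DriftTrace(np.zeros(3), np.zeros(3))
        out = apply_drift_correction(small_table, trace)
        np.testing.assert_allclose(out.df["x"], small_table.df["x"])
        np.testing.assert_allclose(out.df["y"], small_table.df["y"])

    def test_constant_trace_shifts_coordinates_only(self, small_table):
        trace = DriftTrace(np.ones(3), np.ones(3))
        out = apply_drift_correction(small_table, trace)
        np.testing.assert_allclose(out.df["x"], small_table.df["x"] - 1.0)
        np.testing.assert_allclose(out.df["y"], small_table.df["y"] - 1.0)
        np.testing.assert_allclose(out.df["photons"], small_table.df["photons"])

    def test_uncovered_frame_raises(self, small_table):
        trace = DriftTrace(np.zeros(2), np.zeros(2))  # covers frames 0-1, table has 2
        with pytest.raises(ValueError):
            apply_drift_correction(small_table, trace)


class TestSerialization:
    def test_transform_file_round_trip(self, tmp_path):
        t = FieldTransform(ax=RANDOM_CUBIC_AX, ay=RANDOM_CUBIC_AY, reference_wavelength_nm=683.0)
        path = tmp_path / "transform.txt"
        save_field_transform(t, path)
        back = load_field_transform(path)
        np.testing.assert_allclose(back.ax, t.ax, rtol=1e-15)
        np.testing.assert_allclose(back.ay, t.ay, rtol=1e-15)
        assert back.reference_wavelength_nm == 683.0

    def test_drift_csv_round_trip(self, tmp_path):
        trace = DriftTrace(np.array([0.0, 0.1, 0.2]), np.array([0.0, -0.1, -0.2]))
        path = tmp_path / "drift.csv"
        trace.to_csv(path)
        back = DriftTrace.from_csv(path)
        np.testing.assert_allclose(back.dx, trace.dx)
        np.testing.assert_allclose(back.dy, trace.dy)
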