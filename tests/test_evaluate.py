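"""Dose-area metrics, trend fits, gamma analysis, registration, chamber dose."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcplan import evaluate, targets
from dcplan.evaluate import (
    central_axis_dose,
    depth_dta,
    dose_area_percentile,
    dose_from_text,
    dose_to_text,
    fit_depth_trend,
    gamma_pass_rate,
    rigid_register,
    rind_mean_dose_reduction,
)
from dcplan.optimize import DoseDistribution


def _dose(grid, spacing=0.5):
    grid = np.asarray(grid, dtype=float)
    ny, nx = grid.shape
    origin = (-(nx - 1) / 2 * spacing, -(ny - 1) / 2 * spacing)
    return DoseDistribution(grid=grid, spacing=spacing, origin=origin)


class TestDoseAreaPercentile:
    def test_constant_field(self, circle3):
        dose = _dose(np.full(circle3.mask.shape, 5.0))
        assert dose_area_percentile(dose, circle3.mask, 98.0) == 5.0
        assert dose_area_percentile(dose, circle3.mask, 2.0) == 5.0

    def test_matches_sort_oracle(self, rng):
        values = rng.uniform(0, 10, size=(20, 20))
        mask = np.ones((20, 20), dtype=bool)
        dose = _dose(values)
        flat = np.sort(values.ravel())
        for q in (98.0, 50.0, 2.0):
            oracle = np.quantile(flat, 1 - q / 100.0)
            assert dose_area_percentile(dose, mask, q) == pytest.approx(oracle)

    def test_half_and_half_median(self):
        grid = np.concatenate([np.zeros((5, 10)), np.full((5, 10), 10.0)])
        dose = _dose(grid)
        d50 = dose_area_percentile(dose, np.ones_like(grid, dtype=bool), 50.0)
        assert d50 == pytest.approx(np.quantile(grid.ravel(), 0.5))

    @given(
        q1=st.floats(1.0, 99.0),
        q2=st.floats(1.0, 99.0),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_coverage(self, q1, q2, seed):
        values = np.random.default_rng(seed).uniform(0, 5, size=(8, 8))
        dose = _dose(values)
        mask = np.ones_like(values, dtype=bool)
        lo, hi = sorted((q1, q2))
        assert dose_area_percentile(dose, mask, lo) >= dose_area_percentile(dose, mask, hi)

    def test_empty_mask_rejected(self, circle3):
        dose = _dose(np.zeros(circle3.mask.shape))
        with pytest.raises(ValueError):
            dose_area_percentile(dose, np.zeros_like(circle3.mask), 50.0)


class TestRindReduction:
    def test_identical_doses_give_zero(self, circle3):
        rind = targets.make_rind(circle3, 10.0)
        dose = _dose(np.full(circle3.mask.shape, 2.0))
        assert rind_mean_dose_reduction(dose, dose, rind, 5.0) == 0.0

    def test_pointwise_lower_dose_gives_nonnegative(self, circle3, rng):
        rind = targets.make_rind(circle3, 10.0)
        u = rng.uniform(0, 3, size=circle3.mask.shape)
        c = u * rng.uniform(0, 1, size=u.shape)
        red = rind_mean_dose_reduction(_dose(u), _dose(c), rind, 5.0)
        assert red >= 0

    def test_hand_computed_oracle(self):
        parent = targets.TargetGeometry(
            mask=np.pad(np.ones((1, 1), dtype=bool), 2),
            spacing=1.0,
            origin=(-2.0, -2.0),
            shape_label="pixel",
        )
        rind_mask = np.zeros((5, 5), dtype=bool)
        rind_mask[1:4, 1:4] = True
        rind_mask[2, 2] = False
        rind = targets.RindRegion(mask=rind_mask, width=1.0, parent=parent)
        u = np.full((5, 5), 2.0)
        c = np.full((5, 5), 1.25)
        red = rind_mean_dose_reduction(_dose(u, 1.0), _dose(c, 1.0), rind, 5.0)
        assert red == pytest.approx(100.0 * (2.0 - 1.25) / 5.0)


class TestTrendFit:
    def test_exact_line(self):
        fit = fit_depth_trend([(5, 40.0), (10, 30.0), (15, 20.0)], "linear")
        assert fit.slope_pct_per_cm == pytest.approx(-2.0)
        assert fit.zero_crossing_depth == pytest.approx(25.0)

    def test_noisy_slope_within_two_se(self, rng):
        depths = np.arange(5.0, 25.0, 2.5)
        truth = -1.5
        noise = rng.normal(0, 0.8, size=depths.size)
        series = list(zip(depths, 50.0 + truth * depths + noise))
        fit = fit_depth_trend(series, "linear")
        x = depths - depths.mean()
        resid = np.array([r for _, r in series]) - np.polyval(fit.coefficients, depths)
        se = math.sqrt(resid.var(ddof=2) / (x**2).sum())
        assert abs(fit.slope_pct_per_cm - truth) < 2 * se + 1e-9

    def test_no_crossing_reported_when_curve_stays_positive(self):
        fit = fit_depth_trend([(5, 10.0), (10, 10.0), (15, 10.0)], "linear")
        assert fit.zero_crossing_depth is None

    def test_quadratic_needs_four_points(self):
        with pytest.raises(ValueError):
            fit_depth_trend([(5, 4.0), (10, 3.0), (15, 1.0)], "poly2")

    def test_quadratic_crossing(self):
        pts = [(d, 50.0 - 0.1 * d**2) for d in (5.0, 8.0, 12.0, 15.0)]
        fit = fit_depth_trend(pts, "poly2")
        assert fit.zero_crossing_depth == pytest.approx(math.sqrt(500.0), rel=1e-6)


def _brute_force_gamma_pass_rate(ref, ev, crit, dta, threshold):
    """Exhaustive oracle: gamma over every fine-lattice pair."""
    from scipy.interpolate import RegularGridInterpolator

    ref_max = ref.grid.max()
    norm = crit / 100.0 * ref_max
    fine = ref.spacing / 5.0
    nx = int(round((ref.x_coords[-1] - ref.x_coords[0]) / fine)) + 1
    ny = int(round((ref.y_coords[-1] - ref.y_coords[0]) / fine)) + 1
    x = np.linspace(ref.x_coords[0], ref.x_coords[-1], nx)
    y = np.linspace(ref.y_coords[0], ref.y_coords[-1], ny)
    interp = RegularGridInterpolator((ref.y_coords, ref.x_coords), ev.grid)
    xx, yy = np.meshgrid(x, y)
    ev_fine = interp((yy, xx))
    passed = total = 0
    for iy, ry in enumerate(ref.y_coords):
        for ix, rx in enumerate(ref.x_coords):
            rv = ref.grid[iy, ix]
            if rv < threshold / 100.0 * ref_max:
                continue
            total += 1
            dist2 = (xx - rx) ** 2 + (yy - ry) ** 2
            g2 = ((ev_fine - rv) / norm) ** 2 + dist2 / dta**2
            if g2.min() <= 1.0:
                passed += 1
    return 100.0 * passed / total


class TestGamma:
    def test_identical_distributions_pass_fully(self, rng):
        grid = rng.uniform(1, 5, size=(11, 11))
        dose = _dose(grid)
        for crit, dta in ((3.0, 3.0), (3.0, 2.0), (2.0, 2.0)):
            assert gamma_pass_rate(dose, dose, crit, dta).pass_rate == 100.0

    def test_global_two_percent_scaling_passes_three_percent(self):
        # gradient-free field: no spatial trade-off, so gamma is exactly the
        # normalized dose error of 2/3 at every node
        grid = np.full((21, 21), 5.0)
        ref = _dose(grid, spacing=1.0)
        ev = _dose(grid * 1.02, spacing=1.0)
        result = gamma_pass_rate(ref, ev, 3.0, 2.0)
        assert result.pass_rate == 100.0
        assert np.allclose(result.gamma_map, 2.0 / 3.0, atol=1e-9)

    @pytest.mark.parametrize("seed", [1, 7])
    @pytest.mark.parametrize("crit,dta", [(3.0, 2.0), (2.0, 2.0)])
    def test_matches_brute_force_oracle(self, seed, crit, dta):
        rng = np.random.default_rng(seed)
        base = rng.uniform(2, 5, size=(11, 11))
        ref = _dose(base, spacing=1.0)
        ev = _dose(base * rng.uniform(0.95, 1.05, size=base.shape), spacing=1.0)
        ours = gamma_pass_rate(ref, ev, crit, dta, threshold=10.0).pass_rate
        oracle = _brute_force_gamma_pass_rate(ref, ev, crit, dta, 10.0)
        assert ours == pytest.approx(oracle, abs=1e-9)

    def test_looser_criteria_never_fail_more(self, rng):
        base = rng.uniform(2, 5, size=(15, 15))
        ref = _dose(base, spacing=1.0)
        ev = _dose(base * rng.uniform(0.9, 1.1, size=base.shape), spacing=1.0)
        tight = gamma_pass_rate(ref, ev, 2.0, 2.0).pass_rate
        mid = gamma_pass_rate(ref, ev, 3.0, 2.0).pass_rate
        loose = gamma_pass_rate(ref, ev, 3.0, 3.0).pass_rate
        assert loose >= mid >= tight

    def test_relative_mode_ignores_global_scale(self, rng):
        xx, yy = np.meshgrid(np.linspace(-10, 10, 21), np.linspace(-10, 10, 21))
        grid = 5.0 * np.exp(-(xx**2 + yy**2) / 60.0)
        ref = _dose(grid, spacing=1.0)
        ev = _dose(grid * 1.30, spacing=1.0)
        assert gamma_pass_rate(ref, ev, 3.0, 2.0, mode="absolute").pass_rate < 100.0
        assert gamma_pass_rate(ref, ev, 3.0, 2.0, mode="relative").pass_rate == 100.0

    def test_empty_analysis_region_rejected(self):
        ref = _dose(np.zeros((5, 5)))
        with pytest.raises(ValueError):
            gamma_pass_rate(ref, ref, 3.0, 2.0)


@pytest.fixture(scope="module")
def blob():
    n = 101
    x = (np.arange(n) - (n - 1) / 2) * 0.5
    xx, yy = np.meshgrid(x, x)
    grid = 5.0 * np.exp(-(xx**2 + (yy / 1.4) ** 2) / (2 * 7.0**2))
    return DoseDistribution(grid=grid, spacing=0.5, origin=(x[0], x[0]))


class TestRegistration:
    def _resample(self, dose, dx, dy, rot_deg):
        # displace the image by (dx, dy, rot): measured(x) = sim(R^-1 (x - t)),
        # so registering measured against sim recovers exactly (dx, dy, rot)
        th = math.radians(rot_deg)
        c, s = math.cos(th), math.sin(th)
        xx, yy = np.meshgrid(dose.x_coords, dose.y_coords)
        interp = dose.interpolator()
        qx = c * (xx - dx) + s * (yy - dy)
        qy = -s * (xx - dx) + c * (yy - dy)
        vals = interp((qy, qx))
        return DoseDistribution(
            grid=np.nan_to_num(vals, nan=0.0),
            spacing=dose.spacing,
            origin=dose.origin,
        )

    def test_identity(self, blob):
        dx, dy, rot = rigid_register(blob, blob)
        assert abs(dx) < 0.05 and abs(dy) < 0.05 and abs(rot) < 0.05

    def test_recovers_translation(self, blob):
        measured = self._resample(blob, 3.8, -2.0, 0.0)
        dx, dy, rot = rigid_register(measured, blob)
        assert dx == pytest.approx(3.8, abs=0.25)
        assert dy == pytest.approx(-2.0, abs=0.25)

    def test_recovers_rotation(self, blob):
        measured = self._resample(blob, 0.0, 0.0, 2.0)
        dx, dy, rot = rigid_register(measured, blob)
        assert rot == pytest.approx(2.0, abs=0.25)

    def test_constant_image_rejected(self, blob):
        flat = DoseDistribution(
            grid=np.ones_like(blob.grid), spacing=blob.spacing, origin=blob.origin
        )
        with pytest.raises(ValueError):
            rigid_register(flat, blob)


class TestCentralAxisDose:
    def test_uniform_field(self):
        dose = _dose(np.full((41, 41), 3.3), spacing=0.5)
        assert central_axis_dose(dose, 10.0) == pytest.approx(3.3)

    def test_linear_gradient_cancels(self):
        x = (np.arange(41) - 20) * 0.5
        grid = 5.0 + 0.1 * np.meshgrid(x, x)[0]
        dose = _dose(grid, spacing=0.5)
        assert central_axis_dose(dose, 8.0) == pytest.approx(5.0)

    def test_matches_masked_mean_oracle(self, rng):
        grid = rng.uniform(0, 4, size=(41, 41))
        dose = _dose(grid, spacing=0.5)
        x = dose.x_coords
        xx, yy = np.meshgrid(x, dose.y_coords)
        mask = xx**2 + yy**2 <= 5.0**2
        assert central_axis_dose(dose, 10.0) == pytest.approx(grid[mask].mean())

    def test_oversized_footprint_rejected(self):
        dose = _dose(np.ones((11, 11)), spacing=0.5)
        with pytest.raises(ValueError):
            central_axis_dose(dose, 20.0)


def test_depth_dta_picks_smallest_best_offset(blob):
    planes = {
        0.0: blob,
        1.0: blob,
        -2.0: DoseDistribution(
            grid=blob.grid * 1.5, spacing=blob.spacing, origin=blob.origin
        ),
    }
    off, rate = depth_dta(blob, planes, 3.0, 2.0)
    assert off == 0.0
    assert rate == 100.0


def test_dose_text_round_trip(tmp_path, blob):
    path = tmp_path / "dose.txt"
    dose_to_text(blob, path)
    back = dose_from_text(path)
    assert back.spacing == blob.spacing
    assert back.origin == pytest.approx(blob.origin)
    assert np.allclose(back.grid, blob.grid, rtol=1e-5, atol=1e-8)
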