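import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrmsquant.calibration import (
    CalibrationCurve,
    CalibrationLevel,
    Chromatogram,
    CurveMode,
    assign_lod,
    assign_loq,
    estimate_snr,
    fit_curve,
    quantify,
)
from hrmsquant.simulate import simulate_chromatogram


def levels_from_points(points):
    return [CalibrationLevel(x, (y,)) for x, y in points]


def ols_oracle(x, y):
    """Normal equations by hand (independent of the fit implementation)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    pred = slope * x + intercept
    ss_res = ((y - pred) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    return slope, intercept, 1 - ss_res / ss_tot


class TestFitCurve:
    def test_exact_line(self):
        curve = fit_curve(levels_from_points([(1, 2), (2, 4), (5, 10)]))
        assert curve.slope == pytest.approx(2.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.linearity_pass

    def test_three_point_closed_form(self):
        # x=[0,1,2], y=[1,2,2]: slope 1/2, intercept 7/6, R^2 = 3/4
        curve = fit_curve(levels_from_points([(0, 1), (1, 2), (2, 2)]))
        assert curve.slope == pytest.approx(0.5)
        assert round(curve.intercept, 4) == 1.1667
        assert curve.r_squared == pytest.approx(0.75)
        assert not curve.linearity_pass

    def test_r2_forced_to_0985_fails_gate(self):
        # Residual pattern [1,-2,1] is orthogonal to both the constant and
        # x=[0,1,2], so it changes SS_res without moving the fitted line.
        # R^2 = 1 - 6c^2/(2 + 6c^2) = 0.985 at c below.
        c = math.sqrt(2 * 0.015 / (0.985 * 6))
        y = np.array([1.0, 2.0, 3.0]) + c * np.array([1.0, -2.0, 1.0])
        curve = fit_curve(levels_from_points(list(zip([0, 1, 2], y))))
        assert curve.r_squared == pytest.approx(0.985, abs=1e-12)
        assert not curve.linearity_pass

    def test_replicates_averaged_per_level(self):
        curve = fit_curve(
            [
                CalibrationLevel(1.0, (1.5, 2.5)),
                CalibrationLevel(2.0, (4.0, 4.0)),
                CalibrationLevel(3.0, (5.0, 7.0)),
            ]
        )
        assert curve.slope == pytest.approx(2.0)

    def test_fewer_than_three_distinct_levels(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_curve(levels_from_points([(1, 2), (1, 3), (1, 4)]))

    @settings(max_examples=100)
    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0.0, max_value=250.0),
                st.floats(min_value=-1e4, max_value=1e6),
            ),
            min_size=3,
            max_size=10,
        ).filter(lambda pts: len({round(p[0], 6) for p in pts}) >= 3)
    )
    def test_matches_normal_equations(self, points):
        x = [p[0] for p in points]
        y = [p[1] for p in points]
        slope, intercept, _ = ols_oracle(x, y)
        curve = fit_curve(levels_from_points(points))
        assert curve.slope == pytest.approx(slope, rel=1e-8, abs=1e-8)
        assert curve.intercept == pytest.approx(intercept, rel=1e-8, abs=1e-6)


class TestQuantify:
    @pytest.fixture
    def line(self):
        return CalibrationCurve(
            mode=CurveMode.MATRIX_MATCHED, slope=1000.0, intercept=0.0, r_squared=1.0
        )

    def test_simple(self, line):
        assert quantify(50000.0, line).concentration == pytest.approx(50.0)

    def test_dilution_factor(self, line):
        assert quantify(50000.0, line, dilution_factor=10).concentration == pytest.approx(500.0)

    def test_below_intercept_clamps(self):
        curve = CalibrationCurve(
            mode=CurveMode.MATRIX_MATCHED, slope=1000.0, intercept=500.0, r_squared=1.0
        )
        res = quantify(100.0, curve)
        assert res.concentration == 0.0 and res.below_curve

    def test_clamp_can_be_disabled(self):
        curve = CalibrationCurve(
            mode=CurveMode.MATRIX_MATCHED, slope=1000.0, intercept=500.0, r_squared=1.0
        )
        res = quantify(100.0, curve, clamp=False)
        assert res.concentration == pytest.approx(-0.4) and res.below_curve

    def test_zero_slope(self):
        curve = CalibrationCurve(
            mode=CurveMode.SOLVENT, slope=0.0, intercept=0.0, r_squared=0.0
        )
        with pytest.raises(ZeroDivisionError):
            quantify(10.0, curve)

    @given(
        slope=st.floats(min_value=1.0, max_value=1e4),
        intercept=st.floats(min_value=-1e3, max_value=1e3),
        conc=st.floats(min_value=0.0, max_value=1e3),
        df=st.floats(min_value=1.0, max_value=100.0),
        tf=st.floats(min_value=0.1, max_value=10.0),
    )
    def test_roundtrip_identity(self, slope, intercept, conc, df, tf):
        curve = CalibrationCurve(
            mode=CurveMode.MATRIX_MATCHED, slope=slope, intercept=intercept, r_squared=1.0
        )
        area = slope * (conc * tf / df) + intercept
        if area < 0:
            return
        assert quantify(area, curve, df, tf).concentration == pytest.approx(conc, abs=1e-6)


def flat_trace_with_peak():
    times = tuple(np.linspace(0.0, 1.0, 21).tolist())
    y = [0.0] * 21
    y[5] = 300.0  # apex inside (0.2, 0.3)
    # noise window (0.53, 0.77): values with median 0 and sample SD exactly 100
    y[11:16] = [-100.0, -100.0, 0.0, 100.0, 100.0]
    return Chromatogram(times=times, intensities=tuple(y))


class TestEstimateSnr:
    def test_apex_over_known_noise(self):
        chrom = flat_trace_with_peak()
        snr = estimate_snr(chrom, (0.0, 0.45), (0.53, 0.77))
        assert snr == pytest.approx(3.0)

    def test_constant_shift_invariance(self):
        chrom = flat_trace_with_peak()
        shifted = Chromatogram(
            times=chrom.times, intensities=tuple(v + 1234.5 for v in chrom.intensities)
        )
        assert estimate_snr(shifted, (0.0, 0.45), (0.53, 0.77)) == pytest.approx(
            estimate_snr(chrom, (0.0, 0.45), (0.53, 0.77))
        )

    def test_zero_variance_errors(self):
        chrom = Chromatogram(
            times=tuple(np.linspace(0, 1, 20).tolist()), intensities=(5.0,) * 20
        )
        with pytest.raises(ValueError, match="zero noise variance"):
            estimate_snr(chrom, (0.0, 0.45), (0.5, 1.0))

    def test_overlapping_windows_rejected(self):
        chrom = flat_trace_with_peak()
        with pytest.raises(ValueError, match="disjoint"):
            estimate_snr(chrom, (0.0, 0.6), (0.5, 1.0))

    def test_too_few_points_rejected(self):
        chrom = flat_trace_with_peak()
        with pytest.raises(ValueError, match="at least 5"):
            estimate_snr(chrom, (0.19, 0.21), (0.5, 1.0))

    def test_monte_carlo_height500_noise50(self):
        # apex-max estimator carries a positive bias of roughly one noise SD,
        # so the expected mean is ~11, inside the 10 +/- 2 band
        rt, w = 1.0, 0.02
        grid = np.arange(0.75, 1.25, 0.005)
        snrs = [
            estimate_snr(
                simulate_chromatogram(rt, 500.0, w, 50.0, grid, seed),
                (rt - 3 * w, rt + 3 * w),
                (rt + 6 * w, 1.25),
            )
            for seed in range(100)
        ]
        assert abs(float(np.mean(snrs)) - 10.0) <= 2.0


class TestAssignLod:
    def test_rule_application(self):
        assert assign_lod([(0.5, 1.2), (1.0, 3.4), (5.0, 17.0)]) == 1.0

    def test_none_qualify(self):
        assert assign_lod([(0.5, 1.0), (1.0, 2.0)]) is None

    def test_boundary_inclusive(self):
        assert assign_lod([(1.0, 3.0)]) == 1.0

    def test_empty_input(self):
        with pytest.raises(ValueError):
            assign_lod([])

    def test_duplicate_nominals(self):
        with pytest.raises(ValueError, match="distinct"):
            assign_lod([(1.0, 3.0), (1.0, 4.0)])


class TestAssignLoq:
    def test_rule_application(self):
        # CVs: 2.5 -> 28.3%, 5.0 -> 14.1%, 12.5 -> 5.7%
        measurements = {
            2.5: [2.0, 3.0],
            5.0: [4.5, 5.5],
            12.5: [12.0, 13.0],
        }
        assert assign_loq(measurements) == 5.0

    def test_all_above_limit(self):
        assert assign_loq({2.5: [1.0, 4.0], 5.0: [2.0, 8.0]}) is None

    def test_boundary_exactly_20_percent_qualifies(self):
        # {8, 10, 12}: mean 10, sample SD exactly 2 -> CV exactly 20%
        assert assign_loq({5.0: [8.0, 10.0, 12.0]}) == 5.0

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match=">=2 replicates"):
            assign_loq({5.0: [5.0]})
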