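import math

import numpy as np
import pandas as pd
import pytest

from hrmsquant.calibration import CurveMode, estimate_snr
from hrmsquant.simulate import (
    AnalyteSimParams,
    noise_factors,
    simulate_chromatogram,
    simulate_peak_table,
    simulate_validation_campaign,
)
from hrmsquant.workflow import analyze_campaign


class TestNoiseFactors:
    def test_zero_cv_is_ones(self):
        assert np.all(noise_factors(np.random.default_rng(0), 0.0, 10) == 1.0)

    def test_mean_and_sd_match_cv(self):
        f = noise_factors(np.random.default_rng(0), 0.1, 200_000)
        assert np.mean(f) == pytest.approx(1.0, abs=0.002)
        assert np.std(f) == pytest.approx(0.1, abs=0.003)

    def test_floored_above_zero(self):
        f = noise_factors(np.random.default_rng(0), 1.5, 100_000)
        assert np.all(f >= 0.01)


class TestSimParams:
    def test_invalid_recovery(self):
        with pytest.raises(ValueError, match="recovery"):
            AnalyteSimParams("x", slope=100.0, recovery=1.6)

    def test_invalid_matrix_effect(self):
        with pytest.raises(ValueError, match="matrix effect"):
            AnalyteSimParams("x", slope=100.0, matrix_effect=-1.0)


class TestSimulatePeakTable:
    def test_zero_noise_areas_exact(self, make_config):
        cfg = make_config(
            3,
            noise_cv=0.0,
            mz_jitter_ppm=0.0,
            analytes=tuple(
                AnalyteSimParams(a.name, a.slope, recovery=1.0, matrix_effect=0.0)
                for a in make_config(3).analytes
            ),
        )
        frame, truth = simulate_peak_table(cfg, concentrations=[10.0, 50.0])
        slopes = {a.name: a.slope for a in cfg.analytes}
        for row in frame.itertuples():
            conc = truth.true_conc[(row.sample_id, row.analyte_hint)]
            assert row.area == pytest.approx(slopes[row.analyte_hint] * conc)

    def test_same_seed_identical(self, make_config):
        f1, _ = simulate_peak_table(make_config(42))
        f2, _ = simulate_peak_table(make_config(42))
        pd.testing.assert_frame_equal(f1, f2)

    def test_different_seeds_differ(self, make_config):
        f1, _ = simulate_peak_table(make_config(1))
        f2, _ = simulate_peak_table(make_config(2))
        assert not f1["area"].equals(f2["area"])

    def test_dilution_scales_area(self, make_config):
        cfg = make_config(5, noise_cv=0.0)
        f1, _ = simulate_peak_table(cfg, concentrations=[100.0])
        f10, _ = simulate_peak_table(cfg, concentrations=[100.0], dilution_factor=10.0)
        assert np.allclose(f10["area"], f1["area"] / 10.0)

    def test_negative_concentration_rejected(self, make_config):
        with pytest.raises(ValueError):
            simulate_peak_table(make_config(1), concentrations=[-1.0])


class TestSimulateChromatogram:
    def test_noiseless_apex_at_rt(self):
        grid = np.arange(0.5, 1.5001, 0.005)  # contains t = 1.0 exactly
        chrom = simulate_chromatogram(1.0, 300.0, 0.02, 0.0, grid, 0)
        y = np.asarray(chrom.intensities)
        t = np.asarray(chrom.times)
        assert y.max() == pytest.approx(300.0)
        assert t[int(np.argmax(y))] == pytest.approx(1.0)

    def test_numeric_area_matches_gaussian_integral(self):
        h, sd = 500.0, 0.02
        grid = np.arange(0.5, 1.5, 0.002)
        chrom = simulate_chromatogram(1.0, h, sd, 0.0, grid, 0)
        area = np.trapezoid(chrom.intensities, chrom.times)
        assert area == pytest.approx(h * sd * math.sqrt(2 * math.pi), rel=0.005)

    def test_grid_not_covering_peak_rejected(self):
        grid = np.arange(0.95, 1.05, 0.001)  # +/- 2.5 widths only
        with pytest.raises(ValueError, match="cover"):
            simulate_chromatogram(1.0, 300.0, 0.02, 0.0, grid, 0)

    def test_coarse_grid_rejected(self):
        grid = np.arange(0.0, 2.0, 0.05)  # 2-3 points across the peak
        with pytest.raises(ValueError, match="too coarse"):
            simulate_chromatogram(1.0, 300.0, 0.02, 0.0, grid, 0)

    def test_snr_monte_carlo_height300(self):
        # apex-max read biases S/N upward by ~1-1.5 noise SDs above the
        # nominal height/noise ratio of 3
        rt, w = 1.0, 0.02
        grid = np.arange(0.75, 1.25, 0.005)
        snrs = [
            estimate_snr(
                simulate_chromatogram(rt, 300.0, w, 100.0, grid, seed),
                (rt - 3 * w, rt + 3 * w),
                (rt + 6 * w, 1.25),
            )
            for seed in range(100)
        ]
        assert 3.0 <= float(np.mean(snrs)) <= 5.5


class TestValidationCampaign:
    def test_deterministic_regeneration(self, make_config):
        b1 = simulate_validation_campaign(make_config(7))
        b2 = simulate_validation_campaign(make_config(7))
        name = b1.config.analytes[0].name
        assert np.array_equal(b1.spike_areas[name], b2.spike_areas[name])
        assert np.array_equal(b1.mrl_fortified_areas[name], b2.mrl_fortified_areas[name])
        assert b1.curve_levels == b2.curve_levels
        assert np.array_equal(b1.incurred_areas, b2.incurred_areas)

    def test_zero_noise_campaign_is_exact(self, make_config):
        cfg = make_config(9, noise_cv=0.0)
        outcome = analyze_campaign(simulate_validation_campaign(cfg))
        params = {a.name: a for a in cfg.analytes}
        mrls = {t.name: t.mrl for t in cfg.targets}
        for rec in outcome.records:
            p = params[rec.analyte]
            assert rec.r_squared == pytest.approx(1.0)
            assert rec.sensitivity == pytest.approx(
                p.slope * (1 + p.matrix_effect) * p.recovery, rel=1e-9
            )
            for lv, (mean_rec, cv) in rec.recovery_pct.items():
                assert mean_rec == pytest.approx(100.0 * p.recovery, rel=1e-9)
                assert cv == pytest.approx(0.0, abs=1e-9)
            for me_lv, me in rec.matrix_effect_pct.items():
                assert me == pytest.approx(100.0 * p.matrix_effect, rel=1e-9, abs=1e-9)
            for cv in list(rec.intraday_cv.values()) + list(rec.interday_cv.values()):
                assert cv == pytest.approx(0.0, abs=1e-9)
            assert rec.cc_alpha == pytest.approx(mrls[rec.analyte])
            assert rec.cc_beta == pytest.approx(rec.cc_alpha)
            assert rec.loq == 5.0

    def test_campaign_cvs_in_plausible_band(self, make_config):
        # 10% multiplicative noise: interday CVs land in a realistic band
        outcome = analyze_campaign(simulate_validation_campaign(make_config(21, noise_cv=0.10)))
        cvs = [cv for rec in outcome.records for cv in rec.interday_cv.values()]
        # calibration intercept error occasionally wrecks the lowest level
        # for the least sensitive analytes; the bulk sits in a Table-like band
        assert np.mean([0.0 < cv < 40.0 for cv in cvs]) >= 0.9
        assert 3.0 < float(np.median(cvs)) < 20.0

    def test_dilution_roundtrip_high_concentration(self, make_config):
        from hrmsquant.calibration import quantify

        cfg = make_config(13, noise_cv=0.05)
        bundle = simulate_validation_campaign(cfg)
        outcome = analyze_campaign(bundle)
        mm = outcome.curves[bundle.incurred_analyte][CurveMode.MATRIX_MATCHED.value]
        concs = [
            quantify(a, mm, dilution_factor=bundle.incurred_dilution).concentration
            for a in bundle.incurred_areas
        ]
        assert np.mean(concs) == pytest.approx(cfg.incurred_conc, rel=0.10)

    def test_recovery_parameter_recovery_monte_carlo(self, make_config):
        # single-analyte view: mean estimated recovery over 40 campaigns
        # approaches the configured truth
        means = []
        for seed in range(40):
            cfg = make_config(500 + seed, noise_cv=0.05)
            outcome = analyze_campaign(simulate_validation_campaign(cfg))
            rec = next(r for r in outcome.records if r.analyte == "trimethoprim")
            means.append(np.mean([v[0] for v in rec.recovery_pct.values()]))
        grand = float(np.mean(means))
        se = float(np.std(means, ddof=1) / math.sqrt(len(means)))
        assert abs(grand - 90.6) <= max(3 * se, 1.5)
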