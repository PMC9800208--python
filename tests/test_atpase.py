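"""ATPase analysis: standard curve, rate extraction, MM fit, metrics."""

import numpy as np
import pytest

from myocycle import atpase
from myocycle.atpase import (
    ActivityPoint,
    extract_rate,
    fit_michaelis_menten,
    fit_nadh_standard,
    subtract_basal,
)
from myocycle.core import Trace
from myocycle.report import cycle_metric_table
from myocycle.simkit import make_atpase_plate


class TestNadhStandard:
    def test_exact_line_recovers_slope(self):
        conc = np.array([1.0, 0.5, 0.25, 0.125])   # mM; 20 uL -> nmol = 20c
        au = conc * 20.0 / 250.0                   # slope exactly 250 nmol/AU
        std = fit_nadh_standard(conc, au, well_volume_uL=20.0)
        assert std.conversion_factor == pytest.approx(250.0)
        assert std.r_squared == pytest.approx(1.0)

    def test_noisy_dilution_series_slope_within_3pct(self):
        rng = np.random.default_rng(11)
        conc = 1.0 * 0.5 ** np.arange(8)           # 1 -> 0.0078 mM
        au = conc * 1.6
        au = au * (1 + rng.normal(0, 0.01, au.shape))
        std = fit_nadh_standard(conc, au, well_volume_uL=20.0)
        assert std.conversion_factor == pytest.approx(20.0 / 1.6, rel=0.03)

    def test_protocol_range_accepted(self):
        conc = 1.0 * 0.5 ** np.arange(8)
        std = fit_nadh_standard(conc, conc * 1.5)
        assert std.conversion_factor > 0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_nadh_standard([1.0, 0.5], [0.3, 0.2])
        with pytest.raises(ValueError, match="rank"):
            fit_nadh_standard([1.0, 0.5, 0.25], [0.3, 0.3, 0.3])


class TestExtractRate:
    def _standard(self):
        conc = 1.0 * 0.5 ** np.arange(6)
        return fit_nadh_standard(conc, conc * 1.555, well_volume_uL=20.0)

    def test_exact_linear_trace(self):
        std = self._standard()
        t = np.arange(0, 3600.0, 30.0)
        slope = -2e-4                             # AU/s
        trace = Trace(t, 1.5 + slope * t)
        ext = extract_rate(trace, std, myosin_conc=0.4)
        expected = -slope * std.conversion_factor / (0.4 * 20.0 / 1000.0)
        assert ext.rate == pytest.approx(expected, rel=1e-3)
        assert not ext.rejected

    def test_depletion_curvature_uses_initial_slope(self):
        # NADH runs out midway: the early linear segment sets the rate
        std = self._standard()
        t = np.arange(0, 3600.0, 30.0)
        slope = -6e-4
        y = np.maximum(1.5 + slope * t, 0.05)
        ext = extract_rate(Trace(t, y), std, myosin_conc=0.4)
        expected = -slope * std.conversion_factor / (0.4 * 20.0 / 1000.0)
        assert ext.rate == pytest.approx(expected, rel=1e-3)
        assert ext.window[1] <= np.searchsorted(t, 2420) + 1

    def test_short_trace_rejected(self):
        std = self._standard()
        with pytest.raises(ValueError):
            extract_rate(Trace(np.arange(5.0), np.ones(5)), std, 0.4)


class TestSubtractBasal:
    def test_zero_basal_is_identity(self):
        pts = [ActivityPoint(10.0, 0.5)]
        out = subtract_basal(pts, 0.0)
        assert out[0].rate == 0.5 and out[0].basal_subtracted

    def test_arithmetic(self):
        pts = [ActivityPoint(10.0, 0.5), ActivityPoint(50.0, 0.9)]
        out = subtract_basal(pts, 0.1)
        assert [p.rate for p in out] == pytest.approx([0.4, 0.8])

    def test_double_subtraction_rejected(self):
        pts = subtract_basal([ActivityPoint(10.0, 0.5)], 0.1)
        with pytest.raises(ValueError, match="double"):
            subtract_basal(pts, 0.1)


class TestMichaelisMenten:
    def _points(self, kcat, Km, concs):
        return [ActivityPoint(a, kcat * a / (Km + a)) for a in concs]

    def test_noiseless_recovery_python_parameterization(self):
        fit = fit_michaelis_menten(
            self._points(0.60, 79.3, [10, 20, 40, 80, 160, 320]))
        assert fit.kcat == pytest.approx(0.60, rel=1e-3)
        assert fit.Km == pytest.approx(79.3, rel=1e-3)
        assert not fit.rejected

    def test_half_saturation_on_fitted_curve(self):
        fit = fit_michaelis_menten(
            self._points(0.8, 30.0, [5, 15, 30, 60, 120]))
        assert fit.kcat * fit.Km / (fit.Km + fit.Km) == pytest.approx(
            fit.kcat / 2)

    def test_grid_search_agrees_with_optimizer(self):
        pts = self._points(0.9, 40.0, [8, 20, 50, 110, 250])
        rng = np.random.default_rng(5)
        for p in pts:
            p.rate += rng.normal(0, 0.02)
        fit = fit_michaelis_menten(pts)
        a = np.array([p.actin_conc for p in pts])
        r = np.array([p.rate for p in pts])

        def sse(kcat, Km):
            return np.sum((r - kcat * a / (Km + a)) ** 2)

        grid = min(sse(kc, km)
                   for kc in np.linspace(0.5, 1.5, 200)
                   for km in np.linspace(10, 100, 200))
        assert sse(fit.kcat, fit.Km) <= grid + 1e-12

    def test_fitted_curve_monotone_saturating(self):
        fit = fit_michaelis_menten(
            self._points(0.7, 50.0, [10, 30, 60, 120, 240]))
        a = np.linspace(1, 1000, 500)
        curve = fit.kcat * a / (fit.Km + a)
        assert np.all(np.diff(curve) > 0)
        assert curve[-1] < fit.kcat

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError):
            fit_michaelis_menten(self._points(0.8, 30.0, [10, 20, 40]))

    def test_unidentifiable_fit_flagged(self):
        # all concentrations far below Km: kcat/Km only jointly identified
        fit = fit_michaelis_menten(
            self._points(0.8, 5000.0, [1, 2, 4, 8, 16]))
        assert fit.rejected


class TestUnitAudit:
    def test_rate_invariant_under_consistent_rescaling(self):
        base, scaled = [], []
        for myo, vol in [(0.4, 20.0), (0.8, 10.0)]:
            ds = make_atpase_plate(0.8, 35.9, 0.03, [20.0, 60.0],
                                   myosin_conc=myo, noise_sd=0.0, seed=1,
                                   well_volume_uL=vol)
            std = fit_nadh_standard(
                ds.observables["standards"]["conc_mM"],
                ds.observables["standards"]["absorbance"], vol)
            t = ds.observables["wells"]["time_s"].to_numpy()
            rates = [extract_rate(
                Trace(t, ds.observables["wells"][w].to_numpy()), std, myo,
                vol).rate for w in ("actin_20", "actin_60")]
            (base if myo == 0.4 else scaled).append(rates)
        # small window-boundary differences under NADH depletion are allowed
        assert np.allclose(base, scaled, rtol=5e-3)


class TestCycleMetrics:
    def test_beta_cycle_time_rounds_to_point_six(self):
        table, _ = cycle_metric_table({"beta": (1.57, 93.4)})
        assert round(table.loc["beta", "t_cycle"], 1) == 0.6

    def test_kcat_pair_percent_decrease(self):
        _, pairs = cycle_metric_table({"beta": (1.57, 93.4),
                                       "human": (0.80, 35.9)})
        row = pairs[(pairs.metric == "kcat")].iloc[0]
        assert row.reference == "beta"
        assert round(row.pct_decrease) == 49

    def test_identical_fits_zero_difference(self):
        _, pairs = cycle_metric_table({"a": (0.8, 30.0), "b": (0.8, 30.0)})
        assert np.allclose(pairs.pct_decrease, 0.0)
        assert np.allclose(pairs.ratio, 1.0)

    def test_zero_kcat_rejected(self):
        with pytest.raises(ValueError):
            cycle_metric_table({"a": (0.0, 30.0)})


def test_parameter_recovery_study_small():
    """Median kcat error < 5% over seeded noisy plates (reduced study)."""
    errs, cover = [], []
    for seed in range(20):
        ds = make_atpase_plate(0.80, 35.9, 0.03,
                               [10, 15, 20, 30, 45, 60, 80, 100],
                               noise_sd=0.001, seed=seed)
        fit, _, _ = atpase.analyze_plate(
            ds.observables["wells"], ds.observables["well_map"],
            ds.observables["standards"], ds.observables["myosin_conc_uM"])
        errs.append(abs(fit.kcat - 0.80) / 0.80)
        cover.append(fit.kcat_ci[0] <= 0.80 <= fit.kcat_ci[1])
    assert np.median(errs) < 0.05
    assert np.mean(cover) >= 0.8
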