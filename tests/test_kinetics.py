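"""Kill-curve, lag, growth-ratio, gating and respiration estimators."""

import numpy as np
import pytest

from halodyn import (
    EventTable,
    GatePolicy,
    GrowthCurve,
    KillCurveParams,
    OxygenTrace,
    estimate_lag,
    fit_kill_curve,
    gate_events,
    growth_rate_ratio,
    respiration_rate,
    simulate_cytometry_events,
    simulate_kill_curve,
    simulate_oxygen_trace,
    simulate_recovery_curve,
)
from halodyn.synthetic import CytometryMixture


class TestKillCurveFit:
    def test_noise_free_biphasic_recovery(self):
        p = KillCurveParams(f_sensitive=0.99, k_fast=2.0, k_slow=0.05, noise_cv=0.0)
        curve = simulate_kill_curve(p, np.linspace(0, 14, 15), noise=False)
        fit = fit_kill_curve(curve)
        assert fit.selected == "biphasic"
        assert fit.f_sensitive == pytest.approx(0.99, rel=1e-3)
        assert fit.k_fast == pytest.approx(2.0, rel=1e-3)
        assert fit.k_slow == pytest.approx(0.05, rel=1e-3)

    def test_single_exponential_selects_monophasic(self):
        t = np.linspace(0, 10, 11)
        curve = GrowthCurve(time=t, density=np.exp(-0.5 * t), time_unit="d")
        fit = fit_kill_curve(curve)
        assert fit.selected == "monophasic"
        assert fit.k_mono == pytest.approx(0.5, rel=1e-9)

    def test_plateau_asymptote(self):
        p = KillCurveParams(f_sensitive=0.99, k_fast=2.0, k_slow=0.0, noise_cv=0.0)
        curve = simulate_kill_curve(p, np.linspace(0, 30, 16), noise=False)
        fit = fit_kill_curve(curve)
        asymptote = (1.0 - fit.f_sensitive) * fit.n0 * np.exp(-fit.k_slow * 30.0)
        assert asymptote == pytest.approx(0.01, rel=1e-5)

    def test_non_positive_density_rejected(self):
        curve = GrowthCurve(
            time=np.arange(7.0), density=np.array([1, 0.5, 0.2, 0.0, 0.1, 0.05, 0.02]),
            time_unit="d",
        )
        with pytest.raises(ValueError, match="positive"):
            fit_kill_curve(curve)

    def test_too_few_points_rejected(self):
        curve = GrowthCurve(
            time=np.arange(5.0), density=np.full(5, 1.0), time_unit="d"
        )
        with pytest.raises(ValueError, match="6 points"):
            fit_kill_curve(curve)


class TestLagEstimation:
    def test_exponential_from_start_gives_zero_lag(self):
        t = np.arange(0.0, 100.0, 4.0)
        curve = GrowthCurve(time=t, density=0.05 * np.exp(0.05 * t), time_unit="h")
        fit = estimate_lag(curve, n_boot=0)
        assert fit.lag_days == pytest.approx(0.0, abs=1e-6)
        assert not fit.no_growth

    def test_planted_three_day_lag(self):
        t = np.arange(0.0, 8 * 24.0, 4.0)
        curve = simulate_recovery_curve(3.0, 0.05, 0.05, t, noise_cv=0.05, seed=42)
        fit = estimate_lag(curve, n_boot=200, seed=1)
        assert fit.lag_days == pytest.approx(3.0, abs=0.25)
        assert fit.lag_ci_days[0] <= 3.0 <= fit.lag_ci_days[1]

    def test_planted_seven_day_lag(self):
        t = np.arange(0.0, 12 * 24.0, 4.0)
        curve = simulate_recovery_curve(7.0, 0.05, 0.05, t, noise_cv=0.05, seed=43)
        fit = estimate_lag(curve, n_boot=200, seed=2)
        assert fit.lag_days == pytest.approx(7.0, abs=0.5)

    def test_flat_curve_flags_no_growth(self):
        t = np.arange(0.0, 100.0, 4.0)
        rng = np.random.default_rng(0)
        curve = GrowthCurve(
            time=t, density=0.05 * np.exp(rng.normal(0, 0.03, t.size)), time_unit="h"
        )
        fit = estimate_lag(curve)
        assert fit.no_growth
        assert np.isnan(fit.lag_days)


class TestGrowthRateRatio:
    def test_identical_curves_ratio_one(self):
        t = np.arange(0.0, 60.0, 3.0)
        curve = GrowthCurve(time=t, density=0.05 * np.exp(0.08 * t), time_unit="h")
        rr = growth_rate_ratio(curve, curve)
        assert rr.ratio == pytest.approx(1.0, rel=1e-9)

    @pytest.mark.parametrize("rates,expected", [((0.10, 0.02), 5.0), ((0.08, 0.01), 8.0)])
    def test_planted_rate_ratio(self, rates, expected):
        rc, rs = rates
        t = np.arange(0.0, 120.0, 4.0)
        rng = np.random.default_rng(7)
        control = GrowthCurve(
            time=t,
            density=0.05 * np.exp(rc * t + rng.normal(0, 0.01, t.size)),
            time_unit="h",
        )
        stress = GrowthCurve(
            time=t,
            density=0.05 * np.exp(rs * t + rng.normal(0, 0.01, t.size)),
            time_unit="h",
        )
        rr = growth_rate_ratio(control, stress)
        assert rr.ratio == pytest.approx(expected, rel=0.05)
        assert rr.ci[0] < rr.ratio < rr.ci[1]
        assert rr.ratio_err < 0.05 * expected

    def test_no_exponential_window_raises(self):
        t = np.arange(0.0, 60.0, 3.0)
        rng = np.random.default_rng(3)
        flat = GrowthCurve(
            time=t, density=0.05 * np.exp(rng.normal(0, 0.2, t.size)), time_unit="h"
        )
        grow = GrowthCurve(time=t, density=0.05 * np.exp(0.08 * t), time_unit="h")
        with pytest.raises(ValueError, match="stress"):
            growth_rate_ratio(grow, flat)


class TestGating:
    @staticmethod
    def _control(n=5000, seed=0):
        mix = CytometryMixture(components=[(1.0, 3.0, 2.0, 0.15, 0.15)], n_events=n)
        return simulate_cytometry_events(mix, seed=seed)

    def test_all_events_below_cut_gives_zero(self):
        control = self._control()
        events = EventTable(syto9=np.full(100, 1000.0), pi=np.full(100, 1.0))
        res = gate_events(events, control)
        assert res.pi_pos_fraction == 0.0
        assert res.pi_ratio == 0.0

    def test_planted_fraction_recovery(self):
        control = self._control(10_000, seed=1)
        mix = CytometryMixture(
            components=[(0.7, 3.0, 2.0, 0.15, 0.15), (0.3, 2.2, 3.5, 0.15, 0.15)],
            n_events=10_000,
        )
        events = simulate_cytometry_events(mix, seed=2)
        res = gate_events(events, control)
        assert res.pi_pos_fraction == pytest.approx(0.30, abs=0.01)
        assert res.pi_ratio == pytest.approx(0.3 / 0.7, abs=0.03)

    def test_empty_table_rejected(self):
        control = self._control()
        empty = EventTable(syto9=np.array([]), pi=np.array([]))
        with pytest.raises(ValueError, match="empty"):
            gate_events(empty, control)

    def test_small_control_rejected_under_quantile_policy(self):
        small = EventTable(syto9=np.full(50, 100.0), pi=np.full(50, 10.0))
        events = self._control()
        with pytest.raises(ValueError, match="control"):
            gate_events(events, small)

    def test_fixed_policy_overrides_control(self):
        control = self._control()
        events = EventTable(
            syto9=np.array([100.0, 100.0, 100.0, 100.0]),
            pi=np.array([1.0, 1.0, 10.0, 10.0]),
        )
        res = gate_events(
            events, control, GatePolicy(mode="fixed", pi_cut=5.0, syto_cut=0.5)
        )
        assert res.pi_pos_fraction == 0.5
        assert res.thresholds == (5.0, 0.5)

    def test_monotone_in_planted_weight(self):
        control = self._control(10_000, seed=5)
        fractions = []
        for w in np.linspace(0.0, 1.0, 6):
            comps = [c for c in [(1 - w, 3.0, 2.0, 0.15, 0.15), (w, 2.2, 3.5, 0.15, 0.15)] if c[0] > 0]
            ev = simulate_cytometry_events(
                CytometryMixture(components=comps, n_events=10_000), seed=6
            )
            fractions.append(gate_events(ev, control).pi_pos_fraction)
        assert np.all(np.diff(fractions) >= 0)
        assert fractions[0] <= 0.005 + 1e-12
        assert fractions[-1] >= 0.995


class TestRespiration:
    def test_unit_arithmetic_on_exact_trace(self):
        """200 - 1.0·t µmol/L in 5 mL with 2e8 cells gives 2.5 nmol/min/1e8."""
        trace = simulate_oxygen_trace(
            rate=1.0, o2_0=200.0, duration=60.0, cell_count=2e8, volume=0.005
        )
        res = respiration_rate(trace)
        assert res.rate == pytest.approx(2.5, rel=1e-12)

    def test_basal_self_reference_is_100(self):
        trace = simulate_oxygen_trace(rate=1.0, o2_0=200.0, duration=60.0)
        assert respiration_rate(trace, treat_as_basal=True).percent_basal == 100.0

    def test_half_slope_is_50_percent(self):
        basal = simulate_oxygen_trace(rate=1.0, o2_0=200.0, duration=60.0)
        stressed = simulate_oxygen_trace(rate=0.5, o2_0=200.0, duration=60.0)
        assert respiration_rate(stressed, basal=basal).percent_basal == pytest.approx(50.0)

    def test_increasing_trend_flagged(self):
        t = np.arange(0.0, 30.0, 1.0)
        trace = OxygenTrace(time=t, o2=100.0 + 0.5 * t, cell_count=1e8, volume=0.005)
        res = respiration_rate(trace)
        assert "negative_uptake" in res.flags

    def test_window_avoids_zero_clipped_tail(self):
        trace = simulate_oxygen_trace(rate=5.0, o2_0=100.0, duration=60.0)
        res = respiration_rate(trace)
        assert res.fit_window[1] <= 20.0
        assert res.rate == pytest.approx(5.0 * 0.005 * 1e3 / 2.0, rel=1e-9)

    def test_noisy_slope_unbiased(self):
        rates = []
        for s in range(100):
            trace = simulate_oxygen_trace(
                rate=1.0, o2_0=200.0, duration=60.0, noise_sd=2.0, seed=s,
                cell_count=1e8, volume=0.001,
            )
            rates.append(respiration_rate(trace, r2_min=0.95).rate)
        rates = np.array(rates)
        se = rates.std(ddof=1) / np.sqrt(rates.size)
        assert abs(rates.mean() - 1.0) < 2 * se + 1e-9
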