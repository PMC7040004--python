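"""MSD extraction, force-constant estimation and length-scale identities."""

import numpy as np
import pytest

from halodyn import (
    MSDSeries,
    ReducedScan,
    ResilienceModel,
    fit_force_constant,
    fit_msd_series,
    observable_length_scale,
    reduce_bundle,
)
from halodyn.constants import TWO_KB_A2_PER_K


def _reduced_from_u2(u2_values, q=None, rel_err=0.01, temps=None):
    """Exact single-Gaussian reduced scan with I = exp(-Q²u²/6) per T."""
    q = np.arange(0.3, 1.51, 0.1) if q is None else np.asarray(q, float)
    u2_values = np.atleast_1d(u2_values)
    temps = (
        278.0 + 5.0 * np.arange(u2_values.size) if temps is None else np.asarray(temps, float)
    )
    intensity = np.exp(-np.outer(q**2, u2_values) / 6.0)
    return ReducedScan(
        q=q,
        temperature=temps,
        intensity=intensity,
        intensity_err=rel_err * intensity,
        mask=np.ones_like(intensity, dtype=bool),
        provenance=["synthetic exact Gaussian"],
    )


class TestObservableLengthScale:
    def test_low_q_bound(self):
        assert round(observable_length_scale(0.2)) == 31

    def test_high_q_bound(self):
        assert round(observable_length_scale(4.9), 1) == 1.3

    def test_identity_point(self):
        assert observable_length_scale(2 * np.pi) == pytest.approx(1.0)

    def test_non_positive_q_rejected(self):
        with pytest.raises(ValueError):
            observable_length_scale(0.0)


class TestFitMsdSeries:
    def test_single_gaussian_inversion(self):
        """I(Q) = exp(-0.1·Q²) inverts to u² = 0.6 exactly."""
        red = _reduced_from_u2([0.6])
        series = fit_msd_series(red)
        assert series.u2[0] == pytest.approx(0.6, rel=1e-12)

    def test_default_window_lower_edge(self):
        red = _reduced_from_u2([0.6], q=np.arange(0.2, 2.01, 0.1))
        series = fit_msd_series(red)
        assert series.q_window[0, 0] == pytest.approx(0.3)
        assert series.q_window[0, 1] <= 1.5 + 1e-12

    def test_mixture_matches_brute_force_oracle(self, make_bundle):
        """Apparent u² of a 50/50 mixture equals an independent weighted
        polyfit of the exact mixture curve on the same grid."""
        bundle = make_bundle([(0.5, 0.5, 0.3), (0.5, 0.1, 1.5)])
        red = reduce_bundle(bundle)
        series = fit_msd_series(red)
        q = red.q
        sel = (q >= 0.3) & (q <= 1.5)
        for j, T in enumerate(red.temperature):
            i_exact = bundle.truth.elastic_form(q[sel], [T])[:, 0]
            sigma = red.intensity_err[sel, j] / red.intensity[sel, j] * i_exact
            coeff = np.polyfit(q[sel] ** 2, np.log(i_exact), 1, w=i_exact / sigma)
            u2_oracle = -6.0 * coeff[0]
            assert series.u2[j] == pytest.approx(u2_oracle, rel=1e-8)

    def test_gaussian_validity_trimming(self):
        """Large u² triggers high-Q point dropping until q_max²u²/6 <= 2."""
        red = _reduced_from_u2([6.0], q=np.arange(0.3, 2.01, 0.1))
        series = fit_msd_series(red, q_window=(0.3, 2.0))
        q_max = series.q_window[0, 1]
        assert q_max**2 * series.u2[0] / 6.0 <= 2.0 + 1e-9
        assert q_max < 2.0

    def test_too_few_points_fails(self):
        red = _reduced_from_u2([0.6], q=np.array([0.4, 0.6, 0.8]))
        with pytest.raises(ValueError, match="every temperature"):
            fit_msd_series(red)

    def test_nonpositive_intensities_dropped_and_counted(self):
        red = _reduced_from_u2([0.6])
        red.intensity[2, 0] = -0.5
        series = fit_msd_series(red)
        assert series.n_dropped_nonpositive[0] == 1
        assert series.u2[0] == pytest.approx(0.6, rel=1e-10)


class TestFitForceConstant:
    def test_closed_form_slope(self):
        """u²(T) = 0.5 + 0.0138·(T-278) over 8 temperatures gives k' = 0.200 N/m."""
        T = np.linspace(278.0, 315.0, 8)
        u2 = 0.5 + 0.0138 * (T - 278.0)
        series = MSDSeries(
            temperature=T,
            u2=u2,
            u2_err=np.full(8, 1e-6),
            q_window=np.tile([0.3, 1.5], (8, 1)),
            n_points=np.full(8, 13),
            fit_r2=np.ones(8),
            n_dropped_nonpositive=np.zeros(8),
            failed_temperatures=np.array([]),
        )
        fc = fit_force_constant(series)
        assert fc.slope == pytest.approx(0.0138, rel=1e-9)
        assert fc.k_prime == pytest.approx(TWO_KB_A2_PER_K / 0.0138, rel=1e-9)
        assert fc.k_prime == pytest.approx(0.2001, abs=5e-4)

    def test_inverse_proportionality(self):
        T = np.linspace(278.0, 315.0, 8)
        common = dict(
            u2_err=np.full(8, 1e-6),
            q_window=np.tile([0.3, 1.5], (8, 1)),
            n_points=np.full(8, 13),
            fit_r2=np.ones(8),
            n_dropped_nonpositive=np.zeros(8),
            failed_temperatures=np.array([]),
        )
        k1 = fit_force_constant(
            MSDSeries(temperature=T, u2=0.0138 * (T - 278.0), **common)
        ).k_prime
        k2 = fit_force_constant(
            MSDSeries(temperature=T, u2=0.0276 * (T - 278.0), **common)
        ).k_prime
        assert k2 == pytest.approx(k1 / 2.0, rel=1e-9)

    def test_constant_u2_flags_non_positive_slope(self):
        T = np.linspace(278.0, 315.0, 8)
        series = MSDSeries(
            temperature=T,
            u2=np.full(8, 0.5),
            u2_err=np.full(8, 0.01),
            q_window=np.tile([0.3, 1.5], (8, 1)),
            n_points=np.full(8, 13),
            fit_r2=np.ones(8),
            n_dropped_nonpositive=np.zeros(8),
            failed_temperatures=np.array([]),
        )
        fc = fit_force_constant(series)
        assert "non_positive_slope" in fc.flags
        assert not fc.defined
        assert np.isnan(fc.k_prime)

    def test_bootstrap_requires_seed(self, make_bundle):
        series = ResilienceModel.from_bundle(make_bundle([(1.0, 0.2, 0.5)]))._fit_msd()
        with pytest.raises(ValueError, match="seed"):
            fit_force_constant(series, method="bootstrap")

    def test_bootstrap_error_comparable_to_analytic(self, make_bundle):
        bundle = make_bundle([(1.0, 0.2, 0.5)], seed=4, noise=True)
        series = ResilienceModel.from_bundle(bundle)._fit_msd()
        fa = fit_force_constant(series, method="analytic_propagation")
        fb = fit_force_constant(series, method="bootstrap", n_boot=1000, seed=9)
        assert fb.k_prime == pytest.approx(fa.k_prime)
        assert 0.2 < fb.k_prime_err / fa.k_prime_err < 5.0


class TestAnalysisOptions:
    def test_q_unit_flag_gives_identical_k_prime(self, make_bundle):
        """The same analysis with Q expressed in nm⁻¹ returns identical k' in N/m."""
        bundle = make_bundle([(1.0, 0.3, 0.5)], seed=2, noise=True)
        red = reduce_bundle(bundle)
        k_a = fit_force_constant(fit_msd_series(red)).k_prime
        red_nm = ReducedScan(
            q=red.q * 10.0,
            temperature=red.temperature,
            intensity=red.intensity,
            intensity_err=red.intensity_err,
            mask=red.mask,
            provenance=list(red.provenance),
        )
        k_nm = fit_force_constant(
            fit_msd_series(red_nm, q_window=(3.0, 15.0), q_unit="invnm")
        ).k_prime
        assert k_nm == pytest.approx(k_a, rel=1e-12)

    def test_reference_normalization_leaves_slope_invariant(self, make_bundle):
        red = reduce_bundle(make_bundle([(1.0, 0.25, 0.5)]))
        fc_raw = fit_force_constant(fit_msd_series(red))
        fc_ref = fit_force_constant(fit_msd_series(red, normalize_to_reference=True))
        assert fc_ref.slope == pytest.approx(fc_raw.slope, rel=1e-9)
        assert fc_ref.k_prime == pytest.approx(fc_raw.k_prime, rel=1e-9)

    def test_summary_contains_headline_numbers(self, make_bundle):
        res = ResilienceModel.from_bundle(make_bundle([(1.0, 0.2, 0.5)])).fit()
        text = res.summary()
        assert "0.2" in text and "k'" in text


class TestMixtureMonotonicity:
    def test_softer_weight_increases_apparent_msd(self, make_bundle):
        """More weight on the soft subpopulation raises apparent u² at every T."""
        u2_prev = None
        for w in (0.0, 0.3, 0.6, 1.0):
            pops = [p for p in [(1 - w, 0.5, 0.3), (w, 0.1, 1.5)] if p[0] > 0]
            series = ResilienceModel.from_bundle(make_bundle(pops))._fit_msd()
            if u2_prev is not None:
                assert np.all(series.u2 > u2_prev)
            u2_prev = series.u2
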