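"""Tests for exponential fitting, order selection and rate extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ehkin import (
    KobsSeries,
    NoiseModel,
    RateSet,
    ReactionConditions,
    Trace,
    extract_micro_rates,
    fit_exponential,
    fit_kobs_decreasing,
    fit_kobs_hyperbolic,
    fit_michaelis_menten,
    fit_trace_auto,
    gen_trace,
    relaxation_rates,
    select_order,
    single_turnover_k3,
    steady_state_params,
)


def _synthetic_trace(t, endpoint, phases, sigma=0.0, seed=0):
    y = np.full_like(t, endpoint, dtype=float)
    for a, k in phases:
        y = y + a * np.exp(-k * t)
    if sigma > 0:
        y = y + np.random.default_rng(seed).normal(0, sigma, t.size)
    return Trace(time=t, signal=y)


class TestTraceValidation:
    def test_needs_enough_samples(self):
        with pytest.raises(ValueError, match="20 samples"):
            Trace(time=np.linspace(0, 1, 10), signal=np.zeros(10))

    def test_dead_time_excludes_early_samples(self):
        t = np.linspace(0, 1, 100)
        tr = Trace(time=t, signal=np.zeros(100), dead_time_s=0.05)
        t_obs, _ = tr.observed()
        assert t_obs[0] >= 0.05


class TestFitExponential:
    def test_exact_single_exponential_recovery(self):
        t = np.geomspace(1e-4, 0.2, 200)
        tr = _synthetic_trace(t, 0.2, [(1.0, 100.0)])
        fit = fit_exponential(tr, 1)
        assert fit.k_obs[0] == pytest.approx(100.0, rel=1e-6)
        assert fit.amplitudes[0] == pytest.approx(1.0, rel=1e-6)
        assert fit.endpoint == pytest.approx(0.2, rel=1e-6)

    def test_exact_double_exponential_recovery(self):
        t = np.geomspace(1e-4, 1.0, 400)
        tr = _synthetic_trace(t, 0.5, [(0.8, 250.0), (-0.3, 12.0)])
        fit = fit_exponential(tr, 2)
        assert fit.k_obs[0] == pytest.approx(250.0, rel=1e-5)
        assert fit.k_obs[1] == pytest.approx(12.0, rel=1e-5)
        assert fit.k_obs[0] > fit.k_obs[1]  # phase convention

    def test_branched_trace_matches_relaxation_eigenvalues(self, wt_ssa_rates):
        """Both fitted phases of a biphasic quench trace sit on eigenvalues
        of the linearized enzyme system."""
        cond = ReactionConditions(E_total=1.5, S_total=1500.0)
        tr = gen_trace(wt_ssa_rates, cond, NoiseModel(sigma=0.0, n_replicates=1))
        fit = fit_exponential(tr, 2)
        mags = relaxation_rates(wt_ssa_rates, 1500.0)
        for k in fit.k_obs:
            assert np.min(np.abs(mags - k) / k) < 0.05

    def test_order1_systematically_misfits_biphasic_trace(self, wt_ssa_rates):
        """Runs of same-signed residuals betray the missing second phase."""
        cond = ReactionConditions(E_total=1.5, S_total=1500.0)
        tr = gen_trace(wt_ssa_rates, cond, NoiseModel(sigma=0.0, n_replicates=1))
        fit1 = fit_exponential(tr, 1)
        t, y = tr.observed()
        resid = y - fit1.predict(t)
        signs = np.sign(resid[np.abs(resid) > 1e-12])
        n_runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
        n = signs.size
        # expected runs for random residuals ~ n/2 + 1; a handful of long
        # arcs means systematic misfit
        assert n_runs < 0.1 * n
        fit2 = fit_exponential(tr, 2)
        assert fit2.sse < 0.01 * fit1.sse

    def test_constant_signal_flagged(self):
        t = np.linspace(0, 1, 100)
        tr = Trace(time=t, signal=np.full(100, 0.7))
        fit = fit_exponential(tr, 1)
        assert abs(fit.amplitudes[0]) < 1e-9
        assert "amplitude_near_zero" in fit.flags
        assert "rate_ill_determined" in fit.flags

    def test_too_few_points_rejected(self):
        t = np.linspace(0, 1, 25)
        tr = _synthetic_trace(t, 0.0, [(1.0, 5.0)])
        tr.dead_time_s = 0.6  # only 10 observed samples remain
        with pytest.raises(ValueError, match="at least 15"):
            fit_exponential(tr, 2)

    def test_invalid_order(self):
        t = np.linspace(0, 1, 50)
        with pytest.raises(ValueError, match="order"):
            fit_exponential(_synthetic_trace(t, 0.0, [(1.0, 5.0)]), 3)


class TestSelectOrder:
    def test_equal_sse_keeps_simple_model(self):
        from ehkin.transient_fitting import ExpFit
        common = dict(amplitudes=(1.0,), k_obs=(10.0,), endpoint=0.0,
                      se_amplitudes=(0.1,), se_k_obs=(0.1,), se_endpoint=0.1,
                      n_points=100)
        fit1 = ExpFit(order=1, sse=1.0, dof=97, **common)
        fit2 = ExpFit(order=2, sse=1.0, dof=95, **common)
        sel = select_order(fit1, fit2, alpha=0.05)
        assert sel.order == 1 and sel.F == 0.0

    def test_clear_second_phase_detected(self, wt_ssa_rates):
        cond = ReactionConditions(E_total=1.5, S_total=1500.0)
        tr = gen_trace(wt_ssa_rates, cond,
                       NoiseModel(sigma=0.02, seed=3, n_replicates=1))
        fit, sel = fit_trace_auto(tr)
        assert sel.order == 2
        assert min(abs(a) for a in fit.amplitudes) > 0.05 * sum(
            abs(a) for a in fit.amplitudes)

    def test_degenerate_second_phase_rejected_by_auto_fit(self):
        """On a clean single-exponential trace the F-test may accept a
        duplicate-rate second phase; the resolvability guard must drop it."""
        t = np.geomspace(1e-4, 0.3, 300)
        tr = _synthetic_trace(t, 0.1, [(1.0, 50.0)], sigma=1e-5, seed=2)
        fit, sel = fit_trace_auto(tr)
        assert sel.order == 1
        assert fit.k_obs[0] == pytest.approx(50.0, rel=1e-3)

    def test_type_one_error_rate_near_alpha(self):
        """Single-phase truth: the second phase is accepted ~alpha of the time."""
        t = np.geomspace(0.002, 0.1, 250)
        rng = np.random.default_rng(77)
        n, rej = 120, 0
        for _ in range(n):
            y = 0.2 + 1.0 * np.exp(-80.0 * t) + rng.normal(0, 0.02, t.size)
            tr = Trace(time=t, signal=y)
            sel = select_order(fit_exponential(tr, 1), fit_exponential(tr, 2),
                               alpha=0.05)
            rej += sel.order == 2
        # 3-sigma binomial band around 0.05
        assert abs(rej / n - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n)


class TestKobsHyperbolic:
    def test_exact_recovery_from_published_parameter_set(self):
        S = np.array([30., 100., 300., 470., 800., 1500.])
        y = 370.0 * S / (470.0 + S) + 280.0
        fit = fit_kobs_hyperbolic(KobsSeries(S, y))
        assert fit.k2 == pytest.approx(370.0, rel=1e-6)
        assert fit.K_S == pytest.approx(470.0, rel=1e-6)
        assert fit.intercept == pytest.approx(280.0, rel=1e-6)

    def test_flat_series_flags_K_S(self):
        S = np.array([30., 100., 300., 1000.])
        fit = fit_kobs_hyperbolic(KobsSeries(S, np.full(4, 48.0)))
        assert fit.k2 == pytest.approx(0.0, abs=1e-6)
        assert "K_S_ill_determined" in fit.flags

    def test_low_concentration_regime_inflates_errors(self):
        """Sampling only S << K_S leaves k2 and K_S separately unidentified."""
        rng = np.random.default_rng(5)
        S_full = np.geomspace(30., 1500., 10)
        S_low = np.geomspace(5., 45., 10)  # K_S = 470 far above
        noise = 1.005
        k2, K_S, c = 370.0, 470.0, 280.0
        fits = []
        for S in (S_full, S_low):
            y = (k2 * S / (K_S + S) + c) * rng.normal(1.0, 0.005, S.size)
            fits.append(fit_kobs_hyperbolic(KobsSeries(S, y)))
        rel_full = fits[0].se_K_S / fits[0].K_S
        rel_low = fits[1].se_K_S / fits[1].K_S
        assert rel_low > 10 * rel_full or not np.isfinite(rel_low)

    def test_decreasing_series_redirected(self):
        S = np.array([30., 100., 300., 1000.])
        y = 48.0 / (1 + S / 300.0) + 5.0
        with pytest.raises(ValueError, match="decreasing"):
            fit_kobs_hyperbolic(KobsSeries(S, y))

    def test_needs_four_concentrations(self):
        with pytest.raises(ValueError, match="4 distinct"):
            fit_kobs_hyperbolic(KobsSeries([1., 2., 3.], [1., 2., 3.]))


class TestKobsDecreasing:
    def test_intercept_matches_conformer_rate_sum(self):
        """Noiseless two-step data: the S->0 intercept is k_lim + k_rev."""
        S = np.array([30., 100., 300., 600., 1000., 1500.])
        y = 10.0 + 38.0 / (1.0 + S / 500.0)
        fit = fit_kobs_decreasing(KobsSeries(S, y, phase="slow"))
        assert fit.intercept == pytest.approx(48.0, rel=1e-6)
        assert fit.K_app == pytest.approx(500.0, rel=1e-5)

    def test_flat_series_reports_limiting_rate(self):
        S = np.array([30., 100., 300., 1000.])
        fit = fit_kobs_decreasing(KobsSeries(S, np.full(4, 10.0), phase="slow"))
        assert fit.intercept == pytest.approx(10.0, rel=1e-6)

    def test_median_recovery_under_noise(self):
        S = np.array([30., 100., 300., 600., 1000., 1500.])
        y0 = 10.0 + 38.0 / (1.0 + S / 500.0)
        rng = np.random.default_rng(13)
        intercepts = []
        for _ in range(100):
            y = y0 * rng.normal(1.0, 0.05, S.size)
            try:
                intercepts.append(
                    fit_kobs_decreasing(KobsSeries(S, y, phase="slow")).intercept)
            except ValueError:
                continue
        assert abs(np.median(intercepts) - 48.0) / 48.0 < 0.10

    def test_increasing_series_redirected(self):
        S = np.array([30., 100., 300., 1000.])
        y = 370.0 * S / (470.0 + S) + 280.0
        with pytest.raises(ValueError, match="increases"):
            fit_kobs_decreasing(KobsSeries(S, y, phase="slow"))


class TestExtractMicroRates:
    @pytest.mark.parametrize("k2,K_S,s,kcat,k3_pub,k3_se,km2_pub,km2_se", [
        (370.0, 470.0, 280.0, 63.0, 110.0, 10.0, 170.0, 20.0),
        (1400.0, 2700.0, 42.0, 31.0, 32.0, 20.0, 10.0, 30.0),
    ])
    def test_reproduces_published_split(self, k2, K_S, s, kcat,
                                        k3_pub, k3_se, km2_pub, km2_se):
        est = extract_micro_rates(k2, K_S, s, kcat)
        assert abs(est.k3 - k3_pub) <= k3_se
        assert abs(est.k_m2 - km2_pub) <= km2_se
        assert est.k_m2 + est.k3 == pytest.approx(s)

    def test_no_dealkylation_limit(self):
        """If kcat = k2*k3/(k2+k3) exactly, the implied k_m2 is zero."""
        k2, k3 = 500.0, 50.0
        est = extract_micro_rates(k2, 100.0, k3, k2 * k3 / (k2 + k3))
        assert est.k_m2 == pytest.approx(0.0, abs=1e-9)

    def test_inconsistent_inputs_flagged_not_clipped(self):
        est = extract_micro_rates(100.0, 100.0, 10.0, 20.0)
        assert est.k_m2 < 0
        assert "negative_k_m2_implied" in est.flags

    @settings(derandomize=True, max_examples=100)
    @given(k2=st.floats(1.0, 5e3), s=st.floats(0.5, 1e3),
           frac=st.floats(0.05, 0.999))
    def test_left_inverse_of_steady_state_kcat(self, k2, s, frac):
        """extract -> steady_state reproduces kcat exactly (and k_m2 >= 0
        whenever kcat is below the consistent maximum k2*s/(k2+s))."""
        kcat = frac * k2 * s / (k2 + s)
        est = extract_micro_rates(k2, 100.0, s, kcat)
        assert est.k_m2 >= -1e-9
        back = steady_state_params(k2, max(est.k_m2, 0.0), est.k3, 100.0)
        assert back.kcat == pytest.approx(kcat, rel=1e-9)

    def test_delta_method_errors_scale_linearly(self):
        e1 = extract_micro_rates(370., 470., 280., 63., se_kcat=1.0)
        e2 = extract_micro_rates(370., 470., 280., 63., se_kcat=2.0)
        assert e2.se_k3 == pytest.approx(2 * e1.se_k3)


class TestSingleTurnover:
    def test_recovery_rate_matches_committed_eigenvalue(self):
        """[E],[S] >> K_S: the fluorescence recovery decays at the slow
        eigenvalue of ES <-> EA -> E + P; for these rates that is 18% below
        the nominal k3, the intrinsic accuracy limit of the k_obs ~= k3
        reading."""
        r = RateSet(k2=23.0, k_m2=4.5, k3=3.9, K_S=5.5)
        cond = ReactionConditions(E_total=60.0, S_total=50.0,
                                  mode="single_turnover")
        tr = gen_trace(r, cond, NoiseModel(sigma=0.0, n_replicates=1))
        res = single_turnover_k3(tr, K_S=5.5)
        s = 23.0 + 4.5 + 3.9
        lam = (s - np.sqrt(s * s - 4 * 23.0 * 3.9)) / 2.0
        assert res.k3 == pytest.approx(lam, rel=0.05)
        assert res.k3 < 3.9  # the systematic saturation/partitioning bias

    def test_saturation_sweep_monotonically_approaches_limit(self):
        r = RateSet(k2=23.0, k_m2=4.5, k3=3.9, K_S=5.5)
        rates = []
        for mult in (1, 2, 5, 10, 20):
            cond = ReactionConditions(E_total=mult * 5.5, S_total=mult * 5.5,
                                      mode="single_turnover")
            with pytest.warns() if mult < 2 else _nullcontext():
                tr = gen_trace(r, cond, NoiseModel(sigma=0.0, n_replicates=1))
                rates.append(single_turnover_k3(tr, K_S=5.5).k3)
        assert np.all(np.diff(rates) > 0)

    def test_no_hydrolysis_flat_recovery_flagged(self):
        r = RateSet(k2=23.0, k_m2=4.5, k3=0.0, K_S=5.5)
        cond = ReactionConditions(E_total=60.0, S_total=50.0,
                                  mode="single_turnover")
        t = np.geomspace(0.002, 5.0, 500)
        tr = gen_trace(r, cond, NoiseModel(sigma=0.0, n_replicates=1), t_grid=t)
        res = single_turnover_k3(tr, K_S=5.5)
        assert "no_recovery_detected" in res.fit.flags

    def test_multiple_turnover_trace_rejected(self, wt_ssa_rates):
        cond = ReactionConditions(E_total=1.0, S_total=1500.0)
        tr = gen_trace(wt_ssa_rates, cond, NoiseModel(sigma=0.0, n_replicates=1))
        with pytest.raises(ValueError, match="single-turnover"):
            single_turnover_k3(tr)


class TestMichaelisMenten:
    def test_exact_fit(self):
        S = np.geomspace(5, 1500, 10)
        v = 63.0 * 0.05 * S / (77.0 + S)
        fit = fit_michaelis_menten(S, v, 0.05)
        assert fit.kcat == pytest.approx(63.0, rel=1e-6)
        assert fit.Km == pytest.approx(77.0, rel=1e-6)

    def test_saturating_design_flags_Km(self):
        S = np.geomspace(5000, 50000, 6)
        v = 63.0 * 0.05 * S / (77.0 + S)
        fit = fit_michaelis_menten(S, v, 0.05)
        assert "Km_ill_determined" in fit.flags or "no_sub_Km_data" in fit.flags


class _nullcontext:
    def __enter__(self):
        return self

    def __exit__(self, *exc):
        return False
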