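import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breathmech import RunConfig, fit_time_constant, truncate_to_equilibrium
from breathmech.expiratory import loglinear_decay_rate, predict_expiratory_flow
from breathmech.model import RespiratoryMechanics
from breathmech.simulate import simulate_protocol

from conftest import make_scenario


class TestTruncation:
    def test_pure_exponential_window_matches_analytic_t95(self):
        # e^{-K t} = 0.05  =>  t95 = ln(20)/K
        fs, K = 100.0, 2.0
        t = np.arange(int(6 * fs)) / fs
        q = 0.5 * np.exp(-K * t)
        n, ok = truncate_to_equilibrium(q)
        assert ok
        assert n == pytest.approx(np.ceil(np.log(20.0) / K * fs) + 1, abs=1)

    def test_constant_tail_is_subtracted_by_equilibrium_estimate(self):
        fs, K = 100.0, 2.0
        t = np.arange(int(6 * fs)) / fs
        q = 0.5 * np.exp(-K * t)
        n_free, _ = truncate_to_equilibrium(q)
        n_tail, _ = truncate_to_equilibrium(q + 0.02)
        assert abs(n_tail - n_free) <= 1

    def test_constant_series_is_degenerate(self):
        n, ok = truncate_to_equilibrium(np.full(100, 0.3), min_samples=5)
        assert not ok
        assert n == 5


class TestFit:
    def test_recovers_own_family_exactly(self, config):
        t = np.arange(0, 1.5, 0.02)
        fit = fit_time_constant(t, 0.5 * np.exp(-2.0 * t), config)
        assert fit.converged
        assert fit.K == pytest.approx(2.0, rel=1e-6)
        assert fit.Q0 == pytest.approx(0.5, rel=1e-6)
        assert fit.tau == pytest.approx(0.5, rel=1e-6)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(q0=st.floats(0.1, 2.0), k=st.floats(0.5, 20.0))
    def test_exact_recovery_across_parameter_space(self, q0, k):
        t = np.arange(100) / 50.0
        fit = fit_time_constant(t, q0 * np.exp(-k * t), RunConfig())
        assert fit.converged
        assert fit.K == pytest.approx(k, rel=1e-6)
        assert fit.Q0 == pytest.approx(q0, rel=1e-6)

    def test_scale_equivariance(self, config):
        rng = np.random.default_rng(0)
        t = np.arange(80) / 50.0
        q = 0.8 * np.exp(-3.0 * t) * (1 + 0.02 * rng.standard_normal(80))
        base = fit_time_constant(t, q, config)
        flow_scaled = fit_time_constant(t, 2.5 * q, config)
        assert flow_scaled.K == pytest.approx(base.K, rel=1e-8)
        assert flow_scaled.Q0 == pytest.approx(2.5 * base.Q0, rel=1e-8)
        time_scaled = fit_time_constant(2.0 * t, q, config)
        assert time_scaled.K == pytest.approx(base.K / 2.0, rel=1e-8)

    def test_agrees_with_loglinear_oracle_on_clean_data(self, config):
        t = np.arange(120) / 50.0
        q = 1.3 * np.exp(-4.0 * t)
        fit = fit_time_constant(t, q, config)
        k_loglin, _ = loglinear_decay_rate(t, q)
        assert abs(fit.K - k_loglin) / fit.K < 1e-3

    def test_too_few_samples_flagged_unfittable(self, config):
        fit = fit_time_constant(np.arange(3) / 50.0, np.ones(3), config)
        assert not fit.converged
        assert "unfittable" in fit.flags

    def test_noise_robustness_median_within_five_percent(self, config):
        # seeded Monte-Carlo: sigma = 5% of the peak expiratory flow
        rng = np.random.default_rng(12)
        t = np.arange(30) / 50.0   # the 95% window of K=5 at 50 Hz
        errs = []
        for _ in range(200):
            q = 2.0 * np.exp(-5.0 * t) + rng.normal(0, 0.1, t.size)
            fit = fit_time_constant(t, q, config)
            if fit.converged:
                errs.append(abs(fit.K - 5.0) / 5.0)
        assert np.median(errs) < 0.05


class TestPredict:
    def test_value_and_half_life(self, config):
        t = np.arange(0, 1.5, 0.02)
        fit = fit_time_constant(t, 0.5 * np.exp(-2.0 * t), config)
        assert predict_expiratory_flow(fit, np.array([0.0]))[0] == \
            pytest.approx(0.5, rel=1e-6)
        assert predict_expiratory_flow(fit, np.array([np.log(2) / 2.0]))[0] == \
            pytest.approx(0.25, rel=1e-6)

    def test_self_consistency_on_fit_samples(self, config):
        t = np.arange(0, 1.5, 0.02)
        q = 0.5 * np.exp(-2.0 * t)
        fit = fit_time_constant(t, q, config)
        assert np.max(np.abs(predict_expiratory_flow(fit, t) - q)) < 1e-6


def test_fitted_k_monotone_in_simulated_elastance(config):
    # constant R: K = E/R must order the same way as E
    ks = []
    for E in (10.0, 20.0, 40.0, 60.0):
        rec, _ = simulate_protocol(make_scenario(E=E, R=5.0, n=3, seed=1))
        m = RespiratoryMechanics(rec, config).fit().mechanics
        ks.append(m["K"].median())
    assert all(a < b for a, b in zip(ks, ks[1:]))
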