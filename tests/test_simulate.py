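import numpy as np
import pytest

from breathmech import ConfigError
from breathmech.model import RespiratoryMechanics
from breathmech.simulate import (Artefacts, Recruitment, Trajectory,
                                 disease_trajectory,
                                 phase1_scenario, recruitment_model,
                                 scenario_from_dict, simulate_breath,
                                 simulate_protocol)

from conftest import make_scenario


class TestBreath:
    def test_closed_form_pressures_and_peak_flow(self):
        p, q, truth = simulate_breath(25.0, 5.0, 5.0, fs=50.0, t_insp=1.0,
                                      t_pause=0.3, t_exp=1.7, vt=0.4,
                                      artefacts=Artefacts(tail_amp=0.0,
                                                          pressure_delta=0.0))
        vt_d = truth["vt_delivered"]
        n_i, n_p = truth["n_insp"], truth["n_pause"]
        assert p[n_i - 1] == pytest.approx(5.0 * 0.4 + 25.0 * vt_d + 5.0)
        assert p[n_i + n_p - 1] == pytest.approx(25.0 * vt_d + 5.0)
        assert -q[n_i + n_p] == pytest.approx(25.0 * vt_d / 5.0)
        assert truth["K"] == pytest.approx(5.0)

    def test_small_vt_pressures_approach_peep_baseline(self):
        p, _, _ = simulate_breath(25.0, 5.0, 0.0, fs=50.0, t_insp=1.0,
                                  t_pause=0.3, t_exp=1.7, vt=1e-4,
                                  artefacts=Artefacts(tail_amp=0.0,
                                                      pressure_delta=0.0))
        assert np.max(np.abs(p)) < 0.01

    def test_timing_shorter_than_two_samples_is_config_error(self):
        with pytest.raises(ConfigError):
            simulate_breath(25.0, 5.0, 5.0, fs=50.0, t_insp=0.01,
                            t_pause=0.3, t_exp=1.7, vt=0.4)

    def test_volume_conservation(self):
        p, q, truth = simulate_breath(25.0, 5.0, 5.0, fs=50.0, t_insp=1.0,
                                      t_pause=0.3, t_exp=1.7, vt=0.4,
                                      artefacts=Artefacts(tail_amp=0.0,
                                                          pressure_delta=0.0))
        n_i = truth["n_insp"]
        dt = 1.0 / 50.0
        # inspiratory trapezoid equals configured Vt within one sample's flow
        vt_insp = np.trapezoid(q[:n_i], dx=dt)
        assert abs(vt_insp - 0.4) <= 0.4 * dt / 1.0 + 1e-12
        # ideal expiration (tau=0.2 s, span 1.7 s > 5 tau) returns Vt to 0.5%
        exp = -q[n_i + truth["n_pause"]:]
        assert np.trapezoid(exp, dx=dt) == pytest.approx(truth["vt_delivered"],
                                                         rel=5e-3)


class TestTrajectories:
    def test_constant_kind_is_flat(self):
        e, r = disease_trajectory("healthy-constant", duration=100.0)
        assert e(0.0) == e(99.0) == 20.0
        assert r(0.0) == r(99.0) == 5.0

    def test_sigmoid_midpoint(self):
        tr = Trajectory(kind="sigmoid", start=20.0, end=60.0, t_mid=600.0,
                        width=80.0)
        assert tr(600.0) == pytest.approx(40.0)
        assert tr(0.0) == pytest.approx(20.0, abs=0.05)
        assert tr(1e9) == pytest.approx(60.0)

    def test_rising_resistance_transiently_depresses_k(self):
        e, r = disease_trajectory("ards-sigmoid-E-rising-R", duration=1000.0)
        t = np.linspace(0, 1000, 400)
        k = np.array([e(x) / r(x) for x in t])
        assert k.min() < k[0]        # K falls below its healthy value...
        assert k[-1] > k.min()       # ...before elastance drives it back up

    def test_recruitment_minimum_and_hysteresis(self):
        params = Recruitment(curvature=0.1, peep_star=15.0, hysteresis=0.9)
        adds = [recruitment_model(p, "ascending", params)[0]
                for p in (5.0, 10.0, 15.0, 20.0)]
        assert np.argmin(adds) == 2
        _, up = recruitment_model(10.0, "ascending", params)
        _, down = recruitment_model(10.0, "descending", params)
        assert up == 1.0 and down == 0.9
        sym = Recruitment(curvature=0.1, peep_star=15.0, hysteresis=1.0)
        assert recruitment_model(10.0, "ascending", sym)[1] == \
            recruitment_model(10.0, "descending", sym)[1]


class TestProtocol:
    def test_bookkeeping_seven_steps(self):
        rec, truth = simulate_protocol(phase1_scenario(seed=1,
                                                       breaths_per_step=30))
        assert len(truth.table) == 210
        assert list(truth.table["peep"].unique()) == [5.0, 10.0, 15.0, 20.0]

    def test_same_seed_is_bit_identical(self):
        scn = make_scenario(n=10, noise=0.05, clean=False, seed=9)
        r1, t1 = simulate_protocol(scn)
        r2, t2 = simulate_protocol(scn)
        np.testing.assert_array_equal(r1.flow, r2.flow)
        np.testing.assert_array_equal(r1.pressure, r2.pressure)
        assert t1.table.equals(t2.table)

    def test_seed_is_mandatory(self):
        with pytest.raises(ConfigError):
            simulate_protocol(make_scenario(seed=None))

    def test_scenario_from_mapping(self):
        scn = scenario_from_dict({
            "peep_protocol": [[5, 3], [10, 3]],
            "elastance": {"kind": "constant", "value": 30.0},
            "noise_flow": 0.0, "noise_pressure": 0.0, "seed": 4})
        rec, truth = simulate_protocol(scn)
        assert len(truth.table) == 6
        assert truth.table["E"].iloc[0] == 30.0


class TestClosedLoop:
    def test_noise_free_pipeline_recovers_parameters_everywhere(self, config):
        rec, truth = simulate_protocol(make_scenario(E=30.0, R=6.0, n=6,
                                                     seed=2))
        m = RespiratoryMechanics(rec, config).fit().mechanics
        assert len(m) == 6
        np.testing.assert_allclose(m["K"], 5.0, rtol=1e-3)
        np.testing.assert_allclose(m["E_rsIB"], 30.0, rtol=1e-3)
        np.testing.assert_allclose(m["E_static"], 30.0, rtol=1e-3)
        np.testing.assert_allclose(m["R_static"], 6.0, rtol=1e-3)

    def test_k_bias_grows_with_valve_tail_amplitude(self, config):
        # documents why the 95% truncation and Q_eq subtraction exist
        biases = []
        for amp in (0.0, 0.1, 0.3):
            rec, _ = simulate_protocol(make_scenario(
                n=3, seed=3,
                artefacts=Artefacts(tail_amp=amp, tail_tau=5.0,
                                    pressure_delta=0.0)))
            m = RespiratoryMechanics(rec, config).fit().mechanics
            biases.append(abs(m["K"].median() - 5.0))
        assert biases[0] < biases[1] < biases[2]
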