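import json
from dataclasses import replace

import numpy as np
import pytest

import phosphagen as pg
from phosphagen.production import HillInverseTurnover
from oracles import reference_simulate


@pytest.fixture(scope="module")
def short_protocol():
    return pg.FiringProtocol(rate=10, duty=0.5, full_cycle=1.0, n_cycles=2)


class TestStep:
    def test_balanced_rest_is_stationary(self, quiet_terminal, rest_state):
        cfg = pg.SimulationConfig(terminal=quiet_terminal,
                                  protocol=pg.FiringProtocol(1, 0, 1.0, 1),
                                  initial_state=rest_state, dt=1e-3)
        train = pg.SpikeTrain(np.array([]))
        s = rest_state
        for i in range(200):
            s = pg.step(s, i * cfg.dt, cfg, train=train)
        np.testing.assert_allclose(s.as_array(), rest_state.as_array(),
                                   rtol=1e-9, atol=1e-15)

    def test_linear_decay_without_production(self, quiet_terminal, rest_state):
        cfg = pg.SimulationConfig(terminal=quiet_terminal,
                                  protocol=pg.FiringProtocol(1, 0, 1.0, 1),
                                  initial_state=rest_state, t_end=2.0,
                                  production_on=False, equilibration_on=False)
        res = pg.simulate(cfg)
        expected = rest_state.atp - quiet_terminal.base_rate * res.time
        np.testing.assert_allclose(res.atp, expected, rtol=1e-9)

    def test_zero_dt_is_identity(self, quiet_terminal, rest_state):
        cfg = pg.SimulationConfig(terminal=quiet_terminal,
                                  protocol=pg.FiringProtocol(1, 0, 1.0, 1),
                                  initial_state=rest_state)
        out = pg.step(rest_state, 0.0, cfg, train=pg.SpikeTrain(np.array([])),
                      dt=0.0)
        np.testing.assert_allclose(out.as_array(), rest_state.as_array(),
                                   rtol=1e-12)

    def test_exhaustion_raises_step_size_error(self, quiet_terminal, rest_state):
        hungry = replace(quiet_terminal, base_rate=2.16)  # exhausts ATP in ~1 s
        cfg = pg.SimulationConfig(terminal=hungry,
                                  protocol=pg.FiringProtocol(1, 0, 1.0, 1),
                                  initial_state=rest_state, t_end=2.0,
                                  production_on=False, equilibration_on=False)
        with pytest.raises(pg.StepSizeError):
            pg.simulate(cfg)


class TestSimulate:
    def test_zero_cost_protocol_constant_series(self, quiet_terminal, rest_state):
        cfg = pg.SimulationConfig(terminal=quiet_terminal,
                                  protocol=pg.FiringProtocol(10, 0.5, 1.0, 2),
                                  initial_state=rest_state, t_end=3.0)
        res = pg.simulate(cfg)
        assert np.abs(res.states - res.states[0]).max() < 1e-12
        np.testing.assert_allclose(res.production, res.consumption, rtol=1e-9)

    def test_trajectory_matches_independent_reference(self, synth_terminal,
                                                      rest_state, short_protocol):
        dt, stride = 1e-3, 10
        cfg = pg.SimulationConfig(terminal=synth_terminal, protocol=short_protocol,
                                  initial_state=rest_state, dt=dt, t_end=2.0,
                                  record_stride=stride)
        res = pg.simulate(cfg)
        prod = cfg.resolved_production()
        train = pg.spike_times(short_protocol)
        ref = reference_simulate(
            n_steps=2000, dt=dt,
            spike_steps=np.rint(train.times / dt).astype(int),
            n_atp_mm=[synth_terminal.deposit_mm(c) for c in pg.COMPONENTS],
            tau=[synth_terminal.tau[c] for c in pg.COMPONENTS],
            base_rate=synth_terminal.base_rate,
            state0=rest_state.as_array(),
            k_ad=cfg.k.k_ad, k_ph=cfg.k.k_ph, enforce_ph=True,
            base_es=prod.base_es, turnover=HillInverseTurnover(),
            base_prod=prod.base_rate, max_rate=prod.max_rate,
            cap_exp=prod.cap_exponent, record_stride=stride)
        np.testing.assert_allclose(res.states, ref[:, 1:7], rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(res.consumption, ref[:, 7], rtol=1e-9)
        np.testing.assert_allclose(res.production, ref[:, 8], rtol=1e-9)

    def test_custom_turnover_python_path_agrees_with_kernel(self, synth_terminal,
                                                            rest_state,
                                                            short_protocol):
        class SameMathDifferentType:
            def __call__(self, es):
                u = 1.0 / np.asarray(es, dtype=float)
                return u**2.0 / (0.5**2.0 + u**2.0)

        cfg_fast = pg.SimulationConfig(terminal=synth_terminal,
                                       protocol=short_protocol,
                                       initial_state=rest_state, t_end=2.0,
                                       dt=1e-3)
        prod_slow = pg.build_production_model(synth_terminal, rest_state,
                                              turnover=SameMathDifferentType())
        cfg_slow = replace(cfg_fast, production=prod_slow)
        a, b = pg.simulate(cfg_fast), pg.simulate(cfg_slow)
        np.testing.assert_allclose(a.states, b.states, rtol=1e-12)

    def test_mass_balance(self, synth_terminal, rest_state):
        cfg = pg.SimulationConfig(terminal=synth_terminal,
                                  protocol=pg.FiringProtocol(42, 0.8, 1.0, 4),
                                  initial_state=rest_state)
        res = pg.simulate(cfg)
        adenine = res.states[:, :3].sum(axis=1)
        np.testing.assert_allclose(adenine, adenine[0], rtol=1e-10)
        total_p = (3 * res.states[:, 0] + 2 * res.states[:, 1]
                   + res.states[:, 2] + res.states[:, 4] + res.states[:, 5])
        np.testing.assert_allclose(total_p, total_p[0], rtol=1e-10)
        guanidino = res.states[:, 3] + res.states[:, 4]
        np.testing.assert_allclose(guanidino, guanidino[0], rtol=1e-10)

    def test_dt_halving_changes_atp_below_point_one_percent(self, synth_terminal,
                                                            rest_state):
        proto = pg.FiringProtocol(42, 0.8, 1.0, 3)
        base = pg.SimulationConfig(terminal=synth_terminal, protocol=proto,
                                   initial_state=rest_state, t_end=3.0,
                                   dt=1e-4, record_stride=1000)
        halved = replace(base, dt=5e-5, record_stride=2000)
        a, b = pg.simulate(base), pg.simulate(halved)
        rel = np.abs(a.atp - b.atp) / b.atp
        assert rel.max() < 1e-3

    def test_first_order_dt_convergence(self, synth_terminal, rest_state,
                                        short_protocol):
        def run(dt, stride):
            cfg = pg.SimulationConfig(terminal=synth_terminal,
                                      protocol=short_protocol,
                                      initial_state=rest_state, t_end=2.0,
                                      dt=dt, record_stride=stride)
            return pg.simulate(cfg).atp

        ref = run(1.25e-4, 800)
        e1 = np.abs(run(1e-3, 100) - ref).max()
        e2 = np.abs(run(5e-4, 200) - ref).max()
        # Richardson: first-order splitting -> error ratio ~2 (the finite
        # reference biases it slightly above)
        assert 1.5 < e1 / e2 < 4.0

    def test_t_end_must_cover_protocol(self, synth_terminal, rest_state):
        cfg = pg.SimulationConfig(terminal=synth_terminal,
                                  protocol=pg.FiringProtocol(42, 0.8, 1.0, 4),
                                  initial_state=rest_state, t_end=1.0)
        with pytest.raises(pg.InvalidParameterError):
            pg.simulate(cfg)


@pytest.fixture(scope="module")
def paired(synth_terminal, rest_state):
    cfg = pg.SimulationConfig(terminal=synth_terminal,
                              protocol=pg.FiringProtocol(42, 0.8, 1.0, 6),
                              initial_state=rest_state)
    return pg.compare_phosphagen(cfg)


class TestPhosphagenContrast:

    def test_volatility_increases_without_phosphagen(self, paired):
        on, off = paired
        v_on, v_off = on.volatility(on.atp), off.volatility(off.atp)
        assert v_off.mean_ptp > v_on.mean_ptp
        assert v_off.detrended_std > v_on.detrended_std
        assert np.all(v_off.per_cycle_ptp > v_on.per_cycle_ptp)

    def test_atp_adp_minimum_deeper_without_phosphagen(self, paired):
        on, off = paired
        assert on.atp_adp_ratio.min() > off.atp_adp_ratio.min()

    def test_average_atp_similar(self, paired):
        on, off = paired
        assert off.atp.mean() == pytest.approx(on.atp.mean(), rel=0.01)

    def test_free_energy_draws_down_more_without_phosphagen(self, paired):
        on, off = paired
        assert np.abs(off.free_energy).min() < np.abs(on.free_energy).min()


class TestProductionCapEffect:
    def test_higher_cap_weakly_increases_atp_pointwise(self, synth_terminal,
                                                       rest_state):
        proto = pg.FiringProtocol(42, 0.8, 1.0, 4)
        lo = replace(synth_terminal, max_rate_per_density=0.079)
        hi = replace(synth_terminal, max_rate_per_density=0.154)
        r_lo = pg.simulate(pg.SimulationConfig(terminal=lo, protocol=proto,
                                               initial_state=rest_state))
        r_hi = pg.simulate(pg.SimulationConfig(terminal=hi, protocol=proto,
                                               initial_state=rest_state))
        assert np.all(r_hi.atp - r_lo.atp >= -1e-12)


class TestVolatilitySummary:
    def test_constant_series(self):
        t = np.linspace(0, 10, 1001)
        v = pg.volatility(t, np.full_like(t, 2.0), full_cycle=1.0)
        assert v.mean_ptp == 0.0
        assert v.detrended_std == pytest.approx(0.0, abs=1e-12)

    def test_sinusoid_peak_to_trough(self):
        t = np.linspace(0, 10, 10_001)
        a = 0.7
        v = pg.volatility(t, a * np.sin(2 * np.pi * t), full_cycle=1.0)
        assert v.per_cycle_ptp.size == 10
        np.testing.assert_allclose(v.per_cycle_ptp, 2 * a, rtol=1e-4)


class TestCountActionPotentials:
    @pytest.mark.parametrize("protocols, expected", [
        (pg.FiringProtocol(50, 2.0, 4.0, 60), 6060),
        (pg.FiringProtocol(42, 0.8, 1.0, 240), 8160),
        (pg.FiringProtocol(5, 0.0, 1.0, 5), 5),
        ([pg.FiringProtocol(42, 0.8, 1.0, 240),
          pg.FiringProtocol(50, 2.0, 4.0, 60)], 14220),
    ])
    def test_counts(self, protocols, expected):
        assert pg.count_action_potentials(protocols) == expected


class TestOutputs:
    def test_csv_and_metadata(self, tmp_path, synth_terminal, rest_state):
        cfg = pg.SimulationConfig(terminal=synth_terminal,
                                  protocol=pg.FiringProtocol(10, 0.5, 1.0, 1),
                                  initial_state=rest_state, t_end=1.0, dt=1e-3)
        res = pg.simulate(cfg)
        csv, meta = tmp_path / "run.csv", tmp_path / "run.json"
        res.to_csv(csv, metadata_path=meta)
        import pandas as pd
        df = pd.read_csv(csv)
        from phosphagen.simulate import CSV_COLUMNS
        assert list(df.columns) == CSV_COLUMNS
        assert len(df) == res.time.size
        doc = json.loads(meta.read_text())
        assert doc["terminal"]["name"] == synth_terminal.name
        assert doc["protocol"]["rate_hz"] == 10
        assert "sign_convention" in doc

    def test_derived_series_shapes_and_signs(self, synth_terminal, rest_state):
        cfg = pg.SimulationConfig(terminal=synth_terminal,
                                  protocol=pg.FiringProtocol(10, 0.5, 1.0, 1),
                                  initial_state=rest_state, t_end=1.0, dt=1e-3)
        res = pg.simulate(cfg)
        n = res.time.size
        assert res.es.shape == (n,)
        assert res.atp_adp_ratio.shape == (n,)
        assert res.production_acceleration.shape == (n,)
        assert np.all(res.free_energy < 0)
        assert np.all(res.es > 0)
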